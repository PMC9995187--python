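"""Deterministic seed derivation for per-stage random substreams."""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(master: int, *tokens: object) -> int:
    """Derive a stable sub-seed (< 2^31) from a master seed and tokens.

    The same ``(master, tokens)`` always yields the same sub-seed, so pipeline
    stages can be re-run in isolation without replaying the global stream.
    """
    label = zlib.crc32("/".join(str(t) for t in tokens).encode())
    state = np.random.SeedSequence([int(master), int(label)]).generate_state(1)[0]
    return int(state % (2**31))
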