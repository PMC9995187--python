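"""The three oversampling schemes and their moment contracts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppi_flutter.augmentation import (
    AugmentationConfig,
    augment_cohort,
    augment_series,
    bootstrap_draws,
    interpolated_draws,
    interpolation_variance_ratio,
    modified_smote_sample,
    silverman_bandwidth,
    smote_sample,
    smoothed_bootstrap_sample,
    solve_variance_coefficient,
)
from ppi_flutter.interval_data import (
    Cohort,
    IntervalSeries,
    Mechanism,
    Provenance,
    Technique,
    ValidationError,
)
from ppi_flutter.simulate import CohortSpec, generate_cohort

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)
interval = st.floats(min_value=1.0, max_value=300.0, allow_nan=False)


class TestElementarySamplers:
    def test_smote_interpolates_on_the_segment(self):
        assert smote_sample(180, 200, 0.5) == 190
        assert smote_sample(180, 200, 0.0) == 180
        assert smote_sample(180, 200, 1.0) == 200

    def test_modified_smote_extrapolates_by_half_the_segment(self):
        assert modified_smote_sample(180, 200, 0.5) == 195
        assert modified_smote_sample(180, 200, 1.0) == 210

    @pytest.mark.parametrize("alpha", [-0.1, 1.1, np.nan])
    def test_alpha_outside_unit_interval_rejected(self, alpha):
        with pytest.raises(ValidationError):
            smote_sample(180, 200, alpha)
        with pytest.raises(ValidationError):
            modified_smote_sample(180, 200, alpha)

    @given(anchor=interval, neighbor=interval, alpha=unit)
    def test_smote_draw_lies_between_anchor_and_neighbor(self, anchor, neighbor, alpha):
        s = smote_sample(anchor, neighbor, alpha)
        assert min(anchor, neighbor) - 1e-9 <= s <= max(anchor, neighbor) + 1e-9

    def test_smoothed_bootstrap_degenerates_to_classic_bootstrap(self):
        rng = np.random.default_rng(0)
        data = [200.0] * 8
        assert all(
            smoothed_bootstrap_sample(data, 0.0, rng) == 200.0 for _ in range(20)
        )
        with pytest.raises(ValidationError):
            smoothed_bootstrap_sample([], 1.0, rng)


class TestVarianceCoefficient:
    def test_closed_form_is_three_halves(self):
        assert solve_variance_coefficient() == 1.5

    def test_numeric_root_agrees_with_closed_form(self):
        assert abs(solve_variance_coefficient("numeric") - 1.5) <= 1e-12

    def test_uncorrected_coefficient_shrinks_variance_to_two_thirds(self):
        assert interpolation_variance_ratio(1.0) == pytest.approx(2 / 3, abs=1e-15)


@pytest.fixture(scope="module")
def pool():
    return np.random.default_rng(10).normal(220.0, 15.0, 5000)


class TestMomentContracts:
    """Monte-Carlo checks of the closed-form mean/variance contracts."""

    def test_smote_shrinks_variance_by_two_thirds(self, pool):
        draws = interpolated_draws(pool, 50000, np.random.default_rng(11), 1.0)
        ratio = draws.var(ddof=1) / pool.var(ddof=1)
        assert ratio == pytest.approx(2 / 3, abs=0.03)
        assert draws.mean() == pytest.approx(pool.mean(), abs=0.5)

    def test_modified_smote_restores_variance(self, pool):
        c = solve_variance_coefficient()
        draws = interpolated_draws(pool, 50000, np.random.default_rng(12), c)
        ratio = draws.var(ddof=1) / pool.var(ddof=1)
        assert ratio == pytest.approx(1.0, abs=0.03)
        assert draws.mean() == pytest.approx(pool.mean(), abs=0.5)

    def test_smoothed_bootstrap_variance_inflated_by_bandwidth_squared(self, pool):
        h = 8.0
        draws = bootstrap_draws(pool, 50000, h, np.random.default_rng(13))
        assert draws.var(ddof=1) == pytest.approx(pool.var(ddof=1) + h * h, rel=0.05)
        assert draws.mean() == pytest.approx(pool.mean(), abs=0.5)

    def test_silverman_bandwidth_scale(self):
        x = np.random.default_rng(1).normal(0, 10, 400)
        h = silverman_bandwidth(x)
        # 0.9 * min(sd, iqr/1.34) * n^(-1/5), computed independently
        sd = np.std(x, ddof=1)
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        assert h == pytest.approx(0.9 * min(sd, iqr / 1.34) * 400 ** (-0.2))


class TestAugmentSeries:
    def cfg(self, technique, **kw):
        return AugmentationConfig(technique=technique, rate_percent=100, **kw)

    @pytest.mark.parametrize(
        "technique",
        [Technique.SMOTE, Technique.MODIFIED_SMOTE, Technique.SMOOTHED_BOOTSTRAP],
    )
    def test_matches_source_length_and_sets_metadata(self, fafl_series, technique):
        out = augment_series(fafl_series, self.cfg(technique), np.random.default_rng(0))
        assert len(out) == len(fafl_series)
        assert out.provenance is Provenance.SYNTHETIC
        assert out.technique is technique
        assert out.source_record_id == fafl_series.record_id

    def test_same_seed_reproduces_identical_series(self, fafl_series):
        cfg = self.cfg(Technique.MODIFIED_SMOTE)
        a = augment_series(fafl_series, cfg, np.random.default_rng(5))
        b = augment_series(fafl_series, cfg, np.random.default_rng(5))
        assert a == b

    def test_bootstrap_on_constant_series_stays_constant(self):
        const = IntervalSeries("C1", Mechanism.FAFL, [220.0] * 10)
        cfg = self.cfg(
            Technique.SMOOTHED_BOOTSTRAP, kernel_bandwidth_rule="fixed", fixed_bandwidth=0.0
        )
        out = augment_series(const, cfg, np.random.default_rng(2))
        assert np.all(out.intervals == 220.0)

    def test_too_short_source_names_the_record(self):
        short = IntervalSeries("TINY", Mechanism.FAFL, [200.0])
        with pytest.raises(ValidationError, match="TINY"):
            augment_series(short, self.cfg(Technique.SMOTE), np.random.default_rng(0))

    def test_redraw_policy_keeps_values_in_range(self):
        # anchors near the ceiling force modified-SMOTE above 300 ms regularly
        src = IntervalSeries("E1", Mechanism.FAFL, [280.0, 299.0, 260.0, 295.0])
        cfg = self.cfg(Technique.MODIFIED_SMOTE, bounds_policy="redraw")
        out = augment_series(src, cfg, np.random.default_rng(3))
        assert np.all((out.intervals > 0) & (out.intervals <= 300))


class TestAugmentCohort:
    def test_rate_200_on_five_minority_records_adds_ten_series(self):
        cohort = generate_cohort(CohortSpec(seed=4))
        cfg = AugmentationConfig(Technique.SMOTE, rate_percent=200, seed=1)
        out = augment_cohort(cohort, cfg)
        assert len(out.synthetics()) == 10
        assert len(out) == len(cohort) + 10

    def test_rate_800_makes_minority_nine_times_original(self):
        cohort = generate_cohort(CohortSpec(seed=4))
        cfg = AugmentationConfig(Technique.MODIFIED_SMOTE, rate_percent=800, seed=1)
        out = augment_cohort(cohort, cfg)
        fafl = [s for s in out if s.mechanism is Mechanism.FAFL]
        assert len(fafl) == 9 * 5
        counts = out.class_counts()
        assert counts[Mechanism.FAFL] == counts[Mechanism.MAFL] + 4  # 45 vs 41

    def test_rate_zero_returns_cohort_unchanged(self, small_cohort):
        cfg = AugmentationConfig(Technique.SMOTE, rate_percent=0, seed=1)
        assert augment_cohort(small_cohort, cfg) is small_cohort

    def test_originals_untouched_and_order_preserved(self, small_cohort):
        cfg = AugmentationConfig(Technique.SMOOTHED_BOOTSTRAP, rate_percent=300, seed=9)
        out = augment_cohort(small_cohort, cfg)
        assert list(out.series[: len(small_cohort)]) == list(small_cohort.series)
        assert all(s.mechanism is Mechanism.FAFL for s in out.synthetics())

    def test_bit_identical_reproducibility(self, small_cohort):
        cfg = AugmentationConfig(Technique.MODIFIED_SMOTE, rate_percent=400, seed=77)
        a = augment_cohort(small_cohort, cfg)
        b = augment_cohort(small_cohort, cfg)
        assert list(a.series) == list(b.series)

    def test_non_multiple_of_100_rate_rejected(self):
        with pytest.raises(ValidationError, match="multiple of 100"):
            AugmentationConfig(Technique.SMOTE, rate_percent=150)

    def test_pooled_neighbor_mode_is_deterministic_and_labels_sources(self, small_cohort):
        cfg = AugmentationConfig(
            Technique.SMOTE, rate_percent=200, seed=5, pooled_neighbors=True
        )
        a = augment_cohort(small_cohort, cfg)
        b = augment_cohort(small_cohort, cfg)
        assert list(a.synthetics()) == list(b.synthetics())
        sources = {s.source_record_id for s in a.synthetics()}
        assert sources == {"F00", "F01"}
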