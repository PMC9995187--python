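"""The four-test battery comparing augmented to original minority data."""

import numpy as np
import pytest

from ppi_flutter.interval_data import ValidationError
from ppi_flutter.simulate import CohortSpec, generate_cohort
from ppi_flutter.validation import (
    cdf_max_abs_diff,
    empirical_cdf,
    ks_similarity,
    moment_percent_differences,
    quartile_differences,
    rank_techniques,
    validate_augmentation,
)


class TestEmpiricalCDF:
    def test_constant_data_is_a_single_bin_reaching_one(self):
        cdf = empirical_cdf([100.0] * 10, bin_width=5)
        assert cdf.fractions[-1] == 1.0
        assert len(cdf.edges) == 1

    def test_two_points_straddling_a_bin_edge(self):
        cdf = empirical_cdf([95.0, 105.0], bin_width=5)
        assert cdf.fractions[0] == 0.5
        assert cdf.fractions[-1] == 1.0
        assert np.all(np.diff(cdf.fractions) >= 0)

    def test_cdf_compared_with_itself_has_zero_max_diff(self):
        data = [96.0, 101.0, 103.0, 140.0]
        assert cdf_max_abs_diff(data, data) == 0.0

    def test_empty_data_rejected(self):
        with pytest.raises(ValidationError):
            empirical_cdf([])


class TestQuartileDifferences:
    def test_identical_datasets_give_zero(self):
        data = [1.0, 2.0, 5.0, 9.0]
        assert np.all(quartile_differences(data, data) == 0)

    def test_translation_shifts_every_quartile_equally(self):
        data = np.array([180.0, 190.0, 200.0, 215.0, 230.0])
        assert np.allclose(quartile_differences(data, data + 2.0), [2, 2, 2])

    def test_matches_brute_force_order_statistic_interpolation(self):
        # independent oracle: quantile by linear interpolation of sorted values
        def brute_quantile(x, q):
            s = sorted(x)
            pos = q * (len(s) - 1)
            lo = int(np.floor(pos))
            hi = min(lo + 1, len(s) - 1)
            return s[lo] + (pos - lo) * (s[hi] - s[lo])

        a = [201.5, 188.0, 230.0, 196.0, 210.0, 207.5, 215.0, 199.0]
        b = [205.0, 190.0, 220.0, 200.0, 214.0, 203.0, 226.0, 198.5]
        expected = [abs(brute_quantile(a, q) - brute_quantile(b, q)) for q in (0.25, 0.5, 0.75)]
        assert np.allclose(quartile_differences(a, b), expected)


class TestKSSimilarity:
    def test_identical_replicates_have_p_one(self):
        data = list(np.linspace(180, 260, 40))
        res = ks_similarity(data, [data, data])
        assert res.mean_p == pytest.approx(1.0, abs=1e-9)
        assert res.sd_p == pytest.approx(0.0, abs=1e-9)

    def test_well_separated_distributions_have_tiny_p(self):
        rng = np.random.default_rng(6)
        orig = rng.normal(200, 10, 200)
        reps = [rng.normal(260, 10, 200) for _ in range(5)]
        res = ks_similarity(orig, reps)
        assert res.mean_p < 0.01

    def test_statistic_agrees_with_brute_force_cdf_sweep(self):
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(3)
        a, b = rng.normal(200, 10, 150), rng.normal(203, 11, 180)
        grid = np.concatenate([a, b])
        d_brute = max(
            abs(
                np.searchsorted(np.sort(a), v, side="right") / a.size
                - np.searchsorted(np.sort(b), v, side="right") / b.size
            )
            for v in grid
        )
        assert ks_2samp(a, b, method="asymp").statistic == pytest.approx(d_brute)

    def test_short_replicates_skipped_with_warning(self):
        data = list(np.linspace(180, 260, 30))
        with pytest.warns(UserWarning, match="< 2 points"):
            res = ks_similarity(data, [data, [200.0]])
        assert res.n_used == 1 and res.n_skipped == 1


class TestMomentDifferences:
    def test_identical_datasets_give_zero_percent(self):
        data = [180.0, 200.0, 210.0, 222.0, 199.0, 250.0]
        d = moment_percent_differences(data, data)
        assert (d.mean_pct, d.variance_pct, d.skewness_pct) == (0.0, 0.0, 0.0)

    def test_two_thirds_variance_shows_minus_one_third(self):
        rng = np.random.default_rng(8)
        orig = rng.normal(200, 12, 4000)
        shrunk = orig.mean() + np.sqrt(2 / 3) * (orig - orig.mean())
        d = moment_percent_differences(orig, shrunk)
        assert d.variance_pct == pytest.approx(-100 / 3, abs=0.5)
        assert d.mean_pct == pytest.approx(0.0, abs=1e-9)

    def test_matches_hand_computed_sample_moments(self):
        a = [2.0, 4.0, 4.0, 4.0, 5.0, 11.0]
        b = [1.0, 3.0, 5.0, 5.0, 7.0, 9.0]

        def moments(x):
            n = len(x)
            m = sum(x) / n
            var = sum((v - m) ** 2 for v in x) / (n - 1)
            m2 = sum((v - m) ** 2 for v in x) / n
            m3 = sum((v - m) ** 3 for v in x) / n
            g1 = m3 / m2**1.5
            skew = np.sqrt(n * (n - 1)) / (n - 2) * g1  # adjusted Fisher-Pearson
            return m, var, skew

        (ma, va, sa), (mb, vb, sb) = moments(a), moments(b)
        d = moment_percent_differences(a, b)
        assert d.mean_pct == pytest.approx(100 * (mb - ma) / ma)
        assert d.variance_pct == pytest.approx(100 * (vb - va) / va)
        assert d.skewness_pct == pytest.approx(100 * (sb - sa) / sa)

    def test_zero_original_moment_falls_back_to_absolute_difference(self):
        a = [-1.0, 0.0, 1.0]  # mean and skewness are exactly zero
        b = [0.0, 1.0, 2.0]
        with pytest.raises(ValidationError):
            moment_percent_differences([], b)
        d = moment_percent_differences(a, b)
        assert "mean" in d.absolute_fallback
        assert d.mean_pct == pytest.approx(1.0)  # absolute, not percent


class TestRankTechniques:
    table_dominant = {
        "cdf": {"A": 0.01, "B": 0.05, "C": 0.2},
        "ks": {"A": 0.9, "B": 0.5, "C": 0.1},
    }

    def test_dominating_technique_ranks_first_everywhere(self):
        ranks = rank_techniques(self.table_dominant)
        assert all(ranks["A"] == 1)
        assert all(ranks["C"] == 3)

    def test_ties_share_the_better_rank(self):
        ranks = rank_techniques({"cdf": {"A": 0.1, "B": 0.1, "C": 0.4}})
        assert list(ranks.loc["cdf", ["A", "B", "C"]]) == [1, 1, 3]

    def test_agrees_with_exhaustive_pairwise_oracle(self):
        table = {
            "cdf": {"A": 0.03, "B": 0.01, "C": 0.07},
            "quartiles": {"A": 1.5, "B": 2.0, "C": 0.5},
            "ks": {"A": 0.6, "B": 0.8, "C": 0.2},
        }
        ranks = rank_techniques(table)
        for crit, row in table.items():
            better = {"ks": (lambda u, t: row[u] > row[t])}.get(
                crit, lambda u, t: row[u] < row[t]
            )
            for t in row:
                expected = 1 + sum(better(u, t) for u in row)
                assert ranks.loc[crit, t] == expected

    def test_missing_criterion_entry_rejected(self):
        with pytest.raises(ValidationError, match="missing"):
            rank_techniques({"cdf": {"A": 1.0, "B": 2.0}, "ks": {"A": 1, "B": 2, "C": 3}})


@pytest.fixture(scope="module")
def report():
    cohort = generate_cohort(CohortSpec(seed=42))
    return validate_augmentation(cohort, rate_percent=400, n_replicates=30, seed=11)


class TestBattery:
    def test_ranks_are_permutations_per_criterion(self, report):
        for _, row in report.ranks.iterrows():
            assert sorted(row) == [1, 2, 3]

    def test_ks_pvalues_in_unit_interval(self, report):
        for ks in report.ks.values():
            assert 0.0 <= ks.mean_p <= 1.0

    def test_modified_smote_never_worst_at_rate_400(self, report):
        """Seeded regression: the variance-corrected sampler is never rank 3."""
        assert report.ranks["modified_smote"].max() <= 2

    def test_modified_smote_more_similar_than_classic_by_ks(self, report):
        assert report.ks["modified_smote"].mean_p > report.ks["smote"].mean_p
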