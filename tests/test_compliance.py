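import numpy as np
import pytest
from scipy import stats

import rollmetrics as rm
from rollmetrics.compliance import (
    R2Matrix,
    friedman_test,
    kendalls_w,
    outlier_flags,
    pairwise_r2,
    participant_medians,
    rank_table,
)
from rollmetrics.sections import AlignedRun

from cohort_tables import COHORT_MEDIANS, COHORT_RANKS


def _runs_from_profiles(profiles):
    grid = np.arange(len(profiles[0])) + 0.5
    sec = np.ones(grid.size, dtype=int)
    return [
        AlignedRun(dist=grid, v=np.asarray(p, float), copx=np.zeros(grid.size),
                   copy_=np.zeros(grid.size), section=sec, participant_id=f"P{i+1}")
        for i, p in enumerate(profiles)
    ]


class TestPairwiseR2:
    def test_affine_relation_gives_unit_r2(self, rng):
        base = rng.normal(1.2, 0.3, 500)
        runs = _runs_from_profiles([base, base + 0.5, 2.0 * base - 1.0])
        m = pairwise_r2(runs, "v")
        np.testing.assert_allclose(m.values, 1.0, atol=1e-12)

    def test_symmetry_and_unit_diagonal_always(self, rng):
        for _ in range(20):
            runs = _runs_from_profiles(rng.normal(0, 1, (5, 200)))
            m = pairwise_r2(runs, "v").values
            np.testing.assert_array_equal(m, m.T)
            np.testing.assert_allclose(np.diag(m), 1.0)
            assert np.nanmin(m) >= 0.0 and np.nanmax(m) <= 1.0

    def test_independent_profiles_are_uncorrelated(self):
        """Two fully individualistic participants share nothing: pairwise
        speed R^2 stays below 0.1 (20 seed pairs, full-course runs)."""
        profiles = [
            rm.ParticipantProfile("A", compliance_lambda=0.0, noise_seed=0),
            rm.ParticipantProfile("B", compliance_lambda=0.0, noise_seed=1),
        ]
        for seed in range(20):
            runs = rm.simulate_aligned_profiles(profiles=profiles, seed=seed)
            r2 = pairwise_r2(runs, "v").values[0, 1]
            assert r2 < 0.1

    def test_constant_profile_flagged_nan(self, rng):
        runs = _runs_from_profiles([np.ones(100), rng.normal(0, 1, 100), rng.normal(0, 1, 100)])
        m = pairwise_r2(runs, "v").values
        assert np.isnan(m[0, 1]) and np.isnan(m[1, 0])
        assert np.isfinite(m[1, 2])

    def test_mismatched_grids_rejected(self, rng):
        a = _runs_from_profiles(rng.normal(0, 1, (2, 100)))
        b = _runs_from_profiles(rng.normal(0, 1, (1, 50)))
        with pytest.raises(ValueError, match="grid"):
            pairwise_r2([a[0], b[0]], "v")


class TestParticipantMedians:
    def test_hand_computed_median_and_iqr(self):
        vals = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        m = np.eye(7)
        m[0, 1:] = m[1:, 0] = np.concatenate([vals])
        mat = R2Matrix("v", tuple("ABCDEFG"), m)
        med, iqr = participant_medians(mat)
        assert med[0] == pytest.approx(0.35)
        # linear-interpolation quartiles of 6 values: Q1=0.225, Q3=0.475
        assert iqr[0] == pytest.approx(0.25)

    def test_equal_values_zero_iqr(self):
        m = np.full((4, 4), 0.3)
        np.fill_diagonal(m, 1.0)
        med, iqr = participant_medians(R2Matrix("v", tuple("ABCD"), m))
        np.testing.assert_allclose(med, 0.3)
        np.testing.assert_allclose(iqr, 0.0)


class TestOutlierRule:
    def test_low_outlier_flagged(self):
        # mirrors the cohort case: one participant well below the rest
        vals = np.array([0.44, 0.45, 0.46, 0.47, 0.49, 0.50, 0.31])
        flags = outlier_flags(vals)
        assert flags[-1]
        assert flags.sum() == 1
        # brute-force check of the rule itself
        q1, q3 = np.percentile(vals, [25, 75])
        np.testing.assert_array_equal(flags, vals < q1 - 1.5 * (q3 - q1))

    def test_identical_values_no_flags(self):
        assert not outlier_flags(np.full(7, 0.4)).any()

    def test_monotone_spread_without_gap_no_flags(self):
        assert not outlier_flags(np.linspace(0.3, 0.5, 7)).any()


class TestRankTable:
    def test_reproduces_cohort_rank_table(self):
        ranks, sums = rank_table(COHORT_MEDIANS)
        np.testing.assert_array_equal(ranks, COHORT_RANKS)
        np.testing.assert_array_equal(sums, [9, 10, 7, 8, 21, 18, 11])
        assert sums[4] == 21  # most route-driven participant
        assert sums[2] == 7   # most individualistic participant

    def test_rank_sums_total(self, rng):
        m = rng.normal(0, 1, (7, 3))
        _, sums = rank_table(m)
        assert sums.sum() == 3 * 7 * 8 / 2

    def test_identical_columns_and_reversal(self):
        col = np.array([0.3, 0.1, 0.5, 0.2])
        ranks, sums = rank_table(np.column_stack([col, col, col]))
        np.testing.assert_array_equal(sums, 3 * stats.rankdata(col))
        rev, _ = rank_table(np.column_stack([-col]))
        np.testing.assert_array_equal(rev[:, 0], 5 - stats.rankdata(col))


class TestKendallsW:
    def test_identical_rankings(self):
        r = np.tile(np.arange(1, 8)[:, None], (1, 3))
        w, chi2, p = kendalls_w(r)
        assert w == pytest.approx(1.0)
        assert chi2 == pytest.approx(3 * 6)

    def test_reversed_rankings_cancel(self):
        r = np.column_stack([np.arange(1, 6), np.arange(5, 0, -1)])
        w, _, _ = kendalls_w(r)
        assert w == pytest.approx(0.0)

    def test_cohort_rank_table_concordance(self):
        # S = 172, denominator m^2(n^3-n) = 9*336 = 3024 -> W = 0.6825
        w, chi2, p = kendalls_w(COHORT_RANKS)
        assert w == pytest.approx(172 * 12 / 3024, abs=1e-12)
        assert w == pytest.approx(0.683, abs=5e-4)
        assert chi2 == pytest.approx(3 * 6 * w)

    def test_relabelling_invariance(self, rng):
        r = np.column_stack([rng.permutation(6) + 1 for _ in range(3)])
        w0, _, _ = kendalls_w(r)
        perm = rng.permutation(6)
        w1, _, _ = kendalls_w(r[perm])
        assert w1 == pytest.approx(w0, abs=1e-12)

    def test_two_algebraic_forms_agree(self, rng):
        # deviation form vs sum-of-squares form: 12*sum(R_i^2) - 3 m^2 n (n+1)^2
        r = np.column_stack([rng.permutation(7) + 1 for _ in range(3)])
        n, m = r.shape
        w, _, _ = kendalls_w(r)
        ri = r.sum(axis=1)
        w_alt = (12 * np.sum(ri**2) - 3 * m**2 * n * (n + 1) ** 2) / (m**2 * (n**3 - n))
        assert w == pytest.approx(w_alt, abs=1e-12)

    def test_friedman_chisq_relation_against_scipy(self, rng):
        """chi2 = m(n-1)W equals the Friedman statistic computed by scipy
        with judges as blocks and items as treatments (independent oracle
        for the concordance computation)."""
        data = rng.normal(0, 1, (3, 7))  # 3 judges x 7 items, no ties
        ranks = np.column_stack([stats.rankdata(data[j]) for j in range(3)])
        _, chi2, p = kendalls_w(ranks)
        ref = stats.friedmanchisquare(*(data[:, i] for i in range(7)))
        assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_single_item(self):
        with pytest.raises(ValueError):
            kendalls_w(np.ones((1, 3)))


class TestFriedman:
    def test_identical_columns_min_statistic(self):
        x = np.tile(np.arange(10.0)[:, None], (1, 3))
        chi2, p = friedman_test(x)
        assert p == pytest.approx(1.0)

    def test_strong_ordering_detected(self, rng):
        x = rng.normal(0, 1, (20, 3)) + np.array([0.0, 2.0, 4.0])
        chi2, p = friedman_test(x)
        assert p < 0.01

    def test_matches_scipy_oracle(self, rng):
        x = rng.normal(0, 1, (15, 4))
        chi2, p = friedman_test(x)
        ref = stats.friedmanchisquare(*x.T)
        assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_two_conditions_agrees_with_sign_test(self, rng):
        x = rng.normal(0, 1, (15, 2))
        x[:, 1] += 0.8
        _, p = friedman_test(x)
        wins = int(np.sum(x[:, 1] > x[:, 0]))
        p_sign = stats.binomtest(wins, 15, 0.5).pvalue
        assert abs(p - p_sign) < 0.05
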