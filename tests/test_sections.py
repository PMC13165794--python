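import numpy as np
import pytest
from scipy import stats

import rollmetrics as rm
from rollmetrics.sections import (
    AlignedRun,
    SectionComparison,
    assign_sections,
    cohens_d,
    compare_sections,
    effect_network,
    make_distance_grid,
    section_summary,
    studentized_range_sf,
    synchorise,
)


def _aligned(v, section, dist=None, copx=None, copy_=None):
    v = np.asarray(v, dtype=float)
    if dist is None:
        dist = np.arange(v.size) + 0.5
    if copx is None:
        copx = np.zeros_like(v)
    if copy_ is None:
        copy_ = np.zeros_like(v)
    return AlignedRun(dist=dist, v=v, copx=copx, copy_=copy_,
                      section=np.asarray(section, dtype=int))


class TestSynchorise:
    def test_constant_speed_over_course(self, course):
        grid = make_distance_grid(course.total_length, 1.0)
        assert grid.size == 789
        t = np.arange(0, 789, 0.5)
        dist = t * 1.0
        v = np.full_like(t, 1.0)
        out = synchorise(dist, v, grid)
        np.testing.assert_allclose(out, 1.0)

    def test_noise_free_simulation_matches_truth_on_grid(self, noise_free_run, course):
        truth = noise_free_run.truth
        grid = make_distance_grid(course.total_length, 1.0)
        out = synchorise(truth["dist_m"].to_numpy(), truth["v_mps"].to_numpy(), grid)
        expected = course.means("v")[assign_sections(grid, course.boundaries) - 1]
        np.testing.assert_allclose(out, expected, rtol=1e-6)

    def test_decreasing_distance_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            synchorise(np.array([0.0, 2.0, 1.0]), np.zeros(3), np.array([0.5]))

    def test_smoothing_window_applies_moving_average(self):
        grid = make_distance_grid(10, 1.0)
        dist = np.arange(0, 11.0)
        x = np.zeros(11)
        x[5] = 10.0
        raw = synchorise(dist, x, grid)
        smooth = synchorise(dist, x, grid, smooth_m=4.0)
        assert smooth.max() < raw.max()
        assert np.sum(smooth) == pytest.approx(np.sum(raw))


class TestAssignSections:
    def test_half_open_intervals(self, course):
        b = course.boundaries
        assert assign_sections(np.array([500.0]), b)[0] == 8  # 481 <= 500 < 521
        assert assign_sections(np.array([0.0]), b)[0] == 1
        assert assign_sections(np.array([789.0]), b)[0] == 13  # closed end
        assert assign_sections(np.array([47.0]), b)[0] == 2

    def test_overflow_flagged(self, course):
        ids = assign_sections(np.array([789.4, 790.0]), course.boundaries, tolerance=0.5)
        assert ids[0] == 13
        assert ids[1] == 0

    def test_partition_counts_sum_to_grid_length(self, course):
        grid = make_distance_grid(course.total_length, 1.0)
        ids = assign_sections(grid, course.boundaries)
        assert np.sum(ids > 0) == grid.size
        counts = np.bincount(ids, minlength=14)[1:]
        np.testing.assert_array_equal(counts, np.diff(course.boundaries).astype(int))


class TestSectionSummary:
    def test_constant_signal_zero_sd(self):
        run = _aligned(np.ones(20), [1] * 10 + [2] * 10)
        tab = section_summary(run)
        np.testing.assert_allclose(tab["v_sd"], 0.0)
        np.testing.assert_allclose(tab["v_mean"], 1.0)

    def test_two_sample_section_mean_is_midpoint(self):
        run = _aligned([1.0, 2.0], [1, 1])
        tab = section_summary(run)
        assert tab["v_mean"].iloc[0] == 1.5

    def test_empty_section_is_named(self):
        run = _aligned(np.ones(10), [1] * 5 + [3] * 5)
        with pytest.raises(ValueError, match=r"\[2\]"):
            section_summary(run)


class TestStudentizedRange:
    @pytest.mark.parametrize(
        "q,k,df", [(2.0, 5, 20), (3.5, 13, 776), (4.5, 13, 50), (3.0, 3, 10)]
    )
    def test_matches_scipy_distribution(self, q, k, df):
        ours = studentized_range_sf(q, k, df)[0]
        ref = stats.studentized_range.sf(q, k, df)
        assert ours == pytest.approx(ref, abs=5e-5)


class TestCompareSections:
    def test_identical_groups_zero_effect(self):
        v = np.tile(np.arange(10.0), 2)
        run = _aligned(v, [1] * 10 + [2] * 10)
        F, p, comps = compare_sections(run, "v")
        assert comps[0].cohens_d == 0.0
        assert not comps[0].significant

    def test_cohens_d_monte_carlo_two_groups(self, rng):
        # planted standardised difference of 1 between two sections
        ds = []
        for _ in range(30):
            a = rng.normal(0.0, 1.0, 100)
            b = rng.normal(1.0, 1.0, 100)
            ds.append(cohens_d(a, b))
        assert np.mean(ds) == pytest.approx(1.0, abs=0.15)

    def test_tukey_pvalues_match_statsmodels_oracle(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        v = np.concatenate([rng.normal(m, 1.0, 25) for m in (0.0, 0.3, 0.8, 1.5)])
        labels = np.repeat([1, 2, 3, 4], 25)
        run = _aligned(v, labels)
        _, _, comps = compare_sections(run, "v")
        ref = pairwise_tukeyhsd(v, labels)
        np.testing.assert_allclose(
            [c.tukey_p for c in comps], np.asarray(ref.pvalues, float), atol=1e-4
        )
        assert [c.significant for c in comps] == list(np.asarray(ref.reject))

    def test_thirteen_sections_give_78_pairs(self, course, rng):
        grid = make_distance_grid(course.total_length, 1.0)
        sec = assign_sections(grid, course.boundaries)
        run = _aligned(rng.normal(1.2, 0.3, grid.size), sec, dist=grid)
        F, p, comps = compare_sections(run, "v")
        assert len(comps) == 78
        assert {c.pair for c in comps} == {
            (i, j) for i in range(1, 14) for j in range(i + 1, 14)
        }

    def test_null_anova_pvalues_uniform(self):
        """Sections drawn from one distribution: the ANOVA p-value must be
        uniform on [0, 1] (KS check over 500 seeds at the 1 % level)."""
        pvals = []
        sec = np.repeat(np.arange(1, 14), 20)
        for seed in range(500):
            v = np.random.default_rng(seed).normal(1.2, 0.3, sec.size)
            F, p, _ = (lambda r: compare_sections(r, "v"))(_aligned(v, sec))
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_zero_variance_unequal_means_flagged_infinite(self):
        run = _aligned([1.0] * 5 + [2.0] * 5, [1] * 5 + [2] * 5)
        _, _, comps = compare_sections(run, "v")
        assert np.isinf(comps[0].cohens_d)


class TestEffectNetwork:
    def _comp(self, d, sig=True, pair=(1, 2)):
        return [SectionComparison(pair=pair, tukey_p=0.01 if sig else 0.5,
                                  cohens_d=d, significant=sig)]

    def test_small_effects_make_no_edge(self):
        edges = effect_network([self._comp(0.5) for _ in range(7)])
        assert edges == []

    def test_huge_effects_cap_at_weight_one(self):
        edges = effect_network([self._comp(2.5) for _ in range(7)])
        assert len(edges) == 1
        assert edges[0].weight == 1.0

    def test_boundary_mean_gives_zero_weight_edge(self):
        edges = effect_network([self._comp(0.6), self._comp(1.0)])
        assert len(edges) == 1
        assert edges[0].mean_d == pytest.approx(0.8)
        assert edges[0].weight == 0.0

    def test_insignificant_pairs_are_filtered(self):
        edges = effect_network([self._comp(1.5, sig=False) for _ in range(7)])
        assert edges == []
        edges = effect_network(
            [self._comp(1.5, sig=False) for _ in range(7)], require_significance=False
        )
        assert len(edges) == 1

    def test_inconsistent_pair_sets_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            effect_network([self._comp(1.0, pair=(1, 2)), self._comp(1.0, pair=(1, 3))])

    def test_edge_count_monotone_in_threshold(self, rng, course):
        grid = make_distance_grid(course.total_length, 1.0)
        sec = assign_sections(grid, course.boundaries)
        runs = rm.simulate_aligned_profiles(course, seed=3)
        comps = [compare_sections(r, "v")[2] for r in runs]
        counts = [
            len(effect_network(comps, d_floor=th)) for th in (0.2, 0.5, 0.8, 1.2, 2.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
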