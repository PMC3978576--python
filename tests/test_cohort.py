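"""Cohort statistics: arithmetic, consensus, tests, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import enthesomorph as em
from enthesomorph.cohort import strength_category, wilcoxon_paired


class TestMuscleContributions:
    def test_printed_table_averages(self):
        # the published total (682) was rounded separately from the
        # component averages, whose own sum is 681
        vm, rf, vi, vl = em.muscle_contributions(152, 78, 204, 247,
                                                 total=682)
        assert round(vm, 1) == 22.3
        assert round(rf, 1) == 11.4
        assert round(vi, 1) == 29.9

    def test_equal_volumes_quarter_each(self):
        assert em.muscle_contributions(10, 10, 10, 10) == (25, 25, 25, 25)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1.0, max_value=500.0), min_size=4,
                    max_size=4))
    def test_components_sum_to_hundred(self, vols):
        assert sum(em.muscle_contributions(*vols)) == pytest.approx(100.0)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            em.muscle_contributions(0, 78, 204, 247)


class TestRatios:
    def test_vl_vm_from_printed_averages(self):
        # 247/152 = 1.625, which prints as 1.63 under round-half-up
        assert abs(em.vl_vm_ratio(247, 152) - 1.63) <= 0.005

    def test_unity_for_equal_volumes(self):
        assert em.vl_vm_ratio(100.0, 100.0) == 1.0

    def test_lateral_medial_from_printed_ba(self):
        assert em.lateral_medial_ratio(0.41, 0.28) == pytest.approx(1.464,
                                                                    abs=5e-4)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            em.vl_vm_ratio(247, 0)
        with pytest.raises(ValueError):
            em.lateral_medial_ratio(0.4, 0.0)


class TestConsensusICRS:
    def test_highest_defect_grade_per_grader(self):
        assert em.consensus_icrs([[1, 3], [3]]) == 3

    def test_agreement_returns_common_grade(self):
        assert em.consensus_icrs([2, 2]) == 2

    def test_third_grader_majority(self):
        assert em.consensus_icrs([2, 3, 3]) == 3
        assert em.consensus_icrs([2, 3, 2]) == 2

    def test_all_three_differ_falls_back_to_median(self):
        assert em.consensus_icrs([1, 3, 2]) == 2

    def test_two_grader_disagreement_midpoint(self):
        assert em.consensus_icrs([2, 3]) == 2.5

    def test_out_of_range_grade_rejected(self):
        with pytest.raises(ValueError):
            em.consensus_icrs([5, 2])


class TestKSNormality:
    def test_large_normal_sample_passes(self):
        hits = 0
        for seed in range(20):
            v = np.random.default_rng(seed).normal(10, 2, 500)
            hits += em.ks_normality(v).is_normal
        assert hits >= 17  # ~95% acceptance under the null

    def test_bimodal_sample_fails(self):
        fails = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            v = np.concatenate([np.zeros(50), np.ones(50)])
            fails += not em.ks_normality(v + rng.normal(0, 0.01, 100)).is_normal
        assert fails == 10

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            em.ks_normality([1.0, 2.0, 3.0, 4.0])

    def test_constant_sample_degenerate(self):
        res = em.ks_normality([2.0] * 10)
        assert res.degenerate and not res.is_normal


def brute_force_signed_rank_p(d):
    """Enumerate all 2^n sign assignments of the rank vector."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [np.sum(ranks[np.array(signs, bool)])
          for signs in itertools.product([0, 1], repeat=n)]
    ws = np.asarray(ws)
    lo = np.mean(ws <= w_obs + 1e-12)
    hi = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2 * min(lo, hi))


class TestWilcoxonPaired:
    def test_identical_pairs_p_one(self):
        with pytest.warns(UserWarning, match="zero"):
            stat, p = em.wilcoxon_paired([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert p == 1.0

    def test_six_pair_toy_matches_enumeration(self):
        x = [1.1, 2.3, 3.1, 4.9, 5.2, 6.7]
        y = [0.9, 2.0, 3.6, 4.0, 4.8, 5.9]
        _, p = em.wilcoxon_paired(x, y)
        assert p == pytest.approx(brute_force_signed_rank_p(
            np.array(x) - np.array(y)), abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_equals_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        d = np.round(rng.normal(0.3, 1.0, n), 1)
        d[d == 0] = 0.1
        _, p = em.wilcoxon_paired(d, np.zeros(n))
        assert p == pytest.approx(brute_force_signed_rank_p(d), abs=1e-12)

    def test_matches_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, 15)
        y = rng.normal(0.5, 1, 15)
        stat, p = em.wilcoxon_paired(x, y)
        ref = stats.wilcoxon(x, y, method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.4, 1, 60)
        _, p = em.wilcoxon_paired(x, np.zeros(60))
        ref = stats.wilcoxon(x, np.zeros(60), correction=False,
                             method="approx")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_too_few_nonzero_differences_rejected(self):
        with pytest.raises(ValueError):
            em.wilcoxon_paired([1, 2, 3, 4], [0, 0, 0, 0])


class TestSpearman:
    def test_monotone_cube_is_perfect(self):
        x = np.arange(1, 11, dtype=float)
        res = em.spearman_strength(x, x ** 3)
        assert res.r == 1.0
        assert res.strength == "very strong"

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12) + 0.5 * x
        base = em.spearman_strength(x, y).r
        assert em.spearman_strength(np.exp(x), y).r == pytest.approx(base)
        assert em.spearman_strength(x, 3 * y + 7).r == pytest.approx(base)

    def test_exact_permutation_p_small_n(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        res = em.spearman_strength(x, y)
        # oracle: full 6! permutation enumeration
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        rhos = [abs(np.corrcoef(rx, np.array(p))[0, 1])
                for p in itertools.permutations(ry)]
        expect = np.mean(np.array(rhos) >= obs - 1e-12)
        assert res.p == pytest.approx(expect, abs=1e-12)

    def test_printed_strength_examples(self):
        assert strength_category(0.65) == "moderate"
        assert strength_category(-0.32) == "fair"
        r = em.spearman_strength(np.arange(5.0), -np.arange(5.0) ** 3)
        assert r.direction == "inverse"

    def test_strength_total_on_grid(self):
        for r in np.linspace(-1, 1, 201):
            assert strength_category(r) in {"very strong", "moderate",
                                            "fair", "weak"}
        assert strength_category(0.80) == "very strong"
        assert strength_category(0.60) == "moderate"
        assert strength_category(0.30) == "fair"
        assert strength_category(0.2999) == "weak"

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            em.spearman_strength(np.ones(8), np.arange(8.0))


class TestBuildTable2:
    def _ratio_frame(self, n, rng=None, comonotone=False):
        rng = rng or np.random.default_rng(0)
        base = rng.normal(size=n)
        cols = {}
        for i, v in enumerate(("vl_vm", "uf_ratio", "cf_ratio", "ba_ratio",
                               "th_ratio", "icrs")):
            cols[v] = np.exp(base) * (i + 1) if comonotone else rng.normal(
                size=n)
        return pd.DataFrame(cols)

    def test_comonotone_records_all_one(self):
        t2 = em.build_table2(self._ratio_frame(30, comonotone=True))
        assert np.allclose(t2.corr.values, 1.0)

    def test_independent_records_near_zero(self):
        t2 = em.build_table2(self._ratio_frame(2000))
        off = t2.corr.values[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_symmetric_unit_diagonal(self):
        t2 = em.build_table2(self._ratio_frame(40))
        assert np.allclose(t2.corr.values, t2.corr.values.T)
        assert np.allclose(np.diag(t2.corr.values), 1.0)

    def test_incomplete_records_listwise_excluded(self):
        df = self._ratio_frame(20)
        df.loc[3, "icrs"] = np.nan
        t2 = em.build_table2(df)
        assert t2.n == 19 and t2.n_excluded == 1

    def test_calibrated_generator_lands_near_target(self):
        spec = em.CohortSpec(n_donors=250, sex_split=(125, 125), seed=1)
        t2 = em.build_table2(em.add_ratios(em.gen_cohort(spec)))
        assert t2.corr.loc["vl_vm", "ba_ratio"] == pytest.approx(0.81,
                                                                 abs=0.05)
        assert t2.strength.loc["vl_vm", "ba_ratio"] == "very strong"


class TestAddRatios:
    def test_ratios_derived_deterministically(self):
        knees = em.gen_cohort(em.CohortSpec(seed=5))
        r = em.add_ratios(knees)
        k = knees.iloc[0]
        assert r.loc[0, "vl_vm"] == pytest.approx(k.vol_vl / k.vol_vm)
        assert r.loc[0, "ba_ratio"] == pytest.approx(
            k.ba_lateral / k.ba_medial)

    def test_donor_unit_averages_two_knees(self):
        knees = em.gen_cohort(em.CohortSpec(seed=5))
        by_knee = em.add_ratios(knees, unit="knee")
        by_donor = em.add_ratios(knees, unit="donor")
        assert len(by_donor) == len(by_knee) // 2
        d0 = by_knee[by_knee.donor_id == "D001"]["vl_vm"].mean()
        assert by_donor.set_index("donor_id").loc["D001", "vl_vm"] == \
            pytest.approx(d0)

    def test_nonpositive_medial_flagged_and_excluded(self):
        knees = em.gen_cohort(em.CohortSpec(seed=6))
        knees.loc[0, "ba_medial"] = 0.0
        with pytest.warns(UserWarning, match="excluded 1"):
            r = em.add_ratios(knees)
        assert len(r) == len(knees) - 1
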