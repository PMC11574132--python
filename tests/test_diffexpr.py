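"""Differential statistics: BH, one-way ANOVA, ANCOVA, Tukey, t-tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.anova import anova_lm

from conftest import bh_brute_force, group_values, make_matrix
from isrdep.containers import GROUPS, DesignError, parse_contrast
from isrdep.diffexpr import (
    ancova_fit,
    bh_adjust,
    feature_ttest,
    log2_fold_change,
    oneway_anova,
    posthoc_pairwise,
)
from isrdep.synthetic import SimulationParams, generate_truth, simulate_intensities


class TestBhAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.01, 0.03, 0.5]), [0.02, 0.02, 0.04, 0.5], atol=1e-12
        )

    def test_ties_share_one_q(self):
        q = bh_adjust(np.full(10, 0.04))
        np.testing.assert_allclose(q, 0.04, atol=1e-12)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123, abs=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=80))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force_step_up(self, pvals):
        np.testing.assert_allclose(
            bh_adjust(pvals), bh_brute_force(np.array(pvals)), atol=1e-12
        )


class TestOnewayAnova:
    def _matrix(self, design, a_vals, b_vals):
        row = group_values(design, {"ctrl_wt": a_vals, "stress_wt": b_vals,
                                    "ctrl_ko": [0.0] * 4, "stress_ko": [0.0] * 4})
        return make_matrix(row, design)

    def test_hand_anova_f_and_log2fc(self, design4):
        """Groups [1,2,3] vs [4,5,6]: SSB = 13.5, MSW = 1, so F = 13.5."""
        row = group_values(design4, {
            "ctrl_wt": [1, 2, 3, 2], "stress_wt": [4, 5, 6, 5],
            "ctrl_ko": [0, 0, 0, 0], "stress_ko": [0, 0, 0, 0]})
        em = make_matrix(row, design4)
        # restrict to 3 samples per side via a trimmed design
        d3 = design4[~design4["sample_id"].str.endswith("_4")]
        em3 = em.copy_with(em.values[d3["sample_id"]])
        res = oneway_anova(em3, d3, ("ctrl_wt", "stress_wt"))
        f_expected = 13.5
        p_expected = stats.f.sf(f_expected, 1, 4)
        assert res.table["log2fc"].iloc[0] == pytest.approx(3.0)
        assert res.table["p"].iloc[0] == pytest.approx(p_expected, rel=1e-10)

    def test_identical_groups_null_result(self, design4):
        em = self._matrix(design4, [1, 2, 3, 4], [1, 2, 3, 4])
        res = oneway_anova(em, design4, ("ctrl_wt", "stress_wt"))
        assert res.table["log2fc"].iloc[0] == 0.0
        assert res.table["p"].iloc[0] == pytest.approx(1.0)

    def test_swapping_groups_negates_log2fc(self, design4):
        em = self._matrix(design4, [1.0, 2.0, 1.5, 2.5], [4.0, 5.0, 4.5, 5.5])
        fwd = oneway_anova(em, design4, ("ctrl_wt", "stress_wt"))
        rev = oneway_anova(em, design4, ("stress_wt", "ctrl_wt"))
        assert fwd.table["log2fc"].iloc[0] == -rev.table["log2fc"].iloc[0]
        assert fwd.table["p"].iloc[0] == pytest.approx(rev.table["p"].iloc[0])

    def test_zero_variance_deterministic_p(self, design4):
        em = self._matrix(design4, [1, 1, 1, 1], [2, 2, 2, 2])
        res = oneway_anova(em, design4, ("ctrl_wt", "stress_wt"))
        assert res.table["p"].iloc[0] == 0.0


class TestAncova:
    def test_matches_statsmodels_type2(self, design4):
        """Vectorized group F equals statsmodels anova_lm(typ=2) per gene."""
        t = generate_truth(5, seed=3)
        em = simulate_intensities(design4, t, SimulationParams(n_genes=5, seed=3))
        anc = ancova_fit(em, design4)
        for i in range(5):
            df = pd.DataFrame({"y": em.values.iloc[i].to_numpy(),
                               "Group": design4["group"], "Sex": design4["sex"]})
            tab = anova_lm(smf.ols("y ~ C(Group) + C(Sex)", df).fit(), typ=2)
            assert anc.table["group_f"].iloc[i] == pytest.approx(
                tab.loc["C(Group)", "F"], abs=1e-8)
            assert anc.table["sex_p"].iloc[i] == pytest.approx(
                tab.loc["C(Sex)", "PR(>F)"], abs=1e-8)

    def test_nested_model_is_oneway_anova(self, design4):
        """Dropping the covariate reduces the fit to a 4-group one-way ANOVA."""
        t = generate_truth(100, seed=4, effect_params={"sex_effect_fraction": 0.0})
        em = simulate_intensities(design4, t, SimulationParams(n_genes=100, seed=4))
        anc = ancova_fit(em, design4, include_sex=False)
        groups = [em.values[design4.loc[design4.group == g, "sample_id"]].to_numpy().T
                  for g in GROUPS]
        f = stats.f_oneway(*groups).statistic
        np.testing.assert_allclose(anc.table["group_f"].to_numpy(), f, atol=1e-6)

    def test_balanced_sex_offset_leaves_group_estimates_unchanged(self, design4):
        """Adding +1 to all males in a balanced design shifts nothing in the
        group contrasts and shrinks the residual variance estimate."""
        t = generate_truth(50, seed=5, effect_params={"sex_effect_fraction": 0.0})
        em = simulate_intensities(design4, t, SimulationParams(n_genes=50, seed=5))
        male_cols = design4.loc[design4.sex == "M", "sample_id"]
        shifted = em.values.copy()
        shifted[male_cols] += 1.0
        anc0 = ancova_fit(em, design4)
        anc1 = ancova_fit(em.copy_with(shifted), design4)
        for a, b in [("stress_wt", "ctrl_wt"), ("stress_ko", "stress_wt")]:
            d0 = anc0.table[f"adj_mean_{a}"] - anc0.table[f"adj_mean_{b}"]
            d1 = anc1.table[f"adj_mean_{a}"] - anc1.table[f"adj_mean_{b}"]
            np.testing.assert_allclose(d0, d1, atol=1e-9)
        np.testing.assert_allclose(anc0.mse, anc1.mse, atol=1e-9)

    def test_constant_gene_group_p_is_one(self, design4):
        em = make_matrix(np.full((1, 16), 3.0), design4)
        anc = ancova_fit(em, design4)
        assert anc.table["group_p"].iloc[0] == 1.0

    def test_confounded_design_rejected(self, design4):
        bad = design4.copy()
        # sex identical to the ctrl_wt indicator -> aliased with group dummies
        bad["sex"] = np.where(bad["group"] == "ctrl_wt", "F", "M")
        with pytest.raises(DesignError):
            ancova_fit(make_matrix(np.ones((1, 16)), design4), bad)


class TestTukeyPosthoc:
    def test_identical_groups_all_p_near_one(self, design4):
        em = make_matrix(np.tile([1.0, 2.0, 3.0, 4.0], (1, 4)), design4)
        anc = posthoc_pairwise(ancova_fit(em, design4, include_sex=False))
        for ph in anc.posthoc.values():
            assert (ph["adjusted_p"] >= 0.999).all()

    def test_single_elevated_group_dominates(self, design4):
        rng = np.random.default_rng(6)
        rows = np.stack([group_values(design4, {
            "ctrl_wt": rng.normal(0, 0.1, 4), "ctrl_ko": rng.normal(0, 0.1, 4),
            "stress_wt": rng.normal(4, 0.1, 4), "stress_ko": rng.normal(0, 0.1, 4)})
            for _ in range(3)])
        anc = posthoc_pairwise(ancova_fit(make_matrix(rows, design4), design4))
        for name, ph in anc.posthoc.items():
            if "g3" in name:
                assert (ph["adjusted_p"] < 1e-3).all()
            else:
                assert (ph["adjusted_p"] > 1e-3).all()

    def test_adjusted_p_at_least_unadjusted(self, design4):
        rng = np.random.default_rng(7)
        em = make_matrix(rng.normal(5, 1, (30, 16)), design4)
        anc = posthoc_pairwise(ancova_fit(em, design4))
        for name, ph in anc.posthoc.items():
            se = np.sqrt(anc.mse.to_numpy() * (1 / 4 + 1 / 4))
            t = np.abs(ph["estimate"].to_numpy()) / se
            p_unadj = 2 * stats.t.sf(t, anc.df_resid)
            assert (ph["adjusted_p"].to_numpy() >= p_unadj - 1e-12).all()

    def test_group_relabeling_symmetry(self, design4):
        """Swapping two group labels permutes the Tukey p-values accordingly."""
        rng = np.random.default_rng(8)
        em = make_matrix(rng.normal(5, 1, (10, 16)), design4)
        anc = posthoc_pairwise(ancova_fit(em, design4))
        swapped = design4.copy()
        swap = {"ctrl_wt": "ctrl_ko", "ctrl_ko": "ctrl_wt"}
        swapped["group"] = swapped["group"].map(lambda g: swap.get(g, g))
        anc_sw = posthoc_pairwise(ancova_fit(em, swapped))
        np.testing.assert_allclose(
            anc.posthoc["g3_vs_g1"]["adjusted_p"],
            anc_sw.posthoc["g3_vs_g2"]["adjusted_p"], atol=1e-9)

    def test_matches_scipy_tukey_hsd_without_covariate(self, design4):
        """One-way Tukey agrees with scipy.stats.tukey_hsd as oracle."""
        rng = np.random.default_rng(9)
        em = make_matrix(rng.normal(3, 1, (4, 16)), design4)
        anc = posthoc_pairwise(ancova_fit(em, design4, include_sex=False))
        cols = {g: design4.loc[design4.group == g, "sample_id"] for g in GROUPS}
        for i in range(4):
            groups = [em.values.iloc[i][cols[g]].to_numpy() for g in GROUPS]
            oracle = stats.tukey_hsd(*groups)
            for name, ph in anc.posthoc.items():
                a, b = parse_contrast(name)
                ia, ib = GROUPS.index(a), GROUPS.index(b)
                assert ph["adjusted_p"].iloc[i] == pytest.approx(
                    oracle.pvalue[ia, ib], abs=1e-7)


class TestFeatureTtest:
    def _em(self, design, a, b):
        row = group_values(design, {"ctrl_wt": a, "stress_wt": b,
                                    "ctrl_ko": [0.0] * 4, "stress_ko": [0.0] * 4})
        return make_matrix(row, design)

    def test_hand_computed_t(self, design4):
        d3 = design4[~design4["sample_id"].str.endswith("_4")]
        em = self._em(design4, [1, 2, 3, 0], [4, 5, 6, 0])
        em = em.copy_with(em.values[d3["sample_id"]])
        res = feature_ttest(em, d3, ("ctrl_wt", "stress_wt"), "student")
        assert abs(res.table["t"].iloc[0]) == pytest.approx(3.674, abs=5e-4)
        assert res.table["p"].iloc[0] == pytest.approx(0.0213, abs=5e-4)

    def test_equal_groups_give_p_one(self, design4):
        em = self._em(design4, [1, 2, 3, 4], [1, 2, 3, 4])
        res = feature_ttest(em, design4, ("ctrl_wt", "stress_wt"), "student")
        assert res.table["p"].iloc[0] == pytest.approx(1.0)
        assert res.table["t"].iloc[0] == pytest.approx(0.0)

    def test_welch_equals_student_when_balanced_equal_variance(self, design4):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        em = self._em(design4, list(a), list(a + 2.0))  # identical spread
        s = feature_ttest(em, design4, ("ctrl_wt", "stress_wt"), "student")
        w = feature_ttest(em, design4, ("ctrl_wt", "stress_wt"), "welch")
        assert s.table["p"].iloc[0] == pytest.approx(w.table["p"].iloc[0], abs=1e-9)


class TestLog2FoldChange:
    def test_mean_difference_and_antisymmetry(self, design4):
        em = make_matrix(group_values(design4, {
            "ctrl_wt": [3.0] * 4, "stress_wt": [5.0] * 4,
            "ctrl_ko": [0.0] * 4, "stress_ko": [0.0] * 4}), design4)
        fwd = log2_fold_change(em, design4, ("ctrl_wt", "stress_wt"))
        rev = log2_fold_change(em, design4, ("stress_wt", "ctrl_wt"))
        assert fwd.iloc[0] == pytest.approx(2.0)
        assert rev.iloc[0] == pytest.approx(-2.0)

    def test_location_invariance(self, design4):
        rng = np.random.default_rng(10)
        em = make_matrix(rng.normal(5, 1, (8, 16)), design4)
        shifted = em.copy_with(em.values + 3.7)
        np.testing.assert_allclose(
            log2_fold_change(em, design4, ("ctrl_wt", "stress_ko")),
            log2_fold_change(shifted, design4, ("ctrl_wt", "stress_ko")), atol=1e-12)

    def test_unknown_group_rejected(self, design4):
        em = make_matrix(np.ones((1, 16)), design4)
        with pytest.raises(DesignError):
            log2_fold_change(em, design4, ("ctrl_wt", "nonsense"))
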