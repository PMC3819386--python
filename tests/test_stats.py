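import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from voxgraph.stats import (
    RegressionSpec,
    RoiMetricTable,
    StatResult,
    benjamini_hochberg,
    build_interaction,
    dual_threshold_significance,
    hierarchical_regression,
    manova_pillai,
    pearson_correlation,
    rm_group_by_roi_interaction,
    univariate_anova,
)


def two_groups(n_a, n_b):
    return np.array(["a"] * n_a + ["b"] * n_b)


class TestManova:
    def test_hand_computed_one_dv_case(self):
        # {1,2,3} vs {4,5,6}: SSb = 13.5, SSw = 4 -> V = 13.5/17.5
        table = RoiMetricTable(np.array([[1.0], [2], [3], [4], [5], [6]]), two_groups(3, 3))
        res = manova_pillai(table)
        assert res.value == pytest.approx(27 / 35)
        assert res.effect_size == pytest.approx(27 / 35)

    def test_one_dv_equals_anova_eta_squared(self, rng):
        x = rng.normal(size=(16, 1))
        g = two_groups(8, 8)
        x[8:] += 0.8
        v = manova_pillai(RoiMetricTable(x, g)).value
        eta = univariate_anova(x[:, 0], g).effect_size
        assert v == pytest.approx(eta, abs=1e-12)

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        x = rng.normal(size=(24, 3))
        g = two_groups(12, 12)
        x[12:] += [0.6, -0.4, 0.2]
        res = manova_pillai(RoiMetricTable(x, g))
        df = pd.DataFrame(x, columns=["y1", "y2", "y3"])
        df["g"] = g
        ref = MANOVA.from_formula("y1 + y2 + y3 ~ g", data=df).mv_test()
        tbl = ref.results["g"]["stat"]
        assert res.value == pytest.approx(tbl.loc["Pillai's trace", "Value"], abs=1e-8)
        assert res.extras["F"] == pytest.approx(tbl.loc["Pillai's trace", "F Value"], abs=1e-8)
        assert res.p == pytest.approx(tbl.loc["Pillai's trace", "Pr > F"], abs=1e-8)

    def test_df_structure_matches_design(self, rng):
        # 62 subjects, 4 dependent variables -> F(4, 57)
        x = rng.normal(size=(62, 4))
        res = manova_pillai(RoiMetricTable(x, two_groups(31, 31)))
        assert res.df == (4, 57)

    def test_singular_sscp_rejected(self, rng):
        x = rng.normal(size=(10, 2))
        x = np.column_stack([x, x[:, 0]])  # duplicate ROI column
        with pytest.raises(ValueError, match="ROI"):
            manova_pillai(RoiMetricTable(x, two_groups(5, 5)))


class TestAnova:
    def test_hand_computed_case(self):
        res = univariate_anova(np.array([1.0, 2, 3, 4, 5, 6]), two_groups(3, 3))
        assert res.value == pytest.approx(13.5)
        assert res.effect_size == pytest.approx(27 / 35)

    def test_equal_means_near_zero(self):
        res = univariate_anova(np.array([1.0, 2, 3, 1, 2, 3]), two_groups(3, 3))
        assert res.value == pytest.approx(0.0, abs=1e-12)
        assert res.effect_size == pytest.approx(0.0, abs=1e-12)

    def test_f_equals_t_squared(self, rng):
        x = rng.normal(size=30)
        g = two_groups(14, 16)
        res = univariate_anova(x, g)
        t, p = sps.ttest_ind(x[:14], x[14:])
        assert res.value == pytest.approx(t**2, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)


class TestRmInteraction:
    def test_parallel_profiles_no_interaction(self, rng):
        # additive subject + ROI + constant group shift: no interaction signal
        y = (
            rng.normal(size=(20, 1))
            + np.array([[0.0, 1.0, 2.0]])
            + rng.normal(scale=0.3, size=(20, 3))
        )
        y[10:] += 5.0  # constant group shift across ROIs
        res = rm_group_by_roi_interaction(RoiMetricTable(y, two_groups(10, 10)))
        assert res.p > 0.05
        assert res.effect_size < 0.2

    def test_planted_crossover_detected(self, rng):
        y = rng.normal(scale=0.5, size=(30, 4))
        y[:15, :2] += 2.0
        y[15:, 2:] += 2.0
        res = rm_group_by_roi_interaction(RoiMetricTable(y, two_groups(15, 15)))
        assert res.p < 0.001

    def test_df_structure_ten_rois_62_subjects(self, rng):
        y = rng.normal(size=(62, 10))
        res = rm_group_by_roi_interaction(RoiMetricTable(y, two_groups(31, 31)))
        assert res.df == (9, 540)

    @pytest.mark.parametrize("n_a,n_b", [(10, 10), (8, 12)])
    def test_matches_pingouin_reference(self, rng, n_a, n_b):
        import pingouin as pg

        y = rng.normal(size=(n_a + n_b, 3))
        y[n_a:] += [0.5, -0.3, 0.2]
        g = two_groups(n_a, n_b)
        res = rm_group_by_roi_interaction(RoiMetricTable(y, g))
        long = pd.DataFrame(
            [
                {"subj": s, "roi": f"r{r}", "grp": g[s], "y": y[s, r]}
                for s in range(n_a + n_b)
                for r in range(3)
            ]
        )
        aov = pg.mixed_anova(data=long, dv="y", within="roi", subject="subj", between="grp")
        inter = aov[aov["Source"] == "Interaction"].iloc[0]
        assert res.value == pytest.approx(inter["F"], abs=1e-8)
        assert res.p == pytest.approx(inter["p_unc"], abs=1e-8)
        assert res.effect_size == pytest.approx(inter["np2"], abs=1e-8)


class TestHierarchicalRegression:
    def test_orthogonal_predictors_decompose_r2(self, rng):
        n = 64
        # orthonormal, mean-zero predictors (QR of centered columns)
        raw = rng.normal(size=(n, 3))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        x = q * np.sqrt(n)
        y = 0.5 * x[:, 0] - 0.3 * x[:, 1] + 0.2 * x[:, 2]
        data = pd.DataFrame({"y": y, "a": x[:, 0], "b": x[:, 1], "c": x[:, 2]})
        spec = RegressionSpec("y", [["a"], ["b"], ["c"]])
        steps = hierarchical_regression(data, spec)
        total = sum(np.corrcoef(data[c], y)[0, 1] ** 2 for c in "abc")
        assert steps[-1]["r2"] == pytest.approx(total, abs=1e-10)
        assert all(s["delta_r2"] >= -1e-12 for s in steps)

    def test_null_block_adds_nothing(self, rng):
        n = 200
        data = pd.DataFrame(
            {"y": rng.normal(size=n), "a": rng.normal(size=n), "junk": rng.normal(size=n)}
        )
        data["y"] += 0.6 * data["a"]
        steps = hierarchical_regression(data, RegressionSpec("y", [["a"], ["junk"]]))
        assert steps[1]["delta_r2"] < 0.02
        assert abs(steps[1]["coefficients"]["junk"]["beta"]) < 0.15

    def test_r2_nondecreasing_over_steps(self, rng):
        n = 80
        data = pd.DataFrame(rng.normal(size=(n, 4)), columns=["y", "a", "b", "c"])
        steps = hierarchical_regression(data, RegressionSpec("y", [["a"], ["b"], ["c"]]))
        r2s = [s["r2"] for s in steps]
        assert all(r2s[i + 1] >= r2s[i] - 1e-12 for i in range(len(r2s) - 1))

    def test_collinear_block_names_offender(self, rng):
        n = 40
        a = rng.normal(size=n)
        data = pd.DataFrame({"y": rng.normal(size=n), "a": a, "a2": 2 * a})
        with pytest.raises(ValueError, match="a2"):
            hierarchical_regression(data, RegressionSpec("y", [["a", "a2"]]))

    def test_interaction_builder_centers_and_codes(self):
        data = pd.DataFrame(
            {"group": ["young", "old", "young", "old"], "m": [1.0, 2.0, 3.0, 4.0]}
        )
        out = build_interaction(data, "group", "m")
        assert set(out["group_code"]) == {-0.5, 0.5}
        assert out["m_c"].mean() == pytest.approx(0.0)
        np.testing.assert_allclose(out["group_x_m"], out["group_code"] * out["m_c"])


class TestDualThreshold:
    @staticmethod
    def res(p, effect):
        return StatResult("beta", effect, None, p, effect_size=effect)

    def test_both_significant_same_sign(self):
        assert dual_threshold_significance(self.res(0.03, -0.4), self.res(0.04, -0.35))

    def test_one_nonsignificant_fails(self):
        assert not dual_threshold_significance(self.res(0.03, -0.4), self.res(0.08, -0.35))

    def test_sign_conflict_fails_with_warning(self):
        with pytest.warns(UserWarning, match="sign"):
            ok = dual_threshold_significance(self.res(0.01, 0.4), self.res(0.01, -0.4))
        assert not ok


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, 2 * x + 1)
        assert res.value == pytest.approx(1.0)

    def test_null_p_uniform(self, rng):
        ps = []
        for _ in range(500):
            x = rng.normal(size=29)
            y = rng.normal(size=29)
            ps.append(pearson_correlation(x, y).p)
        stat, p = sps.kstest(ps, "uniform")
        assert p > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation(np.ones(10), np.arange(10.0))


class TestBenjaminiHochberg:
    def test_rejects_smallest_p_first(self):
        p = np.array([0.001, 0.2, 0.8, 0.04])
        rej = benjamini_hochberg(p, alpha=0.05)
        assert rej[0] and not rej[2]

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=30) ** 2
        mine = benjamini_hochberg(p, 0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        np.testing.assert_array_equal(mine, ref)
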