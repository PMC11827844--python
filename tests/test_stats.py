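"""Reliability/association statistics against independent closed-form oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import spliceindex as si


def icc_a1_oracle(arr):
    """Two-way ANOVA mean squares -> absolute-agreement single-measure ICC."""
    n, k = arr.shape
    grand = arr.mean()
    msr = k * ((arr.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((arr.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    mse = ((arr - arr.mean(axis=1, keepdims=True) - arr.mean(axis=0) + grand) ** 2).sum() / (
        (n - 1) * (k - 1)
    )
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


FIXED_TABLE = np.array(
    [
        [0.12, 0.15], [0.31, 0.29], [0.44, 0.50], [0.52, 0.47], [0.60, 0.66],
        [0.25, 0.22], [0.71, 0.80], [0.83, 0.79], [0.90, 0.95], [0.38, 0.41],
    ]
)


class TestIcc:
    def test_identical_columns_give_one(self):
        res = si.icc_agreement(np.c_[FIXED_TABLE[:, 0], FIXED_TABLE[:, 0]])
        assert res.icc == pytest.approx(1.0, abs=1e-12)

    def test_constant_shift_penalized(self):
        """Absolute agreement is sensitive to systematic bias."""
        res = si.icc_agreement(np.c_[FIXED_TABLE[:, 0], FIXED_TABLE[:, 0] + 0.1])
        assert res.defined and res.icc < 1.0

    def test_matches_anova_oracle(self):
        res = si.icc_agreement(FIXED_TABLE)
        assert res.icc == pytest.approx(icc_a1_oracle(FIXED_TABLE), abs=1e-10)

    def test_matches_pingouin(self):
        import pingouin as pg

        n = len(FIXED_TABLE)
        long = pd.DataFrame(
            {"t": np.repeat(np.arange(n), 2), "r": np.tile([0, 1], n), "s": FIXED_TABLE.ravel()}
        )
        table = pg.intraclass_corr(long, targets="t", raters="r", ratings="s").set_index("Type")
        label = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
        assert si.icc_agreement(FIXED_TABLE).icc == pytest.approx(table.loc[label, "ICC"], abs=1e-10)

    def test_zero_variance_flagged(self):
        res = si.icc_agreement(np.full((5, 2), 0.3))
        assert not res.defined and np.isnan(res.icc)


class TestCorrelate:
    def test_perfect_positive_and_negative(self):
        x = FIXED_TABLE[:, 0]
        assert si.correlate(x, 2 * x + 1).r == pytest.approx(1.0)
        assert si.correlate(x, -x).r == pytest.approx(-1.0)

    def test_pearson_fisher_z_ci_closed_form(self):
        rng = np.random.default_rng(30)
        x = rng.normal(size=30)
        y = 0.7 * x + rng.normal(scale=np.sqrt(1 - 0.49), size=30)
        res = si.correlate(x, y)
        r_ref, _ = st.pearsonr(x, y)
        z = np.arctanh(r_ref)
        half = st.norm.ppf(0.975) / np.sqrt(30 - 3)  # the 1.96/sqrt(n-3) band
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.ci_low == pytest.approx(np.tanh(z - half), abs=1e-10)
        assert res.ci_high == pytest.approx(np.tanh(z + half), abs=1e-10)

    def test_spearman_monotone_nonlinear(self):
        x = np.linspace(0.1, 2.0, 15)
        res = si.correlate(x, np.exp(x), method="spearman")
        assert res.r == pytest.approx(1.0)

    def test_spearman_matches_scipy_on_ties(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0, 7.0])
        res = si.correlate(x, y, method="spearman")
        rs, p = st.spearmanr(x, y)
        assert res.r == pytest.approx(rs, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)

    def test_zero_variance_flagged(self):
        res = si.correlate(np.ones(10), np.arange(10.0))
        assert not res.defined

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            si.correlate([1, 2, 3], [1, 2, 3])


class TestBlandAltman:
    def test_identity(self):
        x = FIXED_TABLE[:, 0]
        res = si.bland_altman(x, x)
        assert res.bias == 0.0 and res.loa_low == 0.0 and res.loa_high == 0.0

    def test_pure_shift_zero_width(self):
        x = FIXED_TABLE[:, 0]
        res = si.bland_altman(x, x + 0.1)
        assert res.bias == pytest.approx(0.1)
        assert res.loa_high - res.loa_low == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self):
        x, y = FIXED_TABLE[:, 0], FIXED_TABLE[:, 1]
        res = si.bland_altman(x, y)
        d = y - x
        assert res.bias == pytest.approx(d.mean(), abs=1e-12)
        assert res.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1), abs=1e-10)
        assert res.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), abs=1e-10)


class TestLinearModel:
    def test_exact_linear_relationship(self):
        X = pd.DataFrame({"a": FIXED_TABLE[:, 0], "b": FIXED_TABLE[:, 1]})
        y = 3 * X["a"] - 2 * X["b"] + 1
        res = si.fit_linear_model(y, X)
        assert res.adjusted_r2 == pytest.approx(1.0)
        assert res.params["a"] == pytest.approx(3.0, abs=1e-8)

    def test_adjusted_r2_matches_formula(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        y = X["a"] + rng.normal(size=40)
        res = si.fit_linear_model(y, X)
        n, p = 40, 2
        assert res.adjusted_r2 == pytest.approx(
            1 - (1 - res.r2) * (n - 1) / (n - p - 1), abs=1e-12
        )

    def test_null_outcome_near_zero(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({"a": rng.normal(size=500)})
        res = si.fit_linear_model(rng.normal(size=500), X)
        assert abs(res.adjusted_r2) < 0.02

    def test_collinear_columns_named(self):
        X = pd.DataFrame({"a": FIXED_TABLE[:, 0], "dup": 2 * FIXED_TABLE[:, 0]})
        with pytest.raises(ValueError, match="dup"):
            si.fit_linear_model(FIXED_TABLE[:, 1], X)

    def test_adding_baseline_si_improves_followup_model(self):
        """Follow-up strength generated from baseline strength plus baseline
        SI: the two-covariate model must out-explain strength alone."""
        rng = np.random.default_rng(10)
        bl_adf = rng.uniform(20, 100, 60)
        bl_si = rng.uniform(0, 1, 60)
        adf_3m = 0.8 * bl_adf - 15 * bl_si + rng.normal(0, 4, 60)
        both = si.fit_linear_model(adf_3m, pd.DataFrame({"bl_adf": bl_adf, "bl_si": bl_si}))
        alone = si.fit_linear_model(adf_3m, pd.DataFrame({"bl_adf": bl_adf}))
        assert both.adjusted_r2 > alone.adjusted_r2


class TestCompareGroups:
    def test_identical_pairs(self):
        x = FIXED_TABLE[:, 0]
        res = si.compare_groups((x, x), design="paired_t")
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_paired_t_matches_scipy(self):
        a, b = FIXED_TABLE[:, 0], FIXED_TABLE[:, 1]
        res = si.compare_groups((a, b), design="paired_t")
        t, p = st.ttest_rel(b, a)
        assert res["t"] == pytest.approx(t, abs=1e-12)
        assert res["p"] == pytest.approx(p, abs=1e-12)

    def test_anova_tukey_matches_hand_computation(self):
        """Balanced 3-group table: F from hand-computed mean squares and
        Tukey p from the studentized-range distribution."""
        data = {"a": [1.1, 2.0, 2.9, 2.2], "b": [2.4, 3.1, 3.8, 3.0], "c": [5.2, 6.1, 5.5, 6.0]}
        values = np.concatenate(list(data.values()))
        grouping = np.repeat(list(data), 4)
        res = si.compare_groups(values, grouping)
        k, n_per, N = 3, 4, 12
        grand = values.mean()
        means = {g: np.mean(v) for g, v in data.items()}
        ssb = n_per * sum((m - grand) ** 2 for m in means.values())
        ssw = sum(((np.array(v) - means[g]) ** 2).sum() for g, v in data.items())
        f_hand = (ssb / (k - 1)) / (ssw / (N - k))
        assert res["F"] == pytest.approx(f_hand, abs=1e-10)
        mse = ssw / (N - k)
        for pw in res["pairwise"]:
            qa = abs(means[pw["group_a"]] - means[pw["group_b"]]) / np.sqrt(mse / n_per)
            assert pw["p_adj"] == pytest.approx(st.studentized_range.sf(qa, k, N - k), abs=1e-8)

    def test_tiny_group_excluded_with_warning(self):
        values = np.r_[np.arange(5.0), np.arange(5.0) + 2, [9.0]]
        grouping = np.r_[["a"] * 5, ["b"] * 5, ["dmd"]]
        with pytest.warns(UserWarning, match="dmd"):
            res = si.compare_groups(values, grouping)
        assert res["groups"] == ["a", "b"]

    def test_null_case_no_rejections(self):
        rng = np.random.default_rng(11)
        values = rng.normal(size=300)
        grouping = np.repeat(["a", "b", "c"], 100)
        res = si.compare_groups(values, grouping)
        assert all(pw["p_adj"] > 0.05 for pw in res["pairwise"])


class TestDichotomize:
    def test_equal_to_mean_codes_zero(self):
        out = si.dichotomize(np.array([[0.5, 0.7]]), np.array([0.5, 0.6]))
        assert out.tolist() == [[0, 1]]

    def test_all_above_means(self):
        out = si.dichotomize(np.ones((3, 2)), np.zeros(2))
        assert out.sum() == 6

    def test_matches_elementwise_comparison(self):
        rng = np.random.default_rng(13)
        vals = pd.DataFrame(rng.uniform(size=(20, 4)), columns=list("wxyz"))
        means = vals.mean()
        out = si.dichotomize(vals, means)
        assert (out.to_numpy() == (vals.to_numpy() > means.to_numpy())).all()


class TestSelectIndicators:
    def _block_matrix(self, seed=14, n=120):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        cols = {
            "A1": a, "A2": a + rng.normal(0, 0.1, n), "A3": a + rng.normal(0, 0.1, n),
            "B1": b, "B2": b + rng.normal(0, 0.1, n),
            "C1": rng.normal(size=n),
        }
        return pd.DataFrame(cols)

    def test_collinear_pair_pruned(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=50)
        mat = pd.DataFrame({"p": x, "q": x * 1.001 + 1e-4, "r": rng.normal(size=50)})
        sel = si.select_lca_indicators(mat, max_abs_corr=0.9)
        assert not {"p", "q"} <= set(sel)

    def test_independent_events_all_kept(self):
        rng = np.random.default_rng(16)
        mat = pd.DataFrame(rng.normal(size=(200, 5)), columns=list("abcde"))
        assert set(si.select_lca_indicators(mat, max_abs_corr=0.5)) == set("abcde")

    def test_matches_exhaustive_subset_search(self):
        """Block-correlated matrix: the greedy pick reaches the maximal
        admissible subset size found by exhaustive search."""
        mat = self._block_matrix()
        thr = 0.5
        sel = si.select_lca_indicators(mat, max_abs_corr=thr)
        corr = mat.corr().abs()
        best = 0
        for r in range(len(mat.columns), 1, -1):
            from itertools import combinations as comb

            if any(
                all(corr.loc[i, j] <= thr for i, j in comb(sub, 2))
                for sub in comb(mat.columns, r)
            ):
                best = r
                break
        assert len(sel) == best
        assert all(corr.loc[i, j] <= thr for i, j in combinations(sel, 2))

    def test_published_indicator_events_preferred(self):
        rng = np.random.default_rng(17)
        names = ["CAMK2B_e13", "CCPG1_e2", "DMD_e78", "INSR_e11", "GOLGA4_e3", "X1", "X2"]
        mat = pd.DataFrame(rng.normal(size=(150, 7)), columns=names)
        sel = si.select_lca_indicators(
            mat, max_abs_corr=0.8,
            prefer=("CAMK2B_e13", "CCPG1_e2", "DMD_e78", "INSR_e11", "GOLGA4_e3"),
        )
        assert sel[:5] == ["CAMK2B_e13", "CCPG1_e2", "DMD_e78", "INSR_e11", "GOLGA4_e3"]
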