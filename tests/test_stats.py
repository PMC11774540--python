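"""Statistics suite against independent oracles.

The RM-ANOVA is checked against a hand-coded sums-of-squares decomposition,
pingouin (one and two within factors) and statsmodels AnovaRM (three
factors); the JZS Bayes factor against a quadrature oracle that integrates
the noncentral-t likelihood over the Cauchy prior on effect size (a
different route than the implementation's g-integral).
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy import stats as sps

from groupitizing.stats import (bic_inclusion_bf, implied_effect_size,
                                jzs_bf_ttest, one_sample_t, pca_oblimin,
                                posthoc_paired_t, required_sample_size, rm_anova)


def _long(matrix, factor="c"):
    """Subjects x levels matrix -> tidy frame."""
    n, k = matrix.shape
    return pd.DataFrame({
        "subject": np.repeat([f"s{i}" for i in range(n)], k),
        factor: [f"l{j}" for j in range(k)] * n,
        "score": matrix.ravel(),
    })


def _oneway_ss_oracle(Y):
    """Brute-force one-way within-subject decomposition on an n x k matrix."""
    n, k = Y.shape
    grand = Y.mean()
    ss_cond = n * ((Y.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((Y.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((Y - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df_c, df_e = k - 1, (k - 1) * (n - 1)
    F = (ss_cond / df_c) / (ss_err / df_e)
    # Greenhouse-Geisser epsilon from the double-centered covariance matrix
    S = np.cov(Y, rowvar=False, ddof=1)
    Sc = S - S.mean(axis=0) - S.mean(axis=1)[:, None] + S.mean()
    eps = np.trace(Sc) ** 2 / ((k - 1) * (Sc * Sc).sum())
    return F, df_c, df_e, sps.f.sf(F, df_c, df_e), eps, ss_cond / ss_total


class TestRmAnova:
    def test_six_by_three_fixture_matches_ss_oracle(self):
        rng = np.random.default_rng(42)
        Y = rng.normal(size=(6, 3)) + np.array([0.0, 0.4, 1.1])
        res = rm_anova(_long(Y), "score", "c", "subject").iloc[0]
        F, df_c, df_e, p, eps, eta = _oneway_ss_oracle(Y)
        assert res.F == pytest.approx(F, abs=1e-6)
        assert (res.df_num, res.df_den) == (df_c, df_e)
        assert res.p == pytest.approx(p, abs=1e-6)
        assert res.gg_epsilon == pytest.approx(eps, abs=1e-6)
        assert res.eta_sq == pytest.approx(eta, abs=1e-6)

    def test_two_level_factor_equals_squared_paired_t(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(12, 2)) + np.array([0.0, 0.5])
        res = rm_anova(_long(Y), "score", "c", "subject").iloc[0]
        t, p = sps.ttest_rel(Y[:, 0], Y[:, 1])
        assert res.F == pytest.approx(t ** 2, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)
        assert res.gg_epsilon == 1.0 and res.p_gg == res.p

    def test_constant_dv_gives_zero_f(self):
        Y = np.full((6, 3), 4.2)
        res = rm_anova(_long(Y), "score", "c", "subject").iloc[0]
        assert res.F == 0.0 and res.p == 1.0

    def test_matches_pingouin_one_way(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(9, 4)) + np.array([0, .2, .5, .1])
        mine = rm_anova(_long(Y), "score", "c", "subject").iloc[0]
        ref = pg.rm_anova(data=_long(Y), dv="score", within="c",
                          subject="subject", correction=True).iloc[0]
        assert mine.F == pytest.approx(ref.F, abs=1e-9)
        assert mine.p == pytest.approx(ref.p_unc, abs=1e-9)
        assert mine.gg_epsilon == pytest.approx(ref.eps, abs=1e-9)
        assert mine.p_gg == pytest.approx(ref.p_GG_corr, abs=1e-9)
        assert mine.mauchly_W == pytest.approx(ref.W_spher, abs=1e-9)

    def test_matches_pingouin_two_way(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        rows = []
        for i in range(8):
            for a, b in itertools.product("xy", "pqr"):
                rows.append({"subject": f"s{i}", "a": a, "b": b,
                             "score": rng.normal() + 0.3 * (a == "y")
                             + 0.2 * (b == "q")})
        df = pd.DataFrame(rows)
        mine = rm_anova(df, "score", ["a", "b"], "subject")
        ref = pg.rm_anova(data=df, dv="score", within=["a", "b"],
                          subject="subject")
        for i in range(3):
            assert mine.F[i] == pytest.approx(ref.F[i], abs=1e-9)
            assert mine.p[i] == pytest.approx(ref.p_unc[i], abs=1e-9)
            assert mine.p_gg[i] == pytest.approx(ref.p_GG_corr[i], abs=1e-9)

    def test_matches_anovarm_three_way(self):
        from statsmodels.stats.anova import AnovaRM
        rng = np.random.default_rng(5)
        rows = []
        for i in range(6):
            for a, b, c in itertools.product("xy", "pqr", "uv"):
                rows.append({"subject": f"s{i}", "a": a, "b": b, "c": c,
                             "score": rng.normal() + 0.4 * (a == "y") * (c == "v")})
        df = pd.DataFrame(rows)
        mine = rm_anova(df, "score", ["a", "b", "c"], "subject").set_index("term")
        ref = AnovaRM(df, "score", "subject", within=["a", "b", "c"]).fit().anova_table
        for term in ref.index:
            assert mine.loc[term, "F"] == pytest.approx(ref.loc[term, "F Value"],
                                                        abs=1e-9)
            assert mine.loc[term, "p"] == pytest.approx(ref.loc[term, "Pr > F"],
                                                        abs=1e-9)

    def test_gg_correction_raises_p_for_real_effects(self):
        """With F > 1 (the regime where the correction matters), shrinking
        the degrees of freedom by epsilon < 1 can only increase p."""
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(10, 5)) * np.array([1, 1, 1, 1, 3]) \
            + np.array([0, 0.3, 0.6, 0.9, 2.0])
        res = rm_anova(_long(Y), "score", "c", "subject").iloc[0]
        assert res.F > 1
        assert res.gg_epsilon < 1
        assert res.p_gg >= res.p

    def test_missing_cell_named(self):
        df = _long(np.random.default_rng(0).normal(size=(4, 3)))
        df = df[~((df.subject == "s1") & (df.c == "l2"))]
        with pytest.raises(ValueError, match="missing cell.*s1.*l2"):
            rm_anova(df, "score", "c", "subject")

    def test_requires_two_subjects(self):
        df = _long(np.zeros((1, 3)))
        with pytest.raises(ValueError, match="2 subjects"):
            rm_anova(df, "score", "c", "subject")


class TestPairedT:
    def test_identical_vectors(self):
        x = np.arange(5.0)
        res = posthoc_paired_t({"a": x, "b": x}, [("a", "b")]).iloc[0]
        assert res.t == 0.0 and res.p == 1.0 and res.p_bonf == 1.0

    def test_bonferroni_cap(self):
        rng = np.random.default_rng(0)
        res = posthoc_paired_t({"a": rng.normal(size=10),
                                "b": rng.normal(size=10)}, [("a", "b")], m=3).iloc[0]
        assert res.p_bonf == min(1.0, 3 * res.p)
        assert res.p <= res.p_bonf

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError, match="unpaired"):
            posthoc_paired_t({"a": np.zeros(4), "b": np.zeros(5)}, [("a", "b")])

    def test_d_is_t_over_sqrt_n(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0.5, 1, 20), rng.normal(0, 1, 20)
        res = posthoc_paired_t({"a": x, "b": y}, [("a", "b")]).iloc[0]
        assert res.d == pytest.approx(res.t / math.sqrt(20))


class TestOneSampleT:
    def test_values_equal_to_mu(self):
        res = one_sample_t([2.0, 2.0, 2.0, 2.0], mu=2.0)
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_hand_computed_differences(self):
        res = one_sample_t([1.0, 2.0, 3.0], mu=0.0)
        assert res["t"] == pytest.approx(2 / (1 / math.sqrt(3)), abs=1e-4)
        assert res["df"] == 2

    def test_t_is_mean_over_sem_and_d_relation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(10, 25, 28)
        res = one_sample_t(x)
        assert res["t"] == pytest.approx(res["mean"] / res["sem"])
        assert res["d"] == pytest.approx(res["t"] / math.sqrt(28))

    def test_zero_variance_flagged(self):
        res = one_sample_t([3.0, 3.0, 3.0], mu=0.0)
        assert res["degenerate"] and math.isinf(res["t"])


class TestJzsBayesFactor:
    def test_null_favored_at_t_zero(self):
        assert jzs_bf_ttest(0.0, 28) < 0

    def test_monotone_in_t(self):
        vals = [jzs_bf_ttest(t, 28) for t in np.arange(0, 5.5, 0.5)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_against_effect_size_quadrature_oracle(self):
        r = math.sqrt(2) / 2

        def oracle(t, n):
            nu = n - 1
            num, _ = integrate.quad(
                lambda d: sps.nct.pdf(t, nu, d * math.sqrt(n))
                * sps.cauchy.pdf(d, 0, r), -np.inf, np.inf, limit=300)
            return math.log10(num / sps.t.pdf(t, nu))

        for t in np.arange(0.0, 6.1, 0.5):
            for n in (10, 28, 50):
                assert jzs_bf_ttest(t, n) == pytest.approx(oracle(t, n), abs=1e-3)

    def test_reproduces_consistent_printed_values(self):
        """t values whose published log10 JZS Bayes factors verify:
        t=0.44 -> -0.66 and t=2.09 -> 0.12 (n=28, r=sqrt(2)/2); the same
        computation gives 0.787 for t=2.91."""
        assert jzs_bf_ttest(0.44, 28) == pytest.approx(-0.66, abs=0.15)
        assert jzs_bf_ttest(2.09, 28) == pytest.approx(0.12, abs=0.15)
        assert jzs_bf_ttest(2.91, 28) == pytest.approx(0.787, abs=0.15)

    def test_nonfinite_t_rejected(self):
        with pytest.raises(ValueError):
            jzs_bf_ttest(math.inf, 28)


class TestInclusionBf:
    @staticmethod
    def _crossed(effect_a=0.0, noise=0.3, n=10, seed=0):
        rng = np.random.default_rng(seed)
        s = np.repeat([f"s{i}" for i in range(n)], 4)
        a = np.tile(["x", "x", "y", "y"], n)
        b = np.tile(["p", "q", "p", "q"], n)
        score = rng.normal(size=4 * n) * noise + effect_a * (a == "y")
        return pd.DataFrame({"s": s, "a": a, "b": b, "score": score})

    def test_zero_f_term_gets_negative_lbf_strong_effect_positive(self):
        """Noise varies only at the subject x a level, so the b and a:b
        effects are exactly zero (F = 0): their inclusion can only pay the
        BIC penalty. The real a effect earns strong evidence."""
        rng = np.random.default_rng(4)
        n = 10
        noise = {(i, a): rng.normal(0, 0.3) for i in range(n) for a in "xy"}
        rows = [{"s": f"s{i}", "a": a, "b": b,
                 "score": 1.5 * (a == "y") + noise[(i, a)]}
                for i in range(n) for a in "xy" for b in "pq"]
        out = bic_inclusion_bf(pd.DataFrame(rows), "score", ["a", "b"], "s")
        assert out["a"] > 1
        assert out["b"] < 0
        assert out["a:b"] < 0

    def test_single_factor_family_equals_model_vs_null_bf(self):
        import statsmodels.formula.api as smf
        df = self._crossed(effect_a=0.8, seed=3)[["s", "a", "score"]]
        out = bic_inclusion_bf(df, "score", ["a"], "s")
        agg = df.groupby(["s", "a"]).score.mean().reset_index()
        b0 = smf.ols("score ~ C(s)", agg).fit().bic
        b1 = smf.ols("score ~ C(s) + C(a)", agg).fit().bic
        assert out["a"] == pytest.approx((b0 - b1) / (2 * math.log(10)), abs=1e-6)

    def test_matches_direct_bic_enumeration(self):
        """Two-factor family recomputed from scratch: five marginality-closed
        models, BIC weights, matched-model ratios."""
        import statsmodels.formula.api as smf
        df = self._crossed(effect_a=0.6, seed=7)
        out = bic_inclusion_bf(df, "score", ["a", "b"], "s")
        agg = df.groupby(["s", "a", "b"]).score.mean().reset_index()
        rhs = {frozenset(): "C(s)",
               frozenset({"a"}): "C(s) + C(a)",
               frozenset({"b"}): "C(s) + C(b)",
               frozenset({"a", "b"}): "C(s) + C(a) + C(b)",
               frozenset({"ab"}): "C(s) + C(a) + C(b) + C(a):C(b)"}
        bic = {k: smf.ols(f"score ~ {v}", agg).fit().bic for k, v in rhs.items()}
        w = {k: math.exp(-(v - min(bic.values())) / 2) for k, v in bic.items()}
        exp_a = math.log10(
            (w[frozenset({"a"})] + w[frozenset({"a", "b"})])
            / (w[frozenset()] + w[frozenset({"b"})]))
        exp_ab = math.log10(w[frozenset({"ab"})] / w[frozenset({"a", "b"})])
        assert out["a"] == pytest.approx(exp_a, abs=1e-6)
        assert out["a:b"] == pytest.approx(exp_ab, abs=1e-6)


class TestPcaOblimin:
    def test_rank_one_structure(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 1)) @ np.ones((1, 4)) \
            + rng.normal(size=(100, 4)) * 0.05
        res = pca_oblimin(X)
        assert res.n_components == 1
        assert res.variance_explained_pct > 98

    def test_two_block_structure_separates_after_rotation(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=(200, 2))
        X = np.empty((200, 8))
        for j in range(4):
            X[:, j] = math.sqrt(0.8) * f[:, 0] + math.sqrt(0.2) * rng.normal(size=200)
            X[:, j + 4] = math.sqrt(0.8) * f[:, 1] + math.sqrt(0.2) * rng.normal(size=200)
        res = pca_oblimin(X)
        assert res.n_components == 2
        L = np.abs(res.rotated_loadings)
        # each block loads on exactly one rotated factor
        block1 = L[:4].argmax(axis=1)
        block2 = L[4:].argmax(axis=1)
        assert len(set(block1)) == 1 and len(set(block2)) == 1
        assert block1[0] != block2[0]
        assert np.min(L.max(axis=1)) > 0.7
        assert np.max(L.min(axis=1)) < 0.3

    def test_eigenvalues_sum_to_variable_count(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 6))
        res = pca_oblimin(X)
        assert res.eigenvalues.sum() == pytest.approx(6.0, abs=1e-9)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_constant_column_named(self):
        X = pd.DataFrame({"good": np.random.default_rng(0).normal(size=30),
                          "flat": np.ones(30), "ok": np.arange(30.0)})
        with pytest.raises(ValueError, match="flat"):
            pca_oblimin(X)

    def test_shape_requirements(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            pca_oblimin(rng.normal(size=(30, 1)))
        with pytest.raises(ValueError):
            pca_oblimin(rng.normal(size=(4, 6)))


class TestPower:
    def test_unit_effect_standard_power_needs_ten(self):
        assert required_sample_size(1.0, 0.05, 0.8) == 10

    def test_n_non_increasing_in_effect_size(self):
        ns = [required_sample_size(d, 0.05, 0.9) for d in (0.3, 0.5, 0.8, 1.2)]
        assert ns == sorted(ns, reverse=True)

    def test_implied_effect_size_round_trips(self):
        d = implied_effect_size(28, 0.05 / 28, 0.95)
        assert required_sample_size(d * 1.0001, 0.05 / 28, 0.95) == 28
        assert required_sample_size(d * 0.98, 0.05 / 28, 0.95) > 28

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            required_sample_size(-1.0, 0.05, 0.8)
        with pytest.raises(ValueError):
            required_sample_size(1.0, 1.5, 0.8)
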