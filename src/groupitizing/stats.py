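"""Inferential statistics for fully within-subject designs.

Implements the machinery the precision analysis relies on:

* balanced repeated-measures ANOVA for any number of within factors, with
  Mauchly's sphericity test, Greenhouse-Geisser correction and classical
  eta-squared per term;
* paired / one-sample t tests with Bonferroni adjustment and Cohen's d
  (d_z = t / sqrt(n) by default; a pooled-SD paired d is also exposed);
* JZS (Cauchy-prior) Bayes factors for t tests, reported as log10(BF10);
* BIC-approximated inclusion Bayes factors across the matched model
  family of an ANOVA;
* PCA on the correlation matrix with Kaiser (eigenvalue > 1) retention
  and direct-oblimin rotation of the retained loadings;
* a-priori sample-size computation for paired t tests from noncentral-t
  power, and its inverse (the effect size implied by a given n).

The RM-ANOVA is computed from the classical sums-of-squares decomposition
on subject x cell means: for each term the error stratum is its
interaction with subjects. Greenhouse-Geisser epsilon and Mauchly's W are
computed per term from the covariance of orthonormal-contrast scores
(Kronecker products of per-factor Helmert contrasts), so they apply to
interactions as well as main effects.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps
from scipy.linalg import helmert
from scipy.optimize import brentq

__all__ = [
    "rm_anova",
    "posthoc_paired_t",
    "one_sample_t",
    "jzs_bf_ttest",
    "bic_inclusion_bf",
    "pca_oblimin",
    "PcaResult",
    "required_sample_size",
    "implied_effect_size",
    "DEFAULT_CAUCHY_SCALE",
]

DEFAULT_CAUCHY_SCALE = math.sqrt(2.0) / 2.0


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _cell_array(data: pd.DataFrame, dv: str, within: list[str], subject: str):
    """Subject x factor-level ndarray of cell means; errors on missing cells."""
    agg = data.groupby([subject] + within, observed=True)[dv].mean()
    subjects = sorted(data[subject].unique())
    levels = [sorted(data[f].unique()) for f in within]
    shape = (len(subjects),) + tuple(len(l) for l in levels)
    full_index = pd.MultiIndex.from_product([subjects] + levels,
                                            names=[subject] + within)
    aligned = agg.reindex(full_index)
    if aligned.isna().any():
        missing = aligned[aligned.isna()].index[0]
        raise ValueError(f"missing cell in within-subject design: {missing}")
    return aligned.to_numpy().reshape(shape), subjects, levels


def _effect_ss(Y: np.ndarray, dims: tuple[int, ...]) -> float:
    """Sum of squares of the (Mobius-inverted) effect on axis subset ``dims``."""
    nd = Y.ndim
    eff = np.zeros_like(Y, shape=tuple(Y.shape[d] if d in dims else 1
                                       for d in range(nd)))
    for r in range(len(dims) + 1):
        for sub in itertools.combinations(dims, r):
            other = tuple(d for d in range(nd) if d not in sub)
            sign = (-1) ** (len(dims) - len(sub))
            eff = eff + sign * Y.mean(axis=other, keepdims=True)
    scale = np.prod([Y.shape[d] for d in range(nd) if d not in dims])
    return float((eff ** 2).sum() * scale)


def _gg_mauchly(Y: np.ndarray, term: tuple[int, ...], levels: list[list]):
    """Greenhouse-Geisser epsilon and Mauchly's test for one term.

    ``term`` indexes the factor axes (1-based into Y, axis 0 is subject).
    """
    n_subj = Y.shape[0]
    other = tuple(d for d in range(1, Y.ndim) if d not in term)
    M = Y.mean(axis=other) if other else Y  # (subjects, levels of term...)
    M = M.reshape(n_subj, -1)
    C = np.array([[1.0]])
    for d in term:
        C = np.kron(C, helmert(Y.shape[d], full=False))
    Z = M @ C.T                       # contrast scores, (subjects, d)
    d = Z.shape[1]
    if d < 2:
        return 1.0, 1.0, 1.0          # two-level term: sphericity trivial
    S = np.cov(Z, rowvar=False, ddof=1)
    tr = np.trace(S)
    eps = tr ** 2 / (d * float((S * S.T).sum()))
    eps = min(1.0, max(eps, 1.0 / d))
    det = np.linalg.det(S)
    if det <= 0 or n_subj - 1 < d:
        return eps, 0.0, 0.0          # singular covariance: W -> 0
    W = det / (tr / d) ** d
    rho = 1.0 - (2 * d * d + d + 2) / (6.0 * d * (n_subj - 1))
    chi2 = -(n_subj - 1) * rho * math.log(W)
    df_m = d * (d + 1) // 2 - 1
    p_m = float(sps.chi2.sf(chi2, df_m))
    return eps, float(W), p_m


def rm_anova(data: pd.DataFrame, dv: str, within, subject: str,
             sphericity_alpha: float = 0.05) -> pd.DataFrame:
    """Balanced fully within-subject ANOVA (any number of within factors).

    Returns one row per main effect / interaction with columns
    ``term, F, df_num, df_den, p, mauchly_W, mauchly_p, gg_epsilon, p_gg,
    sphericity_violated, eta_sq``. ``p_gg`` is the Greenhouse-Geisser
    corrected p; eta_sq is SS_term / SS_total. Replicate observations per
    subject x cell are averaged first.
    """
    if isinstance(within, str):
        within = [within]
    within = list(within)
    Y, subjects, levels = _cell_array(data, dv, within, subject)
    if len(subjects) < 2:
        raise ValueError("at least 2 subjects are required")
    grand = Y.mean()
    ss_total = float(((Y - grand) ** 2).sum())

    rows = []
    factor_axes = list(range(1, Y.ndim))
    for r in range(1, len(factor_axes) + 1):
        for term in itertools.combinations(factor_axes, r):
            ss_t = _effect_ss(Y, term)
            ss_e = _effect_ss(Y, (0,) + term)
            df_t = int(np.prod([Y.shape[d] - 1 for d in term]))
            df_e = df_t * (len(subjects) - 1)
            ms_t, ms_e = ss_t / df_t, ss_e / df_e
            if ms_e <= 0:
                F = 0.0 if ms_t <= 1e-24 else math.inf
                p = 1.0 if F == 0.0 else 0.0
            else:
                F = ms_t / ms_e
                p = float(sps.f.sf(F, df_t, df_e))
            eps, W, p_m = _gg_mauchly(Y, term, levels)
            p_gg = (float(sps.f.sf(F, eps * df_t, eps * df_e))
                    if (math.isfinite(F) and ms_e > 0) else p)
            rows.append({
                "term": ":".join(within[d - 1] for d in term),
                "F": F, "df_num": df_t, "df_den": df_e, "p": p,
                "mauchly_W": W, "mauchly_p": p_m, "gg_epsilon": eps,
                "p_gg": p_gg, "sphericity_violated": p_m < sphericity_alpha,
                "eta_sq": ss_t / ss_total if ss_total > 0 else 0.0,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------

def _d_pooled(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    pooled = math.sqrt((sx ** 2 + sy ** 2) / 2.0)
    return float((x.mean() - y.mean()) / pooled) if pooled > 0 else 0.0


def posthoc_paired_t(data, comparisons, m: int | None = None,
                     cauchy_scale: float = DEFAULT_CAUCHY_SCALE) -> pd.DataFrame:
    """Two-tailed paired t tests with Bonferroni correction and LBF.

    ``data`` maps condition label -> 1-D paired observations (a dict or a
    wide DataFrame); ``comparisons`` is a list of (a, b) label pairs.
    ``m`` is the Bonferroni family size (defaults to ``len(comparisons)``).
    ``d`` is d_z (mean difference / SD of differences = t / sqrt(n));
    ``d_av`` uses the average-variance pooled SD of the two conditions.
    """
    if m is None:
        m = len(comparisons)
    rows = []
    for a, b in comparisons:
        x = np.asarray(data[a], dtype=float)
        y = np.asarray(data[b], dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError(f"comparison ({a}, {b}): unpaired observation lengths")
        n = len(x)
        diff = x - y
        sd = diff.std(ddof=1)
        if sd == 0:
            t, p, d_z = 0.0, 1.0, 0.0
        else:
            t = float(diff.mean() / (sd / math.sqrt(n)))
            p = float(2 * sps.t.sf(abs(t), n - 1))
            d_z = t / math.sqrt(n)
        rows.append({
            "comparison": f"{a} vs {b}", "t": t, "df": n - 1, "p": p,
            "p_bonf": min(1.0, m * p), "d": d_z, "d_av": _d_pooled(x, y),
            "lbf": jzs_bf_ttest(t, n, cauchy_scale),
        })
    return pd.DataFrame(rows)


def one_sample_t(values, mu: float = 0.0, alpha: float = 0.05,
                 cauchy_scale: float = DEFAULT_CAUCHY_SCALE) -> dict:
    """Two-tailed one-sample t test against ``mu``.

    ``alpha`` is the (already adjusted) significance level the test is
    judged at; ``d`` is d_z = t / sqrt(n). A zero-variance sample with
    mean != mu yields an infinite t, flagged via ``degenerate=True``.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    degenerate = False
    if sd == 0:
        if x.mean() == mu:
            t, p = 0.0, 1.0
        else:
            t, p, degenerate = math.inf, 0.0, True
    else:
        t = float((x.mean() - mu) / (sd / math.sqrt(n)))
        p = float(2 * sps.t.sf(abs(t), n - 1))
    return {
        "mean": float(x.mean()), "sem": float(sd / math.sqrt(n)), "df": n - 1,
        "t": t, "p": p, "alpha": alpha, "significant": p < alpha,
        "d": (t / math.sqrt(n)) if math.isfinite(t) else math.inf,
        "lbf": jzs_bf_ttest(t, n, cauchy_scale) if math.isfinite(t) else math.inf,
        "degenerate": degenerate,
    }


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------

def jzs_bf_ttest(t: float, n: int, cauchy_scale: float = DEFAULT_CAUCHY_SCALE) -> float:
    """JZS Bayes factor for a one-sample / paired t statistic, log10(BF10).

    Cauchy(0, r) prior on the standardized effect size (r = sqrt(2)/2 by
    default), evaluated by quadrature over the variance-inflation parameter
    g, whose prior is InverseGamma(1/2, r^2/2). The integrand is normalized
    by the null likelihood so the ratio stays well scaled for large |t|.
    """
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    if n < 2:
        raise ValueError("n must be >= 2")
    r = cauchy_scale
    nu = n - 1
    null = (1 + t * t / nu)

    def integrand(g):
        ratio = (1 + t * t / ((1 + n * g) * nu)) / null
        return ((1 + n * g) ** -0.5 * ratio ** (-(nu + 1) / 2)
                * sps.invgamma.pdf(g, 0.5, scale=r * r / 2))

    bf10, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return float(np.log10(bf10))


def _marginality_closed_models(terms: list[frozenset]) -> list[frozenset]:
    """All subsets of ``terms`` closed under marginality (an interaction
    requires all its lower-order relatives)."""
    models = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            model = frozenset(combo)
            if all(sub in model for term in model
                   for k in range(1, len(term))
                   for sub in map(frozenset, itertools.combinations(term, k))):
                models.append(model)
    return models


def _term_formula(term: frozenset) -> str:
    return ":".join(f"C({f})" for f in sorted(term))


def bic_inclusion_bf(data: pd.DataFrame, dv: str, within, subject: str
                     ) -> dict[str, float]:
    """BIC-approximated inclusion Bayes factors, log10, per ANOVA term.

    Fits every marginality-closed sub-model (OLS with a fixed subject
    factor), converts BICs to model weights, and compares matched models:
    for each term, models containing it but no higher-order interaction
    involving it, against the same models with the term removed.
    """
    import statsmodels.formula.api as smf

    if isinstance(within, str):
        within = [within]
    within = list(within)
    df = data.groupby([subject] + within, observed=True)[dv].mean().reset_index()
    df = df.rename(columns={dv: "_dv"})

    all_terms = [frozenset(c) for r in range(1, len(within) + 1)
                 for c in itertools.combinations(within, r)]
    models = _marginality_closed_models(all_terms)

    bics = {}
    for model in models:
        rhs = " + ".join([f"C({subject})"] + [_term_formula(t) for t in sorted(
            model, key=lambda s: (len(s), _term_formula(s)))]) or f"C({subject})"
        fit = smf.ols(f"_dv ~ {rhs}", data=df).fit()
        bics[model] = fit.bic
    bmin = min(bics.values())
    weights = {m: math.exp(-(b - bmin) / 2) for m, b in bics.items()}

    out = {}
    for term in all_terms:
        supersets = [t for t in all_terms if term < t]
        with_term = [m for m in models
                     if term in m and not any(s in m for s in supersets)]
        num = sum(weights[m] for m in with_term)
        den = sum(weights[m - {term}] for m in with_term)
        name = ":".join(sorted(term, key=within.index))
        out[name] = float(np.log10(num / den))
    return out


# ---------------------------------------------------------------------------
# PCA with oblimin rotation
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    """Eigenstructure of the correlation matrix plus rotated loadings."""

    eigenvalues: np.ndarray
    n_components: int
    loadings: np.ndarray           # unrotated, variables x retained
    rotated_loadings: np.ndarray   # oblimin pattern matrix
    factor_correlations: np.ndarray
    variance_explained_pct: float
    variables: list[str]


def _oblimin_objective(L: np.ndarray, gamma: float):
    L2 = L ** 2
    p, k = L.shape
    N = np.ones((k, k)) - np.eye(k)
    X = L2 @ N
    if gamma != 0:
        X = (np.eye(p) - gamma / p * np.ones((p, p))) @ X
    return float((L2 * X).sum()) / 4.0, L * X


def _oblimin_rotate(A: np.ndarray, gamma: float = 0.0, max_iter: int = 1000,
                    tol: float = 1e-8):
    """Oblique gradient-projection rotation of loading matrix ``A``.

    Minimizes the direct-oblimin criterion (quartimin when gamma = 0).
    Returns (pattern matrix, factor correlation matrix).
    """
    k = A.shape[1]
    T = np.eye(k)
    L = A.copy()
    f, Gq = _oblimin_objective(L, gamma)
    G = -(L.T @ Gq @ np.linalg.inv(T)).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T * (T * G).sum(axis=0)
        s = np.sqrt((Gp ** 2).sum())
        if s < tol:
            break
        al *= 2.0
        for _ in range(60):
            X = T - al * Gp
            Tt = X / np.sqrt((X ** 2).sum(axis=0))
            Li = A @ np.linalg.inv(Tt).T
            ft, Gq = _oblimin_objective(Li, gamma)
            if ft < f - 0.5 * s * s * al:
                break
            al /= 2.0
        T, f, L = Tt, ft, Li
        G = -(L.T @ Gq @ np.linalg.inv(T)).T
    phi = T.T @ T
    return L, phi


def pca_oblimin(X, gamma: float = 0.0) -> PcaResult:
    """PCA on the correlation matrix, Kaiser retention, oblimin rotation.

    ``X`` is observations x variables (array or DataFrame). Components with
    eigenvalue > 1 are retained (at least one); when two or more are
    retained, their loadings are oblimin-rotated. Raises on constant
    columns, fewer than 2 variables, or n_obs <= n_vars.
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        names = [f"v{i}" for i in range(M.shape[1])]
    n, p = M.shape
    if p < 2:
        raise ValueError("need at least 2 variables")
    if n <= p:
        raise ValueError("need more observations than variables")
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = names[int(np.argmax(sd == 0))]
        raise ValueError(f"constant variable: {bad}")
    R = np.corrcoef(M, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    k = max(1, int((eigval > 1.0).sum()))
    loadings = eigvec[:, :k] * np.sqrt(eigval[:k])
    # fix sign convention: largest-magnitude loading positive per component
    signs = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    loadings = loadings * signs
    if k >= 2:
        rotated, phi = _oblimin_rotate(loadings, gamma=gamma)
        rsigns = np.sign(rotated[np.abs(rotated).argmax(axis=0), np.arange(k)])
        rotated = rotated * rsigns
        phi = phi * np.outer(rsigns, rsigns)
    else:
        rotated, phi = loadings.copy(), np.eye(1)
    return PcaResult(
        eigenvalues=eigval, n_components=k, loadings=loadings,
        rotated_loadings=rotated, factor_correlations=phi,
        variance_explained_pct=float(eigval[:k].sum() / p * 100.0),
        variables=names)


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

def _paired_t_power(n: int, d: float, alpha: float, tails: int) -> float:
    df = n - 1
    nc = d * math.sqrt(n)
    if tails == 2:
        tcrit = sps.t.ppf(1 - alpha / 2, df)
        lower = sps.nct.cdf(-tcrit, df, nc)  # nan at extreme nc where it is ~0
        return float(sps.nct.sf(tcrit, df, nc) + np.nan_to_num(lower))
    tcrit = sps.t.ppf(1 - alpha, df)
    return float(sps.nct.sf(tcrit, df, nc))


def required_sample_size(d: float, alpha: float, power: float,
                         tails: int = 2, max_n: int = 10 ** 6) -> int:
    """Smallest n whose paired/one-sample t test reaches the target power.

    Power is exact noncentral-t: P(|T| > t_crit) with noncentrality
    d * sqrt(n) at df = n - 1.
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    if d <= 0:
        raise ValueError("effect size must be > 0")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    n = 2
    while n <= max_n:
        if _paired_t_power(n, d, alpha, tails) >= power:
            return n
        n += 1
    raise ValueError(f"power {power} unreachable with n <= {max_n}")


def implied_effect_size(n: int, alpha: float, power: float,
                        tails: int = 2) -> float:
    """Effect size at which a paired t test with ``n`` subjects reaches
    exactly the target power (bisection on the noncentral-t power curve)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(brentq(lambda d: _paired_t_power(n, d, alpha, tails) - power,
                        1e-9, 20.0, xtol=1e-10))
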