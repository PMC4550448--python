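"""Nonparametric and categorical test battery.

The conventions follow the statistics packages classically used for this
kind of behavioral data: two-sided p-values throughout, tie-corrected normal
approximations *without* continuity correction, and for the Wilcoxon
signed-rank test a Z whose sign is negative when the first sample dominates
(Z = (mu_W - W+)/sigma), so that a preferred side with larger retention
times prints a negative Z.  Exact small-sample paths are provided and
flagged in the result.

Standard machinery (rank statistics, exact distributions, BH adjustment,
mixed models) is delegated to scipy / statsmodels; this module fixes the
conventions and packages results uniformly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "StatResult",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "kruskal_wallis",
    "chi_square",
    "binomial_test",
    "spearman",
    "levene",
    "fdr_adjust",
    "lmm_step_effect",
]


@dataclass
class StatResult:
    """Uniform container for one test result."""

    test: str
    statistic: float
    p: float
    n: tuple[int, ...]
    df: float | None = None
    z: float | None = None
    tie_corrected: bool = False
    exact: bool = False
    warning: str | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def _rank_ties(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Midranks and the tie-correction sum  Σ (t³ − t)."""
    ranks = stats.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    return ranks, float(np.sum(counts**3 - counts))


def mann_whitney_u(x, y) -> StatResult:
    """Two-sided Mann-Whitney U test.

    Reports U = min(U1, U2).  p is by exact enumeration when
    ``n1 * n2 <= 100`` and no ties are present, else by the tie-corrected
    normal approximation without continuity correction.  Identical constant
    samples give p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks, tie_sum = _rank_ties(pooled)
    u1 = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0)
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    has_ties = tie_sum > 0

    if np.ptp(pooled) == 0:
        return StatResult(
            "mann-whitney", u, 1.0, (n1, n2), z=0.0,
            warning="all values identical across both samples",
        )

    mu = n1 * n2 / 2.0
    nn = n1 + n2
    sigma2 = n1 * n2 / 12.0 * ((nn + 1) - tie_sum / (nn * (nn - 1)))
    z = (u1 - mu) / np.sqrt(sigma2) if sigma2 > 0 else 0.0

    if n1 * n2 <= 100 and not has_ties:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
        exact = True
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
        exact = False
    return StatResult(
        "mann-whitney", u, min(p, 1.0), (n1, n2), z=float(z),
        tie_corrected=has_ties, exact=exact, extras={"U1": u1, "U2": u2},
    )


def wilcoxon_signed_rank(x, y=None) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on pairs (or on differences).

    Zero differences are dropped.  Z = (mu_W - W+)/sigma with tie-corrected
    sigma and no continuity correction, so Z < 0 when x tends to exceed y
    (and flips sign when the samples are swapped).  An exact p is used when
    n <= 15 with no tied |differences|; all-zero differences give p = 1 with
    a warning.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    n = d.size
    if n == 0:
        return StatResult(
            "wilcoxon", 0.0, 1.0, (0,), z=0.0,
            warning="all differences zero; test degenerate",
        )
    ranks, tie_sum = _rank_ties(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    mu = n * (n + 1) / 4.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_sum / 48.0
    z = (mu - w_plus) / np.sqrt(sigma2) if sigma2 > 0 else 0.0
    has_ties = tie_sum > 0

    if n <= 15 and not has_ties:
        p = float(stats.wilcoxon(d, alternative="two-sided", method="exact").pvalue)
        exact = True
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
        exact = False
    return StatResult(
        "wilcoxon", w_plus, min(p, 1.0), (n,), z=float(z),
        tie_corrected=has_ties, exact=exact,
        extras={"W_plus": w_plus, "W_minus": n * (n + 1) / 2.0 - w_plus},
    )


def kruskal_wallis(*groups) -> StatResult:
    """Tie-corrected Kruskal-Wallis H with chi-squared p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be nonempty")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return StatResult(
            "kruskal-wallis", 0.0, 1.0, tuple(a.size for a in arrays),
            df=len(arrays) - 1, warning="all values identical",
        )
    h, p = stats.kruskal(*arrays)
    return StatResult(
        "kruskal-wallis", float(h), float(p), tuple(a.size for a in arrays),
        df=len(arrays) - 1, tie_corrected=True,
    )


def chi_square(table) -> StatResult:
    """Pearson chi-squared on a contingency table, no continuity correction.

    Expected cells below 1 set a warning flag rather than raising.
    """
    t = np.asarray(table, dtype=float)
    chi2, p, df, expected = stats.chi2_contingency(t, correction=False)
    warning = None
    if np.any(expected < 1.0):
        warning = "expected cell count below 1; chi-squared approximation unreliable"
    return StatResult(
        "chi-square", float(chi2), float(p), (int(t.sum()),), df=float(df),
        warning=warning, extras={"expected": expected},
    )


def binomial_test(k: int, n: int, p0: float = 0.5) -> StatResult:
    """Exact two-sided binomial test of k successes in n trials."""
    res = stats.binomtest(k, n, p0, alternative="two-sided")
    return StatResult(
        "binomial", float(k), float(res.pvalue), (n,), exact=True,
        extras={"proportion": k / n if n else np.nan, "p0": p0},
    )


def spearman(x, y) -> StatResult:
    """Spearman rank correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho, p = stats.spearmanr(x, y)
    return StatResult("spearman", float(rho), float(p), (x.size,))


def levene(*groups) -> StatResult:
    """Levene's test for equality of variances, centered on the mean."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    f, p = stats.levene(*arrays, center="mean")
    k, n = len(arrays), sum(a.size for a in arrays)
    return StatResult(
        "levene", float(f), float(p), tuple(a.size for a in arrays),
        df=float(k - 1), extras={"df_denom": n - k},
    )


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def lmm_step_effect(response, step_count, trial) -> StatResult:
    """Random-intercept linear mixed model: response ~ step_count + (1 | trial).

    Fit by REML (statsmodels MixedLM); the fixed slope is tested with a Wald
    z/F statistic.  With a single trial level, or when the random-effect
    variance is not identifiable, the model falls back to ordinary least
    squares with a warning flag.
    """
    import statsmodels.api as sm

    y = np.asarray(response, dtype=float)
    x = np.asarray(step_count, dtype=float)
    g = np.asarray(trial)
    exog = sm.add_constant(x)

    def _ols(reason: str) -> StatResult:
        fit = sm.OLS(y, exog).fit()
        f = float(fit.tvalues[1] ** 2)
        return StatResult(
            "lmm-step-effect", f, float(fit.pvalues[1]), (y.size,),
            df=float(fit.df_resid), warning=f"fell back to OLS: {reason}",
            extras={"slope": float(fit.params[1]), "method": "ols"},
        )

    if np.unique(g).size < 2:
        return _ols("single trial level")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, exog, groups=g)
            fit = model.fit(reml=True)
        slope = float(fit.fe_params[1])
        zval = float(fit.tvalues[1])
        pval = float(fit.pvalues[1])
        if not np.isfinite(pval):
            return _ols("non-identifiable variance")
        return StatResult(
            "lmm-step-effect", zval**2, pval, (y.size,), z=zval,
            extras={
                "slope": slope,
                "re_variance": float(np.asarray(fit.cov_re)[0, 0]),
                "method": "reml",
            },
        )
    except (np.linalg.LinAlgError, ValueError) as e:
        return _ols(str(e))
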