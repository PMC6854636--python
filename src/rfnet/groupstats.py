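"""Mean-level and descriptive group statistics.

Rank-based location tests (robust to the mild non-normality of factor
scores), contingency-table tests for the binarized scales and categorical
descriptives, Welch's t for unequal variances, Benjamini-Hochberg FDR
control across a family of mean comparisons, and a moderation fit testing
whether exposure-group membership modifies change between occasions.

Conventions follow R's ``wilcox.test`` (continuity correction, midranks
and tie-corrected variance in the normal approximation; exact enumeration
available for small samples) and the Yates-corrected chi-square for 2x2
tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError

__all__ = [
    "StatTestResult",
    "wilcoxon_ranksum_cc",
    "wilcoxon_signedrank_cc",
    "chisq_yates_2x2",
    "cochran_armitage_trend",
    "welch_t",
    "bh_fdr",
    "moderation_fit",
]


@dataclass
class StatTestResult:
    method: str
    statistic: float
    p: float
    df: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    estimate: float | None = None
    direction: int = 0
    flags: tuple[str, ...] = ()


def wilcoxon_ranksum_cc(
    x: np.ndarray, y: np.ndarray, exact: bool = False, alpha: float = 0.05
) -> StatTestResult:
    """Independent-sample Wilcoxon rank-sum test with continuity correction.

    The statistic is the Mann-Whitney U of the first sample (the ``W`` that
    R prints). The confidence interval for the location shift x - y is the
    Moses interval from the ordered pairwise differences, and the point
    estimate is the Hodges-Lehmann median difference. ``exact=True``
    switches to full enumeration (no ties supported there by scipy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DomainError("both samples must be non-empty")
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    nx, ny = len(x), len(y)
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    hl = float(np.median(diffs))
    sigma = np.sqrt(nx * ny * (nx + ny + 1) / 12.0)
    z = stats.norm.ppf(1 - alpha / 2)
    k = int(np.floor(nx * ny / 2.0 - z * sigma))
    k = max(k, 0)
    lo = float(diffs[k]) if k < len(diffs) else float(diffs[0])
    hi = float(diffs[len(diffs) - 1 - k]) if k < len(diffs) else float(diffs[-1])
    return StatTestResult(
        method=f"wilcoxon-ranksum-{method}",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        ci_low=lo,
        ci_high=hi,
        estimate=hl,
        direction=int(np.sign(hl)),
    )


def _signedrank_exact_p(ranks: np.ndarray, v_obs: float) -> float:
    """Exact two-sided p for the signed-rank statistic by enumerating the
    distribution of positive-rank sums (dynamic programming over doubled
    ranks so midranks stay integral)."""
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    v2 = int(round(2 * v_obs))
    p_ge = dist[v2:].sum()
    p_le = dist[: v2 + 1].sum()
    return float(min(1.0, 2 * min(p_ge, p_le)))


def wilcoxon_signedrank_cc(
    x_t1: np.ndarray, x_t2: np.ndarray, exact: bool = False, alpha: float = 0.05
) -> StatTestResult:
    """Paired Wilcoxon signed-rank test with continuity correction.

    ``V`` is the sum of positive-difference midranks after dropping zero
    differences (R's convention). The asymptotic p uses the tie-corrected
    normal approximation with a 0.5 continuity correction; ``exact=True``
    enumerates the permutation distribution. The location CI comes from
    the Walsh averages of the differences.
    """
    x_t1 = np.asarray(x_t1, dtype=float)
    x_t2 = np.asarray(x_t2, dtype=float)
    if x_t1.shape != x_t2.shape:
        raise DomainError("paired samples must have equal length")
    d = x_t1 - x_t2
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DomainError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if exact:
        p = _signedrank_exact_p(ranks, v)
    else:
        if var <= 0:
            raise DomainError("zero variance in signed-rank statistic")
        delta = v - mu
        cc = 0.5 * np.sign(delta)
        z = (delta - cc) / np.sqrt(var)
        p = float(min(1.0, 2 * stats.norm.sf(abs(z))))
    walsh = np.sort(((d[:, None] + d[None, :]) / 2.0)[np.triu_indices(n)])
    hl = float(np.median(walsh))
    zq = stats.norm.ppf(1 - alpha / 2)
    k = max(int(np.floor(n * (n + 1) / 4.0 - zq * np.sqrt(var))), 0)
    lo = float(walsh[min(k, len(walsh) - 1)])
    hi = float(walsh[max(len(walsh) - 1 - k, 0)])
    return StatTestResult(
        method=f"wilcoxon-signedrank-{'exact' if exact else 'asymptotic'}",
        statistic=v,
        p=p,
        ci_low=lo,
        ci_high=hi,
        estimate=hl,
        direction=int(np.sign(hl)),
    )


def chisq_yates_2x2(table) -> StatTestResult:
    """Yates-continuity-corrected chi-square for a 2x2 table (df = 1).

    The correction subtracts at most |O - E| from each cell deviation, so
    a perfectly proportional table gives exactly zero.
    """
    T = np.asarray(table, dtype=float)
    if T.shape != (2, 2):
        raise DomainError("expected a 2x2 table")
    if (T < 0).any() or not np.allclose(T, np.round(T)):
        raise DomainError("table entries must be nonnegative integers")
    if (T.sum(axis=0) == 0).any() or (T.sum(axis=1) == 0).any():
        raise DomainError("zero margin in 2x2 table")
    chi2, p, df, expected = stats.chi2_contingency(T, correction=True)
    return StatTestResult(method="chisq-yates", statistic=float(chi2), p=float(p), df=1.0)


def cochran_armitage_trend(table, scores=None) -> StatTestResult:
    """Asymptotic Cochran-Armitage test for trend across k ordered columns.

    Linear-by-linear statistic ``z = (T - E[T]) / sqrt(Var[T])`` with the
    hypergeometric (fixed-margins) variance; two-sided normal p.
    """
    T = np.asarray(table, dtype=float)
    if T.ndim != 2 or T.shape[0] != 2 or T.shape[1] < 3:
        raise DomainError("expected a 2 x k table with k >= 3")
    k = T.shape[1]
    s = np.asarray(scores if scores is not None else np.arange(1, k + 1), dtype=float)
    n1 = T[0].sum()
    n2 = T[1].sum()
    N = n1 + n2
    col = T.sum(axis=0)
    if n1 == 0 or n2 == 0 or N <= 1 or np.count_nonzero(col) < 2:
        raise DomainError("degenerate margins in trend table")
    t_obs = float((s * T[0]).sum())
    e_t = n1 * float((s * col).sum()) / N
    var = n1 * n2 / (N**2 * (N - 1)) * (N * float((s**2 * col).sum()) - float((s * col).sum()) ** 2)
    if var <= 0:
        raise DomainError("zero variance in trend statistic")
    z = (t_obs - e_t) / np.sqrt(var)
    p = float(min(1.0, 2 * stats.norm.sf(abs(z))))
    return StatTestResult(method="cochran-armitage", statistic=float(z), p=p, direction=int(np.sign(z)))


def welch_t(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> StatTestResult:
    """Welch's two-sided t test with Satterthwaite degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DomainError("both samples need at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise DomainError("zero variance in both samples")
    res = stats.ttest_ind(x, y, equal_var=False)
    se = np.sqrt(vx / len(x) + vy / len(y))
    df = float(res.df)
    tq = stats.t.ppf(1 - alpha / 2, df)
    diff = x.mean() - y.mean()
    return StatTestResult(
        method="welch-t",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        df=df,
        ci_low=float(diff - tq * se),
        ci_high=float(diff + tq * se),
        estimate=float(diff),
        direction=int(np.sign(diff)),
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def moderation_fit(
    score: np.ndarray,
    age_indicator: np.ndarray,
    group_indicator: np.ndarray,
    subject_id: np.ndarray | None = None,
    cluster_robust: bool = True,
) -> StatTestResult:
    """Does group membership moderate change between occasions?

    Fits ``score ~ age + group + age x group`` on the long-format panel.
    Continuous outcomes use a linear model and report the interaction
    coefficient b; binary outcomes switch to a logistic link and report the
    interaction odds ratio. Standard errors are cluster-robust by subject
    by default (each subject contributes both occasions).
    """
    yv = np.asarray(score, dtype=float)
    age = np.asarray(age_indicator, dtype=float)
    grp = np.asarray(group_indicator, dtype=float)
    if not (len(yv) == len(age) == len(grp)):
        raise DomainError("inputs must have equal length")
    X = sm.add_constant(np.column_stack([age, grp, age * grp]))
    binary = np.isin(np.unique(yv), (0.0, 1.0)).all()
    cov_kw: dict = {}
    if cluster_robust:
        if subject_id is None:
            raise DomainError("cluster-robust errors need subject_id")
        import pandas as pd

        groups = pd.factorize(np.asarray(subject_id))[0]
        cov_kw = {"cov_type": "cluster", "cov_kwds": {"groups": groups}}
    flags: tuple[str, ...] = ()
    if binary:
        model = sm.GLM(yv, X, family=sm.families.Binomial())
        try:
            fit = model.fit(**cov_kw)
        except Exception as exc:
            raise DomainError(f"logistic moderation fit failed: {exc}") from exc
        b = float(fit.params[3])
        p = float(fit.pvalues[3])
        if abs(b) > 15:
            flags = ("possible-separation",)
        return StatTestResult(
            method="moderation-logit",
            statistic=float(np.exp(b)),
            p=p,
            estimate=b,
            direction=int(np.sign(b)),
            flags=flags,
        )
    fit = sm.OLS(yv, X).fit(**cov_kw)
    b = float(fit.params[3])
    return StatTestResult(
        method="moderation-linear",
        statistic=b,
        p=float(fit.pvalues[3]),
        estimate=b,
        ci_low=float(fit.conf_int()[3][0]),
        ci_high=float(fit.conf_int()[3][1]),
        direction=int(np.sign(b)),
    )
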