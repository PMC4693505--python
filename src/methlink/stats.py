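"""Statistical primitives shared by every pipeline stage.

All hypothesis tests used downstream (differential methylation, enrichment,
methylation--expression correlation, moderated differential expression) are
funnelled through this module so that their exact conventions -- two-sided
definitions, tie handling, FDR family boundaries -- are fixed in one place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "ModerationFit",
    "wilcoxon_rank_sum",
    "bh_fdr",
    "fisher_exact_2x2",
    "correlate",
    "moderated_two_group_test",
    "EXACT_WILCOXON_MAX_N",
]

#: Combined sample size up to which the rank-sum test is computed exactly.
#: Enumeration is cheap here (C(14,4) = 1001 arrangements for a 10-vs-4
#: design) and covers the small-cohort layouts this pipeline targets.
EXACT_WILCOXON_MAX_N = 14


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``method`` records whether the p-value came from an exact (enumerative)
    null distribution or a large-sample approximation.
    """

    statistic: float
    p_value: float
    method: str  # "exact" | "approx"


@dataclass
class ModerationFit:
    """Empirical-Bayes variance moderation parameters.

    ``d0`` (prior degrees of freedom, possibly ``inf``) and ``s0_sq`` (prior
    variance) define the inverse-chi-square prior the per-gene sample
    variances are shrunk toward; ``posterior_var`` holds the resulting
    per-gene posterior variances.
    """

    d0: float
    s0_sq: float
    posterior_var: np.ndarray = field(repr=False)


def _as_1d(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must contain only finite values")
    return arr


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test for two groups.

    Exact p-value by enumeration of rank assignments when the combined
    sample size is at most ``EXACT_WILCOXON_MAX_N`` and there are no ties;
    otherwise a normal approximation with average-rank tie correction and
    continuity correction.  The reported statistic is the rank sum W of the
    first group.
    """
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    n1, n2 = xa.size, ya.size
    combined = np.concatenate([xa, ya])
    ranks = sps.rankdata(combined)
    w = float(ranks[:n1].sum())
    if np.all(combined == combined[0]):
        return TestResult(statistic=w, p_value=1.0, method="approx")
    has_ties = np.unique(combined).size < combined.size
    if n1 + n2 <= EXACT_WILCOXON_MAX_N and not has_ties:
        res = sps.mannwhitneyu(xa, ya, alternative="two-sided", method="exact")
        return TestResult(statistic=w, p_value=float(res.pvalue), method="exact")
    res = sps.mannwhitneyu(
        xa, ya, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    p = float(res.pvalue)
    if math.isnan(p):  # zero variance after tie correction
        p = 1.0
    return TestResult(statistic=w, p_value=min(p, 1.0), method="approx")


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Missing entries propagate as missing and do not count toward the family
    size.  Output is clipped to 1 and satisfies q >= p elementwise.
    """
    arr = np.asarray(p, dtype=float).ravel()
    mask = ~np.isnan(arr)
    if np.any((arr[mask] < 0) | (arr[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(arr, np.nan)
    if mask.sum() > 0:
        q[mask] = multipletests(arr[mask], method="fdr_bh")[1]
    return q


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[TestResult, float]:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    The two-sided p sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed that of the observed
    table (minimum-likelihood rule).  The odds ratio is the sample odds
    ratio a*d / (b*c), reported as ``inf`` when b*c = 0 and a*d > 0 and
    ``nan`` when both products vanish.
    """
    counts = (a, b, c, d)
    if any(int(v) != v or v < 0 for v in counts):
        raise ValueError("table entries must be nonnegative integers")
    a, b, c, d = (int(v) for v in counts)
    res = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        oddsratio = math.inf if a * d > 0 else math.nan
    else:
        oddsratio = (a * d) / (b * c)
    return TestResult(statistic=float(a), p_value=float(res.pvalue), method="exact"), oddsratio


def correlate(x, y, method: str = "spearman") -> tuple[TestResult, float]:
    """Correlation coefficient with a t-distribution p-value (n-2 df).

    Spearman ranks both vectors with average ranks for ties and then applies
    the Pearson formula to the ranks.  Constant input yields an undefined
    coefficient (``nan``) with a missing p-value.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method: {method!r}")
    xa = _as_1d(x, "x")
    ya = _as_1d(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    n = xa.size
    if n < 3:
        raise ValueError("correlation requires at least 3 observations")
    if method == "spearman":
        xa = sps.rankdata(xa)
        ya = sps.rankdata(ya)
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return TestResult(statistic=math.nan, p_value=math.nan, method="approx"), math.nan
    r = float(np.corrcoef(xa, ya)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
        t = math.inf if r > 0 else -math.inf
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return TestResult(statistic=t, p_value=p, method="approx"), r


# ---------------------------------------------------------------------------
# Empirical-Bayes moderated two-group test
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    # Newton iteration for psi'(x) = y; y > 0.  Monotone decreasing target.
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from observed log sample variances.

    Under the scaled-F model, e_g = log(s_g^2) - digamma(d/2) + log(d/2) has
    mean log(s0^2) + digamma(d0/2) - log(d0/2) and excess variance
    trigamma(d0/2) beyond trigamma(d/2); d0 follows by trigamma inversion.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return math.inf, float(np.mean(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    emean = float(e.mean())
    n = e.size
    evar = float(np.sum((e - emean) ** 2) / (n - 1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        d0 = math.inf
        s0_sq = math.exp(emean)
    else:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return d0, s0_sq


def moderated_two_group_test(
    expr,
    groups,
    case: str | None = None,
    control: str | None = None,
    prior_df: float | None = None,
) -> tuple[pd.DataFrame, ModerationFit]:
    """Per-gene moderated t-test between two groups of samples.

    Pools the within-group variance per gene, shrinks it toward an
    inverse-chi-square prior (d0, s0^2) estimated from all genes by
    digamma/trigamma moment matching, and tests the group mean difference
    against the posterior standard error on d0 + d_g degrees of freedom.

    Parameters
    ----------
    expr : DataFrame, genes x samples.
    groups : sequence of group labels aligned with the columns of ``expr``.
    case, control : the two labels; ``log2fc`` is mean(case) - mean(control).
        Default: first and second label in order of appearance.
    prior_df : force d0 to this value instead of estimating it (0 recovers
        the ordinary equal-variance t-test; ``inf`` tests every gene against
        the common prior variance).

    Returns
    -------
    (table, fit) where table has columns log2fc, t, df, p indexed by gene.
    """
    expr = pd.DataFrame(expr)
    labels = pd.Series(list(groups), index=expr.columns)
    uniq = list(dict.fromkeys(labels))
    if case is None or control is None:
        if len(uniq) != 2:
            raise ValueError("expected exactly two group labels")
        case, control = uniq[0], uniq[1]
    case_cols = labels.index[labels == case]
    ctrl_cols = labels.index[labels == control]
    n1, n2 = len(case_cols), len(ctrl_cols)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")

    xc = expr[case_cols].to_numpy(dtype=float)
    xk = expr[ctrl_cols].to_numpy(dtype=float)
    m1 = xc.mean(axis=1)
    m2 = xk.mean(axis=1)
    df_resid = n1 + n2 - 2
    ss = ((xc - m1[:, None]) ** 2).sum(axis=1) + ((xk - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if prior_df is None:
        if expr.shape[0] < 10:
            raise ValueError("prior estimation requires at least 10 genes")
        d0, s0_sq = _fit_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        _, s0_sq = _fit_variance_prior(s2, df_resid) if d0 > 0 else (None, float(np.mean(s2)))

    if math.isinf(d0):
        post_var = np.full_like(s2, s0_sq)
    elif d0 == 0:
        post_var = s2.copy()
    else:
        post_var = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)

    diff = m1 - m2
    se = np.sqrt(post_var * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    total_df = d0 + df_resid
    if math.isinf(total_df):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df=total_df)
    p = np.where(np.isnan(t), np.nan, p)

    table = pd.DataFrame(
        {"log2fc": diff, "t": t, "df": total_df, "p": p}, index=expr.index
    )
    return table, ModerationFit(d0=d0, s0_sq=float(s0_sq), posterior_var=post_var)
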