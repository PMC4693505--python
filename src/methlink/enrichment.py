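"""Category, TFBS and TF-network enrichment analyses.

Enrichment of a foreground probe set (e.g. hypermethylated DMCpGs) against
a background (all probes surviving QC) is quantified per category by the
log2 ratio of foreground to background proportions and a Fisher exact test
on the 2x2 table foreground-in/out vs (background minus foreground)-in/out,
with BH correction across the categories of one annotation field (or
across TFs within one direction).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .stats import bh_fdr, correlate, fisher_exact_2x2

logger = logging.getLogger(__name__)

__all__ = [
    "category_enrichment",
    "tfbs_enrichment",
    "tf_enhancer_methylation_correlation",
    "tf_network_matrix",
]


def _log2_ratio(fg_prop: float, bg_prop: float) -> float:
    if fg_prop > 0 and bg_prop > 0:
        return math.log2(fg_prop / bg_prop)
    if fg_prop == 0 and bg_prop == 0:
        return math.nan
    return -math.inf if fg_prop == 0 else math.inf


def _enrich_one(fg_in: int, fg_total: int, bg_in: int, bg_total: int) -> dict:
    """One enrichment record; comparison column is background minus foreground."""
    rest_in = bg_in - fg_in
    rest_total = bg_total - fg_total
    test, _ = fisher_exact_2x2(
        fg_in, fg_total - fg_in, rest_in, rest_total - rest_in
    )
    fg_prop = fg_in / fg_total
    bg_prop = bg_in / bg_total
    return {
        "fg_count": fg_in,
        "fg_total": fg_total,
        "bg_count": bg_in,
        "bg_total": bg_total,
        "fg_prop": fg_prop,
        "bg_prop": bg_prop,
        "log2_ratio": _log2_ratio(fg_prop, bg_prop),
        "p": test.p_value,
    }


def _membership(annotations: pd.DataFrame, field: str) -> pd.Series:
    """Per-probe set of category labels for one annotation field."""
    col = annotations[field]
    return col.apply(lambda v: v if isinstance(v, (set, frozenset)) else {v})


def category_enrichment(
    fg_probes,
    bg_probes,
    annotations: pd.DataFrame,
    field: str,
) -> pd.DataFrame:
    """Enrichment of the foreground set in each category of ``field``.

    Membership is any-membership: a probe counts once per category it
    touches.  Requires fg to be a subset of bg; BH across the categories.
    """
    fg = pd.Index(fg_probes)
    bg = pd.Index(bg_probes)
    if len(fg) == 0:
        raise ValueError("empty foreground set")
    if not fg.isin(bg).all():
        raise ValueError("foreground must be a subset of the background")
    member = _membership(annotations, field)
    cats = sorted(set().union(*member.loc[bg]))
    rows = {}
    fg_member = member.loc[fg]
    bg_member = member.loc[bg]
    for cat in cats:
        fg_in = int(fg_member.apply(lambda s: cat in s).sum())
        bg_in = int(bg_member.apply(lambda s: cat in s).sum())
        rows[cat] = _enrich_one(fg_in, len(fg), bg_in, len(bg))
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = field
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def tfbs_enrichment(
    hyper_probes,
    hypo_probes,
    bg_probes,
    annotations: pd.DataFrame,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-TF, per-direction binding-site enrichment of DMCpG sets.

    A probe belongs to a TF when it overlaps at least one of that TF's
    binding-site cluster intervals (binary membership).  The proportion of
    member probes in each direction's DMCpG list is compared against the
    background proportion with a Fisher test; BH runs across TFs within
    each direction.  TFs overlapping no background probe are excluded
    (logged).
    """
    bg = pd.Index(bg_probes)
    tf_sets = annotations.loc[bg, "tf_overlaps"]
    all_tfs = sorted(set().union(*tf_sets))
    bg_counts = {tf: 0 for tf in all_tfs}
    for s in tf_sets:
        for tf in s:
            bg_counts[tf] += 1
    absent = [tf for tf in all_tfs if bg_counts[tf] == 0]
    if absent:
        logger.info("excluding %d TFs with no probe overlap: %s", len(absent), absent)
    tfs = [tf for tf in all_tfs if bg_counts[tf] > 0]

    frames = []
    for direction, probes in (("hyper", hyper_probes), ("hypo", hypo_probes)):
        fg = pd.Index(probes)
        fg_sets = annotations.loc[fg, "tf_overlaps"]
        rows = {}
        for tf in tfs:
            fg_in = int(fg_sets.apply(lambda s: tf in s).sum())
            rows[tf] = _enrich_one(fg_in, len(fg), bg_counts[tf], len(bg))
        tab = pd.DataFrame.from_dict(rows, orient="index")
        tab["q"] = bh_fdr(tab["p"].to_numpy())
        tab["significant"] = tab["q"] < q_threshold
        tab.insert(0, "direction", direction)
        tab.index.name = "tf"
        frames.append(tab)
    return pd.concat(frames)


def tf_enhancer_methylation_correlation(
    tf_expr: pd.DataFrame,
    enhancer_sites,
    beta: pd.DataFrame,
    samples=None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Spearman association of TF expression with average enhancer methylation.

    The per-sample average beta over the (non-empty) enhancer site set is
    correlated with each TF's expression across samples; BH across TFs.
    Returns the per-TF table and the average-methylation profile.
    """
    sites = pd.Index(enhancer_sites)
    if len(sites) == 0:
        raise ValueError("empty enhancer site set")
    if samples is None:
        samples = [s for s in tf_expr.columns if s in beta.columns]
    samples = list(samples)
    avg_meth = beta.loc[sites, samples].mean(axis=0)
    rows = {}
    for tf in tf_expr.index:
        res, rho = correlate(
            avg_meth.to_numpy(), tf_expr.loc[tf, samples].to_numpy(), method="spearman"
        )
        rows[tf] = {"rho": rho, "p": res.p_value}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "tf"
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out, avg_meth


def tf_network_matrix(tf_expr: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation matrix of TF expression profiles.

    Returns (r, p): r is symmetric with unit diagonal; p is symmetric with
    a missing diagonal.  Constant TFs yield missing rows/columns.
    """
    if tf_expr.shape[1] < 3:
        raise ValueError("TF network requires >= 3 samples")
    if tf_expr.shape[0] < 2:
        raise ValueError("TF network requires >= 2 TFs")
    tfs = list(tf_expr.index)
    n = len(tfs)
    r = np.full((n, n), np.nan)
    p = np.full((n, n), np.nan)
    np.fill_diagonal(r, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            res, rij = correlate(
                tf_expr.iloc[i].to_numpy(), tf_expr.iloc[j].to_numpy(), method="pearson"
            )
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = res.p_value
    for i in range(n):
        if np.all(tf_expr.iloc[i].to_numpy() == tf_expr.iloc[i].to_numpy()[0]):
            r[i, :] = r[:, i] = np.nan
    return (
        pd.DataFrame(r, index=tfs, columns=tfs),
        pd.DataFrame(p, index=tfs, columns=tfs),
    )
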