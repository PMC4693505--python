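"""Methylation-expression integration.

Differentially methylated probes are paired with the genes they annotate
to (one pair per probe-gene combination whose gene is present in the
expression matrix), each pair's beta values are correlated with the gene's
expression across the shared samples (Spearman), and the BH correction is
applied over the full pair set.  Sign classification (inverse vs positive
association) is reported for significant pairs only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import bh_fdr, correlate

__all__ = ["pair_probes_genes", "correlate_meth_expr", "summarize_correlations"]


def pair_probes_genes(
    dm_probes,
    annotations: pd.DataFrame,
    expr_genes,
) -> pd.DataFrame:
    """Probe-gene pair skeletons from shared gene annotations.

    One row per (probe, annotated gene) with the gene measured in the
    expression data.  Probes with several gene annotations contribute
    several pairs; intergenic probes contribute none.  Output ordering is
    deterministic (sorted by probe then gene).
    """
    expr_genes = set(expr_genes)
    rows = []
    for probe in dm_probes:
        for gene in sorted(annotations.loc[probe, "gene_ids"]):
            if gene in expr_genes:
                rows.append((probe, gene))
    rows.sort()
    return pd.DataFrame(rows, columns=["probe_id", "gene_id"])


def correlate_meth_expr(
    pairs: pd.DataFrame,
    beta: pd.DataFrame,
    expr: pd.DataFrame,
    samples,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of beta vs expression for each probe-gene pair.

    Correlations run over the given shared samples; BH adjustment spans the
    full pair set.  ``sign_class`` is ``inverse`` (rho < 0) or ``positive``
    for pairs with q < threshold, missing otherwise.
    """
    samples = list(samples)
    if len(samples) < 3:
        raise ValueError("correlation requires >= 3 shared samples")
    rhos = np.empty(len(pairs))
    ps = np.empty(len(pairs))
    bvals = beta.loc[:, samples]
    evals = expr.loc[:, samples]
    for i, (probe, gene) in enumerate(zip(pairs["probe_id"], pairs["gene_id"])):
        res, rho = correlate(
            bvals.loc[probe].to_numpy(dtype=float),
            evals.loc[gene].to_numpy(dtype=float),
            method="spearman",
        )
        rhos[i] = rho
        ps[i] = res.p_value
    out = pairs.copy()
    out["rho"] = rhos
    out["p"] = ps
    out["q"] = bh_fdr(ps)
    significant = out["q"] < q_threshold
    out["sign_class"] = pd.Series(
        np.where(out["rho"] < 0, "inverse", "positive"), index=out.index
    ).where(significant.fillna(False))
    return out


def summarize_correlations(
    pairs: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
) -> dict:
    """Summaries of significant pairs by sign, gene region and chromatin.

    Region and chromatin counts use probe-level any-membership (a probe
    counts once per category it touches).  Alongside pair counts the number
    of unique correlating probes and genes is reported.
    """
    sig = pairs.dropna(subset=["sign_class"])
    by_sign = sig["sign_class"].value_counts().reindex(
        ["inverse", "positive"], fill_value=0
    )
    total = int(by_sign.sum())
    summary = {
        "n_pairs_total": len(pairs),
        "n_pairs_significant": total,
        "n_unique_probes": sig["probe_id"].nunique(),
        "n_unique_genes": sig["gene_id"].nunique(),
        "by_sign": pd.DataFrame(
            {
                "n_pairs": by_sign,
                "fraction": by_sign / total if total else np.nan,
            }
        ),
    }
    if annotations is not None and total:
        uniq = sig.drop_duplicates("probe_id").set_index("probe_id")
        region_counts: dict[str, int] = {}
        chromatin_counts: dict[str, int] = {}
        for probe in uniq.index:
            for lab in annotations.loc[probe, "gene_region_labels"]:
                region_counts[lab] = region_counts.get(lab, 0) + 1
            cat = annotations.loc[probe, "chromatin_category"]
            chromatin_counts[cat] = chromatin_counts.get(cat, 0) + 1
        summary["by_gene_region"] = pd.Series(region_counts).sort_index()
        summary["by_chromatin"] = pd.Series(chromatin_counts).sort_index()
    return summary
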