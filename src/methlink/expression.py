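"""Gene filtering, moderated differential expression and qPCR quantities.

The expression pipeline starts from a processed log2 gene x sample matrix.
Genes are filtered on overall signal and variability (median cutoffs, in
that order), differential expression uses the empirical-Bayes moderated
t-test from :mod:`methlink.stats`, and the delta-delta-Ct helpers provide
relative quantification and cross-platform concordance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import bh_fdr, correlate, moderated_two_group_test

logger = logging.getLogger(__name__)

__all__ = [
    "filter_genes",
    "call_degs",
    "ddct_fold_change",
    "platform_concordance",
]


def filter_genes(
    expr: pd.DataFrame,
    groups=None,
    mean_mode: str = "overall",
) -> pd.DataFrame:
    """Drop low-signal then low-variability genes at their median cutoffs.

    Step 1 removes genes whose mean signal is strictly below the median of
    all gene means; step 2 removes genes whose SD is strictly below the
    median SD of the genes surviving step 1.  With ``mean_mode="group_max"``
    step 1 uses the larger of the two group means (requires ``groups``
    aligned with the columns).
    """
    if expr.shape[1] < 2:
        raise ValueError("gene filtering requires at least 2 samples")
    if mean_mode == "overall":
        means = expr.mean(axis=1)
    elif mean_mode == "group_max":
        if groups is None:
            raise ValueError("group_max mode requires group labels")
        labels = pd.Series(list(groups), index=expr.columns)
        means = pd.concat(
            [expr[labels.index[labels == g]].mean(axis=1) for g in labels.unique()],
            axis=1,
        ).max(axis=1)
    else:
        raise ValueError(f"unknown mean_mode {mean_mode!r}")
    keep = expr.loc[means >= means.median()]
    logger.info("mean filter: %d -> %d genes", expr.shape[0], keep.shape[0])
    sds = keep.std(axis=1, ddof=1)
    out = keep.loc[sds >= sds.median()]
    logger.info("SD filter: %d -> %d genes", keep.shape[0], out.shape[0])
    return out


def call_degs(
    expr: pd.DataFrame,
    groups,
    case: str | None = None,
    control: str | None = None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Moderated differential expression with BH correction across genes.

    Returns per-gene ``log2fc`` (case - control), moderated ``t``, ``df``,
    ``p``, ``q``, ``direction`` and ``called`` (q < threshold, strict).
    """
    table, fit = moderated_two_group_test(expr, groups, case=case, control=control)
    table = table.copy()
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["direction"] = np.where(table["log2fc"] > 0, "up", "down")
    table["called"] = (table["q"] < q_threshold).fillna(False)
    table.attrs["moderation_d0"] = fit.d0
    table.attrs["moderation_s0_sq"] = fit.s0_sq
    return table


def ddct_fold_change(
    ct: pd.DataFrame,
    target: str,
    case_samples,
    calibrator_samples,
) -> dict:
    """Relative quantification of one target assay by the delta-delta-Ct rule.

    ``ct`` is a long table with columns ``sample``, ``assay``, ``role``
    (``target`` | ``endogenous_control``) and ``ct``.  Per sample,
    dCt = Ct(target) - mean Ct(endogenous controls); ddCt is the case-group
    mean dCt minus the calibrator-group mean; log2 fold change = -ddCt.
    """
    required = {"sample", "assay", "role", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    controls = ct.loc[ct["role"] == "endogenous_control"]
    if controls.empty:
        raise ValueError("no endogenous control assays in Ct table")
    tgt = ct.loc[(ct["assay"] == target) & (ct["role"] == "target")]
    tgt_ct = tgt.set_index("sample")["ct"]
    ctrl_ct = controls.groupby("sample")["ct"].mean()

    def group_dct(samples) -> pd.Series:
        samples = list(samples)
        for s in samples:
            if s not in tgt_ct.index:
                raise ValueError(f"sample {s!r} lacks a Ct for target {target!r}")
            if s not in ctrl_ct.index:
                raise ValueError(f"sample {s!r} lacks endogenous control Cts")
        return tgt_ct.loc[samples] - ctrl_ct.loc[samples]

    dct_case = group_dct(case_samples)
    dct_cal = group_dct(calibrator_samples)
    ddct = float(dct_case.mean() - dct_cal.mean())
    return {
        "ddct": ddct,
        "log2fc": -ddct,
        "fold_change": 2.0 ** (-ddct),
        "dct_case": dct_case,
        "dct_calibrator": dct_cal,
    }


def platform_concordance(log2fc_a: pd.Series, log2fc_b: pd.Series) -> dict:
    """Pearson concordance of two per-gene fold-change vectors.

    Vectors are matched on gene id; at least 3 shared genes are required.
    Returns r, r squared and the two-sided p-value.
    """
    shared = log2fc_a.index.intersection(log2fc_b.index)
    if len(shared) < 3:
        raise ValueError("platform concordance requires >= 3 shared genes")
    res, r = correlate(
        log2fc_a.loc[shared].to_numpy(),
        log2fc_b.loc[shared].to_numpy(),
        method="pearson",
    )
    return {"r": r, "r_squared": r * r, "p": res.p_value, "n_genes": len(shared)}
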