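"""Differential methylation calling and differentiation remodeling.

A CpG is called differentially methylated (DMCpG) between two groups when
the absolute difference of group mean beta values strictly exceeds the
delta threshold (default 0.25) AND the BH-adjusted rank-test p-value is
strictly below the q threshold (default 0.05), the FDR family being all
probes tested in that comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import EXACT_WILCOXON_MAX_N, bh_fdr, wilcoxon_rank_sum

__all__ = [
    "ComparisonSpec",
    "delta_beta",
    "call_dmcpgs",
    "overlap_sets",
    "remodeling_classification",
    "remodeling_summary",
]


@dataclass(frozen=True)
class ComparisonSpec:
    """A named case-vs-control contrast within one cell stage."""

    name: str
    case_group: str
    control_group: str
    cell_stage: str | None = None


def delta_beta(beta: pd.DataFrame, case_samples, control_samples) -> pd.Series:
    """Per-probe difference of group mean betas, mean(case) - mean(control).

    Missing values are excluded per group; a probe entirely missing in a
    group yields a missing difference.
    """
    case_samples = list(case_samples)
    control_samples = list(control_samples)
    if not case_samples or not control_samples:
        raise ValueError("each group needs at least one sample")
    return beta[case_samples].mean(axis=1) - beta[control_samples].mean(axis=1)


def _rowwise_wilcoxon(case: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    """Two-sided rank-test p per row, matching `stats.wilcoxon_rank_sum`.

    Fast path: rows with complete data and no ties are tested in one
    vectorized exact call when the combined group size permits enumeration;
    remaining rows fall back to the scalar kernel.
    """
    n1, n2 = case.shape[1], ctrl.shape[1]
    nrow = case.shape[0]
    p = np.full(nrow, np.nan)
    combined = np.concatenate([case, ctrl], axis=1)
    complete = ~np.isnan(combined).any(axis=1)
    srt = np.sort(combined[complete], axis=1)
    tied = (np.diff(srt, axis=1) == 0).any(axis=1) if srt.size else np.array([], bool)
    constant = (
        (combined[complete] == combined[complete][:, :1]).all(axis=1)
        if srt.size
        else np.array([], bool)
    )
    fast = np.zeros(nrow, dtype=bool)
    if n1 + n2 <= EXACT_WILCOXON_MAX_N:
        fast[np.flatnonzero(complete)[~tied & ~constant]] = True
    if fast.any():
        res = sps.mannwhitneyu(
            case[fast], ctrl[fast], axis=1, alternative="two-sided", method="exact"
        )
        p[fast] = res.pvalue
    for i in np.flatnonzero(~fast):
        x = case[i][~np.isnan(case[i])]
        y = ctrl[i][~np.isnan(ctrl[i])]
        if x.size == 0 or y.size == 0:
            continue
        p[i] = wilcoxon_rank_sum(x, y).p_value
    return p


def call_dmcpgs(
    beta: pd.DataFrame,
    case_samples,
    control_samples,
    delta_threshold: float = 0.25,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-probe DMCpG table: delta_beta, p, q, direction, called.

    ``called`` requires |delta_beta| > delta_threshold (strict) and BH q <
    q_threshold (strict); ``direction`` is ``hyper`` iff delta_beta > 0.
    """
    case_samples = list(case_samples)
    control_samples = list(control_samples)
    delta = delta_beta(beta, case_samples, control_samples)
    p = _rowwise_wilcoxon(
        beta[case_samples].to_numpy(dtype=float),
        beta[control_samples].to_numpy(dtype=float),
    )
    q = bh_fdr(p)
    out = pd.DataFrame(
        {
            "delta_beta": delta,
            "p": p,
            "q": q,
            "direction": np.where(delta > 0, "hyper", "hypo"),
        },
        index=beta.index,
    )
    out["called"] = (
        (out["delta_beta"].abs() > delta_threshold) & (out["q"] < q_threshold)
    ).fillna(False)
    return out


def overlap_sets(dm_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise (and 3-way) overlap of called DMCpG sets across comparisons.

    For every ordered pair (A, B): intersection size, its share of |A| and
    of |B|, and the direction-concordant intersection size.
    """
    called = {
        name: tab.index[tab["called"]]
        for name, tab in dm_tables.items()
    }
    dirs = {
        name: tab.loc[called[name], "direction"] for name, tab in dm_tables.items()
    }
    rows = []
    names = list(dm_tables)
    for a in names:
        for b in names:
            if a == b:
                continue
            inter = called[a].intersection(called[b])
            concordant = int((dirs[a].loc[inter] == dirs[b].loc[inter]).sum())
            rows.append(
                {
                    "set_a": a,
                    "set_b": b,
                    "n_a": len(called[a]),
                    "n_b": len(called[b]),
                    "n_intersection": len(inter),
                    "share_of_a": len(inter) / len(called[a]) if len(called[a]) else np.nan,
                    "share_of_b": len(inter) / len(called[b]) if len(called[b]) else np.nan,
                    "n_concordant_direction": concordant,
                }
            )
    out = pd.DataFrame(rows)
    if len(names) >= 3:
        inter3 = called[names[0]]
        for n in names[1:]:
            inter3 = inter3.intersection(called[n])
        out.attrs["n_common_all"] = len(inter3)
    return out


def remodeling_classification(
    sites,
    beta_stage1: pd.DataFrame,
    beta_stage2: pd.DataFrame,
    group_samples: dict[str, tuple[list, list]],
    delta_threshold: float = 0.25,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Classify each site as changed/unchanged between two stages, per group.

    A site is *changed* for a group iff the stage1-vs-stage2 comparison
    within that group meets the DMCpG criterion (|delta| > threshold and BH
    q < threshold, FDR over the evaluated site set).  ``group_samples``
    maps group name -> (stage1 sample ids, stage2 sample ids).

    Returns a table indexed by site with, per group, columns
    ``<group>_delta`` (stage2 - stage1), ``<group>_q`` and
    ``<group>_changed``.
    """
    sites = pd.Index(sites)
    out = pd.DataFrame(index=sites)
    for group, (s1, s2) in group_samples.items():
        if not list(s1) or not list(s2):
            raise ValueError(f"group {group!r} lacks samples at one stage")
        b1 = beta_stage1.loc[sites, list(s1)]
        b2 = beta_stage2.loc[sites, list(s2)]
        merged = pd.concat([b2, b1], axis=1)
        tab = call_dmcpgs(
            merged, list(s2), list(s1), delta_threshold, q_threshold
        )
        out[f"{group}_delta"] = tab["delta_beta"]
        out[f"{group}_q"] = tab["q"]
        out[f"{group}_changed"] = tab["called"]
    return out


def remodeling_summary(classified: pd.DataFrame, groups) -> pd.DataFrame:
    """Per-group fractions of sites changed / unchanged / demethylated.

    ``demethylated`` counts sites whose change is significant with a
    negative stage2-minus-stage1 delta (methylation loss across the stage
    transition).
    """
    rows = []
    n = len(classified)
    for g in groups:
        changed = classified[f"{g}_changed"]
        demeth = changed & (classified[f"{g}_delta"] < 0)
        rows.append(
            {
                "group": g,
                "n_sites": n,
                "fraction_changed": changed.mean() if n else np.nan,
                "fraction_unchanged": 1.0 - changed.mean() if n else np.nan,
                "fraction_demethylated": demeth.mean() if n else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")
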