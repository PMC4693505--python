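"""Beta values, probe filtering, variable-site selection and sample structure.

The beta value of a CpG is the fraction methylated, M / (M + U), optionally
with an intensity offset in the denominator.  Probe filtering removes, in
order: SNP-detecting probes, probes failing detection in any sample, and
sex-chromosome probes; the bookkeeping identity
``n_remaining = n_initial - removed(snp) - removed(detection) - removed(sex)``
is asserted on every run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "FilterReport",
    "compute_beta",
    "filter_probes",
    "select_variable_sites",
    "pca_embed",
    "hierarchical_cluster",
]

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass
class FilterReport:
    """Sequential probe-filter bookkeeping; counts must reconcile exactly."""

    n_initial: int
    n_removed_snp: int
    n_removed_detection: int
    n_removed_sex: int
    n_remaining: int
    removed_ids: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        expected = (
            self.n_initial
            - self.n_removed_snp
            - self.n_removed_detection
            - self.n_removed_sex
        )
        if self.n_remaining != expected:
            raise AssertionError(
                f"filter bookkeeping mismatch: {self.n_remaining} != {expected}"
            )


def compute_beta(M, U, offset: float = 0.0) -> pd.DataFrame:
    """Beta values M / (M + U + offset); zero denominator -> missing."""
    Mdf = pd.DataFrame(M).astype(float)
    Udf = pd.DataFrame(U).astype(float)
    if (Mdf.to_numpy() < 0).any() or (Udf.to_numpy() < 0).any():
        raise ValueError("intensities must be nonnegative")
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    denom = Mdf + Udf + offset
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = Mdf / denom
    return beta.where(denom > 0)


def filter_probes(
    beta: pd.DataFrame,
    detection_p: pd.DataFrame | None,
    manifest: pd.DataFrame,
    detection_threshold: float = 0.01,
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove SNP-flagged, detection-failing and sex-chromosome probes.

    ``manifest`` is indexed by probe id with at least ``chrom`` and
    ``snp_flag`` columns.  "Failing detection" means detection p >
    ``detection_threshold`` in at least one sample.  Removal reasons are
    applied sequentially, so each probe is counted under exactly one reason.
    """
    missing = beta.index.difference(manifest.index)
    if len(missing):
        raise KeyError(f"probe {missing[0]!r} absent from manifest")

    n_initial = beta.shape[0]
    man = manifest.loc[beta.index]
    removed: dict[str, list[str]] = {}

    snp_mask = man["snp_flag"].astype(bool) if "snp_flag" in man else pd.Series(False, index=beta.index)
    removed["snp"] = list(beta.index[snp_mask])
    keep = beta.index[~snp_mask]

    if detection_p is not None:
        det = detection_p.loc[keep]
        fail = (det > detection_threshold).any(axis=1)
        removed["detection"] = list(keep[fail])
        keep = keep[~fail]
    else:
        removed["detection"] = []

    sex = man.loc[keep, "chrom"].isin(SEX_CHROMS)
    removed["sex"] = list(keep[sex])
    keep = keep[~sex]

    report = FilterReport(
        n_initial=n_initial,
        n_removed_snp=len(removed["snp"]),
        n_removed_detection=len(removed["detection"]),
        n_removed_sex=len(removed["sex"]),
        n_remaining=len(keep),
        removed_ids=removed,
    )
    logger.info(
        "probe filter: %d initial - %d SNP - %d detection - %d sex = %d remaining",
        report.n_initial,
        report.n_removed_snp,
        report.n_removed_detection,
        report.n_removed_sex,
        report.n_remaining,
    )
    return beta.loc[keep], report


def select_variable_sites(beta: pd.DataFrame, sd_threshold: float = 0.1) -> pd.DataFrame:
    """Probes whose across-sample SD (ddof=1, missing excluded) exceeds the threshold (strict)."""
    if beta.shape[1] < 2:
        raise ValueError("variable-site selection requires at least 2 samples")
    sd = beta.std(axis=1, ddof=1, skipna=True)
    return beta.loc[sd > sd_threshold]


def _impute_probe_means(beta: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    n_missing = int(beta.isna().to_numpy().sum())
    if n_missing:
        logger.info("imputing %d missing values by probe mean", n_missing)
        means = beta.mean(axis=1)
        beta = beta.apply(lambda col: col.fillna(means))
    return beta, n_missing


def pca_embed(beta: pd.DataFrame, n_components: int | None = None):
    """PCA of samples over probe features (mean-centered, unscaled).

    Returns ``(scores, variance_fractions, n_imputed)``.  Component signs
    follow a deterministic convention: the largest-magnitude loading of each
    component is made positive.
    """
    if beta.shape[0] < 2 or beta.shape[1] < 2:
        raise ValueError("PCA requires at least 2 probes and 2 samples")
    filled, n_imputed = _impute_probe_means(beta)
    X = filled.to_numpy(dtype=float).T  # samples x probes
    k = n_components or min(X.shape)
    k = min(k, min(X.shape))
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    # sign convention: per component, largest-|loading| positive
    for j in range(k):
        load = pca.components_[j]
        i = int(np.argmax(np.abs(load)))
        if load[i] < 0:
            pca.components_[j] = -load
            scores[:, j] = -scores[:, j]
    total_var = float(np.var(X - X.mean(axis=0), axis=0, ddof=1).sum())
    if total_var == 0:
        frac = np.zeros(k)
        scores = np.zeros_like(scores)
    else:
        frac = pca.explained_variance_ / total_var
    scores_df = pd.DataFrame(
        scores, index=beta.columns, columns=[f"PC{j + 1}" for j in range(k)]
    )
    return scores_df, np.asarray(frac), n_imputed


def hierarchical_cluster(beta: pd.DataFrame):
    """Average-linkage agglomerative clustering of samples (Euclidean).

    Samples are pre-sorted lexicographically by id so tie-breaks are
    deterministic.  Returns ``(linkage_matrix, leaf_order)`` where
    ``leaf_order`` lists sample ids in dendrogram order.
    """
    if beta.shape[1] < 2:
        raise ValueError("clustering requires at least 2 samples")
    filled, _ = _impute_probe_means(beta)
    cols = sorted(filled.columns)
    X = filled[cols].to_numpy(dtype=float).T
    Z = linkage(X, method="average", metric="euclidean")
    order = [cols[i] for i in leaves_list(Z)]
    return Z, order
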