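"""End-to-end orchestration of the analysis stages.

Glues the stage modules together in the canonical order -- QC filtering,
differential methylation in the terminal neuron stage (and planted-null
stages), probe annotation, differential expression, methylation-expression
integration, enrichment and TF-network analysis -- and, when ground truth
is available, scores the recovered structure against it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotation as ann
from . import dmcpg, enrichment, expression, integration, qc
from .simulate import SyntheticStudy

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "score_against_truth"]


@dataclass
class PipelineResult:
    """Outputs of one full pipeline run."""

    filter_report: qc.FilterReport
    beta_filtered: dict[str, pd.DataFrame]
    dm: dict[str, pd.DataFrame]  # per stage: DMCpG table (case vs control)
    annotations: pd.DataFrame
    deg: pd.DataFrame
    pairs: pd.DataFrame
    pair_summary: dict
    enhancer_enrichment: pd.DataFrame
    tfbs: pd.DataFrame
    tf_meth_corr: pd.DataFrame
    tf_network_r: pd.DataFrame
    remodeling: pd.DataFrame
    remodeling_fractions: pd.DataFrame
    extras: dict = field(default_factory=dict)


def run_pipeline(
    study: SyntheticStudy,
    delta_threshold: float = 0.25,
    q_threshold: float = 0.05,
    detection_threshold: float = 0.01,
    stages_tested: tuple[str, ...] = ("DAn", "fibroblast", "iPSC"),
) -> PipelineResult:
    """Run every analysis stage of the pipeline on one study.

    Differential methylation is called case (pooled) vs control per stage in
    ``stages_tested``; all downstream analyses use the terminal ``DAn``
    stage.  Thresholds mirror the standard criteria: |delta beta| > 0.25,
    BH q < 0.05, detection p <= 0.01.
    """
    # --- QC: filter on the DAn matrix, apply the surviving probe set to all
    beta_dan, report = qc.filter_probes(
        study.beta["DAn"],
        study.detection_p["DAn"],
        study.manifest,
        detection_threshold=detection_threshold,
    )
    keep = beta_dan.index
    beta_f = {stage: b.loc[keep] for stage, b in study.beta.items()}

    # --- differential methylation per stage
    dm: dict[str, pd.DataFrame] = {}
    for stage in stages_tested:
        case = study.samples(stage, "PD")
        ctrl = study.samples(stage, "control")
        dm[stage] = dmcpg.call_dmcpgs(
            beta_f[stage], case, ctrl, delta_threshold, q_threshold
        )
    dm_dan = dm["DAn"]
    called = dm_dan.index[dm_dan["called"]]
    hyper = dm_dan.index[dm_dan["called"] & (dm_dan["direction"] == "hyper")]
    hypo = dm_dan.index[dm_dan["called"] & (dm_dan["direction"] == "hypo")]

    # --- annotation of all surviving probes
    annotations = ann.annotate_probes(
        study.manifest.loc[keep], study.genes, study.cgi, study.chromatin, study.tfbs
    )

    # --- differential expression
    dan_samples = study.samples("DAn")
    groups = [
        "PD" if g != "control" else "control"
        for g in study.sample_sheet.loc[dan_samples, "group"]
    ]
    expr_f = expression.filter_genes(study.expression[dan_samples])
    deg = expression.call_degs(expr_f, groups, case="PD", control="control", q_threshold=q_threshold)

    # --- methylation-expression integration over DAn samples
    pairs = integration.pair_probes_genes(called, annotations, expr_f.index)
    if len(pairs):
        pairs = integration.correlate_meth_expr(
            pairs, beta_f["DAn"], expr_f, dan_samples, q_threshold
        )
    else:
        pairs = pairs.assign(rho=[], p=[], q=[], sign_class=[])
    pair_summary = integration.summarize_correlations(pairs, annotations)

    # --- enrichment of hyper calls by chromatin category, TFBS enrichment
    enh = enrichment.category_enrichment(hyper, keep, annotations, "chromatin_category") if len(hyper) else pd.DataFrame()
    tfbs_tab = (
        enrichment.tfbs_enrichment(hyper, hypo, keep, annotations, q_threshold)
        if len(hyper) and len(hypo)
        else pd.DataFrame()
    )

    # --- TF expression vs enhancer hypermethylation, TF network
    enh_hyper_sites = [
        p for p in hyper if annotations.loc[p, "chromatin_category"] == "enhancer"
    ]
    tf_ids = [g for g in study.expression.index if g.startswith("TF")]
    tf_expr = study.expression.loc[tf_ids, dan_samples]
    if enh_hyper_sites:
        tf_corr, avg_meth = enrichment.tf_enhancer_methylation_correlation(
            tf_expr, enh_hyper_sites, beta_f["DAn"], dan_samples
        )
    else:
        tf_corr, avg_meth = pd.DataFrame(), pd.Series(dtype=float)
    tf_r, tf_p = enrichment.tf_network_matrix(tf_expr)

    # --- iPSC -> DAn remodeling of the called DMCpG set
    group_samples = {
        "control": (study.samples("iPSC", "control"), study.samples("DAn", "control")),
        "case": (study.samples("iPSC", "PD"), study.samples("DAn", "PD")),
    }
    if len(called):
        remod = dmcpg.remodeling_classification(
            called, beta_f["iPSC"], beta_f["DAn"], group_samples,
            delta_threshold, q_threshold,
        )
        remod_frac = dmcpg.remodeling_summary(remod, ["control", "case"])
    else:
        remod = pd.DataFrame()
        remod_frac = pd.DataFrame()

    return PipelineResult(
        filter_report=report,
        beta_filtered=beta_f,
        dm=dm,
        annotations=annotations,
        deg=deg,
        pairs=pairs,
        pair_summary=pair_summary,
        enhancer_enrichment=enh,
        tfbs=tfbs_tab,
        tf_meth_corr=tf_corr,
        tf_network_r=tf_r,
        remodeling=remod,
        remodeling_fractions=remod_frac,
        extras={
            "avg_enhancer_meth": avg_meth,
            "tf_network_p": tf_p,
            "enhancer_hyper_sites": enh_hyper_sites,
        },
    )


def score_against_truth(result: PipelineResult, study: SyntheticStudy) -> dict:
    """Recovery metrics of a pipeline run against the planted truth."""
    truth = study.truth
    dm = result.dm["DAn"]
    called = set(dm.index[dm["called"]])
    planted = set(truth.planted_dm.index)
    tp = len(called & planted)
    scores = {
        "dm_sensitivity": tp / len(planted) if planted else np.nan,
        "dm_empirical_fdr": (len(called) - tp) / len(called) if called else 0.0,
        "dm_n_called": len(called),
    }
    for stage in ("fibroblast", "iPSC"):
        if stage in result.dm:
            scores[f"dm_n_called_{stage}"] = int(result.dm[stage]["called"].sum())

    deg_called = set(result.deg.index[result.deg["called"]])
    deg_planted = set(truth.planted_deg.index) & set(result.deg.index)
    tp_deg = len(deg_called & set(truth.planted_deg.index))
    scores["deg_sensitivity"] = tp_deg / len(deg_planted) if deg_planted else np.nan
    scores["deg_empirical_fdr"] = (
        (len(deg_called) - tp_deg) / len(deg_called) if deg_called else 0.0
    )

    if len(result.enhancer_enrichment):
        scores["enhancer_fisher_p"] = float(
            result.enhancer_enrichment.loc["enhancer", "p"]
        )
        scores["enhancer_log2_ratio"] = float(
            result.enhancer_enrichment.loc["enhancer", "log2_ratio"]
        )
        scores["enhancer_fg_prop"] = float(
            result.enhancer_enrichment.loc["enhancer", "fg_prop"]
        )
        scores["enhancer_bg_prop"] = float(
            result.enhancer_enrichment.loc["enhancer", "bg_prop"]
        )

    if len(result.tf_meth_corr):
        sig = result.tf_meth_corr
        recovered = [
            tf
            for tf in truth.coupled_tfs
            if tf in sig.index and sig.loc[tf, "q"] < 0.05 and sig.loc[tf, "rho"] < 0
        ]
        scores["coupled_tfs_recovered"] = len(recovered)
        scores["coupled_tfs_total"] = len(truth.coupled_tfs)

    if len(result.remodeling_fractions):
        rf = result.remodeling_fractions
        # restrict to enhancer-annotated hypermethylated calls
        dm_dan = result.dm["DAn"]
        hyper = dm_dan.index[dm_dan["called"] & (dm_dan["direction"] == "hyper")]
        enh_sites = [
            p
            for p in hyper
            if result.annotations.loc[p, "chromatin_category"] == "enhancer"
        ]
        if enh_sites:
            sub = result.remodeling.loc[result.remodeling.index.intersection(enh_sites)]
            scores["enhancer_control_changed_fraction"] = float(
                sub["control_changed"].mean()
            )
            scores["enhancer_case_changed_fraction"] = float(sub["case_changed"].mean())
            scores["enhancer_control_demethylated_fraction"] = float(
                (sub["control_changed"] & (sub["control_delta"] < 0)).mean()
            )
            scores["enhancer_case_demethylated_fraction"] = float(
                (sub["case_changed"] & (sub["case_delta"] < 0)).mean()
            )
        scores["control_unchanged_fraction"] = float(
            rf.loc["control", "fraction_unchanged"]
        )
        scores["case_unchanged_fraction"] = float(rf.loc["case", "fraction_unchanged"])
    return scores
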