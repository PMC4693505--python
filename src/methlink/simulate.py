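"""Synthetic case/control methylome-transcriptome study generator.

Generates a complete, self-consistent study -- probe manifest, gene models,
CpG-island / chromatin-state / TFBS tracks, four-stage beta matrices with
detection p-values, a log2 expression matrix and a qPCR Ct panel -- plus a
ground-truth ledger, so every pipeline stage can be exercised and scored
against known planted structure without any external data.

The planted structure mirrors the biology the pipeline is built to detect:

* case-vs-control differential methylation (effect ``planted_delta``,
  default 0.3, exceeding the 0.25 call threshold) confined to the terminal
  differentiated-neuron (DAn) stage -- fibroblasts, undifferentiated iPSCs
  and the non-DAn neural stage are planted null;
* hypermethylated planted sites biased into enhancer chromatin (35% vs a
  12% background rate);
* enhancer remodeling: at planted hyper enhancer sites, controls
  demethylate by ``stage_remodeling`` (default 0.4) from iPSC to DAn while
  cases largely retain the iPSC level, so the case-minus-control DAn
  difference equals ``planted_delta``;
* expression with planted differential genes, and a small set of
  transcription factors whose expression is negatively coupled to the
  per-sample average methylation of the planted hyper enhancer sites.

Noise is logit-normal: Gaussian on the logit scale with a position-scaled
SD so the induced beta-scale SD approximates ``beta_noise_sd`` everywhere,
keeping values inside (0, 1) without truncation artifacts.  A shared
subject-level intercept couples a subject's stages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .annotation import GeneModel, IntervalTrack

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "SimulationTruth", "SyntheticStudy", "simulate_study"]

STAGES = ("fibroblast", "iPSC", "DAn", "neural_notDAn")

#: Background distribution over collapsed chromatin categories.  The
#: enhancer share is the configurable ``enhancer_fraction_bg``; the rest is
#: split in these fixed ratios.
_NON_ENHANCER_CATEGORY_WEIGHTS = {
    "promoter": 0.11,
    "poised_promoter": 0.03,
    "insulator": 0.05,
    "strong_transcription": 0.16,
    "weak_transcription": 0.26,
    "polycomb_repressed": 0.13,
    "heterochromatin": 0.26,
}

_CATEGORY_STATES = {
    "promoter": (1, 2),
    "poised_promoter": (3,),
    "enhancer": (4, 5, 6, 7),
    "insulator": (8,),
    "strong_transcription": (9, 10),
    "weak_transcription": (11,),
    "polycomb_repressed": (12,),
    "heterochromatin": (13, 14, 15),
}


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic generator.

    Defaults encode the study conditions the pipeline targets: a 10-vs-4
    case/control neuron cohort, ~10% of probes carrying a 0.3 beta-scale
    effect, enhancer-biased hypermethylation (35% vs 12% background) and a
    0.4 control-only enhancer demethylation during iPSC-to-DAn
    differentiation.
    """

    seed: int = 1
    n_probes: int = 20_000
    n_case: int = 10
    n_control: int = 4
    n_planted_dm: int = 2_000
    planted_delta: float = 0.3
    beta_noise_sd: float = 0.05
    subject_sd: float = 0.01
    enhancer_subject_sd: float = 0.05
    enhancer_fraction_bg: float = 0.12
    planted_enhancer_bias: float = 0.35
    hyper_fraction: float = 0.5
    stage_remodeling: float = 0.4
    snp_fraction: float = 0.01
    sex_fraction: float = 0.02
    detection_fail_fraction: float = 0.002
    n_genes: int = 5_000
    n_planted_deg: int = 400
    deg_log2fc: float = 1.5
    expr_noise_sd: float = 0.5
    n_tfs: int = 25
    n_coupled_tfs: int = 4
    coupling_slope: float = -4.0
    coupling_intercept: float = 10.0
    tf_noise_sd: float = 0.2
    tf_bg_cover: float = 0.10
    tf_hyper_cover: float = 0.60
    n_qpcr_genes: int = 10
    ct_noise_sd: float = 0.05

    def __post_init__(self):
        fracs = {
            "enhancer_fraction_bg": self.enhancer_fraction_bg,
            "planted_enhancer_bias": self.planted_enhancer_bias,
            "hyper_fraction": self.hyper_fraction,
            "snp_fraction": self.snp_fraction,
            "sex_fraction": self.sex_fraction,
            "detection_fail_fraction": self.detection_fail_fraction,
            "tf_bg_cover": self.tf_bg_cover,
            "tf_hyper_cover": self.tf_hyper_cover,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_planted_dm > self.n_probes:
            raise ValueError("n_planted_dm exceeds n_probes")
        if self.n_planted_deg > self.n_genes:
            raise ValueError("n_planted_deg exceeds n_genes")
        if self.coupling_slope >= 0:
            raise ValueError("coupling_slope must be negative (inverse coupling)")
        # Exact-test granularity: with n1 vs n2 tie-free samples the smallest
        # attainable two-sided p is 2/C(n1+n2, n2); if the BH threshold at
        # the planted fraction cannot reach it, recovery is impossible by
        # construction.
        from math import comb

        min_p = 2.0 / comb(self.n_case + self.n_control, self.n_control)
        bh_reach = 0.05 * self.n_planted_dm / self.n_probes
        if self.n_planted_dm and bh_reach < min_p:
            warnings.warn(
                "planted fraction too small for the exact-test granularity: "
                f"BH threshold {bh_reach:.2e} < minimum attainable p {min_p:.2e}; "
                "planted effects cannot be recovered by design",
                stacklevel=2,
            )


@dataclass
class SimulationTruth:
    """Ground-truth ledger of everything the generator planted."""

    planted_dm: pd.DataFrame  # index probe_id; direction, is_enhancer
    planted_deg: pd.DataFrame  # index gene_id; sign
    coupled_tfs: list[str]
    qpcr_true_log2fc: pd.Series
    stage_group_means: pd.DataFrame = field(default=None)  # planted probes x (stage, group)


@dataclass
class SyntheticStudy:
    """All generated study objects plus configuration and truth."""

    config: SimulationConfig
    sample_sheet: pd.DataFrame
    manifest: pd.DataFrame
    genes: list[GeneModel]
    cgi: IntervalTrack
    chromatin: IntervalTrack
    tfbs: IntervalTrack
    beta: dict[str, pd.DataFrame]
    detection_p: dict[str, pd.DataFrame]
    expression: pd.DataFrame
    ct_table: pd.DataFrame
    truth: SimulationTruth

    def samples(self, stage: str, group: str | None = None) -> list[str]:
        sheet = self.sample_sheet
        mask = sheet["cell_stage"] == stage
        if group == "PD":  # pooled cases
            mask &= sheet["group"].isin(["L2PD", "sPD"])
        elif group is not None:
            mask &= sheet["group"] == group
        return list(sheet.index[mask])


# ---------------------------------------------------------------------------
# generation steps
# ---------------------------------------------------------------------------

_PROBE_SPACING = 1000  # bp between probe anchor positions
_GENE_UNIT = 40_000  # bp of genome reserved per gene model


def _choose_categories(rng, n: int, enhancer_frac: float) -> np.ndarray:
    cats = ["enhancer"] + list(_NON_ENHANCER_CATEGORY_WEIGHTS)
    w_rest = np.array(list(_NON_ENHANCER_CATEGORY_WEIGHTS.values()))
    probs = np.concatenate([[enhancer_frac], (1 - enhancer_frac) * w_rest / w_rest.sum()])
    return rng.choice(cats, size=n, p=probs)


def generate_tracks(config: SimulationConfig):
    """Manifest, gene models and interval tracks with recorded truth.

    Returns ``(manifest, genes, cgi, chromatin, tfbs, aux)`` where ``aux``
    carries the planted-site assignments reused by the later steps.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    n = config.n_probes

    # -- probe layout: evenly spaced anchors on autosomes, plus a gene zone
    n_sex = int(round(config.sex_fraction * n))
    n_auto = n - n_sex
    chroms = np.array([f"chr{1 + i % 4}" for i in range(n_auto)] + ["chrX"] * n_sex)
    offsets = rng.integers(100, _PROBE_SPACING - 100, size=n)
    pos = np.empty(n, dtype=int)
    per_chrom_counter: dict[str, int] = {}
    for i, c in enumerate(chroms):
        k = per_chrom_counter.get(c, 0)
        pos[i] = k * _PROBE_SPACING + offsets[i] + 1  # 1-based
        per_chrom_counter[c] = k + 1
    probe_ids = np.array([f"cg{i:08d}" for i in range(n)])

    snp_flag = np.zeros(n, dtype=bool)
    autosomal = np.flatnonzero(chroms != "chrX")
    snp_idx = rng.choice(autosomal, size=int(round(config.snp_fraction * n)), replace=False)
    snp_flag[snp_idx] = True

    # -- planted differential-methylation sites: clean autosomal probes only
    clean = np.flatnonzero((chroms != "chrX") & ~snp_flag)
    planted_idx = rng.choice(clean, size=config.n_planted_dm, replace=False)
    n_hyper = int(round(config.hyper_fraction * config.n_planted_dm))
    hyper_idx = planted_idx[:n_hyper]
    hypo_idx = planted_idx[n_hyper:]

    # -- gene models on a genomic zone of each chromosome downstream of the
    #    probe anchors
    gene_zone_start = {
        f"chr{c + 1}": (per_chrom_counter.get(f"chr{c + 1}", 0) + 10) * _PROBE_SPACING
        for c in range(4)
    }
    genes: list[GeneModel] = []
    gene_ids = [f"G{k + 1:05d}" for k in range(config.n_genes)]
    gchroms = [f"chr{1 + k % 4}" for k in range(config.n_genes)]
    gene_start = {}
    for k, gid in enumerate(gene_ids):
        c = gchroms[k]
        s = gene_zone_start[c] + (k // 4) * _GENE_UNIT + 15_000
        e = s + 10_000
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=c,
                strand="+",
                tx_start=s,
                tx_end=e,
                first_exon=(s, s + 1000),
                utr5=(s, s + 300),
                utr3=(e - 500, e),
            )
        )
        gene_start[gid] = s

    # -- re-home planted sites and a slice of null probes into gene regions
    #    (TSS windows, body, UTRs) so annotation-based pairing has
    #    structure; done before track construction so every downstream
    #    lookup sees the final coordinates
    rehome = np.concatenate(
        [
            planted_idx,
            rng.choice(
                np.setdiff1d(clean, planted_idx),
                size=min(4000, len(clean) - len(planted_idx)),
                replace=False,
            ),
        ]
    )
    region_offsets = np.array([-150, -800, -5000, 500, 3000, 9800, 1200])
    for j, i in enumerate(rehome):
        gid = gene_ids[j % config.n_genes]
        chroms[i] = gchroms[j % config.n_genes]
        pos[i] = gene_start[gid] + 1 + int(region_offsets[j % len(region_offsets)])

    manifest = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "strand": rng.choice(["+", "-"], size=n),
            "snp_flag": snp_flag.astype(int),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )

    # -- chromatin categories: enhancer bias at planted hyper sites; the
    #    +/-100 bp segments cannot overlap neighbouring probes (min gap 200)
    category = _choose_categories(rng, n, config.enhancer_fraction_bg)
    category[hyper_idx] = _choose_categories(
        rng, len(hyper_idx), config.planted_enhancer_bias
    )
    states = np.array([rng.choice(_CATEGORY_STATES[c]) for c in category], dtype=int)
    chromatin = IntervalTrack(
        [
            (chroms[i], pos[i] - 1 - 100, pos[i] - 1 + 100, str(states[i]))
            for i in range(n)
        ],
        kind="chromatin_state",
    )

    # -- CpG islands: cover ~15% of probes, islands of 200 bp at the probe
    cgi_idx = np.sort(rng.choice(n, size=int(0.15 * n), replace=False))
    cgi = IntervalTrack(
        [(chroms[i], pos[i] - 1 - 100, pos[i] - 1 + 100, "CGI") for i in cgi_idx],
        kind="CGI",
    )

    # -- TFBS clusters: binary coverage, coupled TFs enriched at planted
    #    hyper enhancer sites
    tf_names = [f"TF{k + 1:02d}" for k in range(config.n_tfs)]
    coupled = tf_names[: config.n_coupled_tfs]
    hyper_enh = hyper_idx[category[hyper_idx] == "enhancer"]
    tf_entries = []
    for tf in tf_names:
        cover = rng.random(n) < config.tf_bg_cover
        if tf in coupled:
            cover[hyper_enh] = rng.random(len(hyper_enh)) < config.tf_hyper_cover
        for i in np.flatnonzero(cover):
            tf_entries.append((chroms[i], pos[i] - 1 - 50, pos[i] - 1 + 50, tf))
    tfbs = IntervalTrack(tf_entries, kind="TFBS")

    aux = {
        "planted_idx": planted_idx,
        "hyper_idx": hyper_idx,
        "hypo_idx": hypo_idx,
        "hyper_enhancer_ids": list(probe_ids[hyper_enh]),
        "category": category,
        "probe_ids": probe_ids,
        "tf_names": tf_names,
        "coupled_tfs": coupled,
        "gene_ids": gene_ids,
    }
    return manifest, genes, cgi, chromatin, tfbs, aux


def _logit_noise(rng, mu: np.ndarray, sd_beta: float) -> np.ndarray:
    """Logit-normal perturbation with ~``sd_beta`` SD on the beta scale."""
    mu = np.clip(mu, 0.02, 0.98)
    scale = sd_beta / (mu * (1.0 - mu))  # delta-method logit-scale SD
    z = logit(mu) + rng.standard_normal(mu.shape) * scale
    return expit(z)


def generate_methylomes(config: SimulationConfig, manifest, aux):
    """Per-stage beta and detection-p matrices plus the sample sheet.

    Planted case effects exist only in the DAn stage.  At planted hyper
    enhancer sites the iPSC baseline is high and the iPSC-to-DAn transition
    removes ``stage_remodeling`` in controls but only
    ``stage_remodeling - planted_delta`` in cases, so cases approximately
    retain iPSC levels and the DAn case-control difference equals
    ``planted_delta``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 22]))
    n = config.n_probes
    n_sub = config.n_case + config.n_control
    subjects = [f"S{j + 1:02d}" for j in range(n_sub)]
    groups = (
        ["L2PD"] * (config.n_case // 2)
        + ["sPD"] * (config.n_case - config.n_case // 2)
        + ["control"] * config.n_control
    )
    is_case = np.array([g != "control" for g in groups])

    sheet_rows = []
    for stage in STAGES:
        for subj, grp in zip(subjects, groups):
            sheet_rows.append(
                {
                    "sample": f"{subj}_{stage}",
                    "subject": subj,
                    "group": grp,
                    "cell_stage": stage,
                }
            )
    sample_sheet = pd.DataFrame(sheet_rows).set_index("sample")

    planted_idx = aux["planted_idx"]
    hyper_idx = aux["hyper_idx"]
    hypo_idx = aux["hypo_idx"]
    category = aux["category"]
    hyper_enh_mask = np.zeros(n, dtype=bool)
    hyper_enh_mask[hyper_idx[category[hyper_idx] == "enhancer"]] = True
    hyper_mask = np.zeros(n, dtype=bool)
    hyper_mask[hyper_idx] = True
    hypo_mask = np.zeros(n, dtype=bool)
    hypo_mask[hypo_idx] = True

    # baselines (shared by both groups at fibroblast/iPSC/notDAn).  Planted
    # hyper enhancer sites start methylated and demethylate in control DAn;
    # planted hypo sites start unmethylated and gain methylation in control
    # DAn; non-enhancer hyper sites shift in cases only.
    base = rng.uniform(0.05, 0.95, size=n)
    base[hyper_mask] = rng.uniform(0.20, 0.45, size=int(hyper_mask.sum()))
    base[hyper_enh_mask] = rng.uniform(0.60, 0.80, size=int(hyper_enh_mask.sum()))
    base[hypo_mask] = rng.uniform(0.20, 0.45, size=int(hypo_mask.sum()))

    # mild stage drift on a random 10% of probes, identical for all samples
    stage_shift = {s: np.zeros(n) for s in STAGES}
    drift_idx = rng.choice(n, size=n // 10, replace=False)
    for stage in ("iPSC", "DAn", "neural_notDAn"):
        shift = np.zeros(n)
        shift[drift_idx] = rng.uniform(-0.15, 0.15, size=len(drift_idx))
        stage_shift[stage] = shift
    # keep planted sites free of incidental drift so stage contrasts are
    # governed by the remodeling model alone
    for stage in STAGES:
        stage_shift[stage][planted_idx] = 0.0

    subj_intercept = rng.standard_normal((n_sub, n)) * config.subject_sd
    # per-subject enhancer-methylation factor: inter-individual variation
    # shared across the planted hyper enhancer sites in the DAn stage; this
    # is the variation the TF-expression coupling tracks
    enh_factor = rng.standard_normal(n_sub) * config.enhancer_subject_sd

    beta: dict[str, pd.DataFrame] = {}
    detection: dict[str, pd.DataFrame] = {}
    truth_means = {}
    for stage in STAGES:
        cols = {}
        for j, subj in enumerate(subjects):
            mu = base + stage_shift[stage]
            if stage == "DAn":
                mu = mu.copy()
                partial = config.stage_remodeling - config.planted_delta
                plain_hyper = hyper_mask & ~hyper_enh_mask
                if is_case[j]:
                    # cases: plain hyper sites shift up; remodeling-driven
                    # sites move only partially (incomplete remodeling)
                    mu[plain_hyper] += config.planted_delta
                    mu[hyper_enh_mask] -= partial
                    mu[hypo_mask] += partial
                else:
                    # controls: full iPSC->DAn remodeling at enhancer hyper
                    # (demethylation) and hypo (methylation gain) sites
                    mu[hyper_enh_mask] -= config.stage_remodeling
                    mu[hypo_mask] += config.stage_remodeling
                mu[hyper_enh_mask] += enh_factor[j]
            mu = np.clip(mu + subj_intercept[j], 0.02, 0.98)
            cols[f"{subj}_{stage}"] = _logit_noise(rng, mu, config.beta_noise_sd)
        bdf = pd.DataFrame(cols, index=manifest.index)
        beta[stage] = bdf
        det = pd.DataFrame(
            rng.uniform(0.0, 0.005, size=bdf.shape),
            index=bdf.index,
            columns=bdf.columns,
        )
        # planted detection failures on non-planted probes, one sample each
        n_fail = int(round(config.detection_fail_fraction * n))
        failable = np.setdiff1d(np.arange(n), planted_idx)
        fail_idx = rng.choice(failable, size=n_fail, replace=False)
        fail_col = rng.integers(0, bdf.shape[1], size=n_fail)
        for fi, fc in zip(fail_idx, fail_col):
            det.iloc[fi, fc] = 0.02 + rng.random() * 0.5
        detection[stage] = det
        # expected group means at planted sites
        for grp, mask in (("case", is_case), ("control", ~is_case)):
            mu_g = base[planted_idx] + stage_shift[stage][planted_idx]
            if stage == "DAn":
                he = hyper_enh_mask[planted_idx]
                ph = (hyper_mask & ~hyper_enh_mask)[planted_idx]
                po = hypo_mask[planted_idx]
                mu_g = mu_g.copy()
                partial = config.stage_remodeling - config.planted_delta
                if grp == "case":
                    mu_g[ph] += config.planted_delta
                    mu_g[he] -= partial
                    mu_g[po] += partial
                else:
                    mu_g[he] -= config.stage_remodeling
                    mu_g[po] += config.stage_remodeling
            truth_means[(stage, grp)] = np.clip(mu_g, 0.02, 0.98)

    probe_ids = aux["probe_ids"]
    planted_dm = pd.DataFrame(
        {
            "direction": ["hyper"] * len(hyper_idx) + ["hypo"] * len(hypo_idx),
            "is_enhancer": list(category[hyper_idx] == "enhancer")
            + list(category[hypo_idx] == "enhancer"),
        },
        index=pd.Index(
            list(probe_ids[hyper_idx]) + list(probe_ids[hypo_idx]), name="probe_id"
        ),
    )
    stage_group_means = pd.DataFrame(
        truth_means, index=pd.Index(probe_ids[planted_idx], name="probe_id")
    )
    return sample_sheet, beta, detection, planted_dm, stage_group_means


def generate_expression(config: SimulationConfig, aux, sample_sheet, beta, planted_dm):
    """Expression matrix over DAn samples, with truth and a qPCR Ct panel."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 33]))
    dan = sample_sheet.index[sample_sheet["cell_stage"] == "DAn"]
    is_case = (sample_sheet.loc[dan, "group"] != "control").to_numpy()
    n_samp = len(dan)

    gene_ids = aux["gene_ids"]
    tf_names = aux["tf_names"]
    coupled = aux["coupled_tfs"]

    baseline = rng.uniform(6.0, 12.0, size=len(gene_ids))
    values = (
        baseline[:, None]
        + rng.standard_normal((len(gene_ids), n_samp)) * config.expr_noise_sd
    )
    deg_idx = rng.choice(len(gene_ids), size=config.n_planted_deg, replace=False)
    signs = rng.choice([1.0, -1.0], size=config.n_planted_deg)
    for k, (gi, s) in enumerate(zip(deg_idx, signs)):
        values[gi, is_case] += s * config.deg_log2fc

    # coupled TFs track average methylation at planted hyper enhancer sites
    hyper_enh = planted_dm.index[
        (planted_dm["direction"] == "hyper") & planted_dm["is_enhancer"]
    ]
    avg_meth = beta["DAn"].loc[hyper_enh, dan].mean(axis=0).to_numpy()
    tf_rows = []
    for tf in tf_names:
        if tf in coupled:
            row = (
                config.coupling_intercept
                + config.coupling_slope * avg_meth
                + rng.standard_normal(n_samp) * config.tf_noise_sd
            )
        else:
            row = rng.uniform(6.0, 12.0) + rng.standard_normal(n_samp) * config.expr_noise_sd
        tf_rows.append(row)
    expr = pd.DataFrame(
        np.vstack([values, np.array(tf_rows)]),
        index=pd.Index(gene_ids + tf_names, name="gene_id"),
        columns=dan,
    )

    planted_deg = pd.DataFrame(
        {"sign": signs},
        index=pd.Index([gene_ids[i] for i in deg_idx], name="gene_id"),
    )

    # qPCR panel: Ct = 30 - expression + per-sample offset (+ noise); three
    # endogenous controls cancel the offset under delta-Ct normalization.
    panel = [gene_ids[i] for i in deg_idx[: config.n_qpcr_genes]]
    offsets = rng.uniform(-1.0, 1.0, size=n_samp)
    ct_rows = []
    for gi, gene in zip(deg_idx[: config.n_qpcr_genes], panel):
        for j, s in enumerate(dan):
            ct_rows.append(
                {
                    "sample": s,
                    "assay": gene,
                    "role": "target",
                    "ct": 30.0
                    - values[gi, j]
                    + offsets[j]
                    + rng.standard_normal() * config.ct_noise_sd,
                }
            )
    for hk, base_ct in (("HK_GAPDH", 18.0), ("HK_ACTB", 19.0), ("HK_PPIA", 20.0)):
        for j, s in enumerate(dan):
            ct_rows.append(
                {
                    "sample": s,
                    "assay": hk,
                    "role": "endogenous_control",
                    "ct": base_ct + offsets[j] + rng.standard_normal() * config.ct_noise_sd,
                }
            )
    ct_table = pd.DataFrame(ct_rows)

    true_log2fc = pd.Series(
        {
            gene: float(
                values[gi, is_case].mean() - values[gi, ~is_case].mean()
            )
            for gi, gene in zip(deg_idx[: config.n_qpcr_genes], panel)
        },
        name="true_log2fc",
    )
    return expr, planted_deg, ct_table, true_log2fc


def simulate_study(config: SimulationConfig | None = None, **overrides) -> SyntheticStudy:
    """Generate the full synthetic study under one seed.

    Any :class:`SimulationConfig` field may be overridden by keyword.  The
    same configuration always yields identical objects.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = SimulationConfig(**{**asdict(config), **overrides})

    manifest, genes, cgi, chromatin, tfbs, aux = generate_tracks(config)
    sample_sheet, beta, detection, planted_dm, stage_group_means = generate_methylomes(
        config, manifest, aux
    )
    expr, planted_deg, ct_table, true_log2fc = generate_expression(
        config, aux, sample_sheet, beta, planted_dm
    )
    truth = SimulationTruth(
        planted_dm=planted_dm,
        planted_deg=planted_deg,
        coupled_tfs=list(aux["coupled_tfs"]),
        qpcr_true_log2fc=true_log2fc,
        stage_group_means=stage_group_means,
    )
    logger.info(
        "simulated study: %d probes (%d planted), %d+%d subjects, %d genes, %d TFs",
        config.n_probes,
        config.n_planted_dm,
        config.n_case,
        config.n_control,
        config.n_genes,
        config.n_tfs,
    )
    return SyntheticStudy(
        config=config,
        sample_sheet=sample_sheet,
        manifest=manifest,
        genes=genes,
        cgi=cgi,
        chromatin=chromatin,
        tfbs=tfbs,
        beta=beta,
        detection_p=detection,
        expression=expr,
        ct_table=ct_table,
        truth=truth,
    )
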