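# methlink

Integrative case/control analysis of DNA methylation arrays with matched
gene expression, built for small patient-derived cohort designs (for
example, iPSC-derived neuronal lines from a handful of subjects per
group). The package implements the full analysis chain used in
methylome–transcriptome studies of disease cohorts:

- **Probe QC** — beta values β = M/(M+U) from methylated/unmethylated
  intensities, sequential removal of SNP-detecting probes, probes with
  detection *P* > 0.01 in any sample, and sex-chromosome probes, with
  exact bookkeeping; variable-site selection (SD > 0.1), PCA and
  hierarchical clustering of samples.
- **Differential methylation** — per-CpG Δβ (difference of group means)
  with a two-sided Wilcoxon rank-sum test (exact by enumeration for small
  combined group sizes, normal approximation with tie and continuity
  correction otherwise) and Benjamini–Hochberg FDR; a CpG is a DMCpG when
  |Δβ| > 0.25 and q < 0.05. Cross-comparison overlaps and
  differentiation-stage remodeling classification reuse the same
  criterion.
- **Genomic annotation** — strand-aware gene-region labels (TSS200,
  1.5 kb/10 kb upstream, 5′UTR, first exon, gene body, 3′UTR, 1.5 kb/10 kb
  downstream, intergenic), CpG-island relation (island / shore ≤ 2 kb /
  shelf 2–4 kb / open sea), 15-state chromatin segmentation collapsed to 8
  functional categories, and TFBS-cluster overlaps, under explicit 0-based
  half-open (tracks) vs 1-based (probes) coordinate conventions.
- **Differential expression** — median-based gene filtering and an
  empirical-Bayes moderated t-test: per-gene pooled variance s²_g is
  shrunk toward a prior (d₀, s₀²) fitted by digamma/trigamma moment
  matching, s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), with d₀ + d_g degrees
  of freedom; plus ΔΔCt relative quantification and cross-platform
  concordance.
- **Integration and enrichment** — probe–gene pairing via shared gene
  annotations, Spearman correlation of methylation and expression with
  FDR over the full pair set, Fisher-exact category and TFBS enrichment
  with log₂ proportion ratios, TF-expression vs average enhancer
  methylation correlation, and the TF–TF Pearson co-expression matrix.
- **Synthetic studies** — a generator that plants all of the above
  structure (enhancer-biased hypermethylation, stage-specific effects,
  control-only differentiation remodeling, TF coupling) with a
  ground-truth ledger, so every stage is testable end to end without any
  external data.

## Worked example

```python
import methlink as ml

study = ml.simulate_study(seed=1, n_probes=5000, n_planted_dm=500,
                          n_genes=1000, n_planted_deg=100)
beta, report = ml.filter_probes(study.beta["DAn"],
                                study.detection_p["DAn"], study.manifest)
dm = ml.call_dmcpgs(beta, study.samples("DAn", "PD"),
                    study.samples("DAn", "control"))
print(int(dm["called"].sum()))
```

Running `examples/02_differential_methylation.py` (the script version of
the above) prints:

```
463 DMCpGs called (233 hyper)
sensitivity 0.93, empirical FDR 0.000
fibroblast: 0 calls (planted null)
iPSC: 0 calls (planted null)
```

463 of the 500 planted differentially methylated CpGs are recovered with
no false calls, and the precursor cell stages — where no effect was
planted — yield nothing, as they should. The other scripts under
`examples/` walk through annotation and enhancer enrichment, moderated
differential expression and methylation–expression pairing, TF-network
coupling, remodeling classification and ΔΔCt recovery, each printing the
numbers it computes and what they mean.

A subcommand CLI mirrors the library for shell use:

```sh
methlink simulate --out work/ --seed 1
methlink qc --workdir work/
methlink dm --workdir work/ --case PD --control control --stage DAn
methlink annotate --workdir work/ && methlink deg --workdir work/
methlink integrate --workdir work/ && methlink enrich --workdir work/
methlink report --workdir work/
```

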