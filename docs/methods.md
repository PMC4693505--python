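# Methods

## Scope and model

`methlink` analyses two-group (case/control) DNA methylation array data
with matched log2 expression, in cohort designs where each subject is
measured at several cell stages (fibroblast, iPSC, differentiated neuron,
non-target neural culture). The central measurement is the beta value
β = M/(M+U+offset) ∈ [0,1]; the default offset is 0 (the pure intensity
ratio), with an optional nonnegative offset for platforms that stabilise
low-intensity probes.

## Statistical kernels

**Wilcoxon rank-sum.** Two-sided. Exact by enumeration of rank
assignments whenever the combined group size is ≤ 14 and the data are
tie-free; the cutoff covers the 10-vs-4 and smaller designs this package
targets while keeping enumeration trivial (C(14,4) = 1001 arrangements).
Otherwise a normal approximation with average-rank tie correction and
continuity correction is used; tied exact-eligible input also falls back
to the approximation. Degenerate input (all values identical) returns
p = 1. The exact two-sided p is 2·min(P(W ≤ w), P(W ≥ w)) capped at 1.
Note the granularity consequence: with n₁ = 10 vs n₂ = 4 the smallest
attainable two-sided p is 2/1001 ≈ 0.002, and with 4 vs 4 it is
2/70 ≈ 0.029. Any FDR threshold must be reachable given this floor and
the number of true effects; the simulator warns when a configuration
makes recovery impossible by construction.

**Benjamini–Hochberg.** Step-up adjustment, clipped at 1, applied per
comparison family (one DMCpG contrast, one enrichment run, one pair set)
and never pooled across families. Missing p-values propagate and do not
count toward the family size.

**Fisher exact test.** Two-sided by the minimum-likelihood
(probability-mass) rule: the p-value sums hypergeometric probabilities of
all tables with the observed margins whose probability does not exceed
the observed table's (within relative tolerance 1e-7). The odds ratio is
the sample odds ratio ad/bc with an infinity sentinel when bc = 0.

**Correlation.** Spearman ranks with average ranks for ties, then the
Pearson formula; p from the t-distribution with n−2 df in both modes,
also at small n (no exact permutation p). Constant input yields an
undefined-coefficient sentinel with missing p.

**Moderated two-group test.** Per gene, the within-group pooled variance
s²_g on d_g = n₁+n₂−2 df is shrunk toward an inverse-chi-square prior
(d₀, s₀²) estimated from all genes by moment matching on
e_g = log s²_g − ψ(d_g/2) + log(d_g/2): the mean of e identifies s₀² and
the excess of its variance over ψ′(d_g/2) identifies d₀ through trigamma
inversion (Newton iteration). The posterior variance is the convex
combination s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g); the moderated t uses
d₀+d_g df. Estimated d₀ = ∞ (no variance heterogeneity, as in fully
homoskedastic simulations) tests every gene against s₀²; forcing d₀ = 0
recovers the ordinary equal-variance t exactly. Zero-variance genes are
handled by the prior whenever d₀ > 0. Only two-group contrasts are
supported; multi-group designs are analysed as pairwise contrasts. The
implementation is cross-checked against the Bioconductor limma reference
in the test suite.

## Pipeline conventions

**Probe filtering** removes, sequentially and disjointly: SNP-flagged
probes, probes with detection p > 0.01 in *at least one* sample (the
strictest reading of "poor detection"), and all probes on chrX/chrY (the
operational stand-in for "sex-specific methylation"; an explicit probe
list can be supplied through the manifest instead). The bookkeeping
identity n_remaining = n_initial − removed(snp) − removed(detection) −
removed(sex) is asserted on every run.

**DMCpG calling**: Δβ = mean(case) − mean(control) with per-group missing
exclusion; called iff |Δβ| > 0.25 (strict) and BH q < 0.05 (strict), FDR
family = all probes tested in that comparison. Direction is hyper iff
Δβ > 0. Calls are antisymmetric under group swap.

**Remodeling classification**: a called site is "changed" between two
stages within a group iff the stage1-vs-stage2 comparison restricted to
the evaluated site set meets the identical DMCpG criterion; the FDR
family is that site set, not the whole array. The stage comparison is
unpaired even though subjects overlap across stages — it reuses the
stated calling machinery verbatim; a paired variant is out of scope.

**Coordinates**: interval tracks are BED 0-based half-open; probe
positions are 1-based; the single conversion pos−1 is applied in the
overlap helper. CGI distance bands are shore = [1, 2000] and
shelf = [2001, 4000] bp from the nearest island edge, inclusive on both
ends, so the relation partitions positions without gaps. Upstream gene
windows are TSS200 = [1, 200], 1.5 kb = [201, 1500], 10 kb = [1501,
10000] bp 5′ of the TSS (strand-aware), mirrored downstream of the 3′
end; the gene body runs from the end of the first exon to the transcript
3′ end. A probe keeps every label from every overlapping gene
(any-membership), and category counts downstream count a probe once per
category.

**Gene filtering** removes genes with mean signal strictly below the
median of all gene means, then genes with SD strictly below the median SD
of the survivors — in that order, which matters and is asserted by a
fixture. "Mean signal" is the overall mean across samples; a
max-of-group-means variant exists behind a flag.

**Enrichment**: 2×2 tables compare the foreground against the background
*excluding* the foreground, keeping the two columns disjoint; the log₂
ratio still uses the plain fg/bg proportion ratio. Zero proportions give
±∞ sentinels rather than pseudocounts (a 0.5-pseudocount option exists);
the Fisher p carries the inference. TF membership is binary per probe
(≥ 1 overlapping cluster interval). The background defaults to all
QC-surviving probes.

**Integration**: one pair per (called probe, annotated gene) with the
gene present in the filtered expression matrix; Spearman across the
pooled case+control sample set; BH over the full pair set; sign classes
(inverse/positive) reported for significant pairs only, with both
pair-level and unique-probe/gene counts.

## Synthetic study generator

The generator emulates the study geometry the pipeline targets, with
defaults: 20,000 probes, 10 cases vs 4 controls, 2,000 planted DMCpGs
(half hyper, half hypo) with effect Δβ = 0.3 — above the 0.25 call
threshold by one noise SD — beta noise 0.05, 12% background enhancer
chromatin, 35% enhancer rate among planted hyper sites, 5,000 genes with
400 planted DEGs at |log2FC| = 1.5 and residual SD 0.5, 25 TFs of which
4 are coupled to enhancer methylation, and a 0.4 control-only
iPSC→neuron remodeling amplitude.

Noise is logit-normal: Gaussian on the logit scale with the SD scaled by
1/(μ(1−μ)) so the induced beta-scale SD approximates the configured
value at every baseline, keeping values strictly inside (0,1) without
truncation. Subjects carry a small shared intercept across stages
(SD 0.01) and, at the planted hyper enhancer sites in the neuron stage, a
per-subject enhancer-methylation factor (SD 0.05) shared across sites —
the inter-individual variation that the TF-coupling analysis measures.

The planted effect model is stage-specific. Fibroblast, iPSC and
non-target neural stages are null for the case/control contrast. In the
neuron stage: non-enhancer hyper sites shift +0.3 in cases; hyper
enhancer sites start methylated (0.6–0.8) in precursors and demethylate
by 0.4 in control neurons but only by 0.1 in case neurons; hypo sites
start unmethylated and gain 0.4 in controls but only 0.1 in cases. Both
remodeling-driven classes therefore realise a case−control difference of
exactly ±0.3 while cases approximately retain precursor levels — the
incomplete-remodeling signature — and the number of control-changing
sites is large enough that the 4-vs-4 exact-test p floor (0.029) clears
the BH threshold within the evaluated site set. Coupled TF expression is
a + b·(average beta over planted hyper enhancer sites) + noise with
b = −4 per beta unit; the qPCR panel derives Ct = 30 − log2-expression
plus a per-sample offset that the three endogenous-control assays cancel
under ΔΔCt.

What the generator does *not* emulate: probe-type chemistry differences
and dye bias, batch structure, cell-composition heterogeneity, spatially
correlated methylation (neighbouring CpGs are independent), realistic
gene/TFBS genomic density, and mean–variance coupling in expression
(genes are homoskedastic, so the moderation prior is typically estimated
as d₀ = ∞ on synthetic expression; heteroskedastic recovery is exercised
separately with scaled-inverse-chi-square simulations). Passing the
end-to-end tests therefore demonstrates correctness of the statistical
machinery and bookkeeping under the planted model, not robustness to
those real-data artefacts.

## Problem sizes and numerics

The default test and acceptance runs use the full 20,000-probe, 4-stage,
14-subject configuration (about ten seconds end to end); unit tests use
400–2,000-probe versions of the same geometry. Kernel oracles enumerate
all rank assignments up to combined n = 12 and all 2×2 tables to N = 30
exhaustively plus a random slice to N = 40. All randomness flows from a
single integer seed through independent named streams (tracks,
methylomes, expression), so every object is bit-reproducible under a
fixed configuration; reruns write byte-identical files. Trigamma
inversion uses Newton iteration with a relative tolerance of 1e-10;
PCA signs follow a largest-|loading|-positive convention; hierarchical
clustering pre-sorts samples lexicographically so ties break
deterministically.

## Known limitations

Two-group contrasts only (no covariates, no design matrices); unpaired
stage comparisons; no region-level (DMR) aggregation; no dye-bias or
quantile normalisation (inputs are assumed preprocessed); the chromatin
segmentation and TFBS resources are user-supplied tracks, not bundled;
GO/ontology enrichment against live databases is out of scope (the
generic category-enrichment statistic is the supported primitive).
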