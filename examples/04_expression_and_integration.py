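"""Differential expression and methylation-expression correlation.

Genes are filtered at the median of means then the median of SDs,
differential expression uses an empirical-Bayes moderated t-test, and the
called DMCpGs are paired with the genes they annotate to and correlated
(Spearman) with their expression across the shared neuron samples.
"""

import methlink as ml

study = ml.simulate_study(seed=1, n_probes=5000, n_planted_dm=500,
                          n_genes=1000, n_planted_deg=100)
beta, _ = ml.filter_probes(study.beta["DAn"], study.detection_p["DAn"], study.manifest)
dan = study.samples("DAn")
groups = ["PD" if g != "control" else "control"
          for g in study.sample_sheet.loc[dan, "group"]]

expr = ml.filter_genes(study.expression[dan])
deg = ml.call_degs(expr, groups, case="PD", control="control")
print(f"{len(expr)} genes tested, {int(deg['called'].sum())} DEGs "
      f"(moderation prior d0 = {deg.attrs['moderation_d0']:.1f})")

dm = ml.call_dmcpgs(beta, study.samples("DAn", "PD"), study.samples("DAn", "control"))
ann = ml.annotate_probes(study.manifest.loc[beta.index], study.genes,
                         study.cgi, study.chromatin, study.tfbs)
pairs = ml.pair_probes_genes(dm.index[dm["called"]], ann, expr.index)
pairs = ml.correlate_meth_expr(pairs, beta, expr, dan)
summary = ml.summarize_correlations(pairs, ann)
print(f"{summary['n_pairs_total']} probe-gene pairs, "
      f"{summary['n_pairs_significant']} significant "
      f"({summary['n_unique_probes']} unique probes)")
# Pairing follows shared gene annotations; BH correction runs over the
# full pair set, and significant pairs are classified inverse/positive.
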