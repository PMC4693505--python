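"""Transcription-factor coupling to enhancer hypermethylation.

Four planted TFs have expression negatively coupled to the per-sample
average methylation of the hypermethylated enhancer sites.  The analysis
averages methylation over those sites, correlates every TF's expression
with it (Spearman, BH across TFs), and computes the TF-TF Pearson
co-expression matrix.
"""

import methlink as ml

study = ml.simulate_study(seed=1, n_probes=5000, n_planted_dm=500,
                          n_genes=1000, n_planted_deg=100)
beta, _ = ml.filter_probes(study.beta["DAn"], study.detection_p["DAn"], study.manifest)
dan = study.samples("DAn")
dm = ml.call_dmcpgs(beta, study.samples("DAn", "PD"), study.samples("DAn", "control"))
ann = ml.annotate_probes(study.manifest.loc[beta.index], study.genes,
                         study.cgi, study.chromatin, study.tfbs)

hyper = dm.index[dm["called"] & (dm["direction"] == "hyper")]
enh_sites = [p for p in hyper if ann.loc[p, "chromatin_category"] == "enhancer"]
tf_expr = study.expression.loc[[g for g in study.expression.index if g.startswith("TF")], dan]

corr, avg_meth = ml.tf_enhancer_methylation_correlation(tf_expr, enh_sites, beta, dan)
hits = corr[(corr["q"] < 0.05) & (corr["rho"] < 0)]
print(f"average methylation over {len(enh_sites)} hyper enhancer sites: "
      f"{avg_meth.min():.2f}-{avg_meth.max():.2f}")
print(f"TFs inversely coupled (q < 0.05): {sorted(hits.index)}")
print(f"planted coupled TFs:              {sorted(study.truth.coupled_tfs)}")

r, p = ml.tf_network_matrix(tf_expr)
block = r.loc[study.truth.coupled_tfs, study.truth.coupled_tfs]
print(f"mean |r| within the coupled TF block: "
      f"{block.abs().to_numpy()[~(block == 1).to_numpy()].mean():.2f}")
# The coupled TFs share the enhancer-methylation signal, so they also
# co-express as a block in the TF-TF correlation matrix.
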