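"""Differentiation remodeling of DMCpGs and qPCR fold-change recovery.

For each called DMCpG, the iPSC -> neuron transition is re-tested within
each group with the same calling criterion; controls remodel (demethylate
enhancers, methylate the hypomethylation targets) while cases largely
retain precursor levels.  The delta-delta-Ct helper then recovers the
planted fold changes from the synthetic qPCR panel.
"""

import methlink as ml

study = ml.simulate_study(seed=1, n_probes=5000, n_planted_dm=500,
                          n_genes=1000, n_planted_deg=100)
result = ml.run_pipeline(study)

print(result.remodeling_fractions.round(3).to_string())
# Controls change most DMCpGs across differentiation; cases keep them --
# the incomplete-remodeling signature the pipeline is built to expose.

sheet = study.sample_sheet
dan = sheet.index[sheet["cell_stage"] == "DAn"]
case = [s for s in dan if sheet.loc[s, "group"] != "control"]
ctrl = [s for s in dan if sheet.loc[s, "group"] == "control"]
print("\nqPCR panel (delta-delta-Ct vs planted truth):")
for gene, true_fc in study.truth.qpcr_true_log2fc.items():
    est = ml.ddct_fold_change(study.ct_table, gene, case, ctrl)["log2fc"]
    print(f"  {gene}: log2FC {est:+.2f} (planted {true_fc:+.2f})")
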