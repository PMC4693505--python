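"""Generate a synthetic case/control methylation study and run probe QC.

The generator plants 10% differentially methylated CpGs (effect 0.3 on the
beta scale) in the neuron stage of a 10-case / 4-control cohort, then the
QC step removes SNP-flagged, detection-failing and sex-chromosome probes
and selects variable sites for exploratory analysis.
"""

import methlink as ml

study = ml.simulate_study(seed=1, n_probes=5000, n_planted_dm=500,
                          n_genes=1000, n_planted_deg=100)

beta, report = ml.filter_probes(
    study.beta["DAn"], study.detection_p["DAn"], study.manifest
)
print(f"probes: {report.n_initial} initial"
      f" - {report.n_removed_snp} SNP"
      f" - {report.n_removed_detection} detection"
      f" - {report.n_removed_sex} sex = {report.n_remaining} remaining")

variable = ml.select_variable_sites(beta, sd_threshold=0.1)
print(f"{variable.shape[0]} sites with across-sample SD > 0.1")

scores, var_frac, _ = ml.pca_embed(variable)
print(f"PC1 explains {var_frac[0]:.1%} of variance; sample scores:")
print(scores["PC1"].round(2).to_string())
# Cases and controls separate on PC1 because the planted case-only effect
# dominates the variable-site signal in the neuron stage.
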