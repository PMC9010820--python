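# Example pipeline configuration: simulate a small cohort and analyse it.
# Use input paths instead of the simulate block for real data:
#   [input]
#   quant = "quant.tsv"
#   sheet = "samples.tsv"

seed = 1
outdir = "pipeline_demo"

[simulate]
n_patients = 12
n_proteins = 2000

[thresholds]
stage_fc = 4.0
stage_q = 0.05
compartment_fc = 2.0
compartment_q = 0.05
min_obs = 3

[preprocess]
max_missing = 0.5
n_components = 5
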