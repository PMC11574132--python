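# Demo pipeline: three simulated models sharing a planted 51-gene core,
# microarray-style intensities, full chain through enrichment.
seed: 0
outdir: isrdep_demo
mode: intensity
n_genes: 2000
n_per_group: 4
k_models: 3
shared_core: 51
model_private: 20
noise_sd: 0.25
effect_size: 2.0
reversion_fraction: 1.0
target_set_size: 80
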