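# Demo pipeline configuration (all values are the package defaults).
seed: 42
image_chromosome: 9
half_width_um: 1.2
window_um: 2.0
min_prominence_rel: 0.15
merge_window_um: 1.0
smooth_sigma_um: 0.15
k_sd: 0.5
aggregation: mean
n_levels: 8
alpha: 0.05
profile_noise_sd: 10.0
image_noise_sd: 5.0
stage_contractions: [0.40, 0.45, 0.656, 0.158, 0.30]
stage_base_lengths: [4.87, 6.5, 5.5, 5.0, 4.6]
n_stages: 6
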