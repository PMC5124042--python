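output_dir: demo_out
seed: 1
simulate:
  n_subjects: 8
  age_range: [49, 87]
  geometry:
    shape: [16, 16, 16]
    layout: two_compartment
  tissues:
    - {label: GM, region_label: 1, proton_density: 1000, t2_ms: 90, t2_age_slope: 0.0}
    - {label: WM, region_label: 2, proton_density: 1000, t2_ms: 70, t2_age_slope: 0.3}
  acquisition:
    noise_sigma: 14
region_pairs:
  - [GM, WM]
modalities: [T2w, T2map]
trend:
  n_boot: 200
reliability:
  magnitudes: [0.5, 1.0]
  n_iter: 10
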