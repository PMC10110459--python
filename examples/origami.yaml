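# 3x3 DNA-origami grid, 12-nm spacing, repeated-binding imaging
optics:
  fwhm_conf: 250.0
  sbr_max: 60.0
localizer:
  alpha: 0.15
  e_max: 1.0
  n_on: 100
  max_duration_ms: 200.0
sample:
  kind: origami
  spacing_nm: 12.0
  layout: rect
  duration_s: 120.0
  kinetics:
    mean_bound_ms: 150.0
    mean_dark_s: 30.0
    labeling_efficiency: 0.85
    linker_length_nm: 1.0
    site_jitter_nm: 0.72
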