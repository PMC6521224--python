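# End-to-end demo: small phantom + cohort of 40, all stages.
seed: 7
outdir: pufa_demo
stages: [phantom, segment, cohort, screen, randomize, simulate, power, analyze]
phantom:
  grid_shape: [48, 48, 48]
lesions:
  - center: [14, 32, 32]
    semi_axes: [3, 3, 3]
    z: 4.0
    intended_class: deep
cohort:
  n: 40
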