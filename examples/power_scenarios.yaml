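# The trial's design scenarios for two-arm comparisons of mean 3-year change.
# Load with pufakit.pipeline.RunConfig (power_scenarios:) or read directly.
power_scenarios:
  - name: wmh_primary        # placebo 7.0 vs active 3.5 cm^3, SD 5
    delta: 3.5
    sd1: 5.0
    sd2: 5.0
  - name: sicam              # 269.34 (78.89) vs 219.19 (39.12) ng/mL
    delta: 50.15
    sd1: 39.12
    sd2: 78.89
  - name: trails_b           # 3-year change 12 (13) vs 3.7 (13) seconds
    delta: 8.3
    sd1: 13.0
    sd2: 13.0
  - name: digit_symbol       # 3-year change 2.3 (2) vs 0.7 (2) points
    delta: 1.6
    sd1: 2.0
    sd2: 2.0
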