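# ARAF knockout with compensatory BRAF overexpression, oncogenic RAS.
# Base: [BRAF] = [CRAF] = 50 nM, [ARAF] = 200 nM (ARAF-high parental state).
# Variant: [BRAF] = 100 nM, [CRAF] = 50 nM, [ARAF] = 0 nM (knockout clone).
# Expected: the knockout condition crosses below basal at a lower Type II
# dose (sensitization) but shows no such sensitization for Type I1/2.
name: fig4a_araf_ko
condition:
  araf: 200.0
  braf: 50.0
  craf: 50.0
  ras_status: mutant
  rtk_activity: low
variants:
  - araf: 0.0
    braf: 100.0
inhibitors:
  - preset: II
  - preset: I_half
doses:
  unit: kd
  lo: 0.01
  hi: 3000.0
  points_per_decade: 3
analyses:
  - kind: dose_response
    inhibitor: II
  - kind: dose_response
    inhibitor: I_half
expected:
  typeII_sensitized_by_ko: true
  typeIhalf_not_sensitized: true
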