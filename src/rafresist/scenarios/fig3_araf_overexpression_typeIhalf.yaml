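# Companion to fig3_araf_overexpression for the Type I1/2 preset (a separate
# scenario because the pairwise cross-factors differ between inhibitor pairs).
name: fig3_araf_overexpression_typeIhalf
condition:
  araf: 50.0
  braf: 50.0
  craf: 50.0
  ras_status: mutant
  rtk_activity: low
variants:
  - araf: 200.0
inhibitors:
  - preset: I_half
doses:
  unit: kd
  lo: 0.01
  hi: 3000.0
  points_per_decade: 3
analyses:
  - kind: dose_response
    inhibitor: I_half
expected:
  paradox_range_increases_with_araf: true
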