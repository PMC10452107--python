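# Oncogenic-RAS cells (stationary RAS-GTP ~250 nM).  ARAF 50 nM (base) versus
# 200 nM (variant); BRAF = CRAF = 50 nM.  Dose responses for all three
# inhibitor-type presets.  Expected: ARAF overexpression increases both the
# peak fold-activation and the basal-crossing dose for every inhibitor type.
name: fig3_araf_overexpression
condition:
  araf: 50.0
  braf: 50.0
  craf: 50.0
  ras_status: mutant
  rtk_activity: low
variants:
  - araf: 200.0
inhibitors:
  - preset: II
  - preset: I
doses:
  unit: kd
  lo: 0.01
  hi: 3000.0
  points_per_decade: 3
analyses:
  - kind: dose_response
    inhibitor: II
  - kind: dose_response
    inhibitor: I
expected:
  paradox_range_increases_with_araf: true
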