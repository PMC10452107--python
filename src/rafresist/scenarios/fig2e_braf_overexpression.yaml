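# Wild-type RAS cells (stationary RAS-GTP ~25 nM), Type II RAF inhibitor.
# BRAF abundance 50 nM (base) versus 200 nM (variant); CRAF = ARAF = 50 nM.
# Expected: the overexpressed-BRAF condition has a higher basal ppERK and a
# smaller range of paradoxical activation relative to that basal.
name: fig2e_braf_overexpression
condition:
  araf: 50.0
  braf: 50.0
  craf: 50.0
  ras_status: wild-type
  rtk_activity: low
variants:
  - braf: 200.0
inhibitors:
  - preset: II
doses:
  unit: kd
  lo: 0.01
  hi: 3000.0
  points_per_decade: 3
analyses:
  - kind: dose_response
    inhibitor: II
expected:
  basal_raised_by_braf: true
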