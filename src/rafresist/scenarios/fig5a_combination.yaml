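# Combination of Type I and Type II RAF inhibitors in RAF-overexpressing
# oncogenic-RAS cells: [BRAF] = [ARAF] = 100 nM, [CRAF] = 50 nM.
# Expected: concave Loewe isoboles with median combination index < 1 over a
# wide range of effect levels (synergy).
name: fig5a_combination
condition:
  araf: 100.0
  braf: 100.0
  craf: 50.0
  ras_status: mutant
  rtk_activity: low
inhibitors:
  - preset: I
  - preset: II
doses:
  unit: kd
  lo: 0.1
  hi: 1000.0
  points_per_decade: 2
analyses:
  - kind: combination
  - kind: isobole
    effects: [0.5, 0.3, 0.2, 0.1]
expected:
  median_ci_below_1: true
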