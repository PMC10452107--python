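# rafresist

Mechanistic models of drug resistance caused by overexpression of a targeted
kinase, built around the RAS/RAF/MEK/ERK (MAPK) pathway and
conformation-specific RAF inhibitors.

When a tumour cell raises the abundance of the kinase a drug targets, the dose
needed to keep the same inhibition level rises.  How steeply it rises depends
on whether the kinase dimerizes and on the allosteric effects of the drug:
RAF inhibitors promote RAF dimerization, and a singly-drug-bound RAF dimer
keeps (and transactivates) one catalytically active protomer — the source of
*paradoxical activation* of ERK signalling.  `rafresist` implements this
physics at three levels:

1. **`core_monomer`** — analytic dose-shift model for a non-dimerizing kinase
   E with substrate S under non-competitive inhibition.  Conservation laws
   `E(1+I/Kd)(1+S/KS) = Etot`, `S[1+(E/KS)(1+kcat/kp+I/Kd)] = Stot`; the exact
   fold-increase in dose F(L) after L-fold overexpression is solved by
   bracketed root finding, with closed forms
   `F = (L(1+I0/Kd)−1)/(I0/Kd)` (kinase-limiting) and a substrate-limiting
   form that plateaus at `(KS+Stot)/E0tot`.
2. **`dimer_kinase`** — five-species equilibrium model (R, RI, RR, RRI, IRRI)
   of a dimerizing kinase with thermodynamic factors f (drug-induced
   dimerization) and g (second-site cooperativity); closed-form equilibrium
   and IC50-fold curves F(L).
3. **`pathway_network` + `inhibitor_pharmacology` + `response_analysis`** —
   a rule-based, energy-consistent model of RTK→SOS→RAS→RAF(ARAF/BRAF/CRAF)
   →MEK→ERK with ppERK negative feedback, expanded to an explicit reaction
   network (551 species, ~5,000 reactions at the default configuration) and
   integrated to steady state; dose-response curves, paradoxical-activation
   metrics (peak fold-activation, basal-crossing dose), two-drug surfaces and
   Loewe isobole/combination-index synergy analysis on top.

Inhibitors are classed by preferred kinase conformation — Type I
(αC-IN/DFG-IN), Type II (αC-IN/DFG-OUT), Type I½ (αC-OUT/DFG-IN) — and their
dimer-context affinities by the eight thermodynamic factors fa…g3b with an
explicit free-energy cycle-closure validator.  See `docs/methods.md` for the
model description, parameter defaults and their rationale.

## Worked example

Steady state of the full pathway model in oncogenic-RAS cells (RAS-GAP rate
divided by 10), no drug:

```
$ rafresist simulate --ras mutant
ppERK: 2.1209
ppMEK: 30.2894
RASGTP: 259.9472
dimer_BB: 1.7246
dimer_BC: 1.0873
dimer_total: 3.9085
raf_activity: 18.9185
converged: True (t = 20 h)
```

The stationary RAS-GTP pool is ~260 nM of the 750 nM total (vs ~26 nM for
`--ras wild-type`): the ten-fold GAP reduction raises active RAS ten-fold.
Basal ppERK (2.1 nM here) is the reference level for dose-response analysis —
absolute ppERK values are model units; the meaningful outputs are fold-changes
and dose orderings.

A Type II RAF inhibitor dose-response under the same condition:

```
$ rafresist dose-response --ras mutant --inhibitor II --lo 0.3 --hi 3000
...
basal: 2.1209
peak fold-activation: 7.002 at 7.536 nM
basal-crossing dose: 69.16 nM
```

ppERK rises to ~7× basal before falling — paradoxical activation caused by
drug-promoted dimerization with transactivation of the unoccupied protomer —
and only drops below the drug-free baseline beyond ~69 nM (6.9× the
inhibitor's Kd).  Raising ARAF abundance (`--araf 200`) increases both the
peak fold and the crossing dose for every inhibitor type: overexpression of
the target widens the paradoxical window, i.e. resistance.  A combination of
Type I and Type II inhibitors suppresses ERK synergistically
(`rafresist isobole --ras mutant --araf 100 --braf 100`; median Loewe
combination index < 1, concave isoboles).

Packaged scenarios provide ready-made reference conditions (BRAF/ARAF
overexpression, ARAF knockout with BRAF compensation, drug combinations):

```
$ rafresist scenario list
fig2e_braf_overexpression
fig3_araf_overexpression
fig3_araf_overexpression_typeIhalf
fig4a_araf_ko
fig5a_combination
$ rafresist scenario run fig3_araf_overexpression --outdir out/
```

Each run writes CSV curve/surface tables plus a provenance record (full
parameter snapshot and package version); repeated runs are byte-identical.

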