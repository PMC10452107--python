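# Methods

`rafresist` models how overexpression of a targeted kinase produces resistance
to small-molecule inhibitors, from a minimal analytic treatment up to a
rule-based model of the RAS/RAF/MEK/ERK (MAPK) pathway with three RAF isoforms
and conformation-specific RAF inhibitors.  Concentrations are nM and rates 1/s
throughout; simulated horizons are expressed in hours at the interface.

## 1. Monomeric-kinase dose-shift model (`core_monomer`)

A kinase E phosphorylates substrate S (product P, dephosphorylated at rate
kp); a non-competitive inhibitor I binds E and ES with the same Kd
(independent-site binding, so kinase occupancy factorizes).  Steady-state
moiety conservation gives

    E (1 + I/Kd)(1 + S/KS) = Etot
    S [1 + (E/KS)(1 + kcat/kp + I/Kd)] = Stot

with flux kcat·E·S/KS.  Given a reference dose I0 (any fixed inhibition level,
e.g. the IC50) at abundance E0tot, the dose fold F(L) that restores the
reference flux after L-fold overexpression is solved by bracketed root finding
on log10 F over [-12, 12] (Brent; flux is strictly decreasing in F, so the
bracketed root is unique; residual tolerance 1e-10 relative on the flux).

Two closed forms bound the exact solution:

* **kinase-limiting** (L·E0tot ≪ Stot):
  `F = (L(1 + I0/Kd) − 1)/(I0/Kd)`; for I0 ≫ Kd, F ≈ L — the dose tracks the
  abundance one-for-one.
* **substrate-limiting** (L·E0tot ≫ Stot ≫ E0tot):
  `F = [L(1+I0/Kd)(1+Stot/KS) − 1 − (L·E0tot/KS)(1+kcat/kp)] · KS·Kd/(L·E0tot·I0)`,
  which tends to `(KS + Stot)/E0tot` for I0 ≫ Kd, independent of L: once the
  substrate is limiting, further overexpression no longer demands much more
  drug.  This closed form was re-derived symbolically from the approximate
  conservation laws of the substrate-limited regime (the test suite repeats
  the derivation with sympy) and is validated against the exact solver to
  < 5% deep in its regime.

Callers get a `RegimeWarning` when a closed form is evaluated outside its
domain of validity, and a `RegimeError` when the substrate-limited form turns
negative (its assumptions are then violated, e.g. an extremely slow
phosphatase making P the dominant substrate pool).

## 2. Dimerizing-kinase model (`dimer_kinase`)

Five species — monomer R, inhibited monomer RI, dimer RR, singly-inhibited
dimer RRI, doubly-inhibited dimer IRRI — with two thermodynamic factors:
`f` (fold-increase in dimerization affinity caused by one bound inhibitor;
equivalently the fold-increase in inhibitor affinity for a dimer protomer) and
`g` (fold-change in affinity of the second inhibitor molecule).  With the
inhibitor clamped (total ≈ free; a conservation mode is available), every
species is an explicit function of free monomer R and protomer conservation is
a quadratic in R, so the equilibrium is closed-form.  Statistical factors use
the convention RR = R²/Kdim, RRI = 2fIR²/(Kdim·KdI), IRRI = f²gI²R²/(Kdim·KdI²),
which satisfies detailed balance around the binding cycle by construction.

Activity = a_mono·R + 2·a_dimer·RR + a_half·RRI.  Defaults: dimer protomers
10× more active than monomers (a_dimer = a_half = 10·a_mono); Kdim = 6.4·Rtot,
placing ~20% of protomers in dimers at baseline; KdI = 10 nM.  The default
allosteric inhibitor has f = 10, g = 0.005.  The product f²g < 1 is the
essential property: the drug promotes dimerization and first-site binding but
obstructs the second site, so silencing a dimer costs more drug than silencing
two monomers.  IC50-fold curves F(L) restore the reference activity (the dose
halving the uninhibited baseline activity) at L-fold abundance by bracketed
root search; points whose target is unreachable within the searched dose range
are reported as unbounded rather than failing the curve.

## 3. Inhibitor classes and thermodynamic factors (`inhibitor_pharmacology`)

RAF inhibitors are classified by the kinase conformation they prefer:
Type I (αC-IN/DFG-IN), Type II (αC-IN/DFG-OUT), Type I½ (αC-OUT/DFG-IN).
Conformational preference is treated thermodynamically (a Kd penalty for
non-preferred conformations) rather than as explicit conformational species.
Eight factors (fa, fb, g1a, g1b, g2a, g2b, g3a, g3b) scale the dissociation
constant of each binding context in a dimer for two inhibitor slots.  A
free-energy function exists only if every pair of binding orders reaching the
same doubly-bound dimer agrees: g2 = f·g1 per slot and fa·g3b = fb·g3a for the
mixed dimer.  `validate_cycle_closure` enumerates the orders and reports the
free-energy discrepancy of every violated cycle; the network builder rejects
inconsistent sets.  `closed_factors` constructs consistent sets from the free
parameters (f, g1 per slot, one cross-cooperativity).

Packaged presets (design choices; they encode qualitative structural
knowledge, not published numbers):

| preset | f | g1 | isoform Kd multipliers | rationale |
|---|---|---|---|---|
| I   | 0.05 | 100 | ARAF ×3 | αC-IN: binds and promotes dimers; strong second-site negative cooperativity; moderately ARAF-tolerant |
| II  | 0.1  | 30  | ARAF ×30 | αC-IN/DFG-OUT: weaker dimer promotion and window; ARAF pocket poorly druggable |
| I½  | 0.2  | 150 | ARAF ×0.3, CRAF ×10 | αC-OUT: cannot occupy the second protomer of a dimer at practical doses ("cannot inhibit RAF dimers"); BRAF-selective, weak CRAF binder |

Cross-cooperativity between two *different* inhibitor types is mild (×2)
because the two protomers of a dimer can adopt different conformations and
accommodate structurally different ligands — the mechanistic basis of the
combination synergy.

## 4. Rule-based pathway model (`pathway_network`)

### Molecules and sites

ARAF/BRAF/CRAF each carry: RBD (RAS binding), dimerization domain, inhibitor
pocket (two slots), inhibitory phosphosite, ppERK-feedback phosphosite;
ARAF/CRAF additionally carry the NtA activation phosphosite.  RTK activity is
a rate modifier; GRB2–SOS is one translocating unit; RAS cycles GDP/GTP; MEK
and ERK carry two phosphosites each.

### Structural assumptions that prune the state space

* Inhibitory phosphorylation (AKT/14-3-3-type autoinhibition) and ppERK
  feedback phosphorylation both lock RAF in a closed state: phosphorylated
  monomers can neither bind RAS nor dimerize, and the sites are only
  (de)phosphorylated on monomers.  Dimer protomers therefore carry
  unphosphorylated inhibitory/feedback sites.
* Oligomers beyond dimers are not modeled; dimers are unordered protomer
  pairs (canonicalized by sorting), homodimer kinetics carry the statistical
  factor 2 bookkeeping derived by explicit embedding enumeration.
* Inhibitor doses are clamped free concentrations (drug in excess).

### Energetics

Each species has a free energy: ln Kd per bond plus coupling terms — ln f per
(inhibitor, dimer bond), the pair coupling of two inhibitors in one dimer
(g1-derived for same drug, g3-derived for different drugs), −ln c_mem per
RAS-bound protomer of a dimer (membrane co-localization driving
dimerization), and per-pair dimer-interface multipliers.  Every reversible
binding reaction takes its equilibrium constant from this function, so
detailed balance holds around every cycle by construction; the kinetic split
φ = 0.5 distributes context-induced equilibrium shifts between forward and
reverse rates (steady-state binding equilibria are φ-independent, verified in
tests).

### Catalysis and feedback

MEK is phosphorylated (two steps, mass action) at a rate proportional to the
summed catalytic weight of RAF species: RAS-bound monomers at isoform-specific
weights (ARAF 0, BRAF 0.05 — autoinhibited as a monomer, CRAF 0.25); dimer
protomers with a free pocket at weight 1 (ARAF/CRAF require NtA
phosphorylation, which occurs in dimers, else weight 0.15); a protomer whose
partner is drug-bound is transactivated (weight ×3).  Dimer-interface
multipliers encode isoform hierarchy: ARAF is the weakest dimerizer (AA ×10,
AB/AC ×5 on the dimerization Kd) and BRAF the strongest homodimerizer
(BB ×0.3).  ppMEK phosphorylates
ERK (two steps); all dephosphorylations are first order.  ppERK
phosphorylates SOS (reducing RAS activation) and monomeric RAF (blocking RAS
binding and dimerization) — the negative feedback whose relief contributes to
pathway reactivation under drug.

### RAS module calibration

The GAP is saturable: every RAS-GTP moiety (free or RAF-bound) is hydrolysed
at rate `v_gap_max·[X]/(km_gap + T)` with T the total RAS-GTP, so the summed
flux is Michaelis–Menten in T and the RAS cycle decouples exactly from RAF
sequestration.  With basal exchange k_gef and total RAS 750 nM, requiring the
stationary RAS-GTP level to be 25 nM in wild-type cells (low RTK) and 250 nM
after dividing the GAP rate by 10 (oncogenic RAS) pins km_gap = 475 nM and
v_gap_max = 14500·k_gef.  SOS-driven exchange is a small perturbation at low
RTK (≤5% of basal); the SOS–GRB2 recruitment equilibrium is scaled 5-fold and
RTK activity multiplies the recruitment rate (×50 at high activity).

### Network generation and integration

Rules are expanded to a fixed point from the condition's seed species with
canonical deduplication and a species cap (default 50,000; overflow names the
runaway rule); every reaction is mass-balance-checked per elementary moiety.
The default three-isoform, two-inhibitor configuration expands to 551 species
and ~5,000 reactions; the engine always reports its own counts
(`net.n_species`, `net.n_reactions`).  ODEs are integrated with BDF and an
analytic sparse Jacobian (including the GAP competition cross-terms) at
rtol = 1e-8; atol defaults to 1e-8 × the system's concentration scale because
an absolute tolerance is unit-bound (with atol = 1e-8 nM the stepper spends
two orders of magnitude more steps resolving sub-femtomolar detail).  Each
condition is equilibrated for 10 h; if the stationarity criterion
max |dX/dt|/max(X, 1 nM) < 1e-6 h⁻¹ is not met the horizon doubles up to 80 h
before the result is flagged non-stationary.  Dose sweeps warm-start from the
neighbouring steady state.

## 5. Response analysis (`response_analysis`)

Dose grids are log-spaced and always include the zero dose; the packaged
default resolution is 4–7 points per decade (an explicit compute/resolution
trade-off: the curve metrics below interpolate between grid points, and
refinement can insert midpoints where neighbouring ppERK values differ by
more than 10% of basal).  Paradoxical activation is quantified by the peak
fold-activation (max ppERK / basal, flagged absent when the curve never
exceeds basal by >1%) and the basal-crossing dose — the smallest dose beyond
the peak at which ppERK falls back below the drug-free basal, log-linearly
interpolated, right-censored at the grid maximum when the curve never
returns.  Ties break toward the smaller dose.

Combination surfaces are full factorial steady-state evaluations whose margins
follow the exact single-drug code path.  Loewe isoboles are level sets of
ppERK traced row-wise with log-linear interpolation; the combination index at
an iso-effect point (d1, d2) is CI = d1/D1 + d2/D2 with D1, D2 the
equi-effective single-agent doses.  A point lies below the straight
additivity isobole exactly when CI < 1, so "concave isoboles" and "median
CI < 1" coincide.  Classification thresholds 0.9/1.1 on the median CI are
package conventions.  A synthetic exactly-additive surface (two dilutions of
one Hill curve) serves as the oracle: the pipeline must return CI = 1 ± 0.02
on it.

## 6. What the defaults do and do not claim

All kinetic parameters and thermodynamic factors are package defaults chosen
once to satisfy the documented qualitative constraints (dimer-driven
resistance orderings, paradoxical-activation windows, isoform-composition
effects, combination synergy) plus the quantitative RAS-module calibration;
they are not fitted to any dataset.  Consequences of this choice that a user
should know:

* Absolute ppERK numbers are model units, meaningful only relative to each
  condition's basal; only orderings and fold-changes are interpreted.
* Wild-type basal signaling is low (RAS-GTP is stoichiometrically limiting at
  25 nM), so wild-type dose responses operate near the bottom of the ERK
  cascade's amplification range.
* The simulated "cell" has no transcriptional adaptation, trafficking,
  degradation or pharmacokinetics; drug exposure is an equilibrium
  free-concentration clamp.
* BRAF^V600E monomer-driven signaling is out of scope; the model covers
  wild-type RAF with wild-type or mutant RAS.

Every empirical statement above (calibration values, orderings, CI behavior,
equilibrium equivalences) is recomputed by the test suite or by
`scripts/acceptance.py`; none is asserted from memory.
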