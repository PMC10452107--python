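"""Rule-based model definition and exhaustive network generation.

Species are canonical tuples:

* ``("RASgdp",)``, ``("RASgtp",)`` — free RAS nucleotide states;
* ``("SOS", loc)`` with loc in {"cyt", "mem", "phos"};
* ``("MEK", n)`` / ``("ERK", n)`` with n phosphorylated sites (0..2);
* ``("RAFm", p)`` — a RAF monomer with protomer state ``p``;
* ``("RAFd", p1, p2)`` — a RAF dimer, protomers sorted so that isomorphic
  (swapped) dimers map to a single canonical species.

A protomer state tracks isoform (A/B/C for ARAF/BRAF/CRAF), RBD occupancy
(``ras``), inhibitor pocket (``poc``: 0 free, 1 slot a, 2 slot b), the
inhibitory phosphosite (``ip``), the ppERK-feedback phosphosite (``fp``) and,
for ARAF/CRAF only, the NtA activation phosphosite (``ap``).  Two structural
constraints prune the state space and encode the biology of both regulatory
phosphosites: an inhibitory-phosphorylated RAF (14-3-3-clamped, autoinhibited)
and a feedback-phosphorylated RAF can neither bind RAS nor dimerize, so
``ip``/``fp`` are nonzero only on RBD-free monomers.

Binding energetics are defined by a free-energy function over species: each
bond contributes ``ln Kd`` and each allosteric coupling contributes the log of
its thermodynamic factor (inhibitor-dimer coupling f, inhibitor-inhibitor
coupling within a dimer derived from g1/g3, membrane co-localization 1/c_mem
per RAS-bound protomer of a dimer).  Every reversible binding reaction derives
its equilibrium constant from this function, so detailed balance holds around
every cycle by construction; the kinetic split parameter ``phi`` distributes
context-induced changes of the equilibrium constant between forward and
reverse rates.  Statistical factors for the two equivalent protomer positions
are counted by explicit enumeration of rule embeddings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, NamedTuple

import numpy as np
import pandas as pd

from ..errors import InvalidParameterError, NetworkOverflowError
from ..inhibitor_pharmacology import (
    InhibitorSpec,
    ThermodynamicFactors,
    validate_cycle_closure,
)
from .params import ISOFORMS, PathwayParameters, SimulationCondition

SpeciesKey = tuple


class Protomer(NamedTuple):
    iso: str  # "A" | "B" | "C"
    ras: int  # RBD: 0 free, 1 RAS-GTP bound
    poc: int  # inhibitor pocket: 0 free, 1 slot a, 2 slot b
    ip: int   # inhibitory phosphosite
    fp: int   # ppERK-feedback phosphosite
    ap: int   # NtA activation phosphosite (ARAF/CRAF only)


@dataclass(frozen=True)
class MoleculeTypeSpec:
    """Declarative molecule-type inventory entry (name + sites with states)."""

    name: str
    sites: tuple[tuple[str, tuple[str, ...]], ...]


def molecule_types() -> tuple[MoleculeTypeSpec, ...]:
    """The molecule types of the pathway model."""
    raf_sites = (
        ("RBD", ("free", "RAS")),
        ("dimerization", ("free", "bound")),
        ("pocket", ("free", "RAFi1", "RAFi2")),
        ("inhibitory_P", ("0", "P")),
        ("feedback_P", ("0", "P")),
    )
    act_site = (("activation_P", ("0", "P")),)
    return (
        MoleculeTypeSpec("ARAF", raf_sites + act_site),
        MoleculeTypeSpec("BRAF", raf_sites),
        MoleculeTypeSpec("CRAF", raf_sites + act_site),
        MoleculeTypeSpec("RTK", (("activity", ("low", "high")),)),
        MoleculeTypeSpec("SOS", (("location", ("cyt", "mem", "phos")),)),
        MoleculeTypeSpec("RAS", (("nucleotide", ("GDP", "GTP")),
                                 ("effector", ("free", "RAF")))),
        MoleculeTypeSpec("MEK", (("S218", ("0", "P")), ("S222", ("0", "P")))),
        MoleculeTypeSpec("ERK", (("T185", ("0", "P")), ("Y187", ("0", "P")))),
    )


@dataclass(frozen=True)
class RuleSpec:
    """Descriptor of one rule (documentation / BNGL export, not execution)."""

    name: str
    description: str
    reversible: bool
    forward_rate: float
    equilibrium_kd: float | None = None
    factors: str = ""
    phi: float = 0.5


@dataclass(frozen=True)
class Reaction:
    """One expanded unidirectional reaction (species referred to by key)."""

    reactants: tuple[SpeciesKey, ...]  # length 1 or 2; repeated key = order 2
    products: tuple[SpeciesKey, ...]
    k: float          # rate constant (per the rate_class semantics)
    rate_class: str   # "plain" | "dose_a" | "dose_b" | "gap"
    rule: str


@dataclass(frozen=True)
class ModelConfig:
    """Structural switches (used to build reduced/toy models)."""

    include_ras: bool = True
    include_sos: bool = True
    include_mek_erk: bool = True
    enable_feedback: bool = True
    enable_activation_phos: bool = True
    enable_inhibitory_phos: bool = True
    species_cap: int = 50_000


@dataclass(frozen=True)
class RuleModel:
    """A built rule model: condition, parameters, inhibitors and rule inventory."""

    condition: SimulationCondition
    params: PathwayParameters
    inhibitors: tuple[InhibitorSpec | None, InhibitorSpec | None]
    factors: ThermodynamicFactors
    config: ModelConfig
    rules: tuple[RuleSpec, ...]

    @property
    def isoforms(self) -> tuple[str, ...]:
        ab = self.condition.raf_abundance
        return tuple(i for i in ISOFORMS if ab[i] > 0)


def build_model(
    cond: SimulationCondition,
    inhibitors: Iterable[InhibitorSpec] = (),
    factors: ThermodynamicFactors | None = None,
    params: PathwayParameters | None = None,
    config: ModelConfig | None = None,
) -> RuleModel:
    """Assemble the rule model; inhibitor factor sets must pass cycle closure."""
    params = params or PathwayParameters()
    config = config or ModelConfig()
    factors = factors or ThermodynamicFactors()
    inh_list = list(inhibitors)
    if len(inh_list) > 2:
        raise InvalidParameterError("at most two simultaneous inhibitors supported")
    report = validate_cycle_closure(factors)
    if not report.passed:
        raise InvalidParameterError(
            "thermodynamic factors violate cycle closure: "
            + "; ".join(f"{name}: |dG| = {dg:.3g} kT" for name, dg in report.violations)
        )
    slots: tuple[InhibitorSpec | None, InhibitorSpec | None] = (
        inh_list[0] if len(inh_list) > 0 else None,
        inh_list[1] if len(inh_list) > 1 else None,
    )
    rules = _rule_inventory(cond, params, slots, config)
    return RuleModel(condition=cond, params=params, inhibitors=slots,
                     factors=factors, config=config, rules=rules)


def _rule_inventory(cond, params, slots, config) -> tuple[RuleSpec, ...]:
    p = params
    rules: list[RuleSpec] = []
    if config.include_sos and cond.sos_total > 0:
        rules.append(RuleSpec(
            "sos_translocation",
            "RTK-dependent GRB2-SOS membrane recruitment (KSOStransl-scaled)",
            True, p.sos_recruit_rate(cond.rtk_activity),
            p.k_sos_release / p.sos_recruit_rate(cond.rtk_activity)))
        if config.enable_feedback and config.include_mek_erk:
            rules.append(RuleSpec(
                "sos_feedback_phos", "ppERK phosphorylates SOS (negative feedback)",
                False, p.k_fb_sos))
            rules.append(RuleSpec(
                "sos_dephos", "SOS dephosphorylation", False, p.k_sos_dephos))
    if config.include_ras and cond.ras_total > 0:
        rules.append(RuleSpec(
            "ras_exchange_basal", "basal RAS GDP->GTP nucleotide exchange",
            False, p.gef_rate(cond.rtk_activity)))
        if config.include_sos and cond.sos_total > 0:
            rules.append(RuleSpec(
                "ras_exchange_sos", "membrane-SOS catalysed GDP->GTP exchange",
                False, p.k_gef_sos))
        rules.append(RuleSpec(
            "ras_gap", "saturable RAS-GAP hydrolysis of every RAS-GTP moiety",
            False, p.gap_vmax(cond.ras_status)))
        rules.append(RuleSpec(
            "raf_ras_binding", "RAF RBD binding to RAS-GTP (membrane recruitment)",
            True, p.kon_rbd, p.k_rbd, factors="1/c_mem per dimerized protomer",
            phi=p.phi))
    rules.append(RuleSpec(
        "raf_dimerization", "RAF homo-/heterodimerization (all isoform pairs)",
        True, p.kon_dim, p.kdim0,
        factors="f per bound inhibitor, pairwise g-derived coupling, "
                "1/c_mem per RAS-bound protomer", phi=p.phi))
    for n, spec in enumerate(slots, start=1):
        if spec is not None:
            rules.append(RuleSpec(
                f"inhibitor{n}_binding",
                f"{spec.name} (Type {spec.type_label}) pocket binding, "
                "dimer-context-dependent Kd",
                True, p.kon_inh, spec.Kd_ref, factors="f, g1, g3 per context",
                phi=p.phi))
    if config.enable_activation_phos:
        rules.append(RuleSpec(
            "nta_activation_phos",
            "NtA activation phosphorylation of ARAF/CRAF protomers in dimers",
            False, p.k_actp))
        rules.append(RuleSpec(
            "nta_dephos", "activation-site dephosphorylation", False, p.k_actdp))
    if config.enable_feedback and config.include_mek_erk:
        rules.append(RuleSpec(
            "raf_feedback_phos",
            "ppERK phosphorylates monomeric RAF; blocks RAS binding and "
            "dimerization", False, p.k_fb_raf))
        rules.append(RuleSpec(
            "raf_feedback_dephos", "feedback-site dephosphorylation",
            False, p.k_fb_dephos))
    if config.enable_inhibitory_phos:
        rules.append(RuleSpec(
            "raf_inhibitory_phos",
            "constitutive inhibitory-site phosphorylation of monomeric RAF "
            "(autoinhibited, cannot bind RAS or dimerize)", False, p.k_inh_phos))
        rules.append(RuleSpec(
            "raf_inhibitory_dephos", "inhibitory-site dephosphorylation",
            False, p.k_inh_dephos))
    if config.include_mek_erk:
        rules.append(RuleSpec(
            "mek_phosphorylation",
            "catalytically active RAF species phosphorylate MEK (2 sites)",
            False, p.k_mek))
        rules.append(RuleSpec("mek_dephos", "MEK dephosphorylation", False,
                              p.k_mek_dephos))
        rules.append(RuleSpec(
            "erk_phosphorylation", "ppMEK phosphorylates ERK (2 sites)",
            False, p.k_erk))
        rules.append(RuleSpec("erk_dephos", "ERK dephosphorylation", False,
                              p.k_erk_dephos))
    return tuple(rules)


# ---------------------------------------------------------------------------
# Energetics


def _slot_f(factors: ThermodynamicFactors, slot: int) -> float:
    return factors.fa if slot == 1 else factors.fb


def _pair_coupling(factors: ThermodynamicFactors, n: int, m: int) -> float:
    """Inhibitor-inhibitor coupling of a doubly-occupied dimer (slots n, m)."""
    if n == m:
        return factors.g1a if n == 1 else factors.g1b
    # cross coupling; cycle closure guarantees g3a/fa == g3b/fb
    return factors.g3a / factors.fa


def _site_kd(model: RuleModel, slot: int, iso: str) -> float:
    spec = model.inhibitors[slot - 1]
    assert spec is not None
    penalty = model.params.isoform_kd_penalty.get(spec.type_label, {}).get(iso, 1.0)
    return spec.Kd_ref * penalty


def _inhibitor_kd_eff(model: RuleModel, slot: int, protomer: Protomer,
                      partner: Protomer | None) -> float:
    """Context-dependent Kd for binding inhibitor `slot` to `protomer`."""
    kd = _site_kd(model, slot, protomer.iso)
    if partner is None:
        return kd
    kd *= _slot_f(model.factors, slot)
    if partner.poc != 0:
        kd *= _pair_coupling(model.factors, slot, partner.poc)
    return kd


def _dimer_kd_eff(model: RuleModel, p1: Protomer, p2: Protomer) -> float:
    """Dimerization Kd between two protomer states (from the energy function)."""
    kd = model.params.kdim0
    kd *= model.params.dimer_kd_mult.get(frozenset({p1.iso, p2.iso}), 1.0)
    for p in (p1, p2):
        if p.poc != 0:
            kd *= _slot_f(model.factors, p.poc)
        if p.ras:
            kd /= model.params.c_mem
    if p1.poc != 0 and p2.poc != 0:
        kd *= _pair_coupling(model.factors, p1.poc, p2.poc)
    return kd


def _ras_kd_eff(model: RuleModel, in_dimer: bool) -> float:
    kd = model.params.k_rbd
    if in_dimer:
        kd /= model.params.c_mem
    return kd


def _split_rates(kon: float, kd_eff: float, kd_base: float, phi: float
                 ) -> tuple[float, float]:
    """phi-split forward/reverse rates for a context-modified binding step."""
    kf = kon * (kd_eff / kd_base) ** (-phi)
    return kf, kf * kd_eff


# ---------------------------------------------------------------------------
# Species helpers


def _mono(p: Protomer) -> SpeciesKey:
    return ("RAFm", p)


def _dimer(p1: Protomer, p2: Protomer) -> SpeciesKey:
    a, b = sorted((p1, p2))
    return ("RAFd", a, b)


def _is_mono(sp: SpeciesKey) -> bool:
    return sp[0] == "RAFm"


def _is_dimer(sp: SpeciesKey) -> bool:
    return sp[0] == "RAFd"


def species_name(sp: SpeciesKey) -> str:
    """Human-readable canonical species identifier."""
    kind = sp[0]
    if kind in ("RASgdp", "RASgtp"):
        return {"RASgdp": "RAS_GDP", "RASgtp": "RAS_GTP"}[kind]
    if kind == "SOS":
        return f"SOS_{sp[1]}"
    if kind in ("MEK", "ERK"):
        return f"{kind}" + ("", "_p", "_pp")[sp[1]]
    if kind == "RAFm":
        return f"RAF{sp[1].iso}({_protomer_flags(sp[1])})"
    if kind == "RAFd":
        return (f"RAF{sp[1].iso}({_protomer_flags(sp[1])})"
                f":RAF{sp[2].iso}({_protomer_flags(sp[2])})")
    raise InvalidParameterError(f"unknown species kind {kind!r}")


def _protomer_flags(p: Protomer) -> str:
    flags = []
    if p.ras:
        flags.append("ras")
    if p.poc:
        flags.append(f"i{p.poc}")
    if p.ip:
        flags.append("ipP")
    if p.fp:
        flags.append("fbP")
    if p.ap:
        flags.append("actP")
    return ",".join(flags)


def moiety_counts(sp: SpeciesKey) -> dict[str, int]:
    """Elementary-component counts of a species (for mass-balance checks)."""
    counts: dict[str, int] = {}
    kind = sp[0]
    if kind == "RASgdp" or kind == "RASgtp":
        counts["RAS"] = 1
    elif kind == "SOS":
        counts["SOS"] = 1
    elif kind in ("MEK", "ERK"):
        counts[kind] = 1
    elif kind == "RAFm":
        counts[f"RAF_{sp[1].iso}"] = 1
        counts["RAS"] = sp[1].ras
    elif kind == "RAFd":
        for p in (sp[1], sp[2]):
            counts[f"RAF_{p.iso}"] = counts.get(f"RAF_{p.iso}", 0) + 1
            counts["RAS"] = counts.get("RAS", 0) + p.ras
    return {k: v for k, v in counts.items() if v}


def gtp_count(sp: SpeciesKey) -> int:
    """Number of RAS-GTP moieties carried by a species."""
    if sp[0] == "RASgtp":
        return 1
    if sp[0] == "RAFm":
        return sp[1].ras
    if sp[0] == "RAFd":
        return sp[1].ras + sp[2].ras
    return 0


def catalytic_activity(sp: SpeciesKey, params: PathwayParameters) -> float:
    """MEK-kinase activity weight of a RAF species.

    Monomers signal only when RAS-bound with a free pocket (ARAF monomers are
    silent); dimer protomers signal with a free pocket, at full weight for BRAF
    or NtA-phosphorylated ARAF/CRAF and at a reduced weight before NtA
    phosphorylation.  A singly-inhibited dimer retains its non-inhibited
    protomer's activity, further boosted by drug-induced transactivation
    (``act_transactivation``) — the combination of drug-promoted dimerization
    and partner transactivation drives paradoxical activation.
    """
    if _is_mono(sp):
        p = sp[1]
        if p.ras == 1 and p.poc == 0:
            return params.act_mono[p.iso]
        return 0.0
    if _is_dimer(sp):
        total = 0.0
        pair = (sp[1], sp[2])
        for i, p in enumerate(pair):
            if p.poc != 0:
                continue
            if p.iso == "B":
                w = params.act_dimer
            else:
                w = params.act_dimer if p.ap else params.act_dimer_unphos
            if pair[1 - i].poc != 0:
                w *= params.act_transactivation
            total += w
        return total
    return 0.0


# ---------------------------------------------------------------------------
# Network generation


@dataclass
class ReactionNetwork:
    """Expanded reaction network (canonical species, indexed reactions)."""

    species: list[SpeciesKey]
    reactions: list[Reaction]
    model: RuleModel
    index: dict[SpeciesKey, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {sp: i for i, sp in enumerate(self.species)}

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "index": range(self.n_species),
            "name": [species_name(sp) for sp in self.species],
        })

    def reaction_table(self) -> pd.DataFrame:
        rows = []
        for j, rxn in enumerate(self.reactions):
            rows.append({
                "index": j,
                "rule": rxn.rule,
                "reactants": " + ".join(species_name(s) for s in rxn.reactants),
                "products": " + ".join(species_name(s) for s in rxn.products),
                "rate_constant": rxn.k,
                "rate_class": rxn.rate_class,
            })
        return pd.DataFrame(rows)

    def check_mass_balance(self) -> None:
        """Every reaction conserves each elementary moiety (raises on failure)."""
        for rxn in self.reactions:
            lhs: dict[str, int] = {}
            rhs: dict[str, int] = {}
            for sp in rxn.reactants:
                for k, v in moiety_counts(sp).items():
                    lhs[k] = lhs.get(k, 0) + v
            for sp in rxn.products:
                for k, v in moiety_counts(sp).items():
                    rhs[k] = rhs.get(k, 0) + v
            if lhs != rhs:
                raise NetworkOverflowError(
                    f"mass imbalance in rule {rxn.rule!r}: {lhs} -> {rhs}"
                )


def _seed_species(model: RuleModel) -> list[SpeciesKey]:
    cond, config = model.condition, model.config
    seeds: list[SpeciesKey] = []
    if config.include_ras and cond.ras_total > 0:
        seeds.append(("RASgdp",))
    if config.include_sos and cond.sos_total > 0 and config.include_ras:
        seeds.append(("SOS", "cyt"))
    if config.include_mek_erk:
        seeds.append(("MEK", 0))
        seeds.append(("ERK", 0))
    for iso in model.isoforms:
        seeds.append(_mono(Protomer(iso, 0, 0, 0, 0, 0)))
    return seeds


def _positions(sp: SpeciesKey) -> tuple[Protomer, ...]:
    if _is_mono(sp):
        return (sp[1],)
    return (sp[1], sp[2])


def _replace_position(sp: SpeciesKey, i: int, q: Protomer) -> SpeciesKey:
    if _is_mono(sp):
        return _mono(q)
    ps = [sp[1], sp[2]]
    ps[i] = q
    return _dimer(ps[0], ps[1])


def _positional_edits(
    sp: SpeciesKey,
    eligible: Callable[[Protomer], bool],
    transform: Callable[[Protomer], Protomer],
) -> dict[tuple[SpeciesKey, Protomer, Protomer | None], int]:
    """Apply a per-protomer edit at every position; group by product species.

    Returns {(product, edited_protomer, partner): multiplicity}.  For a dimer
    whose two protomers are in the same eligible state the two embeddings give
    the same product (multiplicity 2); distinct states give distinct products.
    """
    out: dict[tuple[SpeciesKey, Protomer, Protomer | None], int] = {}
    ps = _positions(sp)
    for i, p in enumerate(ps):
        if not eligible(p):
            continue
        q = transform(p)
        partner = ps[1 - i] if len(ps) == 2 else None
        key = (_replace_position(sp, i, q), p, partner)
        out[key] = out.get(key, 0) + 1
    return out


def _reverse_multiplicity(product: SpeciesKey, reactant: SpeciesKey,
                          reverse: Callable[[Protomer], Protomer | None]) -> int:
    """Number of positions of `product` whose reversal restores `reactant`."""
    count = 0
    for i, p in enumerate(_positions(product)):
        q = reverse(p)
        if q is not None and _replace_position(product, i, q) == reactant:
            count += 1
    return count


def generate_network(model: RuleModel, *, species_cap: int | None = None
                     ) -> ReactionNetwork:
    """Exhaustively expand the rule set to a canonical reaction network.

    Expansion iterates rule application to a fixed point starting from the
    seed species of the condition; isomorphic complexes are canonicalized
    (sorted protomer tuples) so symmetric dimers are counted once.  Exceeding
    the species cap raises :class:`NetworkOverflowError` naming the rule that
    overflowed.
    """
    cap = species_cap or model.config.species_cap
    species: dict[SpeciesKey, None] = dict.fromkeys(_seed_species(model))
    reactions: dict[tuple, Reaction] = {}

    while True:
        reactions.clear()
        new_species: dict[SpeciesKey, None] = {}

        def emit(reactants, products, k, rate_class, rule):
            key = (tuple(reactants), tuple(products), rule, rate_class)
            if key in reactions:
                return
            reactions[key] = Reaction(tuple(reactants), tuple(products), k,
                                      rate_class, rule)
            for sp in products:
                if sp not in species and sp not in new_species:
                    new_species[sp] = None
                    if len(species) + len(new_species) > cap:
                        raise NetworkOverflowError(
                            f"species cap {cap} exceeded while expanding rule "
                            f"{rule!r}"
                        )

        _apply_rules(model, list(species), emit)
        if not new_species:
            break
        species.update(new_species)

    net = ReactionNetwork(species=list(species), reactions=list(reactions.values()),
                          model=model)
    net.check_mass_balance()
    return net


def _apply_rules(model: RuleModel, species: list[SpeciesKey], emit) -> None:
    cond, p, config = model.condition, model.params, model.config
    factors = model.factors
    have = set(species)
    monomers = [sp for sp in species if _is_mono(sp)]
    raf_species = [sp for sp in species if _is_mono(sp) or _is_dimer(sp)]
    erkpp = ("ERK", 2)
    mekpp = ("MEK", 2)

    # --- SOS translocation and feedback ---
    if ("SOS", "cyt") in have:
        emit([("SOS", "cyt")], [("SOS", "mem")],
             p.sos_recruit_rate(cond.rtk_activity), "plain", "sos_translocation")
        emit([("SOS", "mem")], [("SOS", "cyt")], p.k_sos_release, "plain",
             "sos_translocation")
        if config.enable_feedback and config.include_mek_erk:
            for loc in ("cyt", "mem"):
                emit([erkpp, ("SOS", loc)], [erkpp, ("SOS", "phos")],
                     p.k_fb_sos, "plain", "sos_feedback_phos")
            emit([("SOS", "phos")], [("SOS", "cyt")], p.k_sos_dephos, "plain",
                 "sos_dephos")

    # --- RAS nucleotide cycling ---
    if ("RASgdp",) in have:
        emit([("RASgdp",)], [("RASgtp",)], p.gef_rate(cond.rtk_activity),
             "plain", "ras_exchange_basal")
        if ("SOS", "cyt") in have:
            emit([("SOS", "mem"), ("RASgdp",)], [("SOS", "mem"), ("RASgtp",)],
                 p.k_gef_sos, "plain", "ras_exchange_sos")
        # saturable GAP acts on every RAS-GTP moiety, free or RAF-bound
        for sp in species:
            n_gtp = gtp_count(sp)
            if n_gtp == 0:
                continue
            if sp == ("RASgtp",):
                emit([sp], [("RASgdp",)], 1.0, "gap", "ras_gap")
            else:
                for (product, _, _), mult in _positional_edits(
                    sp, lambda q: q.ras == 1, lambda q: q._replace(ras=0)
                ).items():
                    emit([sp], [product, ("RASgdp",)], float(mult), "gap",
                         "ras_gap")

        # --- RAF recruitment to RAS-GTP ---
        for sp in raf_species:
            def rbd_free(q: Protomer) -> bool:
                return q.ras == 0 and q.ip == 0 and q.fp == 0

            for (product, _, _), mult in _positional_edits(
                sp, rbd_free, lambda q: q._replace(ras=1)
            ).items():
                kd_eff = _ras_kd_eff(model, in_dimer=_is_dimer(sp))
                kf, kr = _split_rates(p.kon_rbd, kd_eff, p.k_rbd, p.phi)
                m_r = _reverse_multiplicity(
                    product, sp, lambda q: q._replace(ras=0) if q.ras else None)
                emit([("RASgtp",), sp], [product], kf * mult, "plain",
                     "raf_ras_binding")
                emit([product], [("RASgtp",), sp], kr * m_r, "plain",
                     "raf_ras_binding")

    # --- RAF dimerization ---
    # Association over all monomer pairs; dissociation over all dimer species.
    # Dimers can also arise from in-dimer phosphorylation, so dissociation must
    # be emitted from the dimer side (its monomer products then enter the
    # expansion and pick up their association reaction at the next round).
    dimerizable = [sp for sp in monomers if sp[1].ip == 0 and sp[1].fp == 0]
    for a in range(len(dimerizable)):
        for b in range(a, len(dimerizable)):
            p1, p2 = dimerizable[a][1], dimerizable[b][1]
            kd_eff = _dimer_kd_eff(model, p1, p2)
            kf, _ = _split_rates(p.kon_dim, kd_eff, p.kdim0, p.phi)
            mult = 1 if p1 == p2 else 2
            emit([dimerizable[a], dimerizable[b]], [_dimer(p1, p2)], kf * mult,
                 "plain", "raf_dimerization")
    for sp in raf_species:
        if _is_dimer(sp):
            p1, p2 = sp[1], sp[2]
            kd_eff = _dimer_kd_eff(model, p1, p2)
            _, kr = _split_rates(p.kon_dim, kd_eff, p.kdim0, p.phi)
            emit([sp], [_mono(p1), _mono(p2)], kr, "plain", "raf_dimerization")

    # --- inhibitor binding (doses enter at simulation time) ---
    for slot in (1, 2):
        spec = model.inhibitors[slot - 1]
        if spec is None:
            continue
        rate_class = "dose_a" if slot == 1 else "dose_b"
        rule = f"inhibitor{slot}_binding"
        for sp in raf_species:
            for (product, protomer, partner), mult in _positional_edits(
                sp, lambda q: q.poc == 0, lambda q: q._replace(poc=slot)
            ).items():
                kd_eff = _inhibitor_kd_eff(model, slot, protomer, partner)
                kf, kr = _split_rates(p.kon_inh, kd_eff, spec.Kd_ref, p.phi)
                m_r = _reverse_multiplicity(
                    product, sp,
                    lambda q: q._replace(poc=0) if q.poc == slot else None)
                emit([sp], [product], kf * mult, rate_class, rule)
                emit([product], [sp], kr * m_r, "plain", rule)

    # --- NtA activation phosphorylation (in dimers) and dephosphorylation ---
    if config.enable_activation_phos:
        for sp in raf_species:
            if _is_dimer(sp):
                for (product, _, _), mult in _positional_edits(
                    sp, lambda q: q.iso in ("A", "C") and q.ap == 0,
                    lambda q: q._replace(ap=1)
                ).items():
                    emit([sp], [product], p.k_actp * mult, "plain",
                         "nta_activation_phos")
            for (product, _, _), mult in _positional_edits(
                sp, lambda q: q.ap == 1, lambda q: q._replace(ap=0)
            ).items():
                emit([sp], [product], p.k_actdp * mult, "plain", "nta_dephos")

    # --- ppERK negative feedback on monomeric RAF ---
    if config.enable_feedback and config.include_mek_erk:
        for sp in monomers:
            q = sp[1]
            if q.ras == 0 and q.fp == 0:
                emit([erkpp, sp], [erkpp, _mono(q._replace(fp=1))],
                     p.k_fb_raf, "plain", "raf_feedback_phos")
            if q.fp == 1:
                emit([sp], [_mono(q._replace(fp=0))], p.k_fb_dephos, "plain",
                     "raf_feedback_dephos")

    # --- inhibitory phosphosite (constitutive, monomers only) ---
    if config.enable_inhibitory_phos:
        for sp in monomers:
            q = sp[1]
            if q.ras == 0 and q.ip == 0:
                emit([sp], [_mono(q._replace(ip=1))], p.k_inh_phos, "plain",
                     "raf_inhibitory_phos")
            if q.ip == 1:
                emit([sp], [_mono(q._replace(ip=0))], p.k_inh_dephos, "plain",
                     "raf_inhibitory_dephos")

    # --- MEK/ERK cascade ---
    if config.include_mek_erk and ("MEK", 0) in have:
        for sp in raf_species:
            w = catalytic_activity(sp, p)
            if w <= 0:
                continue
            for n in (0, 1):
                emit([sp, ("MEK", n)], [sp, ("MEK", n + 1)], p.k_mek * w,
                     "plain", "mek_phosphorylation")
        for n in (1, 2):
            emit([("MEK", n)], [("MEK", n - 1)], p.k_mek_dephos, "plain",
                 "mek_dephos")
        for n in (0, 1):
            emit([mekpp, ("ERK", n)], [mekpp, ("ERK", n + 1)], p.k_erk,
                 "plain", "erk_phosphorylation")
        for n in (1, 2):
            emit([("ERK", n)], [("ERK", n - 1)], p.k_erk_dephos, "plain",
                 "erk_dephos")
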