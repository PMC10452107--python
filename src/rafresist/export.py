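"""Export of expanded networks: SBML Level 3, BNGL-style rule text, CSV tables.

The SBML writer is a minimal, self-contained Level 3 Version 2 core serializer
(species, parameters, reactions with explicit mass-action kinetic laws).  The
saturable RAS-GAP rate law references a global parameter ``RAS_GTP_total``
maintained by an assignment rule summing all RAS-GTP-carrying species, so the
exported document reproduces the exact kinetics of the simulator.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from xml.dom import minidom

from .pathway_network.model import ReactionNetwork, gtp_count, species_name
from .pathway_network.params import SimulationCondition
from .pathway_network.simulate import initial_state

__all__ = ["network_to_sbml", "model_to_bngl"]

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _sid(i: int) -> str:
    return f"s{i}"


def _math(parent: ET.Element) -> ET.Element:
    return ET.SubElement(parent, f"{{{_MATHML_NS}}}math")


def _apply_times(parent: ET.Element, items: list[ET.Element]) -> None:
    apply_el = ET.SubElement(parent, f"{{{_MATHML_NS}}}apply")
    ET.SubElement(apply_el, f"{{{_MATHML_NS}}}times")
    for el in items:
        apply_el.append(el)


def _ci(name: str) -> ET.Element:
    el = ET.Element(f"{{{_MATHML_NS}}}ci")
    el.text = f" {name} "
    return el


def _cn(value: float) -> ET.Element:
    el = ET.Element(f"{{{_MATHML_NS}}}cn")
    el.text = f" {value!r} "
    return el


def network_to_sbml(net: ReactionNetwork,
                    cond: SimulationCondition | None = None) -> str:
    """Serialize a network (with condition-resolved rate constants) to SBML L3."""
    cond = cond or net.model.condition
    params = net.model.params
    ET.register_namespace("", _SBML_NS)
    ET.register_namespace("math", _MATHML_NS)
    sbml = ET.Element(f"{{{_SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{_SBML_NS}}}model",
                          {"id": "rafresist_pathway", "substanceUnits": "item",
                           "timeUnits": "second"})
    comps = ET.SubElement(model, f"{{{_SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{_SBML_NS}}}compartment",
                  {"id": "cell", "constant": "true", "size": "1",
                   "spatialDimensions": "3"})

    y0 = initial_state(net, cond)
    species_el = ET.SubElement(model, f"{{{_SBML_NS}}}listOfSpecies")
    for i, sp in enumerate(net.species):
        ET.SubElement(species_el, f"{{{_SBML_NS}}}species", {
            "id": _sid(i), "name": species_name(sp), "compartment": "cell",
            "initialConcentration": repr(float(y0[i])),
            "hasOnlySubstanceUnits": "false", "boundaryCondition": "false",
            "constant": "false",
        })

    plist = ET.SubElement(model, f"{{{_SBML_NS}}}listOfParameters")
    ET.SubElement(plist, f"{{{_SBML_NS}}}parameter",
                  {"id": "km_gap", "value": repr(params.km_gap),
                   "constant": "true"})
    ET.SubElement(plist, f"{{{_SBML_NS}}}parameter",
                  {"id": "RAS_GTP_total", "value": "0", "constant": "false"})
    for pid, value in (("dose1", cond.dose1), ("dose2", cond.dose2),
                       ("v_gap", params.gap_vmax(cond.ras_status))):
        ET.SubElement(plist, f"{{{_SBML_NS}}}parameter",
                      {"id": pid, "value": repr(float(value)), "constant": "true"})

    gtp_terms = [(i, gtp_count(sp)) for i, sp in enumerate(net.species)
                 if gtp_count(sp) > 0]
    rules_el = ET.SubElement(model, f"{{{_SBML_NS}}}listOfRules")
    rule_el = ET.SubElement(rules_el, f"{{{_SBML_NS}}}assignmentRule",
                            {"variable": "RAS_GTP_total"})
    math_el = _math(rule_el)
    apply_el = ET.SubElement(math_el, f"{{{_MATHML_NS}}}apply")
    ET.SubElement(apply_el, f"{{{_MATHML_NS}}}plus")
    for i, n in gtp_terms:
        if n == 1:
            apply_el.append(_ci(_sid(i)))
        else:
            times = ET.SubElement(apply_el, f"{{{_MATHML_NS}}}apply")
            ET.SubElement(times, f"{{{_MATHML_NS}}}times")
            times.append(_cn(float(n)))
            times.append(_ci(_sid(i)))

    rxns_el = ET.SubElement(model, f"{{{_SBML_NS}}}listOfReactions")
    for j, rxn in enumerate(net.reactions):
        r_el = ET.SubElement(rxns_el, f"{{{_SBML_NS}}}reaction",
                             {"id": f"r{j}", "name": rxn.rule,
                              "reversible": "false"})
        reac_el = ET.SubElement(r_el, f"{{{_SBML_NS}}}listOfReactants")
        counts: dict[int, int] = {}
        for sp in rxn.reactants:
            counts[net.index[sp]] = counts.get(net.index[sp], 0) + 1
        for i, n in counts.items():
            ET.SubElement(reac_el, f"{{{_SBML_NS}}}speciesReference",
                          {"species": _sid(i), "stoichiometry": str(n),
                           "constant": "true"})
        prod_el = ET.SubElement(r_el, f"{{{_SBML_NS}}}listOfProducts")
        counts = {}
        for sp in rxn.products:
            counts[net.index[sp]] = counts.get(net.index[sp], 0) + 1
        for i, n in counts.items():
            ET.SubElement(prod_el, f"{{{_SBML_NS}}}speciesReference",
                          {"species": _sid(i), "stoichiometry": str(n),
                           "constant": "true"})
        kl = ET.SubElement(r_el, f"{{{_SBML_NS}}}kineticLaw")
        math_el = _math(kl)
        terms = [_cn(float(rxn.k))]
        for sp in rxn.reactants:
            terms.append(_ci(_sid(net.index[sp])))
        if rxn.rate_class == "dose_a":
            terms.append(_ci("dose1"))
        elif rxn.rate_class == "dose_b":
            terms.append(_ci("dose2"))
        elif rxn.rate_class == "gap":
            terms.append(_ci("v_gap"))
            divide = ET.Element(f"{{{_MATHML_NS}}}apply")
            ET.SubElement(divide, f"{{{_MATHML_NS}}}divide")
            divide.append(_cn(1.0))
            plus = ET.SubElement(divide, f"{{{_MATHML_NS}}}apply")
            ET.SubElement(plus, f"{{{_MATHML_NS}}}plus")
            plus.append(_ci("km_gap"))
            plus.append(_ci("RAS_GTP_total"))
            terms.append(divide)
        _apply_times(math_el, terms)

    raw = ET.tostring(sbml, encoding="unicode")
    return minidom.parseString(raw).toprettyxml(indent="  ")


def model_to_bngl(net: ReactionNetwork) -> str:
    """BNGL-compatible text of the model: molecule types + expanded reactions.

    The rule inventory is emitted as comments; the reaction block lists the
    fully expanded network with resolved rate constants, which any BNGL-style
    simulator can consume directly.
    """
    from .pathway_network.model import molecule_types

    lines = ["begin model", "", "begin molecule types"]
    for mt in molecule_types():
        sites = ",".join(
            f"{name}~" + "~".join(states) for name, states in mt.sites
        )
        lines.append(f"  {mt.name}({sites})")
    lines.append("end molecule types")
    lines.append("")
    lines.append("# rule inventory (expanded below):")
    for rule in net.model.rules:
        arrow = "<->" if rule.reversible else "->"
        lines.append(f"#   {rule.name} {arrow}  kf={rule.forward_rate:g}"
                     + (f"  Kd={rule.equilibrium_kd:g}" if rule.equilibrium_kd else "")
                     + (f"  [{rule.factors}]" if rule.factors else ""))
    lines.append("")
    lines.append("begin species")
    for i, sp in enumerate(net.species):
        lines.append(f"  {species_name(sp)}  0  # {_sid(i)}")
    lines.append("end species")
    lines.append("")
    lines.append("begin reactions")
    for j, rxn in enumerate(net.reactions):
        lhs = " + ".join(species_name(s) for s in rxn.reactants)
        rhs = " + ".join(species_name(s) for s in rxn.products)
        note = "" if rxn.rate_class == "plain" else f"  # {rxn.rate_class}"
        lines.append(f"  {lhs} -> {rhs}  {rxn.k:.6g}{note}")
    lines.append("end reactions")
    lines.append("")
    lines.append("end model")
    return "\n".join(lines) + "\n"
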