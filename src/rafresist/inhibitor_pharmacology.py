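"""Conformation-specific RAF inhibitors and dimer-context thermodynamic factors.

RAF kinase domains toggle two regulatory motifs, the alphaC-helix and the DFG
motif, between IN and OUT positions.  ATP-competitive RAF inhibitors are grouped
by the conformation they prefer: Type I (alphaC-IN/DFG-IN), Type II
(alphaC-IN/DFG-OUT) and Type I1/2 (alphaC-OUT/DFG-IN).  Conformational
preference is treated thermodynamically: the preferred conformation gets the
reference dissociation constant ``Kd_ref`` and every other conformation a
multiplicative penalty, rather than tracking conformations as dynamic species.

Eight dimensionless factors modulate inhibitor-protomer dissociation constants
inside RAF dimers, for two inhibitor slots "a" (RAFi1) and "b" (RAFi2):

========  ==================================================================
factor    Kd ratio it multiplies (all relative to the free-monomer Kd unless
          stated otherwise)
========  ==================================================================
fa, fb    binding to a protomer of an inhibitor-free dimer
g1a, g1b  binding to the second protomer vs binding to the first protomer
          (applied on top of fa/fb)
g2a, g2b  binding to a protomer whose partner carries the same inhibitor
g3a, g3b  binding to a protomer whose partner carries the other inhibitor
========  ==================================================================

Because a dimer doubly bound by one inhibitor can be assembled in two binding
orders, a free-energy function exists only if ``g2 = f * g1`` for each slot and
``fa * g3b = fb * g3a`` for the mixed dimer.  ``validate_cycle_closure``
enumerates the binding orders and reports each violated cycle with its
free-energy discrepancy; the pathway-network builder rejects factor sets that
fail.  Factors below 1 mean dimer-enhanced binding, which by the same closed
cycles also means inhibitor-promoted dimerization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "Conformation",
    "ConformationState",
    "InhibitorSpec",
    "ThermodynamicFactors",
    "BindingContext",
    "CycleReport",
    "effective_kd",
    "validate_cycle_closure",
    "closed_factors",
    "preset_inhibitor",
    "preset_pair",
    "factors_table",
    "PRESET_LABELS",
]


class Conformation(str, Enum):
    IN = "IN"
    OUT = "OUT"


@dataclass(frozen=True)
class ConformationState:
    """Joint alphaC-helix / DFG-motif state (four possibilities)."""

    alphaC: Conformation
    DFG: Conformation

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphaC", Conformation(self.alphaC))
        object.__setattr__(self, "DFG", Conformation(self.DFG))


_PREFERRED = {
    "I": ConformationState(Conformation.IN, Conformation.IN),
    "II": ConformationState(Conformation.IN, Conformation.OUT),
    "I_half": ConformationState(Conformation.OUT, Conformation.IN),
}


@dataclass(frozen=True)
class InhibitorSpec:
    """One RAF inhibitor: conformational class, reference Kd and off-type penalty."""

    name: str
    type_label: str  # "I" | "II" | "I_half"
    Kd_ref: float  # nM, for the preferred conformation
    penalty: float = 100.0  # Kd multiplier for each non-preferred conformation

    def __post_init__(self) -> None:
        if self.type_label not in _PREFERRED:
            raise InvalidParameterError(
                f"type_label must be one of {sorted(_PREFERRED)}, got {self.type_label!r}"
            )
        if not np.isfinite(self.Kd_ref) or self.Kd_ref <= 0:
            raise InvalidParameterError(f"Kd_ref must be positive, got {self.Kd_ref!r}")
        if self.penalty < 1.0:
            raise InvalidParameterError(f"penalty must be >= 1, got {self.penalty!r}")

    @property
    def preferred(self) -> ConformationState:
        return _PREFERRED[self.type_label]


@dataclass(frozen=True)
class ThermodynamicFactors:
    """The eight dimer-context Kd ratios for inhibitor slots a and b."""

    fa: float = 1.0
    fb: float = 1.0
    g1a: float = 1.0
    g1b: float = 1.0
    g2a: float = 1.0
    g2b: float = 1.0
    g3a: float = 1.0
    g3b: float = 1.0

    def __post_init__(self) -> None:
        for name in ("fa", "fb", "g1a", "g1b", "g2a", "g2b", "g3a", "g3b"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(
                    f"ThermodynamicFactors.{name} must be > 0, got {value!r}"
                )

    def slot(self, which: str) -> tuple[float, float, float, float]:
        """(f, g1, g2, g3) for slot 'a' or 'b'."""
        if which == "a":
            return self.fa, self.g1a, self.g2a, self.g3a
        if which == "b":
            return self.fb, self.g1b, self.g2b, self.g3b
        raise InvalidParameterError(f"slot must be 'a' or 'b', got {which!r}")


class BindingContext(str, Enum):
    MONOMER = "monomer"
    FIRST_IN_DIMER = "first-in-dimer"
    SECOND_PROTOMER = "second-protomer-in-dimer"
    PARTNER_SAME = "partner-occupied-same"
    PARTNER_OTHER = "partner-occupied-other"


def effective_kd(
    inh: InhibitorSpec,
    factors: ThermodynamicFactors,
    context: BindingContext | str,
    *,
    slot: str = "a",
    conformation: ConformationState | None = None,
) -> float:
    """Context-dependent dissociation constant (nM) for one binding event.

    ``conformation`` pins the protomer's conformational state; if it differs
    from the inhibitor's preferred state the off-type penalty applies once.
    """
    try:
        context = BindingContext(context)
    except ValueError as exc:
        raise InvalidParameterError(f"unknown binding context {context!r}") from exc
    f, g1, g2, g3 = factors.slot(slot)
    kd = inh.Kd_ref
    if conformation is not None and conformation != inh.preferred:
        kd *= inh.penalty
    if context is BindingContext.MONOMER:
        return kd
    if context is BindingContext.FIRST_IN_DIMER:
        return kd * f
    if context is BindingContext.SECOND_PROTOMER:
        return kd * f * g1
    if context is BindingContext.PARTNER_SAME:
        return kd * g2
    return kd * g3  # PARTNER_OTHER


@dataclass(frozen=True)
class CycleReport:
    """Result of brute-force enumeration of binding orders to shared end states."""

    cycles: tuple[tuple[str, float, float, float], ...]  # (name, prodA, prodB, |dG|)
    tol: float
    passed: bool

    @property
    def violations(self) -> list[tuple[str, float]]:
        return [(name, dg) for name, _, _, dg in self.cycles
                if dg > self.tol]


def validate_cycle_closure(
    factors: ThermodynamicFactors, *, tol: float = 1e-9
) -> CycleReport:
    """Check that all binding orders reaching a fully-bound dimer agree.

    For each end state the products of stepwise Kd ratios along the two binding
    orders are compared; the discrepancy is reported as |ln(ratio)| in units of
    kT.  A factor set passes when every cycle closes to the relative tolerance.
    """
    fa, fb = factors.fa, factors.fb
    cycles = []
    # Doubly bound by the same inhibitor: bind first then second (fa * fa*g1a)
    # versus bind "the other protomer first" then the partner-occupied one
    # (fa * g2a).
    for name, f, g1, g2 in (("a-a dimer", fa, factors.g1a, factors.g2a),
                            ("b-b dimer", fb, factors.g1b, factors.g2b)):
        prod_1 = f * (f * g1)
        prod_2 = f * g2
        cycles.append((name, prod_1, prod_2, abs(math.log(prod_1 / prod_2))))
    # Mixed dimer: RAFi1 first then RAFi2 (fa * g3b) versus the reverse order
    # (fb * g3a).  The mixed cycle only constrains anything when the second
    # inhibitor slot is actually in use; with slot b fully neutral the factor
    # set describes a single-inhibitor experiment and the cycle is skipped.
    slot_b_in_use = any(
        v != 1.0 for v in (fb, factors.g1b, factors.g2b, factors.g3a, factors.g3b)
    )
    if slot_b_in_use:
        prod_1 = fa * factors.g3b
        prod_2 = fb * factors.g3a
        cycles.append(("a-b dimer", prod_1, prod_2, abs(math.log(prod_1 / prod_2))))

    passed = all(dg <= tol for _, _, _, dg in cycles)
    return CycleReport(cycles=tuple(cycles), tol=tol, passed=passed)


def closed_factors(
    *, fa: float = 1.0, fb: float = 1.0, g1a: float = 1.0, g1b: float = 1.0,
    h_cross: float = 1.0,
) -> ThermodynamicFactors:
    """Build a cycle-consistent factor set from its free parameters.

    ``h_cross`` is the cooperativity between the two *different* inhibitors
    co-occupying a dimer (g3a = fa*h_cross, g3b = fb*h_cross); g2 factors are
    fixed by closure (g2 = f*g1).
    """
    return ThermodynamicFactors(
        fa=fa, fb=fb, g1a=g1a, g1b=g1b,
        g2a=fa * g1a, g2b=fb * g1b,
        g3a=fa * h_cross, g3b=fb * h_cross,
    )


# Packaged defaults.  The qualitative constraints they encode: alphaC-IN
# inhibitors (Types I and II) bind dimer protomers tighter than monomers
# (f < 1), hence promote dimerization and block dimers effectively; the
# alphaC-OUT Type I1/2 neither promotes dimers (f ~ 1) nor can occupy the
# second protomer of a dimer (strong negative cooperativity, g1 >> 1), so it
# cannot inhibit RAF dimers.  Cross-cooperativity below 1 between Type I and
# Type II encodes that two structurally different inhibitors co-occupy a dimer
# more readily than two copies of either one.
_PRESET_PARAMS: dict[str, dict[str, float]] = {
    "I": {"Kd_ref": 10.0, "penalty": 100.0, "f": 0.05, "g1": 100.0},
    "II": {"Kd_ref": 10.0, "penalty": 100.0, "f": 0.1, "g1": 30.0},
    "I_half": {"Kd_ref": 10.0, "penalty": 100.0, "f": 0.2, "g1": 150.0},
}
_PRESET_NAMES = {"I": "TypeI", "II": "TypeII", "I_half": "TypeI.5"}
# Two structurally different inhibitors select different conformations of the
# two protomers and therefore co-occupy a dimer without paying the same-drug
# second-site penalty (g1); only a mild steric cross-penalty remains.
_CROSS_COOPERATIVITY: dict[frozenset[str], float] = {
    frozenset({"I", "II"}): 2.0,
    frozenset({"I", "I_half"}): 2.0,
    frozenset({"II", "I_half"}): 2.0,
}
PRESET_LABELS = tuple(_PRESET_PARAMS)


def _cross(label1: str, label2: str) -> float:
    if label1 == label2:
        return _PRESET_PARAMS[label1]["g1"]
    return _CROSS_COOPERATIVITY[frozenset({label1, label2})]


def preset_inhibitor(type_label: str) -> tuple[InhibitorSpec, ThermodynamicFactors]:
    """Packaged single-inhibitor preset (slot b mirrors slot a)."""
    if type_label not in _PRESET_PARAMS:
        raise InvalidParameterError(
            f"unknown inhibitor preset {type_label!r}; choose from {sorted(_PRESET_PARAMS)}"
        )
    p = _PRESET_PARAMS[type_label]
    spec = InhibitorSpec(name=_PRESET_NAMES[type_label], type_label=type_label,
                         Kd_ref=p["Kd_ref"], penalty=p["penalty"])
    factors = closed_factors(fa=p["f"], fb=p["f"], g1a=p["g1"], g1b=p["g1"],
                             h_cross=p["g1"])
    return spec, factors


def preset_pair(
    label1: str, label2: str
) -> tuple[InhibitorSpec, InhibitorSpec, ThermodynamicFactors]:
    """Packaged two-inhibitor preset with cross-cooperativity factors."""
    spec1, _ = preset_inhibitor(label1)
    spec2, _ = preset_inhibitor(label2)
    p1, p2 = _PRESET_PARAMS[label1], _PRESET_PARAMS[label2]
    factors = closed_factors(fa=p1["f"], fb=p2["f"], g1a=p1["g1"], g1b=p2["g1"],
                             h_cross=_cross(label1, label2))
    return spec1, spec2, factors


def factors_table(factors: ThermodynamicFactors) -> pd.DataFrame:
    """One-row parameter table (CSV-ready) of the eight factors."""
    names = ("fa", "fb", "g1a", "g1b", "g2a", "g2b", "g3a", "g3b")
    return pd.DataFrame([{n: getattr(factors, n) for n in names}])
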