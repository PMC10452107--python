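"""Equilibrium model of a dimerizing kinase with an allosteric inhibitor.

Species: free monomer R, inhibited monomer RI, free dimer RR, singly-inhibited
dimer RRI and doubly-inhibited dimer IRRI.  Two thermodynamic factors couple
inhibitor binding to dimerization:

``f``
    fold-increase in dimerization affinity induced by one bound inhibitor
    (equivalently, fold-increase in inhibitor affinity for a dimer protomer;
    the two statements are the same closed thermodynamic cycle).
``g``
    fold-change in affinity of the second inhibitor molecule for a
    singly-inhibited dimer (g < 1: negative cooperativity).

With free inhibitor I (clamped by default; total-inhibitor conservation is
optional) every species is an explicit function of the free monomer R:

    RI   = R * I / KdI
    RR   = R**2 / Kdim
    RRI  = 2 * f * R**2 * I / (Kdim * KdI)          (statistical factor 2)
    IRRI = f**2 * g * R**2 * I**2 / (Kdim * KdI**2)

so protomer conservation R + RI + 2*(RR + RRI + IRRI) = Rtot is a quadratic in
R with a unique positive root.  Detailed balance around the cycle
R -> RI -> RRI versus R -> RR -> RRI holds by construction: dimerization of an
inhibitor-bound protomer uses Kdim/f and inhibitor binding to a dimer protomer
uses KdI/f.

Catalytic activity is a weighted sum: monomers contribute ``a_mono * R``, free
dimers ``2 * a_dimer * RR`` (two active protomers) and singly-inhibited dimers
``a_half * RRI`` (the non-inhibited protomer); RI and IRRI are silent.  RAF-like
defaults make dimer protomers 10x more active than monomers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .core_monomer import FoldShiftResult
from .errors import InvalidParameterError, NumericalError

__all__ = [
    "DimerSystem",
    "DimerSpeciesDistribution",
    "default_dimer_system",
    "dimer_equilibrium",
    "dimer_activity",
    "total_activity",
    "ic50_fold_curve",
]


@dataclass(frozen=True)
class DimerSystem:
    """Dimerizing-kinase equilibrium parameters (concentrations in nM)."""

    Rtot: float
    I: float
    Kdim: float
    KdI: float
    f: float
    g: float
    a_mono: float = 1.0
    a_dimer: float = 10.0
    a_half: float = 10.0

    def __post_init__(self) -> None:
        for name in ("Rtot", "Kdim", "KdI", "f", "g"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(
                    f"DimerSystem.{name} must be strictly positive, got {value!r}"
                )
        if self.I < 0:
            raise InvalidParameterError(f"DimerSystem.I must be >= 0, got {self.I!r}")
        for name in ("a_mono", "a_dimer", "a_half"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"DimerSystem.{name} must be >= 0")


@dataclass(frozen=True)
class DimerSpeciesDistribution:
    """Equilibrium concentrations (nM) of the five dimer-model species."""

    R: float
    RI: float
    RR: float
    RRI: float
    IRRI: float

    @property
    def protomer_total(self) -> float:
        return self.R + self.RI + 2.0 * (self.RR + self.RRI + self.IRRI)


def default_dimer_system(Rtot: float = 100.0, I: float = 0.0, *, f: float = 10.0,
                         g: float = 0.005) -> DimerSystem:
    """Packaged default parameter set.

    Kdim = 6.4 * Rtot puts ~20% of protomers into dimers at baseline abundance
    without inhibitor (R = 0.8*Rtot, 2*RR = 0.2*Rtot); KdI = 10 nM; dimer
    protomers are 10x as active as monomers.  The default allosteric inhibitor
    promotes dimerization and first-site binding (f = 10) but strongly
    disfavours the second inhibitor molecule (g = 0.005, so f**2 * g < 1): the
    net effect is that silencing a dimer takes more drug than silencing two
    monomers, which is what makes dimerizing kinases resistant.
    """
    return DimerSystem(Rtot=Rtot, I=I, Kdim=6.4 * Rtot, KdI=10.0, f=f, g=g)


def _species_given_R(sys: DimerSystem, R: float, I: float) -> DimerSpeciesDistribution:
    RI = R * I / sys.KdI
    RR = R * R / sys.Kdim
    RRI = 2.0 * sys.f * R * R * I / (sys.Kdim * sys.KdI)
    IRRI = sys.f**2 * sys.g * R * R * I * I / (sys.Kdim * sys.KdI**2)
    return DimerSpeciesDistribution(R=R, RI=RI, RR=RR, RRI=RRI, IRRI=IRRI)


def _solve_R(sys: DimerSystem, I: float) -> float:
    a = (2.0 / sys.Kdim) * (
        1.0 + 2.0 * sys.f * I / sys.KdI + sys.f**2 * sys.g * (I / sys.KdI) ** 2
    )
    b = 1.0 + I / sys.KdI
    # a*R^2 + b*R - Rtot = 0, positive root (numerically stable form)
    disc = math.sqrt(b * b + 4.0 * a * sys.Rtot)
    return 2.0 * sys.Rtot / (b + disc)


def dimer_equilibrium(
    sys: DimerSystem, *, conserve_inhibitor: bool = False, Itot: float | None = None
) -> DimerSpeciesDistribution:
    """Unique physical equilibrium of the five-species scheme.

    By default the free inhibitor concentration is clamped at ``sys.I`` (dose
    axes in this package are total-dose based and the inhibitor is typically in
    large excess).  With ``conserve_inhibitor=True`` the free concentration is
    solved so that I + RI + RRI + 2*IRRI equals ``Itot`` (default ``sys.I``).
    """
    if not conserve_inhibitor:
        dist = _species_given_R(sys, _solve_R(sys, sys.I), sys.I)
    else:
        total = sys.I if Itot is None else float(Itot)
        if total == 0.0:
            dist = _species_given_R(sys, _solve_R(sys, 0.0), 0.0)
        else:
            def residual(I_free: float) -> float:
                d = _species_given_R(sys, _solve_R(sys, I_free), I_free)
                return I_free + d.RI + d.RRI + 2.0 * d.IRRI - total

            I_free = brentq(residual, 0.0, total, xtol=1e-300, rtol=8.9e-16)
            dist = _species_given_R(sys, _solve_R(sys, I_free), I_free)

    rel = abs(dist.protomer_total - sys.Rtot) / sys.Rtot
    if rel > 1e-9:
        raise NumericalError(f"protomer conservation residual {rel:.2e} exceeds 1e-9")
    return dist


def dimer_activity(dist: DimerSpeciesDistribution, sys: DimerSystem) -> float:
    """Catalytic activity of a species distribution (nM-weighted rate units).

    Inhibited monomers (RI) and doubly-inhibited dimers (IRRI) contribute zero.
    """
    return sys.a_mono * dist.R + 2.0 * sys.a_dimer * dist.RR + sys.a_half * dist.RRI


def total_activity(sys: DimerSystem, *, Rtot: float | None = None,
                   I: float | None = None) -> float:
    """Equilibrium activity at the given (optionally overridden) abundance/dose."""
    eff = sys
    if Rtot is not None or I is not None:
        eff = replace(sys, Rtot=sys.Rtot if Rtot is None else Rtot,
                      I=sys.I if I is None else I)
    return dimer_activity(dimer_equilibrium(eff), eff)


def _dimer_fraction(dist: DimerSpeciesDistribution) -> float:
    return 2.0 * (dist.RR + dist.RRI + dist.IRRI) / dist.protomer_total


def _regime_label(sys: DimerSystem, Rtot: float, I: float) -> str:
    eff = replace(sys, Rtot=Rtot, I=I)
    frac = _dimer_fraction(dimer_equilibrium(eff))
    if frac < 0.01:
        return "monomeric"
    if frac > 0.5:
        return "dimeric"
    return "mixed"


def ic50_fold_curve(
    sys: DimerSystem, L_grid: Sequence[float], *, max_fold: float = 1e12
) -> list[FoldShiftResult]:
    """Dose multipliers F(L) restoring the reference activity at L-fold abundance.

    The reference dose I0 halves the uninhibited activity at baseline ``Rtot``;
    for each L the dose multiplier restoring that same absolute activity at
    ``L * Rtot`` is found by bracketed root search on log10(F) over
    ``[1/max_fold, max_fold]`` times the reference dose.  When the activity at
    the top of the bracket is still above the target (the inhibitor cannot push
    the system back down within the searched range), that L is reported with
    ``F = inf`` and regime ``"unbounded"`` instead of failing the whole curve.
    """
    if any(L < 1.0 for L in L_grid):
        raise InvalidParameterError("L_grid values must be >= 1")

    A0 = total_activity(sys, I=0.0)
    target = 0.5 * A0
    half_width = math.log10(max_fold)

    def act_at(dose: float, Rtot: float) -> float:
        return total_activity(sys, Rtot=Rtot, I=dose)

    def find_dose(Rtot: float, ref_dose_hint: float) -> float | None:
        lo = math.log10(ref_dose_hint) - half_width
        hi = math.log10(ref_dose_hint) + half_width
        f_lo = act_at(10.0**lo, Rtot) - target
        f_hi = act_at(10.0**hi, Rtot) - target
        if f_lo < 0:
            raise NumericalError("activity below target at vanishing dose")
        if f_hi > 0:
            return None  # floor above target: unbounded dose
        u = brentq(lambda x: act_at(10.0**x, Rtot) - target, lo, hi,
                   xtol=1e-13, rtol=8.9e-16)
        return 10.0**u

    I0 = find_dose(sys.Rtot, sys.KdI)
    if I0 is None:
        raise NumericalError(
            "no reference IC50: activity cannot be halved at baseline abundance"
        )

    results: list[FoldShiftResult] = []
    for L in L_grid:
        dose = find_dose(L * sys.Rtot, I0)
        if dose is None:
            results.append(FoldShiftResult(L=float(L), F=math.inf, regime="unbounded"))
        else:
            results.append(
                FoldShiftResult(
                    L=float(L), F=dose / I0,
                    regime=_regime_label(sys, L * sys.Rtot, dose),
                )
            )
    return results
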