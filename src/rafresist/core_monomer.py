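"""Dose-shift analytics for a non-dimerizing kinase under non-competitive inhibition.

The model: a kinase E phosphorylates a substrate S (product P, dephosphorylated at
rate kp).  A non-competitive inhibitor I binds both free kinase E and the
enzyme-substrate complex ES with the same dissociation constant Kd
(independent-site binding), so kinase occupancy factorises as
``(1 + I/Kd) * (1 + S/KS)``.  At steady state the moiety conservation laws read

    E * (1 + I/Kd) * (1 + S/KS) = Etot
    S * (1 + (E/KS) * (1 + kcat/kp + I/Kd)) = Stot

with E, S the free concentrations.  The phosphorylation flux is
``kcat * ES = kcat * E * S / KS``.

Given a reference dose I0 producing some fixed inhibition level at kinase
abundance E0tot, overexpressing the kinase L-fold requires an F-fold larger dose
to restore the same flux.  ``fold_dose_implicit`` solves the equal-flux condition
exactly by bracketed root finding; ``fold_dose_linear`` and
``fold_dose_saturated`` are the closed forms valid when the kinase is much less,
respectively much more, abundant than its substrate.  All concentrations are in
nM and all rates in 1/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import InvalidParameterError, NumericalError, RegimeError, RegimeWarning

__all__ = [
    "MonomerSystem",
    "FoldShiftResult",
    "solve_reference_state",
    "fold_dose_implicit",
    "fold_dose_linear",
    "fold_dose_saturated",
    "fold_curve",
]

_KS_RTOL = 1e-9


@dataclass(frozen=True)
class MonomerSystem:
    """Parameters of the single-kinase inhibition scheme.

    Parameters
    ----------
    Kd : float
        Inhibitor-kinase dissociation constant (nM), identical for E and ES.
    KS : float
        Substrate dissociation constant (nM).
    kcat : float
        Catalytic rate constant (1/s).
    kp : float
        Product dephosphorylation rate constant (1/s).
    E0tot : float
        Baseline total kinase (nM).
    Stot : float
        Total substrate moiety (nM); includes S, ES, ESI and P.
    I0 : float
        Reference inhibitor dose (nM), e.g. the baseline IC50.
    kSp, kSn : float, optional
        Elementary substrate association (1/nM/s) and dissociation (1/s)
        constants.  If supplied they must satisfy ``KS == kSn / kSp``.
    """

    Kd: float
    KS: float
    kcat: float
    kp: float
    E0tot: float
    Stot: float
    I0: float
    kSp: float | None = None
    kSn: float | None = None

    def __post_init__(self) -> None:
        for name in ("Kd", "KS", "kcat", "kp", "E0tot", "Stot", "I0"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(
                    f"MonomerSystem.{name} must be strictly positive, got {value!r}"
                )
        if (self.kSp is None) != (self.kSn is None):
            raise InvalidParameterError("kSp and kSn must be supplied together")
        if self.kSp is not None:
            if self.kSp <= 0 or self.kSn <= 0:
                raise InvalidParameterError("elementary constants must be positive")
            implied = self.kSn / self.kSp
            if abs(implied - self.KS) > _KS_RTOL * self.KS:
                raise InvalidParameterError(
                    f"KS={self.KS} inconsistent with kSn/kSp={implied}"
                )


@dataclass(frozen=True)
class FoldShiftResult:
    """Fold-increase F in inhibitor dose matching an L-fold kinase increase."""

    L: float
    F: float
    regime: str  # "linear" | "intermediate" | "saturated"


def _regime_label(sys: MonomerSystem, L: float) -> str:
    ratio = L * sys.E0tot / sys.Stot
    if ratio <= 0.1:
        return "linear"
    if ratio >= 10.0:
        return "saturated"
    return "intermediate"


def solve_reference_state(
    sys: MonomerSystem, dose: float, *, Etot: float | None = None
) -> tuple[float, float]:
    """Free (E, S) satisfying both conservation laws at the given inhibitor dose.

    The kinase law is solved for E as a function of S and substituted into the
    substrate law, which is then strictly increasing in S; the unique root is
    bracketed on [0, Stot].  ``Etot`` overrides the total kinase (defaults to
    ``sys.E0tot``), which is how overexpressed states are evaluated.
    """
    if dose < 0 or not np.isfinite(dose):
        raise InvalidParameterError(f"dose must be non-negative, got {dose!r}")
    total_E = sys.E0tot if Etot is None else float(Etot)
    if total_E <= 0 or sys.Stot <= 0:
        raise InvalidParameterError("totals must be strictly positive")

    inh = 1.0 + dose / sys.Kd
    occ = 1.0 + sys.kcat / sys.kp + dose / sys.Kd

    def free_E(S: float) -> float:
        return total_E / (inh * (1.0 + S / sys.KS))

    def substrate_residual(S: float) -> float:
        return S * (1.0 + free_E(S) * occ / sys.KS) - sys.Stot

    lo, hi = 0.0, sys.Stot
    if substrate_residual(hi) < 0:  # numerically impossible, but guard anyway
        raise NumericalError("substrate conservation residual negative at S=Stot")
    S = brentq(substrate_residual, lo, hi, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    E = free_E(S)

    res_E = abs(E * inh * (1.0 + S / sys.KS) - total_E) / total_E
    res_S = abs(S * (1.0 + E * occ / sys.KS) - sys.Stot) / sys.Stot
    if res_E > 1e-10 or res_S > 1e-10:
        raise NumericalError(
            f"conservation residuals too large: kinase {res_E:.2e}, substrate {res_S:.2e}"
        )
    return E, S


def _flux_ES(sys: MonomerSystem, Etot: float, dose: float) -> float:
    """Phosphorylation flux up to the constant kcat/KS, i.e. E*S."""
    E, S = solve_reference_state(sys, dose, Etot=Etot)
    return E * S


def fold_dose_implicit(sys: MonomerSystem, L: float) -> FoldShiftResult:
    """Exact dose fold F restoring the reference flux after L-fold overexpression.

    Solves ``flux(L*E0tot, F*I0) == flux(E0tot, I0)`` by bisection/Brent on
    log10(F) over [-12, 12]; the flux is strictly decreasing in F so the root is
    unique when bracketed.
    """
    if not np.isfinite(L) or L <= 0:
        raise InvalidParameterError(f"L must be strictly positive, got {L!r}")
    target = _flux_ES(sys, sys.E0tot, sys.I0)

    def h(log10F: float) -> float:
        return _flux_ES(sys, L * sys.E0tot, 10.0**log10F * sys.I0) - target

    lo, hi = -12.0, 12.0
    h_lo, h_hi = h(lo), h(hi)
    if h_lo < 0:
        raise RegimeError(
            "target flux unreachable: flux at F=1e-12 already below reference "
            "(kinase abundance decreased too far)"
        )
    if h_hi > 0:
        raise RegimeError(
            "target flux unreachable: flux at F=1e12 still above reference "
            "(dose cannot be raised enough within the bracket)"
        )
    log10F = brentq(h, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    F = 10.0**log10F
    if abs(h(log10F)) > 1e-8 * target:
        raise NumericalError(f"flux residual {h(log10F)/target:.2e} exceeds 1e-8")
    return FoldShiftResult(L=float(L), F=F, regime=_regime_label(sys, L))


def fold_dose_linear(sys: MonomerSystem, L: float) -> FoldShiftResult:
    """Closed-form F in the kinase-limiting regime (E0tot << Stot, L*E0tot << Stot).

    F = (L*(1 + I0/Kd) - 1) / (I0/Kd).  When IC50 doses vastly exceed Kd this
    reduces to F ~= L: the dose tracks the abundance one-for-one.
    """
    if not np.isfinite(L) or L <= 0:
        raise InvalidParameterError(f"L must be strictly positive, got {L!r}")
    if L * sys.E0tot > 0.1 * sys.Stot:
        warnings.warn(
            f"linear closed form used with L*E0tot = {L * sys.E0tot:.3g} nM > "
            f"0.1*Stot = {0.1 * sys.Stot:.3g} nM; result unreliable",
            RegimeWarning,
            stacklevel=2,
        )
    r = sys.I0 / sys.Kd
    F = (L * (1.0 + r) - 1.0) / r
    return FoldShiftResult(L=float(L), F=F, regime=_regime_label(sys, L))


def fold_dose_saturated(sys: MonomerSystem, L: float) -> FoldShiftResult:
    """Closed-form F in the substrate-limiting regime (L*E0tot >> Stot >> E0tot).

    Derived by equating the approximate fluxes of the two regimes:

        F = [L*(1+I0/Kd)*(1+Stot/KS) - 1 - (L*E0tot/KS)*(1+kcat/kp)]
            * KS*Kd / (L*E0tot*I0)

    In the further limit I0 >> Kd this tends to (KS + Stot)/E0tot, independent
    of L: once the substrate is limiting, additional overexpression no longer
    demands large dose increases.
    """
    if not np.isfinite(L) or L <= 0:
        raise InvalidParameterError(f"L must be strictly positive, got {L!r}")
    if L * sys.E0tot < 10.0 * sys.Stot or sys.E0tot > 0.1 * sys.Stot:
        warnings.warn(
            "saturated closed form used outside its regime "
            f"(need L*E0tot >> Stot >> E0tot; got L*E0tot={L * sys.E0tot:.3g}, "
            f"Stot={sys.Stot:.3g}, E0tot={sys.E0tot:.3g})",
            RegimeWarning,
            stacklevel=2,
        )
    r = sys.I0 / sys.Kd
    numerator = (
        L * (1.0 + r) * (1.0 + sys.Stot / sys.KS)
        - 1.0
        - (L * sys.E0tot / sys.KS) * (1.0 + sys.kcat / sys.kp)
    )
    F = numerator * sys.KS / (L * sys.E0tot * r)
    if F <= 0:
        raise RegimeError(
            f"saturated closed form produced F={F:.3g} <= 0; the regime "
            "assumption L*E0tot >> Stot is violated"
        )
    return FoldShiftResult(L=float(L), F=F, regime=_regime_label(sys, L))


def fold_curve(
    sys: MonomerSystem, L_values: Sequence[float], method: str = "implicit"
) -> pd.DataFrame:
    """Tabulate F(L) with columns L, F, regime (CSV-ready)."""
    solver = {
        "implicit": fold_dose_implicit,
        "linear": fold_dose_linear,
        "saturated": fold_dose_saturated,
    }.get(method)
    if solver is None:
        raise InvalidParameterError(f"unknown method {method!r}")
    rows = [solver(sys, L) for L in L_values]
    return pd.DataFrame(
        {"L": [r.L for r in rows], "F": [r.F for r in rows], "regime": [r.regime for r in rows]}
    )
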