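"""Dose-response curves, paradoxical-activation metrics and Loewe synergy.

All analyses run on steady-state ppERK from the pathway model.  A
``DoseResponseCurve`` records ppERK over a log-spaced dose grid that includes
the zero dose; its ``basal`` is the zero-dose entry.  ``paradoxical_range``
quantifies paradoxical activation by the peak fold-activation (max ppERK over
basal) and the basal-crossing dose: the smallest dose beyond the peak at which
ppERK falls back below the drug-free basal level (log-linearly interpolated).
Two-drug surfaces are summarized by Loewe isoboles — level sets of equal
ppERK in the dose plane — and the combination index CI = d1/D1 + d2/D2, where
D1, D2 are the single-agent doses reaching the same effect.  A point lies
below the straight additivity isobole (the chord between the axis intercepts)
exactly when CI < 1, so concave isoboles and median CI < 1 are the same
statement of Loewe synergy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .inhibitor_pharmacology import InhibitorSpec, ThermodynamicFactors
from .pathway_network import (
    ReactionNetwork,
    SimulationCondition,
    build_model,
    generate_network,
    observables,
    simulate_steady_state,
)
from .pathway_network.params import PathwayParameters

__all__ = [
    "DoseResponseCurve",
    "ParadoxicalRange",
    "CombinationGrid",
    "SynergyAssessment",
    "log_dose_grid",
    "dose_response",
    "paradoxical_range",
    "combination_grid",
    "loewe_isobole",
    "additive_reference_grid",
]

_PARADOX_REL = 0.01  # curve must exceed basal by >1% to count as paradoxical


def log_dose_grid(lo: float, hi: float, points_per_decade: float = 7,
                  *, include_zero: bool = True) -> np.ndarray:
    """Log-spaced dose grid over [lo, hi] nM, optionally prefixed with 0."""
    if lo <= 0 or hi <= lo:
        raise InvalidParameterError("need 0 < lo < hi")
    n = max(2, int(round(math.log10(hi / lo) * points_per_decade)) + 1)
    grid = np.logspace(math.log10(lo), math.log10(hi), n)
    if include_zero:
        grid = np.concatenate([[0.0], grid])
    return grid


@dataclass
class DoseResponseCurve:
    """ppERK versus dose of one inhibitor under a fixed condition."""

    inhibitor: str
    doses: np.ndarray
    pperk: np.ndarray
    condition: SimulationCondition
    converged: np.ndarray  # bool per point

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.pperk = np.asarray(self.pperk, dtype=float)
        if self.doses[0] != 0.0:
            raise InvalidParameterError("dose grid must include the zero dose first")
        if np.any(np.diff(self.doses) <= 0):
            raise InvalidParameterError("dose grid must be strictly increasing")

    @property
    def basal(self) -> float:
        return float(self.pperk[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dose": self.doses, "ppERK": self.pperk, "basal": self.basal,
            "converged": self.converged,
        })


@dataclass(frozen=True)
class ParadoxicalRange:
    """Peak and basal-crossing metrics of one dose-response curve."""

    peak_dose: float
    peak_fold: float          # max ppERK / basal
    crossing_dose: float      # smallest dose beyond peak with ppERK < basal
    no_paradox: bool
    crossing_censored: bool   # curve never returned below basal within the grid


@dataclass
class CombinationGrid:
    """ppERK over a factorial two-drug dose grid (margins = single-drug curves)."""

    inhibitor1: str
    inhibitor2: str
    doses1: np.ndarray
    doses2: np.ndarray
    pperk: np.ndarray  # shape (len(doses1), len(doses2))
    condition: SimulationCondition
    converged: np.ndarray = field(default=None)

    @property
    def basal(self) -> float:
        return float(self.pperk[0, 0])

    def margin1(self) -> np.ndarray:
        return self.pperk[:, 0]

    def margin2(self) -> np.ndarray:
        return self.pperk[0, :]

    def to_frame(self) -> pd.DataFrame:
        d1, d2 = np.meshgrid(self.doses1, self.doses2, indexing="ij")
        return pd.DataFrame({
            "dose1": d1.ravel(), "dose2": d2.ravel(),
            "ppERK": self.pperk.ravel(), "basal": self.basal,
        })


@dataclass
class SynergyAssessment:
    """Loewe isobole at one effect level with combination indices."""

    effect: float
    isobole: list[tuple[float, float]]      # (dose1, dose2) polyline
    ci: list[float | None]                  # CI per isobole point (None = censored)
    classification: str                     # "synergy" | "additivity" | "antagonism"
    d1_single: float | None
    d2_single: float | None

    @property
    def median_ci(self) -> float:
        vals = [c for c in self.ci if c is not None]
        return float(np.median(vals)) if vals else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dose1": [p[0] for p in self.isobole],
            "dose2": [p[1] for p in self.isobole],
            "effect": self.effect,
            "CI": [np.nan if c is None else c for c in self.ci],
        })


# ---------------------------------------------------------------------------


def _build_network(cond, inhibitors, factors, params):
    model = build_model(cond, inhibitors, factors, params=params)
    return generate_network(model)


def dose_response(
    cond: SimulationCondition,
    inhibitor: InhibitorSpec | Sequence[InhibitorSpec],
    factors: ThermodynamicFactors,
    grid: Sequence[float],
    *,
    slot: int = 1,
    params: PathwayParameters | None = None,
    net: ReactionNetwork | None = None,
    refine: bool = False,
    max_refinements: int = 20,
) -> DoseResponseCurve:
    """Steady-state ppERK for each dose of one inhibitor.

    Simulations are warm-started from the previous dose's steady state (the
    dose axis is swept in increasing order).  With ``refine=True`` midpoints
    are inserted (in log-dose) wherever neighbouring ppERK values differ by
    more than 10% of basal, up to ``max_refinements`` extra points.
    """
    inhibitors = [inhibitor] if isinstance(inhibitor, InhibitorSpec) else list(inhibitor)
    if net is None:
        net = _build_network(cond, inhibitors, factors, params)
    grid = np.asarray(sorted(set(float(g) for g in grid)))
    if grid[0] != 0.0:
        raise InvalidParameterError("dose grid must include 0")

    def sweep(doses):
        pperk, conv = [], []
        y0 = None
        for d in doses:
            c = cond.with_doses(dose1=d) if slot == 1 else cond.with_doses(dose2=d)
            res = simulate_steady_state(net, c, y0=y0)
            y0 = res.y
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pperk.append(observables(res)["ppERK"])
            conv.append(res.converged)
        return np.array(pperk), np.array(conv)

    pperk, conv = sweep(grid)
    if refine:
        budget = max_refinements
        while budget > 0:
            basal = pperk[0]
            gaps = np.abs(np.diff(pperk)) > 0.1 * max(basal, 1e-12)
            gaps[0] = False  # cannot bisect between 0 and the first dose in log space
            if not gaps.any():
                break
            mids = np.sqrt(grid[:-1][gaps] * grid[1:][gaps])[:budget]
            budget -= len(mids)
            grid = np.sort(np.concatenate([grid, mids]))
            pperk, conv = sweep(grid)

    label = inhibitors[slot - 1].name if len(inhibitors) >= slot else "none"
    return DoseResponseCurve(inhibitor=label, doses=grid, pperk=pperk,
                             condition=cond, converged=conv)


def _log_interp_crossing(d_lo, d_hi, v_lo, v_hi, target):
    """Dose where the curve crosses `target` between two grid points.

    Interpolates linearly in log10(dose); ties and degenerate segments resolve
    toward the smaller dose.
    """
    if v_lo == v_hi:
        return d_lo
    t = (target - v_lo) / (v_hi - v_lo)
    t = min(max(t, 0.0), 1.0)
    if d_lo <= 0:
        return d_lo + t * (d_hi - d_lo)
    return 10.0 ** (math.log10(d_lo) + t * (math.log10(d_hi) - math.log10(d_lo)))


def paradoxical_range(curve: DoseResponseCurve) -> ParadoxicalRange:
    """Peak fold-activation and basal-crossing dose of a dose-response curve.

    ``no_paradox`` is set when the curve never exceeds basal by more than 1%
    relative; the crossing dose is then the first grid dose below basal.  If
    the curve never returns below basal within the grid, the crossing dose is
    right-censored at the grid maximum.
    """
    basal = curve.basal
    i_peak = int(np.argmax(curve.pperk))
    peak = float(curve.pperk[i_peak])
    no_paradox = peak <= basal * (1.0 + _PARADOX_REL)
    peak_dose = float(curve.doses[i_peak]) if not no_paradox else 0.0
    peak_fold = peak / basal if basal > 0 else math.inf

    start = i_peak if not no_paradox else 0
    crossing, censored = float(curve.doses[-1]), True
    for j in range(max(start, 0) + 1, len(curve.doses)):
        if curve.pperk[j] < basal:
            if no_paradox:
                crossing = float(curve.doses[j])  # first dose below basal
            else:
                crossing = _log_interp_crossing(
                    curve.doses[j - 1], curve.doses[j],
                    curve.pperk[j - 1], curve.pperk[j], basal,
                )
            censored = False
            break
    return ParadoxicalRange(peak_dose=peak_dose, peak_fold=peak_fold,
                            crossing_dose=crossing, no_paradox=no_paradox,
                            crossing_censored=censored)


def combination_grid(
    cond: SimulationCondition,
    inh1: InhibitorSpec,
    inh2: InhibitorSpec,
    factors: ThermodynamicFactors,
    grid1: Sequence[float],
    grid2: Sequence[float],
    *,
    params: PathwayParameters | None = None,
    net: ReactionNetwork | None = None,
) -> CombinationGrid:
    """Full factorial steady-state ppERK surface for two inhibitors.

    The zero row/column follow the exact same simulation path as
    :func:`dose_response` on the same two-inhibitor network, so margins
    reproduce the single-drug curves bit-for-bit.
    """
    if net is None:
        net = _build_network(cond, [inh1, inh2], factors, params)
    grid1 = np.asarray(sorted(set(float(g) for g in grid1)))
    grid2 = np.asarray(sorted(set(float(g) for g in grid2)))
    if grid1[0] != 0.0 or grid2[0] != 0.0:
        raise InvalidParameterError("both dose grids must include 0")

    pperk = np.empty((len(grid1), len(grid2)))
    conv = np.empty((len(grid1), len(grid2)), dtype=bool)
    # sweep drug 1 first (column 0 = dose_response path of drug 1), then each
    # row in increasing dose2, warm-starting from the previous point in the row
    col0 = None
    y_col = []
    for i, d1 in enumerate(grid1):
        res = simulate_steady_state(net, cond.with_doses(dose1=d1, dose2=0.0),
                                    y0=col0)
        col0 = res.y
        y_col.append(res.y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pperk[i, 0] = observables(res)["ppERK"]
        conv[i, 0] = res.converged
    for i, d1 in enumerate(grid1):
        y0 = y_col[i]
        for j, d2 in enumerate(grid2[1:], start=1):
            res = simulate_steady_state(net, cond.with_doses(dose1=d1, dose2=d2),
                                        y0=y0)
            y0 = res.y
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pperk[i, j] = observables(res)["ppERK"]
            conv[i, j] = res.converged
    return CombinationGrid(inhibitor1=inh1.name, inhibitor2=inh2.name,
                           doses1=grid1, doses2=grid2, pperk=pperk,
                           condition=cond, converged=conv)


def _single_agent_dose(doses: np.ndarray, values: np.ndarray,
                       effect: float) -> float | None:
    """Smallest dose beyond the curve's peak reaching `effect`.

    Uses monotone cubic (PCHIP) interpolation in log10(dose) along the
    beyond-peak tail when enough points are available, falling back to
    log-linear interpolation; ties resolve toward the smaller dose.
    """
    i_peak = int(np.argmax(values))
    for j in range(i_peak + 1, len(doses)):
        if values[j] <= effect:
            if values[j] == effect:
                return float(doses[j])
            lo = max(i_peak, 1 if doses[0] <= 0 else 0)
            if doses[j - 1] > 0 and j - lo >= 1 and len(doses) - lo >= 3:
                from scipy.interpolate import PchipInterpolator
                from scipy.optimize import brentq

                x = np.log10(doses[lo:])
                f = PchipInterpolator(x, values[lo:], extrapolate=False)
                a, b = math.log10(doses[j - 1]), math.log10(doses[j])
                fa_, fb_ = f(a) - effect, f(b) - effect
                if np.isfinite(fa_) and np.isfinite(fb_) and fa_ * fb_ < 0:
                    return 10.0 ** brentq(lambda t: float(f(t)) - effect, a, b)
            return _log_interp_crossing(doses[j - 1], doses[j],
                                        values[j - 1], values[j], effect)
    if values[i_peak] <= effect and i_peak == 0:
        return 0.0
    return None


def loewe_isobole(grid: CombinationGrid, effect: float) -> SynergyAssessment:
    """Extract the iso-effect contour and Loewe combination indices.

    The isobole is traced row-wise: for every dose2 level the dose1 value at
    which ppERK falls to ``effect`` is found by log-linear interpolation along
    that row (beyond the row's peak; ties toward the smaller dose).  CI at
    each point is d1/D1 + d2/D2 with D1, D2 the single-agent equi-effective
    doses; when the effect is unreachable by a single agent the CI at that
    point is censored (None) and the isobole is still returned.
    Classification by median CI: < 0.9 synergy, > 1.1 antagonism, otherwise
    additivity.
    """
    vmin, vmax = float(np.min(grid.pperk)), float(np.max(grid.pperk))
    if not (vmin <= effect <= vmax):
        raise InvalidParameterError(
            f"effect {effect} outside the surface's range [{vmin:.3g}, {vmax:.3g}]"
        )
    D1 = _single_agent_dose(grid.doses1, grid.margin1(), effect)
    D2 = _single_agent_dose(grid.doses2, grid.margin2(), effect)

    isobole: list[tuple[float, float]] = []
    ci: list[float | None] = []
    for j, d2 in enumerate(grid.doses2):
        row = grid.pperk[:, j]
        if row[0] < effect:
            # drug 2 alone already pushes below the effect level at this d2:
            # the level set does not pass through this row
            continue
        d1 = _single_agent_dose(grid.doses1, row, effect)
        if d1 is None:
            continue
        isobole.append((d1, float(d2)))
        if D1 is not None and D2 is not None and D2 > 0:
            ci.append(d1 / D1 + d2 / D2 if D1 > 0 else None)
        else:
            ci.append(None)
    vals = [c for c in ci if c is not None]
    med = float(np.median(vals)) if vals else float("nan")
    if math.isnan(med):
        classification = "additivity"
    elif med < 0.9:
        classification = "synergy"
    elif med > 1.1:
        classification = "antagonism"
    else:
        classification = "additivity"
    return SynergyAssessment(effect=effect, isobole=isobole, ci=ci,
                             classification=classification,
                             d1_single=D1, d2_single=D2)


def additive_reference_grid(
    doses1: Sequence[float], doses2: Sequence[float], *,
    e0: float = 100.0, ic50: float = 10.0, hill: float = 1.0,
    potency_ratio: float = 2.0,
) -> CombinationGrid:
    """Synthetic exactly-Loewe-additive surface from a shared Hill curve.

    Drug 2 is a dilution of drug 1 (dose-equivalence d_eq = d1 +
    d2/potency_ratio), so every isobole is a straight line and CI = 1
    identically; used as the oracle for the synergy pipeline.
    """
    d1 = np.asarray(sorted(set(float(d) for d in doses1)))
    d2 = np.asarray(sorted(set(float(d) for d in doses2)))
    eq = d1[:, None] + d2[None, :] / potency_ratio
    surface = e0 / (1.0 + (eq / ic50) ** hill)
    cond = SimulationCondition()
    return CombinationGrid(inhibitor1="hill1", inhibitor2="hill2",
                           doses1=d1, doses2=d2, pperk=surface, condition=cond,
                           converged=np.ones(surface.shape, dtype=bool))
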