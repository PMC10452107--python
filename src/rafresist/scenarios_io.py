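"""Scenario configuration, packaged figure-condition presets, and run bundles.

A scenario is a self-contained YAML document describing a simulation condition,
the inhibitors applied (packaged presets or custom specs), the dose grids and
the analyses to run (dose-response curves, two-drug combination surfaces,
Loewe isoboles).  Packaged presets reproduce the simulated conditions of the
reference figures; everything is deterministic, so re-running a scenario
produces byte-identical CSV output.

Schema (top level keys)::

    name:        unique scenario identifier (string, required)
    condition:   SimulationCondition fields (abundances nM, ras_status, ...)
    variants:    list of condition overrides run in addition to the base
    inhibitors:  list of {preset: I|II|I_half} or custom
                 {name, type_label, Kd_ref, penalty}
    doses:       {unit: kd|nM, lo, hi, points_per_decade}
    analyses:    list of {kind: dose_response|combination|isobole, ...}
    parameters:  optional PathwayParameters overrides
    expected:    free-form notes on the qualitative outcome (not executed)

Unknown keys anywhere are rejected with the offending key names and, when the
source text is available, their line numbers.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .inhibitor_pharmacology import (
    InhibitorSpec,
    ThermodynamicFactors,
    preset_inhibitor,
    preset_pair,
)
from .pathway_network import SimulationCondition, build_model, generate_network
from .pathway_network.params import PathwayParameters
from .response_analysis import (
    combination_grid,
    dose_response,
    log_dose_grid,
    loewe_isobole,
    paradoxical_range,
)

__all__ = ["Scenario", "load_scenario", "save_scenario", "run_scenario",
           "list_presets", "ScenarioResult"]

logger = logging.getLogger("rafresist")

_TOP_KEYS = {"name", "condition", "variants", "inhibitors", "doses", "analyses",
             "parameters", "expected"}
_COND_KEYS = {f.name for f in dataclasses.fields(SimulationCondition)}
_DOSE_KEYS = {"unit", "lo", "hi", "points_per_decade"}
_ANALYSIS_KEYS = {"kind", "inhibitor", "inhibitor2", "effects"}
_INH_KEYS = {"preset", "name", "type_label", "Kd_ref", "penalty"}


@dataclass(frozen=True)
class Scenario:
    """A fully validated, self-contained simulation scenario."""

    name: str
    condition: SimulationCondition
    inhibitors: tuple[dict, ...]
    doses: dict
    analyses: tuple[dict, ...]
    variants: tuple[dict, ...] = ()
    parameters: dict = field(default_factory=dict)
    expected: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "condition": dataclasses.asdict(self.condition),
            "variants": [dict(v) for v in self.variants],
            "inhibitors": [dict(i) for i in self.inhibitors],
            "doses": dict(self.doses),
            "analyses": [dict(a) for a in self.analyses],
            "parameters": dict(self.parameters),
            "expected": dict(self.expected),
        }


def _reject_unknown(mapping: dict, allowed: set, where: str, text: str | None):
    unknown = set(mapping) - allowed
    if unknown:
        locations = []
        for key in sorted(unknown):
            line = None
            if text is not None:
                for ln, raw in enumerate(text.splitlines(), start=1):
                    if raw.lstrip().startswith(f"{key}:"):
                        line = ln
                        break
            locations.append(f"{key!r}" + (f" (line {line})" if line else ""))
        raise ConfigurationError(
            f"unknown key(s) in {where}: " + ", ".join(locations)
        )


def _parse_scenario(data: Any, text: str | None = None) -> Scenario:
    if not isinstance(data, dict) or not data:
        raise ConfigurationError("scenario file is empty or not a mapping")
    _reject_unknown(data, _TOP_KEYS, "scenario", text)
    if "name" not in data:
        raise ConfigurationError("scenario must have a 'name'")
    cond_map = data.get("condition", {}) or {}
    _reject_unknown(cond_map, _COND_KEYS, "condition", text)
    condition = SimulationCondition(**cond_map)
    variants = tuple(data.get("variants", []) or [])
    for v in variants:
        _reject_unknown(v, _COND_KEYS, "variants entry", text)
    inhibitors = tuple(data.get("inhibitors", []) or [])
    for entry in inhibitors:
        _reject_unknown(entry, _INH_KEYS, "inhibitors entry", text)
        if "preset" not in entry and "type_label" not in entry:
            raise ConfigurationError(
                "inhibitor entry needs 'preset' or a custom 'type_label' spec"
            )
    doses = data.get("doses", {"unit": "kd", "lo": 0.01, "hi": 1000.0,
                               "points_per_decade": 5})
    _reject_unknown(doses, _DOSE_KEYS, "doses", text)
    analyses = tuple(data.get("analyses", []) or [])
    if not analyses:
        raise ConfigurationError("scenario must request at least one analysis")
    for a in analyses:
        _reject_unknown(a, _ANALYSIS_KEYS, "analyses entry", text)
        if a.get("kind") not in ("dose_response", "combination", "isobole"):
            raise ConfigurationError(
                f"unknown analysis kind {a.get('kind')!r}; expected "
                "dose_response | combination | isobole"
            )
    params = data.get("parameters", {}) or {}
    valid_params = {f.name for f in dataclasses.fields(PathwayParameters)}
    _reject_unknown(params, valid_params, "parameters", text)
    return Scenario(
        name=str(data["name"]), condition=condition, inhibitors=inhibitors,
        doses=dict(doses), analyses=analyses, variants=variants,
        parameters=dict(params), expected=dict(data.get("expected", {}) or {}),
    )


def list_presets() -> list[str]:
    """Names of the packaged scenario fixtures."""
    pkg = resources.files("rafresist.scenarios")
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_scenario(source: str | Path) -> Scenario:
    """Load a scenario from a YAML file path or a packaged preset name."""
    path = Path(source)
    if path.suffix in (".yaml", ".yml") or path.exists():
        if not path.exists():
            raise ConfigurationError(f"scenario file not found: {path}")
        text = path.read_text()
    else:
        pkg = resources.files("rafresist.scenarios")
        candidate = pkg / f"{source}.yaml"
        if not candidate.is_file():
            raise ConfigurationError(
                f"unknown scenario {source!r}; packaged presets: {list_presets()}"
            )
        text = candidate.read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"YAML parse error: {exc}") from exc
    return _parse_scenario(data, text)


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    """Write a scenario as YAML (round-trips through load_scenario)."""
    Path(path).write_text(yaml.safe_dump(scenario.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------


def _yaml_safe(obj):
    """Recursively convert frozenset dict keys (isoform pairs) for YAML."""
    if isinstance(obj, dict):
        return {
            ("+".join(sorted(k)) if isinstance(k, frozenset) else k):
                _yaml_safe(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    return obj


@dataclass
class ScenarioResult:
    """Outputs of one scenario run: tables plus a provenance record."""

    scenario: Scenario
    tables: dict[str, pd.DataFrame]
    provenance: dict

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for key, df in self.tables.items():
            target = outdir / f"{self.scenario.name}__{key}.csv"
            df.to_csv(target, index=False, float_format="%.10g")
            written.append(target)
        prov = outdir / f"{self.scenario.name}__provenance.yaml"
        prov.write_text(yaml.safe_dump(self.provenance, sort_keys=True))
        written.append(prov)
        return written


def _resolve_inhibitors(scenario: Scenario):
    """(specs, factors) for the scenario's inhibitor list."""
    entries = scenario.inhibitors
    presets = [e.get("preset") for e in entries]
    if len(entries) == 0:
        return [], ThermodynamicFactors()
    if all(p is not None for p in presets):
        if len(entries) == 1:
            spec, factors = preset_inhibitor(presets[0])
            return [spec], factors
        s1, s2, factors = preset_pair(presets[0], presets[1])
        return [s1, s2], factors
    specs = []
    for e in entries:
        if "preset" in e:
            specs.append(preset_inhibitor(e["preset"])[0])
        else:
            specs.append(InhibitorSpec(
                name=e.get("name", e["type_label"]),
                type_label=e["type_label"], Kd_ref=float(e["Kd_ref"]),
                penalty=float(e.get("penalty", 100.0)),
            ))
    return specs, ThermodynamicFactors()


def _dose_grid(scenario: Scenario, spec: InhibitorSpec) -> np.ndarray:
    d = scenario.doses
    scale = spec.Kd_ref if d.get("unit", "kd") == "kd" else 1.0
    return log_dose_grid(float(d.get("lo", 0.01)) * scale,
                         float(d.get("hi", 1000.0)) * scale,
                         int(d.get("points_per_decade", 5)))


def _spec_by_label(specs, label):
    for i, s in enumerate(specs):
        if s.type_label == label or s.name == label:
            return i, s
    raise ConfigurationError(f"analysis references unknown inhibitor {label!r}")


def run_scenario(scenario: Scenario, outdir: str | Path | None = None
                 ) -> ScenarioResult:
    """Execute every analysis of a scenario over its condition variants.

    Fully deterministic: there is no randomness anywhere in the pipeline.
    The provenance record snapshots the complete parameter set, condition and
    package version; per-dose convergence flags are kept in the tables.
    """
    params = PathwayParameters(**scenario.parameters) if scenario.parameters \
        else PathwayParameters()
    specs, factors = _resolve_inhibitors(scenario)
    conditions = [("base", scenario.condition)]
    for v in scenario.variants:
        label = "_".join(f"{k}{v[k]:g}" if isinstance(v[k], (int, float))
                         else f"{k}-{v[k]}" for k in sorted(v))
        conditions.append((label, replace(scenario.condition, **v)))

    tables: dict[str, pd.DataFrame] = {}
    for cond_label, cond in conditions:
        net = None
        if specs:
            net = generate_network(build_model(cond, specs, factors,
                                               params=params))
        for a in scenario.analyses:
            kind = a["kind"]
            if kind == "dose_response":
                slot, spec = _spec_by_label(specs, a.get("inhibitor",
                                                         specs[0].type_label))
                grid = _dose_grid(scenario, spec)
                logger.info("scenario %s: dose_response %s under %s",
                            scenario.name, spec.name, cond_label)
                curve = dose_response(cond, specs, factors, grid,
                                      slot=slot + 1, params=params, net=net)
                pr = paradoxical_range(curve)
                df = curve.to_frame()
                df["peak_dose"] = pr.peak_dose
                df["peak_fold"] = pr.peak_fold
                df["crossing_dose"] = pr.crossing_dose
                tables[f"{cond_label}__dose_response_{spec.name}"] = df
            elif kind in ("combination", "isobole"):
                if len(specs) < 2:
                    raise ConfigurationError(
                        f"{kind} analysis needs two inhibitors")
                grid1 = _dose_grid(scenario, specs[0])
                grid2 = _dose_grid(scenario, specs[1])
                logger.info("scenario %s: %s %s+%s under %s", scenario.name,
                            kind, specs[0].name, specs[1].name, cond_label)
                key = f"{cond_label}__combination"
                if key not in tables:
                    surface = combination_grid(cond, specs[0], specs[1],
                                               factors, grid1, grid2,
                                               params=params, net=net)
                    tables[key] = surface.to_frame()
                    tables[key].attrs["surface"] = surface
                if kind == "isobole":
                    surface = tables[key].attrs["surface"]
                    basal = surface.basal
                    effects = a.get("effects",
                                    [0.5, 0.3, 0.2, 0.1])
                    rows = []
                    for level in effects:
                        assessment = loewe_isobole(surface, level * basal)
                        df = assessment.to_frame()
                        df["effect_fraction_of_basal"] = level
                        df["median_CI"] = assessment.median_ci
                        df["classification"] = assessment.classification
                        rows.append(df)
                    tables[f"{cond_label}__isoboles"] = pd.concat(
                        rows, ignore_index=True)

    provenance = {
        "package_version": __version__,
        "scenario": scenario.to_dict(),
        "parameters": _yaml_safe(dataclasses.asdict(params)),
        "factors": dataclasses.asdict(factors),
        "inhibitors": [dataclasses.asdict(s) for s in specs],
    }
    result = ScenarioResult(scenario=scenario, tables=tables,
                            provenance=provenance)
    if outdir is not None:
        result.write(outdir)
    return result
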