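"""Orchestration: full projections, what-if variants and sensitivity sweeps.

``run_scenario`` composes the needs and supply engines into a complete
deterministic :class:`~hwfplan.scenario_model.ProjectionResult`.  Variants
apply parameter overrides (addressed by dotted path, with list items keyed
by their identifying label) to a deep copy of the base scenario; three
common what-ifs ship as built-ins:

* ``no-rate-change`` — hold health status at baseline levels;
* ``no-support-adjustment`` — drop the SAAF inflation;
* ``tertiary-standards`` — switch the run to tertiary-facility activity
  standards.

``sensitivity_sweep`` draws uniform independent samples of selected
parameters over stated ranges (seeded) and reports the min/max envelope of
need, supply and gap per cadre-year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel

from . import gap_cost_engine, needs_engine, supply_engine
from .scenario_model import ProjectionResult, Scenario, validate_scenario

__all__ = [
    "run_scenario",
    "ScenarioVariant",
    "BUILTIN_VARIANTS",
    "apply_overrides",
    "apply_variant",
    "compare_scenarios",
    "SweepEnvelope",
    "sensitivity_sweep",
]

logger = logging.getLogger(__name__)

_CADRE_YEAR_COLUMNS = [
    "cadre_id",
    "year",
    "need_fte",
    "need_rounded",
    "supply",
    "supply_rounded",
    "absolute_gap",
    "sar",
    "income",
    "cost_of_need",
    "cost_of_supply",
]


def run_scenario(scenario: Scenario, rate_method: str = "geometric") -> ProjectionResult:
    """Run a full projection: need, supply, gaps, SAR and wage bills.

    Deterministic: identical inputs yield identical outputs.  The cost of
    need uses the rounded (whole-person) need; the cost of supply follows
    the un-rounded supply path.
    """
    scenario = validate_scenario(scenario)
    years = scenario.years
    logger.info(
        "running scenario %r: %d cadres, %d services, years %d-%d (rate method %s, "
        "rate-of-change %s, support adjustment %s)",
        scenario.name,
        len(scenario.cadres),
        len(scenario.services),
        years[0],
        years[-1],
        rate_method,
        "on" if scenario.flags.apply_rate_of_change else "off",
        "on" if scenario.flags.apply_support_adjustment else "off",
    )
    volumes = needs_engine.compute_service_volumes(scenario, method=rate_method)

    svc_rows = [
        {"service_id": sid, "year": year, "volume": vol}
        for sid, by_year in volumes.items()
        for year, vol in sorted(by_year.items())
    ]
    service_volumes = pd.DataFrame(svc_rows, columns=["service_id", "year", "volume"])

    rows = []
    for cadre in scenario.cadres:
        need = {
            year: needs_engine.compute_workforce_requirement(
                scenario, cadre.cadre_id, year, service_volumes=volumes
            )
            for year in years
        }
        supply = supply_engine.project_supply(cadre, years).effective_supply_by_year
        incomes = gap_cost_engine.income_series(cadre.baseline_income, cadre.income_inflation, years)
        for year in years:
            need_r = gap_cost_engine.round_half_up(need[year])
            supply_r = gap_cost_engine.round_half_up(supply[year])
            sar = supply_r / need_r if need_r > 0 else float("nan")
            rows.append(
                {
                    "cadre_id": cadre.cadre_id,
                    "year": year,
                    "need_fte": need[year],
                    "need_rounded": need_r,
                    "supply": supply[year],
                    "supply_rounded": supply_r,
                    "absolute_gap": supply_r - need_r,
                    "sar": sar,
                    "income": incomes[year],
                    "cost_of_need": need_r * incomes[year],
                    "cost_of_supply": supply[year] * incomes[year],
                }
            )
    cadre_years = pd.DataFrame(rows, columns=_CADRE_YEAR_COLUMNS)
    return ProjectionResult(
        scenario_name=scenario.name, cadre_years=cadre_years, service_volumes=service_volumes
    )


@dataclass(frozen=True)
class ScenarioVariant:
    """A named set of parameter overrides on a base scenario."""

    name: str
    overrides: dict[str, object] = field(default_factory=dict)


BUILTIN_VARIANTS: dict[str, ScenarioVariant] = {
    "no-rate-change": ScenarioVariant("no-rate-change", {"flags.apply_rate_of_change": False}),
    "no-support-adjustment": ScenarioVariant(
        "no-support-adjustment", {"flags.apply_support_adjustment": False}
    ),
    "tertiary-standards": ScenarioVariant("tertiary-standards", {"practice_setting": "tertiary"}),
}

_LIST_KEYS = {
    "cadre_id",
    "service_id",
    "indicator_id",
    "name",
}


def _descend(obj, segment: str, path: str):
    """Resolve one path segment on a model, list or dict."""
    if isinstance(obj, BaseModel):
        if segment not in type(obj).model_fields:
            raise KeyError(f"override path {path!r}: no field {segment!r} on {type(obj).__name__}")
        return getattr(obj, segment)
    if isinstance(obj, list):
        for item in obj:
            if isinstance(item, BaseModel):
                for key in _LIST_KEYS:
                    if getattr(item, key, None) == segment:
                        return item
            if getattr(item, "key", None) == segment:
                return item
        raise KeyError(f"override path {path!r}: no list item labelled {segment!r}")
    if isinstance(obj, dict):
        if segment in obj:
            return obj[segment]
        try:
            as_int = int(segment)
        except ValueError:
            as_int = None
        if as_int is not None and as_int in obj:
            return obj[as_int]
        raise KeyError(f"override path {path!r}: no key {segment!r}")
    raise KeyError(f"override path {path!r}: cannot descend into {type(obj).__name__} at {segment!r}")


def _set_value(parent, segment: str, value, path: str) -> None:
    if isinstance(parent, BaseModel):
        if segment not in type(parent).model_fields:
            raise KeyError(f"override path {path!r}: no field {segment!r} on {type(parent).__name__}")
        setattr(parent, segment, value)
        return
    if isinstance(parent, dict):
        if segment in parent:
            parent[segment] = value
            return
        try:
            as_int = int(segment)
        except ValueError:
            as_int = None
        if as_int is not None and as_int in parent:
            parent[as_int] = value
            return
        raise KeyError(f"override path {path!r}: no key {segment!r}")
    raise KeyError(f"override path {path!r}: cannot assign at {segment!r}")


def apply_overrides(scenario: Scenario, overrides: Mapping[str, object]) -> Scenario:
    """Return a deep copy of the scenario with dotted-path overrides applied.

    Paths address fields by name and list items by their identifying label,
    e.g. ``cadres.midwife.attrition_rate`` or
    ``services.anc_visit.frequency_per_person_in_need``.  Every overridden
    path must exist in the base scenario.
    """
    out = scenario.model_copy(deep=True)
    for path, value in overrides.items():
        segments = path.split(".")
        node = out
        for segment in segments[:-1]:
            node = _descend(node, segment, path)
        _set_value(node, segments[-1], value, path)
    return out


def apply_variant(scenario: Scenario, variant: Union[str, ScenarioVariant]) -> Scenario:
    """Apply a built-in (by name) or explicit variant to a scenario."""
    if isinstance(variant, str):
        if variant not in BUILTIN_VARIANTS:
            raise KeyError(
                f"unknown built-in variant {variant!r}; available: {sorted(BUILTIN_VARIANTS)}"
            )
        variant = BUILTIN_VARIANTS[variant]
    logger.info("applying variant %r: %s", variant.name, variant.overrides)
    out = apply_overrides(scenario, variant.overrides)
    out.name = f"{scenario.name}:{variant.name}"
    return out


_COMPARE_METRICS = ["need_fte", "supply", "absolute_gap", "sar"]


def compare_scenarios(base: ProjectionResult, variant: ProjectionResult) -> pd.DataFrame:
    """Side-by-side comparison of two projections, per cadre-year and metric.

    Columns: cadre_id, year, metric, base, variant, abs_diff, pct_diff
    (pct_diff is NaN where the base value is 0).
    """
    if base.cadre_ids != variant.cadre_ids or base.years != variant.years:
        raise ValueError(
            "cannot compare projections with different cadres or horizons: "
            f"{base.cadre_ids}/{base.years[0]}-{base.years[-1]} vs "
            f"{variant.cadre_ids}/{variant.years[0]}-{variant.years[-1]}"
        )
    key = ["cadre_id", "year"]
    b = base.cadre_years.set_index(key)
    v = variant.cadre_years.set_index(key)
    rows = []
    for (cadre_id, year) in b.index:
        for metric in _COMPARE_METRICS:
            base_val = float(b.loc[(cadre_id, year), metric])
            var_val = float(v.loc[(cadre_id, year), metric])
            diff = var_val - base_val
            pct = diff / base_val * 100.0 if base_val != 0 else float("nan")
            rows.append(
                {
                    "cadre_id": cadre_id,
                    "year": year,
                    "metric": metric,
                    "base": base_val,
                    "variant": var_val,
                    "abs_diff": diff,
                    "pct_diff": pct,
                }
            )
    return pd.DataFrame(rows, columns=["cadre_id", "year", "metric", "base", "variant", "abs_diff", "pct_diff"])


@dataclass
class SweepEnvelope:
    """Min/max bands of need, supply and gap per cadre-year over a sweep.

    ``table`` columns: cadre_id, year, then ``{metric}_{min,max,base}`` for
    need_fte, supply and absolute_gap.  The base trajectory is always one of
    the bounded trajectories.
    """

    table: pd.DataFrame
    n_samples: int
    seed: int


_SWEEP_METRICS = ["need_fte", "supply", "absolute_gap"]


def sensitivity_sweep(
    scenario: Scenario,
    ranges: Mapping[str, tuple[float, float]],
    n_samples: int,
    seed: int,
) -> SweepEnvelope:
    """Uniform independent parameter sweep (best/worst-case exploration).

    Each sample draws every swept parameter uniformly from its (low, high)
    range, runs the full projection, and the envelope records the min and
    max of need, supply and gap per cadre-year across all samples plus the
    base run.  Reproducible under a fixed seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    for path, (low, high) in ranges.items():
        if low > high:
            raise ValueError(f"invalid range for {path!r}: low {low} > high {high}")
        # fail early on unknown paths, before any sampling
        apply_overrides(scenario, {path: low})

    rng = np.random.default_rng(seed)
    paths = sorted(ranges)
    runs = [run_scenario(scenario)]
    for _ in range(n_samples):
        draw = {p: float(rng.uniform(ranges[p][0], ranges[p][1])) for p in paths}
        runs.append(run_scenario(apply_overrides(scenario, draw)))

    base = runs[0].cadre_years.set_index(["cadre_id", "year"])
    stacked = pd.concat([r.cadre_years for r in runs]).set_index(["cadre_id", "year"])
    grouped = stacked.groupby(level=["cadre_id", "year"])
    table = base[[]].copy()
    for metric in _SWEEP_METRICS:
        table[f"{metric}_min"] = grouped[metric].min()
        table[f"{metric}_max"] = grouped[metric].max()
        table[f"{metric}_base"] = base[metric]
    table = table.reset_index().sort_values(["cadre_id", "year"]).reset_index(drop=True)
    return SweepEnvelope(table=table, n_samples=n_samples, seed=seed)
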