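"""Reading and writing scenarios and results.

A scenario on disk is one YAML (or JSON) config referencing CSV tables,
resolved relative to the config file:

* ``population.csv`` — ``age_cohort,gender,location,year,count``
* ``indicators.csv`` — ``indicator_id,age_cohorts,genders,locations,
  baseline_year,baseline_value,second_year,second_value,rate_of_change``
  (selector columns are ``;``-separated label lists, blank = all strata)
* ``services.csv`` — ``service_id,indicator_id,frequency_per_person_in_need,
  service_standard,work_division`` where ``service_standard`` is a number or
  ``setting:value`` pairs (``primary:0.5;tertiary:0.75``) and
  ``work_division`` is ``cadre:share`` pairs summing to one
* ``cadres.yaml`` — a list of cadre parameter blocks

Column names are fixed and case-sensitive.  Percent notation (``"15%"``)
is accepted anywhere a proportion is expected and converted to a fraction
on read; everything is stored as fractions in memory and written back as
fractions.  Written results are byte-stable: re-running over the same
inputs reproduces identical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Optional, Union

import pandas as pd
import yaml

from .scenario_model import (
    ProjectionResult,
    Scenario,
    validate_scenario,
)

__all__ = ["load_scenario", "write_scenario", "write_results"]

logger = logging.getLogger(__name__)

_POPULATION_COLUMNS = ["age_cohort", "gender", "location", "year", "count"]
_INDICATOR_COLUMNS = [
    "indicator_id",
    "age_cohorts",
    "genders",
    "locations",
    "baseline_year",
    "baseline_value",
    "second_year",
    "second_value",
    "rate_of_change",
]
_SERVICE_COLUMNS = [
    "service_id",
    "indicator_id",
    "frequency_per_person_in_need",
    "service_standard",
    "work_division",
]


def _num(value: Any) -> float:
    """Parse a number, converting trailing-% notation to a fraction."""
    if isinstance(value, str):
        value = value.strip()
        if value.endswith("%"):
            return float(value[:-1]) / 100.0
        return float(value)
    return float(value)


def _convert_percents(obj: Any) -> Any:
    """Recursively convert '...%' strings to fractions in parsed YAML data."""
    if isinstance(obj, dict):
        return {k: _convert_percents(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_convert_percents(v) for v in obj]
    if isinstance(obj, str) and obj.strip().endswith("%"):
        try:
            return _num(obj)
        except ValueError:
            return obj
    return obj


def _split_list(cell: Any) -> Optional[list[str]]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return None
    return [part.strip() for part in str(cell).split(";") if part.strip()]


def _split_pairs(cell: str, what: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for part in str(cell).split(";"):
        part = part.strip()
        if not part:
            continue
        if ":" not in part:
            raise ValueError(f"malformed {what} entry {part!r} (expected 'label:value')")
        label, value = part.split(":", 1)
        out[label.strip()] = _num(value)
    return out


def _opt(cell: Any, cast):
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return None
    return cast(cell)


def _read_table(path: Path, columns: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"referenced table not found: {path}")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def load_scenario(path: Union[str, Path]) -> Scenario:
    """Load and validate a scenario from a YAML/JSON config file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"scenario config not found: {path}")
    text = path.read_text()
    config = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    base_dir = path.parent
    tables = config.get("tables", {})

    def table_path(key: str, default: str) -> Path:
        return base_dir / tables.get(key, default)

    pop_df = _read_table(table_path("population", "population.csv"), _POPULATION_COLUMNS)
    strata: dict[tuple[str, str, str], dict[int, float]] = {}
    for row in pop_df.itertuples(index=False):
        key = (row.age_cohort, row.gender, row.location)
        strata.setdefault(key, {})[int(row.year)] = _num(row.count)
    population = [
        {"age_cohort": a, "gender": g, "location": l, "counts_by_year": counts}
        for (a, g, l), counts in strata.items()
    ]

    ind_df = _read_table(table_path("indicators", "indicators.csv"), _INDICATOR_COLUMNS)
    indicators = []
    for row in ind_df.itertuples(index=False):
        indicators.append(
            {
                "indicator_id": row.indicator_id,
                "stratum_selector": {
                    "age_cohorts": _split_list(row.age_cohorts),
                    "genders": _split_list(row.genders),
                    "locations": _split_list(row.locations),
                },
                "baseline_year": int(row.baseline_year),
                "baseline_value": _num(row.baseline_value),
                "second_year": _opt(row.second_year, lambda v: int(float(v))),
                "second_value": _opt(row.second_value, _num),
                "rate_of_change": _opt(row.rate_of_change, _num),
            }
        )

    svc_df = _read_table(table_path("services", "services.csv"), _SERVICE_COLUMNS)
    services = []
    for row in svc_df.itertuples(index=False):
        standard_cell = str(row.service_standard)
        standard: Union[float, dict[str, float]]
        if ":" in standard_cell:
            standard = _split_pairs(standard_cell, "service_standard")
        else:
            standard = _num(standard_cell)
        services.append(
            {
                "service_id": row.service_id,
                "indicator_id": row.indicator_id,
                "frequency_per_person_in_need": _num(row.frequency_per_person_in_need),
                "service_standard": standard,
                "work_division": _split_pairs(row.work_division, "work_division"),
            }
        )

    cadres_path = base_dir / tables.get("cadres", "cadres.yaml")
    if not cadres_path.exists():
        raise FileNotFoundError(f"referenced table not found: {cadres_path}")
    cadres = _convert_percents(yaml.safe_load(cadres_path.read_text()))

    raw = {
        "name": config.get("name", path.stem),
        "base_year": int(config["base_year"]),
        "horizon_end": int(config["horizon_end"]),
        "population": population,
        "indicators": indicators,
        "services": services,
        "cadres": cadres,
        "practice_setting": config.get("practice_setting"),
        "flags": config.get("flags", {}),
    }
    scenario = validate_scenario(raw)
    logger.info(
        "loaded scenario %r from %s: %d strata, %d indicators, %d services, %d cadres",
        scenario.name,
        path,
        len(scenario.population),
        len(scenario.indicators),
        len(scenario.services),
        len(scenario.cadres),
    )
    return scenario


def _fmt_pairs(pairs: dict[str, float]) -> str:
    return ";".join(f"{k}:{v!r}" for k, v in pairs.items())


def write_scenario(scenario: Scenario, out_dir: Union[str, Path]) -> Path:
    """Write a scenario as a config + CSV set; returns the config path.

    ``load_scenario(write_scenario(s, d))`` reproduces an equal scenario.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    pop_rows = [
        {"age_cohort": s.age_cohort, "gender": s.gender, "location": s.location, "year": y, "count": repr(c)}
        for s in scenario.population
        for y, c in sorted(s.counts_by_year.items())
    ]
    pd.DataFrame(pop_rows, columns=_POPULATION_COLUMNS).to_csv(out_dir / "population.csv", index=False)

    ind_rows = []
    for ind in scenario.indicators:
        sel = ind.stratum_selector
        ind_rows.append(
            {
                "indicator_id": ind.indicator_id,
                "age_cohorts": ";".join(sel.age_cohorts) if sel.age_cohorts else "",
                "genders": ";".join(sel.genders) if sel.genders else "",
                "locations": ";".join(sel.locations) if sel.locations else "",
                "baseline_year": ind.baseline_year,
                "baseline_value": repr(ind.baseline_value),
                "second_year": "" if ind.second_year is None else ind.second_year,
                "second_value": "" if ind.second_value is None else repr(ind.second_value),
                "rate_of_change": "" if ind.rate_of_change is None else repr(ind.rate_of_change),
            }
        )
    pd.DataFrame(ind_rows, columns=_INDICATOR_COLUMNS).to_csv(out_dir / "indicators.csv", index=False)

    svc_rows = []
    for svc in scenario.services:
        standard = svc.service_standard
        svc_rows.append(
            {
                "service_id": svc.service_id,
                "indicator_id": svc.indicator_id,
                "frequency_per_person_in_need": repr(svc.frequency_per_person_in_need),
                "service_standard": _fmt_pairs(standard) if isinstance(standard, dict) else repr(standard),
                "work_division": _fmt_pairs(svc.work_division),
            }
        )
    pd.DataFrame(svc_rows, columns=_SERVICE_COLUMNS).to_csv(out_dir / "services.csv", index=False)

    cadres = [c.model_dump(mode="python") for c in scenario.cadres]
    (out_dir / "cadres.yaml").write_text(yaml.safe_dump(cadres, sort_keys=False))

    config = {
        "name": scenario.name,
        "base_year": scenario.base_year,
        "horizon_end": scenario.horizon_end,
        "practice_setting": scenario.practice_setting,
        "flags": scenario.flags.model_dump(),
        "tables": {
            "population": "population.csv",
            "indicators": "indicators.csv",
            "services": "services.csv",
            "cadres": "cadres.yaml",
        },
    }
    config_path = out_dir / "scenario.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return config_path


def write_results(result: ProjectionResult, out_dir: Union[str, Path]) -> list[Path]:
    """Write result tables (CSV) and a Markdown summary; returns the paths.

    Layout: ``need.csv``/``supply.csv`` carry the real-valued and rounded
    series; ``gaps.csv`` carries whole-person gaps with SAR to 0.1 %;
    ``costs.csv`` carries wage bills to the cent; ``services.csv`` the
    needed service volumes.  Output is deterministic byte-for-byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cy = result.cadre_years.sort_values(["cadre_id", "year"]).reset_index(drop=True)

    paths = []

    def emit(name: str, df: pd.DataFrame) -> None:
        target = out_dir / name
        df.to_csv(target, index=False)
        paths.append(target)

    need = cy[["cadre_id", "year", "need_fte", "need_rounded"]].copy()
    need["need_fte"] = need["need_fte"].map(repr)
    emit("need.csv", need)

    supply = cy[["cadre_id", "year", "supply", "supply_rounded"]].copy()
    supply["supply"] = supply["supply"].map(repr)
    emit("supply.csv", supply)

    gaps = cy[["cadre_id", "year", "need_rounded", "supply_rounded", "absolute_gap"]].copy()
    gaps.columns = ["cadre_id", "year", "need", "supply", "gap"]
    gaps["sar_pct"] = cy["sar"].map(lambda v: f"{v * 100.0:.1f}")
    emit("gaps.csv", gaps)

    costs = cy[["cadre_id", "year"]].copy()
    for col in ("income", "cost_of_need", "cost_of_supply"):
        costs[col] = cy[col].map(lambda v: f"{v:.2f}")
    emit("costs.csv", costs)

    volumes = result.service_volumes.sort_values(["service_id", "year"]).reset_index(drop=True).copy()
    volumes["volume"] = volumes["volume"].map(repr)
    emit("services.csv", volumes)

    lines = [f"# Projection summary: {result.scenario_name}", ""]
    years = result.years
    lines.append(f"Horizon: {years[0]}-{years[-1]}")
    lines.append("")
    lines.append("| cadre | year | need | supply | gap | SAR |")
    lines.append("|---|---|---|---|---|---|")
    for row in cy.itertuples(index=False):
        if row.year in (years[0], years[len(years) // 2], years[-1]):
            lines.append(
                f"| {row.cadre_id} | {row.year} | {row.need_rounded} | {row.supply_rounded} "
                f"| {row.absolute_gap} | {row.sar * 100.0:.1f}% |"
            )
    lines.append("")
    summary = out_dir / "summary.md"
    summary.write_text("\n".join(lines))
    paths.append(summary)
    return paths
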