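"""Domain types and validation for needs-based workforce planning scenarios.

A :class:`Scenario` is a closed, self-consistent description of one planning
world: a stratified population projection, health-status indicators with
their trends, service norms that translate need into countable activities,
and cadre profiles covering the supply pipeline, productivity and income
parameters.  Every downstream engine reads from a validated scenario and
nothing else.

Validation is split in two layers.  The pydantic models perform parsing and
type coercion; cross-field and cross-object invariants (work divisions
summing to one, dense year coverage, support allowances below 100 % of
working time, ...) are collected by :func:`check_scenario` as a list of
:class:`Violation` records, each naming the offending parameter path.
:func:`validate_scenario` raises :class:`ScenarioValidationError` when any
violation is present, so engines can assume a clean world.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict

__all__ = [
    "PopulationStratum",
    "StratumSelector",
    "HealthIndicator",
    "ServiceNorm",
    "AwtComponents",
    "SupportActivity",
    "EducationPipeline",
    "CadreProfile",
    "Scenario",
    "ScenarioFlags",
    "ProjectionResult",
    "Violation",
    "ScenarioValidationError",
    "check_scenario",
    "validate_scenario",
]

_REL_TOL = 1e-9


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=False)


class PopulationStratum(_Model):
    """One population cell: age cohort x gender x location, with annual counts.

    Labels are free-form so planners can use any cohort scheme; joins are by
    exact label match.  A location of ``"all"`` denotes a composite
    (non-disaggregated) analysis.
    """

    age_cohort: str
    gender: str
    location: str = "all"
    counts_by_year: dict[int, float]

    @property
    def key(self) -> str:
        return f"{self.age_cohort}/{self.gender}/{self.location}"


class StratumSelector(_Model):
    """Selects population strata by label; ``None`` on a dimension matches all."""

    age_cohorts: Optional[list[str]] = None
    genders: Optional[list[str]] = None
    locations: Optional[list[str]] = None

    def matches(self, stratum: PopulationStratum) -> bool:
        if self.age_cohorts is not None and stratum.age_cohort not in self.age_cohorts:
            return False
        if self.genders is not None and stratum.gender not in self.genders:
            return False
        if self.locations is not None and stratum.location not in self.locations:
            return False
        return True


class HealthIndicator(_Model):
    """A stratified proportion-in-need measure with its annual rate of change.

    The rate may be supplied directly (``rate_of_change``) or estimated from
    a second observation (``second_value`` at ``second_year``); exactly one
    of the two conventions must be used.  Projected values are proportions
    and are clamped to [0, 1].
    """

    indicator_id: str
    stratum_selector: StratumSelector = StratumSelector()
    baseline_value: float
    baseline_year: int
    second_value: Optional[float] = None
    second_year: Optional[int] = None
    rate_of_change: Optional[float] = None

    def has_direct_rate(self) -> bool:
        return self.rate_of_change is not None

    def has_two_points(self) -> bool:
        return self.second_value is not None and self.second_year is not None


class ServiceNorm(_Model):
    """One countable service activity.

    ``service_standard`` is hours per service, either a single value or one
    value per practice setting (e.g. ``{"primary": 0.5, "tertiary": 0.75}``);
    the scenario's ``practice_setting`` selects which applies for a run.
    ``work_division`` splits the service volume across cadres and must sum
    to one.  ``work_division_overrides`` optionally replaces the split for
    specific years; by default the division is time-invariant.
    """

    service_id: str
    indicator_id: str
    frequency_per_person_in_need: float
    service_standard: Union[float, dict[str, float]]
    work_division: dict[str, float]
    work_division_overrides: dict[int, dict[str, float]] = {}

    def standard_for(self, practice_setting: Optional[str]) -> float:
        """Resolve the service standard (hours/service) for a setting."""
        if isinstance(self.service_standard, dict):
            if practice_setting is None or practice_setting not in self.service_standard:
                raise KeyError(
                    f"service {self.service_id!r} has per-setting standards "
                    f"{sorted(self.service_standard)}; practice_setting "
                    f"{practice_setting!r} does not select one"
                )
            return self.service_standard[practice_setting]
        return self.service_standard

    def division_for(self, year: int) -> dict[str, float]:
        return self.work_division_overrides.get(year, self.work_division)


class AwtComponents(_Model):
    """Available-working-time components, WISN convention.

    Available days = possible working days minus public holidays and all
    leave/absence categories; AWT = available days x hours per day.
    """

    possible_working_days: float
    public_holidays: float = 0.0
    annual_leave: float = 0.0
    sick_leave: float = 0.0
    other_absences: float = 0.0
    hours_per_day: float = 8.0

    @property
    def available_days(self) -> float:
        return self.possible_working_days - (
            self.public_holidays + self.annual_leave + self.sick_leave + self.other_absences
        )


class SupportActivity(_Model):
    """A non-countable (indirect care) activity consuming a share of AWT."""

    name: str
    sas: float


class EducationPipeline(_Model):
    """Training pipeline feeding a cadre: enrolments, losses and licensure.

    Entrants in year t are the enrolment cohort of year t - training_duration
    reduced by the dropout rate, plus immigrants, all adjusted by the
    licensure pass rate.
    """

    enrolment_by_year: dict[int, float] = {}
    dropout_rate: float = 0.0
    training_duration: int = 0
    pass_rate: float = 1.0
    immigration_by_year: dict[int, float] = {}


class CadreProfile(_Model):
    """One health-professional category's complete parameter set."""

    cadre_id: str
    baseline_stock: float
    attrition_rate: float
    participation_rate: float = 1.0
    awt: AwtComponents
    support_activities: list[SupportActivity] = []
    pipeline: EducationPipeline = EducationPipeline()
    baseline_income: float = 0.0
    income_inflation: float = 0.0

    @property
    def total_sas(self) -> float:
        return sum(a.sas for a in self.support_activities)


class ScenarioFlags(_Model):
    apply_rate_of_change: bool = True
    apply_support_adjustment: bool = True


class Scenario(_Model):
    """A complete, self-consistent parameter set for one projection run."""

    name: str
    base_year: int
    horizon_end: int
    population: list[PopulationStratum]
    indicators: list[HealthIndicator]
    services: list[ServiceNorm]
    cadres: list[CadreProfile]
    practice_setting: Optional[str] = None
    flags: ScenarioFlags = ScenarioFlags()

    @property
    def years(self) -> list[int]:
        return list(range(self.base_year, self.horizon_end + 1))

    def get_indicator(self, indicator_id: str) -> HealthIndicator:
        for ind in self.indicators:
            if ind.indicator_id == indicator_id:
                return ind
        raise KeyError(f"unknown indicator {indicator_id!r}")

    def get_cadre(self, cadre_id: str) -> CadreProfile:
        for cadre in self.cadres:
            if cadre.cadre_id == cadre_id:
                return cadre
        raise KeyError(f"unknown cadre {cadre_id!r}")

    def get_service(self, service_id: str) -> ServiceNorm:
        for svc in self.services:
            if svc.service_id == service_id:
                return svc
        raise KeyError(f"unknown service {service_id!r}")

    def strata_for(self, selector: StratumSelector) -> list[PopulationStratum]:
        return [s for s in self.population if selector.matches(s)]

    def services_for_cadre(self, cadre_id: str) -> list[ServiceNorm]:
        return [s for s in self.services if cadre_id in s.work_division]


@dataclass
class ProjectionResult:
    """Per cadre-year projection output plus per service-year volumes.

    ``cadre_years`` columns: cadre_id, year, need_fte, need_rounded,
    supply, supply_rounded, absolute_gap, sar, income, cost_of_need,
    cost_of_supply.  ``service_volumes`` columns: service_id, year, volume.
    """

    scenario_name: str
    cadre_years: pd.DataFrame
    service_volumes: pd.DataFrame

    def series(self, cadre_id: str, column: str) -> dict[int, float]:
        df = self.cadre_years
        sub = df[df["cadre_id"] == cadre_id].sort_values("year")
        if sub.empty:
            raise KeyError(f"unknown cadre {cadre_id!r}")
        return dict(zip(sub["year"], sub[column]))

    @property
    def cadre_ids(self) -> list[str]:
        return sorted(self.cadre_years["cadre_id"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.cadre_years["year"].unique())


@dataclass(frozen=True)
class Violation:
    """One invariant breach, located by a dotted parameter path."""

    path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}: {self.message}"


class ScenarioValidationError(ValueError):
    def __init__(self, violations: list[Violation]):
        self.violations = violations
        lines = "\n".join(f"  - {v}" for v in violations)
        super().__init__(f"scenario failed validation with {len(violations)} violation(s):\n{lines}")


def _check_proportion(value: float, path: str, out: list[Violation], *, name: str = "value") -> None:
    if not (0.0 <= value <= 1.0):
        out.append(Violation(path, f"{name} {value} outside [0, 1]"))


def check_scenario(scenario: Scenario) -> list[Violation]:
    """Collect every invariant violation in a scenario.

    Each distinct defect yields exactly one violation naming the offending
    parameter path; a valid scenario yields an empty list.
    """
    out: list[Violation] = []

    if scenario.base_year > scenario.horizon_end:
        out.append(
            Violation("horizon_end", f"base_year {scenario.base_year} > horizon_end {scenario.horizon_end}")
        )
        years: list[int] = []
    else:
        years = scenario.years

    cadre_ids = {c.cadre_id for c in scenario.cadres}
    indicator_ids = {i.indicator_id for i in scenario.indicators}

    for s in scenario.population:
        path = f"population.{s.key}"
        missing = [y for y in years if y not in s.counts_by_year]
        if missing:
            out.append(Violation(f"{path}.counts_by_year", f"missing years {missing}"))
        negative = sorted(y for y, c in s.counts_by_year.items() if c < 0)
        if negative:
            out.append(Violation(f"{path}.counts_by_year", f"negative counts in years {negative}"))

    for ind in scenario.indicators:
        path = f"indicators.{ind.indicator_id}"
        _check_proportion(ind.baseline_value, f"{path}.baseline_value", out, name="baseline_value")
        direct, twopt = ind.has_direct_rate(), ind.has_two_points()
        if direct == twopt:
            which = "both" if direct else "neither"
            out.append(
                Violation(
                    path,
                    f"{which} of rate_of_change and (second_value, second_year) supplied; exactly one required",
                )
            )
        if twopt:
            _check_proportion(ind.second_value, f"{path}.second_value", out, name="second_value")  # type: ignore[arg-type]
            if ind.second_year == ind.baseline_year:
                out.append(Violation(f"{path}.second_year", "second_year equals baseline_year"))

    for svc in scenario.services:
        path = f"services.{svc.service_id}"
        if svc.indicator_id not in indicator_ids:
            out.append(Violation(f"{path}.indicator_id", f"unknown indicator {svc.indicator_id!r}"))
        if svc.frequency_per_person_in_need < 0:
            out.append(
                Violation(
                    f"{path}.frequency_per_person_in_need",
                    f"negative frequency {svc.frequency_per_person_in_need}",
                )
            )
        standards = (
            svc.service_standard
            if isinstance(svc.service_standard, dict)
            else {"": svc.service_standard}
        )
        for setting, ss in standards.items():
            if ss <= 0:
                sub = f".{setting}" if setting else ""
                out.append(Violation(f"{path}.service_standard{sub}", f"service_standard {ss} <= 0"))
        if isinstance(svc.service_standard, dict):
            if scenario.practice_setting not in svc.service_standard:
                out.append(
                    Violation(
                        f"{path}.service_standard",
                        f"practice_setting {scenario.practice_setting!r} not among "
                        f"settings {sorted(svc.service_standard)}",
                    )
                )
        divisions: list[tuple[str, Mapping[str, float]]] = [(f"{path}.work_division", svc.work_division)]
        divisions += [
            (f"{path}.work_division_overrides.{y}", d) for y, d in sorted(svc.work_division_overrides.items())
        ]
        for dpath, division in divisions:
            total = sum(division.values())
            if abs(total - 1.0) > _REL_TOL:
                out.append(Violation(dpath, f"work_division sums to {total:g} != 1"))
            unknown = sorted(set(division) - cadre_ids)
            if unknown:
                out.append(Violation(dpath, f"unknown cadres {unknown}"))
            bad = sorted(c for c, w in division.items() if not (0.0 <= w <= 1.0))
            if bad:
                out.append(Violation(dpath, f"proportions outside [0, 1] for {bad}"))

    for cadre in scenario.cadres:
        path = f"cadres.{cadre.cadre_id}"
        if cadre.baseline_stock < 0:
            out.append(Violation(f"{path}.baseline_stock", f"negative stock {cadre.baseline_stock}"))
        if not (0.0 <= cadre.attrition_rate < 1.0):
            out.append(Violation(f"{path}.attrition_rate", f"attrition_rate {cadre.attrition_rate} outside [0, 1)"))
        if not (0.0 < cadre.participation_rate <= 1.0):
            out.append(
                Violation(f"{path}.participation_rate", f"participation_rate {cadre.participation_rate} outside (0, 1]")
            )
        if cadre.awt.available_days <= 0:
            out.append(
                Violation(f"{path}.awt", f"available days {cadre.awt.available_days:g} <= 0 after absences")
            )
        if cadre.awt.hours_per_day <= 0:
            out.append(Violation(f"{path}.awt.hours_per_day", f"hours_per_day {cadre.awt.hours_per_day} <= 0"))
        total_sas = cadre.total_sas
        if total_sas >= 1.0:
            out.append(
                Violation(f"{path}.support_activities", f"Σ SAS = {total_sas:g} >= 1")
            )
        for act in cadre.support_activities:
            if not (0.0 <= act.sas < 1.0):
                out.append(
                    Violation(f"{path}.support_activities.{act.name}.sas", f"sas {act.sas} outside [0, 1)")
                )
        pipe, ppath = cadre.pipeline, f"{path}.pipeline"
        if not (0.0 <= pipe.dropout_rate <= 1.0):
            out.append(Violation(f"{ppath}.dropout_rate", f"dropout_rate {pipe.dropout_rate} outside [0, 1]"))
        if not (0.0 < pipe.pass_rate <= 1.0):
            out.append(Violation(f"{ppath}.pass_rate", f"pass_rate {pipe.pass_rate} outside (0, 1]"))
        if pipe.training_duration < 0:
            out.append(Violation(f"{ppath}.training_duration", f"negative duration {pipe.training_duration}"))
        for label, series in (("enrolment_by_year", pipe.enrolment_by_year), ("immigration_by_year", pipe.immigration_by_year)):
            negative = sorted(y for y, c in series.items() if c < 0)
            if negative:
                out.append(Violation(f"{ppath}.{label}", f"negative counts in years {negative}"))
        if cadre.baseline_income < 0:
            out.append(Violation(f"{path}.baseline_income", f"negative income {cadre.baseline_income}"))

    return out


def validate_scenario(raw: Union[Scenario, Mapping]) -> Scenario:
    """Parse (if needed) and validate a scenario; raise on any violation.

    Validation is idempotent: a valid ``Scenario`` passes through unchanged.
    """
    scenario = raw if isinstance(raw, Scenario) else Scenario.model_validate(raw)
    violations = check_scenario(scenario)
    if violations:
        raise ScenarioValidationError(violations)
    return scenario
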