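"""Bundled fixtures: the Ghana printed-series data, a seeded synthetic
scenario generator, and a hand-derivable known-answer scenario.

The Ghana maternal and new-born care application published its full annual
output series (needs-based requirements and anticipated supply for midwives
and obstetrician/gynaecologists, 2020-2030, plus wage bills and support
allowance standards) but not its raw inputs, which live in an unpublished
workbook.  :func:`ghana_printed_fixture` therefore exposes the printed
OUTPUT series digit-for-digit, to be used as fixed inputs to the gap, SAR,
growth and cost operations.  The needs and supply engines themselves are
exercised against synthetic scenarios whose full results are derivable by
independent arithmetic (:func:`known_answer_scenario`) or brute force
(:func:`generate_synthetic_scenario`).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .scenario_model import (
    AwtComponents,
    CadreProfile,
    EducationPipeline,
    HealthIndicator,
    PopulationStratum,
    ProjectionResult,
    Scenario,
    ServiceNorm,
    StratumSelector,
    SupportActivity,
    validate_scenario,
)

__all__ = [
    "PrintedSeriesFixture",
    "ghana_printed_fixture",
    "SyntheticSpec",
    "generate_synthetic_scenario",
    "known_answer_scenario",
]

MIDWIFE = "midwife"
OBGYN = "obstetrician_gynaecologist"


@dataclass(frozen=True)
class PrintedSeriesFixture:
    """The published Ghana output series, digit-for-digit.

    ``need`` and ``supply`` are {cadre: {year: persons}} over 2020-2030;
    ``cost_of_need``/``cost_of_supply`` are US$ wage bills at 2020/2025/2030;
    ``cost_totals`` the printed both-cadre totals; ``support_activities``
    the support-allowance standards (fractions of available working time);
    ``printed_adjustment_pct`` the published percentage upward adjustment
    for support activities per cadre.
    """

    need: dict[str, dict[int, int]]
    supply: dict[str, dict[int, int]]
    cost_of_need: dict[str, dict[int, float]]
    cost_of_supply: dict[str, dict[int, float]]
    cost_totals: dict[int, dict[str, float]]
    support_activities: dict[str, list[SupportActivity]]
    printed_adjustment_pct: dict[str, float]

    @property
    def cadre_ids(self) -> list[str]:
        return sorted(self.need)

    @property
    def years(self) -> list[int]:
        return sorted(next(iter(self.need.values())))


def _data_rows(name: str) -> list[dict[str, str]]:
    text = (resources.files("hwfplan") / "data" / "ghana_printed" / name).read_text()
    return list(csv.DictReader(text.splitlines()))


def ghana_printed_fixture() -> PrintedSeriesFixture:
    """Load the published Ghana maternal/new-born care series."""
    need: dict[str, dict[int, int]] = {}
    for row in _data_rows("requirements.csv"):
        need.setdefault(row["cadre_id"], {})[int(row["year"])] = int(row["need"])
    supply: dict[str, dict[int, int]] = {}
    for row in _data_rows("supply.csv"):
        supply.setdefault(row["cadre_id"], {})[int(row["year"])] = int(row["supply"])
    cost_of_need: dict[str, dict[int, float]] = {}
    cost_of_supply: dict[str, dict[int, float]] = {}
    for row in _data_rows("wage_bill.csv"):
        year = int(row["year"])
        cost_of_need.setdefault(row["cadre_id"], {})[year] = float(row["cost_of_need"])
        cost_of_supply.setdefault(row["cadre_id"], {})[year] = float(row["cost_of_supply"])
    cost_totals = {
        int(row["year"]): {
            "need": float(row["cost_of_need_total"]),
            "supply": float(row["cost_of_supply_total"]),
        }
        for row in _data_rows("wage_bill_totals.csv")
    }
    support: dict[str, list[SupportActivity]] = {}
    for row in _data_rows("support_activities.csv"):
        support.setdefault(row["cadre_id"], []).append(
            SupportActivity(name=row["activity"], sas=float(row["sas"]))
        )
    return PrintedSeriesFixture(
        need=need,
        supply=supply,
        cost_of_need=cost_of_need,
        cost_of_supply=cost_of_supply,
        cost_totals=cost_totals,
        support_activities=support,
        printed_adjustment_pct={MIDWIFE: 21.2, OBGYN: 17.6},
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Sampling ranges for the synthetic-scenario generator.

    Defaults mirror the published application's shape: an 11-year horizon,
    two cadres sharing maternal-care-like services, a population stratified
    by age cohort, gender and rural/urban location, indicator trends of a
    few percent a year, WISN-style activity standards under an hour, and
    modest support allowances.  All sampled parameters satisfy the scenario
    invariants by construction.
    """

    seed: int = 0
    base_year: int = 2020
    horizon_years: int = 10
    n_age_cohorts: int = 5
    n_locations: int = 2
    n_services: int = 6
    n_cadres: int = 2
    population_range: tuple[float, float] = (10_000.0, 500_000.0)
    population_growth_range: tuple[float, float] = (0.0, 0.03)
    h_baseline_range: tuple[float, float] = (0.05, 0.9)
    rh_range: tuple[float, float] = (-0.02, 0.03)
    frequency_range: tuple[float, float] = (0.5, 6.0)
    ss_range: tuple[float, float] = (0.1, 2.0)
    sas_range: tuple[float, float] = (0.02, 0.12)
    max_support_activities: int = 2
    attrition_range: tuple[float, float] = (0.02, 0.08)
    participation_range: tuple[float, float] = (0.85, 1.0)
    dropout_range: tuple[float, float] = (0.0, 0.2)
    pass_rate_range: tuple[float, float] = (0.7, 1.0)
    max_training_duration: int = 4
    stock_range: tuple[float, float] = (100.0, 20_000.0)
    enrolment_fraction_range: tuple[float, float] = (0.02, 0.10)
    income_range: tuple[float, float] = (8_000.0, 30_000.0)
    inflation_range: tuple[float, float] = (0.0, 0.08)


def _check_range(name: str, rng: tuple[float, float]) -> None:
    if rng[0] > rng[1]:
        raise ValueError(f"infeasible range for {name}: {rng}")


def generate_synthetic_scenario(spec: SyntheticSpec = SyntheticSpec()) -> Scenario:
    """Draw a fully specified, valid scenario from the spec's ranges.

    Deterministic under ``spec.seed``.  Always exercises at least two
    stratification dimensions (age cohorts x genders, plus locations when
    ``n_locations`` > 1) and at least one multi-cadre work division when
    ``n_cadres`` > 1.
    """
    for name in (
        "population_range",
        "population_growth_range",
        "h_baseline_range",
        "rh_range",
        "frequency_range",
        "ss_range",
        "sas_range",
        "attrition_range",
        "participation_range",
        "dropout_range",
        "pass_rate_range",
        "stock_range",
        "enrolment_fraction_range",
        "income_range",
        "inflation_range",
    ):
        _check_range(name, getattr(spec, name))
    if spec.n_cadres < 1 or spec.n_services < 1 or spec.n_age_cohorts < 1 or spec.n_locations < 1:
        raise ValueError("scenario dimensions must all be >= 1")

    rng = np.random.default_rng(spec.seed)
    base_year = spec.base_year
    horizon_end = base_year + spec.horizon_years
    years = list(range(base_year, horizon_end + 1))

    cohorts = [f"{10 * k + 5}-{10 * k + 14}" for k in range(spec.n_age_cohorts)]
    genders = ["female", "male"]
    locations = ["rural", "urban"][: spec.n_locations] if spec.n_locations <= 2 else [
        f"loc{k}" for k in range(spec.n_locations)
    ]

    population = []
    for cohort in cohorts:
        for gender in genders:
            for location in locations:
                base = float(rng.uniform(*spec.population_range))
                growth = float(rng.uniform(*spec.population_growth_range))
                counts = {y: base * (1.0 + growth) ** (y - base_year) for y in years}
                population.append(
                    PopulationStratum(
                        age_cohort=cohort, gender=gender, location=location, counts_by_year=counts
                    )
                )

    cadre_ids = [f"cadre_{k}" for k in range(spec.n_cadres)]

    indicators = []
    services = []
    for s in range(spec.n_services):
        indicator_id = f"indicator_{s}"
        # selectors restrict age cohorts and (for odd services) gender, so
        # joins across at least two strata dimensions are always exercised
        n_sel = int(rng.integers(1, spec.n_age_cohorts + 1))
        sel_cohorts = sorted(rng.choice(cohorts, size=n_sel, replace=False).tolist())
        sel_genders = ["female"] if s % 2 == 1 else None
        baseline = float(rng.uniform(*spec.h_baseline_range))
        rate = float(rng.uniform(*spec.rh_range))
        indicators.append(
            HealthIndicator(
                indicator_id=indicator_id,
                stratum_selector=StratumSelector(age_cohorts=sel_cohorts, genders=sel_genders),
                baseline_value=baseline,
                baseline_year=base_year,
                rate_of_change=rate,
            )
        )
        if spec.n_cadres > 1 and s % 2 == 0:
            share = float(rng.uniform(0.1, 0.9))
            division = {cadre_ids[0]: share, cadre_ids[1]: 1.0 - share}
        else:
            division = {cadre_ids[int(rng.integers(0, spec.n_cadres))]: 1.0}
        ss_primary = float(rng.uniform(*spec.ss_range))
        services.append(
            ServiceNorm(
                service_id=f"service_{s}",
                indicator_id=indicator_id,
                frequency_per_person_in_need=float(rng.uniform(*spec.frequency_range)),
                service_standard={"primary": ss_primary, "tertiary": ss_primary * float(rng.uniform(1.0, 2.0))},
                work_division=division,
            )
        )

    cadres = []
    for cadre_id in cadre_ids:
        stock = float(rng.uniform(*spec.stock_range))
        duration = int(rng.integers(0, spec.max_training_duration + 1))
        enrol_frac = float(rng.uniform(*spec.enrolment_fraction_range))
        enrolment = {
            y: stock * enrol_frac * float(rng.uniform(0.8, 1.2))
            for y in range(base_year - duration, horizon_end - duration + 1)
        }
        immigration = {y: stock * 0.002 * float(rng.uniform(0.0, 1.0)) for y in years}
        n_support = int(rng.integers(0, spec.max_support_activities + 1))
        supports = [
            SupportActivity(name=f"support_{k}", sas=float(rng.uniform(*spec.sas_range)))
            for k in range(n_support)
        ]
        cadres.append(
            CadreProfile(
                cadre_id=cadre_id,
                baseline_stock=stock,
                attrition_rate=float(rng.uniform(*spec.attrition_range)),
                participation_rate=float(rng.uniform(*spec.participation_range)),
                awt=AwtComponents(
                    possible_working_days=260,
                    public_holidays=float(rng.integers(5, 12)),
                    annual_leave=float(rng.integers(15, 30)),
                    sick_leave=float(rng.integers(0, 10)),
                    other_absences=float(rng.integers(0, 8)),
                    hours_per_day=8.0,
                ),
                support_activities=supports,
                pipeline=EducationPipeline(
                    enrolment_by_year=enrolment,
                    dropout_rate=float(rng.uniform(*spec.dropout_range)),
                    training_duration=duration,
                    pass_rate=float(rng.uniform(*spec.pass_rate_range)),
                    immigration_by_year=immigration,
                ),
                baseline_income=float(rng.uniform(*spec.income_range)),
                income_inflation=float(rng.uniform(*spec.inflation_range)),
            )
        )

    scenario = Scenario(
        name=f"synthetic-{spec.seed}",
        base_year=base_year,
        horizon_end=horizon_end,
        population=population,
        indicators=indicators,
        services=services,
        cadres=cadres,
        practice_setting="primary",
    )
    return validate_scenario(scenario)


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def known_answer_scenario() -> tuple[Scenario, ProjectionResult]:
    """A tiny scenario whose full projection is derivable by hand.

    Three years (2020-2022), two population strata, two services, one
    cadre.  The expected result returned alongside is computed here by
    straight-line arithmetic — explicit per-year, per-stratum loops with no
    engine involvement — so it can serve as an independent oracle.
    """
    years = [2020, 2021, 2022]
    strata = [
        PopulationStratum(
            age_cohort="15-49",
            gender="female",
            location="all",
            counts_by_year={2020: 1000.0, 2021: 1100.0, 2022: 1210.0},
        ),
        PopulationStratum(
            age_cohort="50+",
            gender="female",
            location="all",
            counts_by_year={2020: 500.0, 2021: 500.0, 2022: 500.0},
        ),
    ]
    indicators = [
        HealthIndicator(
            indicator_id="ind_a",
            stratum_selector=StratumSelector(age_cohorts=["15-49"]),
            baseline_value=0.2,
            baseline_year=2020,
            rate_of_change=0.05,
        ),
        HealthIndicator(
            indicator_id="ind_b",
            stratum_selector=StratumSelector(age_cohorts=["50+"]),
            baseline_value=0.3,
            baseline_year=2010,
            second_value=0.36,
            second_year=2015,
        ),
    ]
    services = [
        ServiceNorm(
            service_id="svc_a",
            indicator_id="ind_a",
            frequency_per_person_in_need=4.0,
            service_standard=0.5,
            work_division={"c1": 1.0},
        ),
        ServiceNorm(
            service_id="svc_b",
            indicator_id="ind_b",
            frequency_per_person_in_need=2.0,
            service_standard=1.0,
            work_division={"c1": 1.0},
        ),
    ]
    cadre = CadreProfile(
        cadre_id="c1",
        baseline_stock=100.0,
        attrition_rate=0.1,
        participation_rate=0.9,
        awt=AwtComponents(
            possible_working_days=260,
            public_holidays=9,
            annual_leave=21,
            sick_leave=5,
            other_absences=4,
            hours_per_day=8,
        ),
        support_activities=[
            SupportActivity(name="handover", sas=0.1),
            SupportActivity(name="meetings", sas=0.075),
        ],
        pipeline=EducationPipeline(
            enrolment_by_year={2019: 10.0, 2020: 10.0, 2021: 10.0},
            dropout_rate=0.1,
            training_duration=1,
            pass_rate=0.8,
            immigration_by_year={2021: 2.0},
        ),
        baseline_income=10_000.0,
        income_inflation=0.05,
    )
    scenario = validate_scenario(
        Scenario(
            name="known-answer",
            base_year=2020,
            horizon_end=2022,
            population=strata,
            indicators=indicators,
            services=services,
            cadres=[cadre],
        )
    )

    # --- independent straight-line arithmetic (no engine calls) ---------
    pop_a = {2020: 1000.0, 2021: 1100.0, 2022: 1210.0}
    pop_b = {2020: 500.0, 2021: 500.0, 2022: 500.0}

    h_a = {2020: 0.2, 2021: 0.2 * 1.05, 2022: 0.2 * 1.05 * 1.05}
    rate_b = (0.36 / 0.3) ** (1.0 / 5.0) - 1.0  # two survey waves, 2010 and 2015
    h_b = {}
    level = 0.3
    for year in range(2010, 2023):
        if year > 2010:
            level = min(1.0, level * (1.0 + rate_b))
        if year in years:
            h_b[year] = level

    vol_a = {y: pop_a[y] * h_a[y] * 4.0 for y in years}
    vol_b = {y: pop_b[y] * h_b[y] * 2.0 for y in years}

    awt = (260 - 9 - 21 - 5 - 4) * 8.0  # 1768 hours
    sw_a = awt / 0.5
    sw_b = awt / 1.0
    saaf = 1.0 / (1.0 - (0.1 + 0.075))
    need = {y: (vol_a[y] / sw_a + vol_b[y] / sw_b) * saaf for y in years}

    inflow = {2021: (10.0 * 0.9 + 2.0) * 0.8, 2022: (10.0 * 0.9) * 0.8}
    stock = {2020: 100.0}
    stock[2021] = stock[2020] * 0.9 + inflow[2021]
    stock[2022] = stock[2021] * 0.9 + inflow[2022]
    supply = {y: stock[y] * 0.9 for y in years}

    income = {y: 10_000.0 * 1.05 ** (y - 2020) for y in years}

    rows = []
    for y in years:
        need_r = _round_half_up(need[y])
        supply_r = _round_half_up(supply[y])
        rows.append(
            {
                "cadre_id": "c1",
                "year": y,
                "need_fte": need[y],
                "need_rounded": need_r,
                "supply": supply[y],
                "supply_rounded": supply_r,
                "absolute_gap": supply_r - need_r,
                "sar": supply_r / need_r,
                "income": income[y],
                "cost_of_need": need_r * income[y],
                "cost_of_supply": supply[y] * income[y],
            }
        )
    svc_rows = [
        {"service_id": sid, "year": y, "volume": vols[y]}
        for sid, vols in (("svc_a", vol_a), ("svc_b", vol_b))
        for y in years
    ]
    expected = ProjectionResult(
        scenario_name="known-answer",
        cadre_years=pd.DataFrame(rows),
        service_volumes=pd.DataFrame(svc_rows),
    )
    return scenario, expected
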