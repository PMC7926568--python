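"""Gap, staff-availability-ratio and wage-bill analysis.

Integrates need and supply series per cadre and year:

* absolute gap = supply - need (negative = shortage, the number "needed to
  be trained"; positive = needs-based oversupply);
* staff availability ratio SAR = supply / need (1 = equilibrium);
* wage bill = headcount x average income, with income compounding at an
  annual inflation rate.

Gaps and SAR are computed on headcounts rounded half-up to whole persons
(you employ whole people); SAR is conventionally reported to 0.1 %.  The
cost of meeting need uses the rounded need, while the cost of the
anticipated supply follows the un-rounded supply path; both conventions are
overridable by passing pre-rounded series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "round_half_up",
    "absolute_gap",
    "staff_availability_ratio",
    "project_income",
    "income_series",
    "cost_series",
    "aggregate_costs",
    "GrowthSummary",
    "summarize_growth",
    "GapRecord",
    "gap_series",
]


def round_half_up(x: float) -> int:
    """Round to the nearest whole person, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def absolute_gap(supply: float, need: float) -> float:
    """Supply minus need; negative values are needs-based shortages."""
    if supply < 0 or need < 0:
        raise ValueError("supply and need must be non-negative")
    return supply - need


def staff_availability_ratio(supply: float, need: float) -> float:
    """Share of the needs-based requirement met by the supply: supply / need."""
    if need <= 0:
        raise ValueError(f"SAR undefined for need {need}; need must be positive")
    if supply < 0:
        raise ValueError("supply must be non-negative")
    return supply / need


def project_income(baseline_income: float, inflation: float, years_elapsed: int) -> float:
    """Average annual income after compounding inflation for a number of years."""
    if years_elapsed < 0:
        raise ValueError("years_elapsed must be >= 0")
    return baseline_income * (1.0 + inflation) ** years_elapsed


def income_series(baseline_income: float, inflation: float, years: list[int]) -> dict[int, float]:
    base = min(years)
    return {y: project_income(baseline_income, inflation, y - base) for y in years}


def cost_series(
    headcount_by_year: Mapping[int, float], income_by_year: Mapping[int, float]
) -> dict[int, float]:
    """Annual wage bill: headcount x average income, year by year."""
    if set(headcount_by_year) != set(income_by_year):
        raise ValueError(
            f"year ranges differ: headcount {sorted(headcount_by_year)} vs income {sorted(income_by_year)}"
        )
    return {y: headcount_by_year[y] * income_by_year[y] for y in sorted(headcount_by_year)}


def aggregate_costs(*series: Mapping[int, float]) -> dict[int, float]:
    """Sum cost series across cadres; all series must cover the same years."""
    if not series:
        return {}
    years = set(series[0])
    for s in series[1:]:
        if set(s) != years:
            raise ValueError("cost series cover different year ranges")
    return {y: sum(s[y] for s in series) for y in sorted(years)}


@dataclass(frozen=True)
class GrowthSummary:
    """Year-on-year percentage changes plus compound annual growth rate.

    All figures are percentages (3.5 means 3.5 %).  ``total_pct`` is the
    cumulative change from the first to the last year.
    """

    annual_pct: dict[int, float]
    cagr_pct: float
    total_pct: float


def summarize_growth(series_by_year: Mapping[int, float]) -> GrowthSummary:
    """Growth profile of a positive annual series.

    CAGR solves ``first (1+g)^n = last`` with ``n`` the number of elapsed
    years between the first and last observation.
    """
    years = sorted(series_by_year)
    if len(years) < 2:
        raise ValueError("growth summary needs at least two years")
    if any(series_by_year[y] <= 0 for y in years):
        raise ValueError("growth summary requires strictly positive values")
    annual = {
        y1: (series_by_year[y1] / series_by_year[y0] - 1.0) * 100.0
        for y0, y1 in zip(years, years[1:])
    }
    first, last = series_by_year[years[0]], series_by_year[years[-1]]
    span = years[-1] - years[0]
    cagr = (last / first) ** (1.0 / span) - 1.0
    total = last / first - 1.0
    return GrowthSummary(annual_pct=annual, cagr_pct=cagr * 100.0, total_pct=total * 100.0)


@dataclass(frozen=True)
class GapRecord:
    cadre_id: str
    year: int
    need_rounded: int
    supply_rounded: int
    absolute_gap: int
    sar: float


def gap_series(
    cadre_id: str,
    need_by_year: Mapping[int, float],
    supply_by_year: Mapping[int, float],
) -> list[GapRecord]:
    """Gap and SAR per year on half-up-rounded headcounts."""
    if set(need_by_year) != set(supply_by_year):
        raise ValueError("need and supply series cover different year ranges")
    records = []
    for year in sorted(need_by_year):
        need_r = round_half_up(need_by_year[year])
        supply_r = round_half_up(supply_by_year[year])
        records.append(
            GapRecord(
                cadre_id=cadre_id,
                year=year,
                need_rounded=need_r,
                supply_rounded=supply_r,
                absolute_gap=supply_r - need_r,
                sar=staff_availability_ratio(supply_r, need_r),
            )
        )
    return records
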