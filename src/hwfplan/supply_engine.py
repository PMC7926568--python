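"""Stock-and-flow supply projection.

The registered stock of a cadre evolves by the annual recursion

    T_t = T_{t-1} x (1 - a) + I_t

where ``a`` is the attrition rate (deaths, retirement, ill health,
out-migration as a share of the previous stock) and ``I_t`` is the inflow of
newly licensed professionals.  Inflows enter after attrition is applied to
the previous stock: new graduates are not attrited in their entry year.
The effective (practising) supply applies the labour-participation rate:
``S_t = T_t x P``.

The inflow combines the education pipeline and immigration: the enrolment
cohort of year ``t - training_duration`` is reduced by the dropout rate,
immigrants are added, and the sum is adjusted by the licensure pass rate.
Headcounts stay real-valued through the recursion; rounding happens only at
reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .scenario_model import CadreProfile, EducationPipeline

__all__ = [
    "SupplySeries",
    "compute_attrition_rate",
    "compute_pipeline_inflow",
    "project_supply",
]

logger = logging.getLogger(__name__)


@dataclass
class SupplySeries:
    """Registered stock and effective (practising) supply per year."""

    cadre_id: str
    registered_stock_by_year: dict[int, float]
    effective_supply_by_year: dict[int, float]


def compute_attrition_rate(exits: float, opening_stock: float) -> float:
    """Attrition rate over a period: exits as a share of the opening stock."""
    if opening_stock <= 0:
        raise ValueError(f"opening stock must be positive; got {opening_stock}")
    if exits < 0:
        raise ValueError(f"exits must be non-negative; got {exits}")
    if exits > opening_stock:
        raise ValueError(f"exits ({exits}) exceed the opening stock ({opening_stock})")
    return exits / opening_stock


def compute_pipeline_inflow(pipeline: EducationPipeline, year: int) -> float:
    """New licensed entrants in a year from training and immigration.

    Domestic graduates are the enrolment cohort ``training_duration`` years
    earlier, net of dropout; if that cohort was never recorded the domestic
    term is zero (with a logged warning).  Immigrants join graduates before
    the licensure pass-rate adjustment.
    """
    cohort_year = year - pipeline.training_duration
    enrolment = pipeline.enrolment_by_year.get(cohort_year)
    if enrolment is None:
        logger.warning(
            "no enrolment recorded for cohort year %d (entry year %d); domestic inflow taken as 0",
            cohort_year,
            year,
        )
        enrolment = 0.0
    graduates = enrolment * (1.0 - pipeline.dropout_rate)
    immigration = pipeline.immigration_by_year.get(year, 0.0)
    return (graduates + immigration) * pipeline.pass_rate


def project_supply(cadre: CadreProfile, years: Iterable[int]) -> SupplySeries:
    """Project registered stock and effective supply over consecutive years.

    The first requested year is the baseline: the registered stock equals
    ``baseline_stock`` and no attrition or inflow is applied to it.
    """
    years = sorted(years)
    if not years:
        raise ValueError("no projection years supplied")
    if years != list(range(years[0], years[-1] + 1)):
        raise ValueError("projection years must be consecutive")
    registered: dict[int, float] = {}
    effective: dict[int, float] = {}
    stock = float(cadre.baseline_stock)
    for year in years:
        if year > years[0]:
            inflow = compute_pipeline_inflow(cadre.pipeline, year)
            stock = stock * (1.0 - cadre.attrition_rate) + inflow
        stock = max(stock, 0.0)
        registered[year] = stock
        effective[year] = stock * cadre.participation_rate
    return SupplySeries(
        cadre_id=cadre.cadre_id,
        registered_stock_by_year=registered,
        effective_supply_by_year=effective,
    )
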