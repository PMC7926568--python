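"""Needs-based requirement engine.

Turns population demography, health-status levels and service norms into an
evidence-based service requirement, then into workforce requirements:

* the needed volume of a service in year t is the sum over matching
  population strata of ``P x H_t x L`` — stratum size, proportion in need,
  and planned per-person service frequency;
* the proportion in need evolves by annual compounding,
  ``H_t = H_{t-1} (1 + R_h)``, clamped to [0, 1], where R_h is the annual
  rate of change of the indicator (supplied or estimated from two survey
  waves);
* a cadre's direct-care requirement divides each service volume, after the
  work-division split, by the cadre's standard workload SW = AWT / SS
  (annual available hours over hours per service);
* the support-activities adjustment factor SAAF = 1 / (1 - ΣSAS) inflates
  the direct-care requirement to cover indirect (non-countable) work.

All quantities are deterministic and real-valued; rounding to whole persons
happens only at the gap/reporting stage.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Optional

from .scenario_model import (
    AwtComponents,
    HealthIndicator,
    Scenario,
    ServiceNorm,
    SupportActivity,
)

__all__ = [
    "estimate_rate_of_change",
    "resolve_rate_of_change",
    "project_health_status",
    "project_indicators",
    "compute_service_need",
    "compute_service_volumes",
    "compute_awt",
    "compute_standard_workload",
    "compute_saaf",
    "compute_workforce_requirement",
]

logger = logging.getLogger(__name__)

RATE_METHODS = ("geometric", "continuous")


def estimate_rate_of_change(
    value_1: float,
    year_1: int,
    value_2: float,
    year_2: int,
    method: str = "geometric",
) -> float:
    """Annual rate of change of an indicator observed at two time points.

    ``geometric`` solves ``value_1 (1+r)^(year_2-year_1) = value_2`` — the
    convention matching how the rate is applied (discrete annual
    compounding).  ``continuous`` returns ``ln(value_2/value_1) / Δt``, the
    instantaneous-rate convention.  The sign reflects the direction of
    change.
    """
    if method not in RATE_METHODS:
        raise ValueError(f"method must be one of {RATE_METHODS}, got {method!r}")
    if year_2 == year_1:
        raise ValueError("cannot estimate a rate from two observations in the same year")
    if value_1 <= 0.0:
        raise ValueError(
            f"rate of change undefined for a baseline value of {value_1} (must be > 0)"
        )
    if value_2 < 0.0:
        raise ValueError(f"second value {value_2} is negative")
    span = year_2 - year_1
    ratio = value_2 / value_1
    if method == "geometric":
        return ratio ** (1.0 / span) - 1.0
    return math.log(ratio) / span


def resolve_rate_of_change(indicator: HealthIndicator, method: str = "geometric") -> float:
    """The indicator's annual rate: given directly, or estimated from two waves."""
    if indicator.has_direct_rate():
        return float(indicator.rate_of_change)  # type: ignore[arg-type]
    if indicator.has_two_points():
        return estimate_rate_of_change(
            indicator.baseline_value,
            indicator.baseline_year,
            indicator.second_value,  # type: ignore[arg-type]
            indicator.second_year,  # type: ignore[arg-type]
            method=method,
        )
    raise ValueError(
        f"indicator {indicator.indicator_id!r} has neither a direct rate nor a second observation"
    )


def project_health_status(
    indicator: HealthIndicator,
    years: Iterable[int],
    apply_rate: bool = True,
    method: str = "geometric",
) -> dict[int, float]:
    """Project the proportion in need for each requested year.

    Starting from the baseline value at the baseline year, the level
    compounds annually at the indicator's rate of change and is clamped to
    [0, 1].  With ``apply_rate`` false the baseline level is held constant
    over the whole horizon (the static-health convention of earlier
    needs-based models).
    """
    years = sorted(years)
    if not years:
        return {}
    if apply_rate:
        rate = resolve_rate_of_change(indicator, method=method)
    else:
        rate = 0.0
    first, last = years[0], years[-1]
    if first < indicator.baseline_year:
        raise ValueError(
            f"cannot project indicator {indicator.indicator_id!r} before its "
            f"baseline year {indicator.baseline_year}"
        )
    level = indicator.baseline_value
    out: dict[int, float] = {}
    wanted = set(years)
    for year in range(indicator.baseline_year, last + 1):
        if year > indicator.baseline_year:
            level = min(1.0, max(0.0, level * (1.0 + rate)))
        if year in wanted:
            out[year] = level
    return out


def project_indicators(scenario: Scenario, method: str = "geometric") -> dict[str, dict[int, float]]:
    """Projected level by year for every indicator in the scenario."""
    apply_rate = scenario.flags.apply_rate_of_change
    if not apply_rate:
        logger.info("rate-of-change application disabled: health status held at baseline levels")
    return {
        ind.indicator_id: project_health_status(ind, scenario.years, apply_rate=apply_rate, method=method)
        for ind in scenario.indicators
    }


def compute_service_need(
    scenario: Scenario,
    service: ServiceNorm,
    year: int,
    indicator_levels: Optional[Mapping[str, Mapping[int, float]]] = None,
    method: str = "geometric",
) -> float:
    """Needed annual volume of one service: Σ over strata of P x H_t x L."""
    indicator = scenario.get_indicator(service.indicator_id)
    if indicator_levels is not None:
        level = indicator_levels[service.indicator_id][year]
    else:
        level = project_health_status(
            indicator, [year], apply_rate=scenario.flags.apply_rate_of_change, method=method
        )[year]
    strata = scenario.strata_for(indicator.stratum_selector)
    total_population = sum(s.counts_by_year[year] for s in strata)
    return total_population * level * service.frequency_per_person_in_need


def compute_service_volumes(
    scenario: Scenario, method: str = "geometric"
) -> dict[str, dict[int, float]]:
    """Needed volumes for every service and horizon year."""
    levels = project_indicators(scenario, method=method)
    return {
        svc.service_id: {
            year: compute_service_need(scenario, svc, year, indicator_levels=levels)
            for year in scenario.years
        }
        for svc in scenario.services
    }


def compute_awt(components: AwtComponents) -> float:
    """Available working time in hours/year: available days x hours/day."""
    days = components.available_days
    if days <= 0:
        raise ValueError(
            f"available working days must be positive; got {days:g} after subtracting absences"
        )
    if components.hours_per_day <= 0:
        raise ValueError(f"hours_per_day must be positive; got {components.hours_per_day}")
    return days * components.hours_per_day


def compute_standard_workload(awt: float, service_standard: float) -> float:
    """Annual service units one professional could deliver: AWT / SS."""
    if awt <= 0:
        raise ValueError(f"available working time must be positive; got {awt}")
    if service_standard <= 0:
        raise ValueError(f"service standard must be positive; got {service_standard}")
    return awt / service_standard


def compute_saaf(support_activities: Iterable[SupportActivity]) -> float:
    """Support-activities adjustment factor 1 / (1 - ΣSAS); 1.0 with no support time."""
    total = sum(a.sas for a in support_activities)
    if total >= 1.0:
        raise ValueError(f"support allowance standards sum to {total:g} >= 1")
    if total < 0.0:
        raise ValueError(f"support allowance standards sum to {total:g} < 0")
    return 1.0 / (1.0 - total)


def compute_workforce_requirement(
    scenario: Scenario,
    cadre_id: str,
    year: int,
    service_volumes: Optional[Mapping[str, Mapping[int, float]]] = None,
    method: str = "geometric",
) -> float:
    """Needs-based FTE requirement for one cadre in one year.

    Sums, over the services the cadre shares in, the cadre's slice of the
    needed volume divided by its standard workload for that service, then
    applies the SAAF when the scenario's support adjustment is enabled.
    """
    cadre = scenario.get_cadre(cadre_id)
    services = scenario.services_for_cadre(cadre_id)
    if not services:
        logger.warning("cadre %r participates in no service work division; requirement is 0", cadre_id)
        return 0.0
    if service_volumes is None:
        service_volumes = compute_service_volumes(scenario, method=method)
    awt = compute_awt(cadre.awt)
    direct = 0.0
    for svc in services:
        share = svc.division_for(year).get(cadre_id, 0.0)
        if share == 0.0:
            continue
        volume = service_volumes[svc.service_id][year]
        workload = compute_standard_workload(awt, svc.standard_for(scenario.practice_setting))
        direct += volume * share / workload
    if scenario.flags.apply_support_adjustment:
        return direct * compute_saaf(cadre.support_activities)
    return direct
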