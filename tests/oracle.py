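"""Independent brute-force oracles.

Straight per-stratum / per-service / per-year Python loops, written without
reference to the package's engine code paths, used to cross-check the
engines on arbitrary scenarios.
"""

from __future__ import annotations


def oracle_indicator_levels(scenario, method: str = "geometric") -> dict[str, dict[int, float]]:
    levels: dict[str, dict[int, float]] = {}
    for ind in scenario.indicators:
        if not scenario.flags.apply_rate_of_change:
            rate = 0.0
        elif ind.rate_of_change is not None:
            rate = ind.rate_of_change
        else:
            span = ind.second_year - ind.baseline_year
            ratio = ind.second_value / ind.baseline_value
            if method == "geometric":
                rate = ratio ** (1.0 / span) - 1.0
            else:
                import math

                rate = math.log(ratio) / span
        series: dict[int, float] = {}
        level = ind.baseline_value
        for year in range(ind.baseline_year, scenario.horizon_end + 1):
            if year > ind.baseline_year:
                level = level * (1.0 + rate)
                if level > 1.0:
                    level = 1.0
                if level < 0.0:
                    level = 0.0
            if scenario.base_year <= year:
                series[year] = level
        levels[ind.indicator_id] = series
    return levels


def oracle_service_volumes(scenario, method: str = "geometric") -> dict[str, dict[int, float]]:
    levels = oracle_indicator_levels(scenario, method)
    volumes: dict[str, dict[int, float]] = {}
    for svc in scenario.services:
        ind = next(i for i in scenario.indicators if i.indicator_id == svc.indicator_id)
        sel = ind.stratum_selector
        by_year: dict[int, float] = {}
        for year in range(scenario.base_year, scenario.horizon_end + 1):
            total = 0.0
            for stratum in scenario.population:
                if sel.age_cohorts is not None and stratum.age_cohort not in sel.age_cohorts:
                    continue
                if sel.genders is not None and stratum.gender not in sel.genders:
                    continue
                if sel.locations is not None and stratum.location not in sel.locations:
                    continue
                total += (
                    stratum.counts_by_year[year]
                    * levels[svc.indicator_id][year]
                    * svc.frequency_per_person_in_need
                )
            by_year[year] = total
        volumes[svc.service_id] = by_year
    return volumes


def oracle_need(scenario, method: str = "geometric") -> dict[str, dict[int, float]]:
    """Per-cadre needs-based FTE by year via explicit loops."""
    volumes = oracle_service_volumes(scenario, method)
    out: dict[str, dict[int, float]] = {}
    for cadre in scenario.cadres:
        awt_days = cadre.awt.possible_working_days - (
            cadre.awt.public_holidays
            + cadre.awt.annual_leave
            + cadre.awt.sick_leave
            + cadre.awt.other_absences
        )
        awt = awt_days * cadre.awt.hours_per_day
        saaf = 1.0 / (1.0 - sum(a.sas for a in cadre.support_activities))
        by_year: dict[int, float] = {}
        for year in range(scenario.base_year, scenario.horizon_end + 1):
            total = 0.0
            for svc in scenario.services:
                division = svc.work_division_overrides.get(year, svc.work_division)
                share = division.get(cadre.cadre_id, 0.0)
                if share == 0.0:
                    continue
                ss = svc.service_standard
                if isinstance(ss, dict):
                    ss = ss[scenario.practice_setting]
                workload = awt / ss
                total += volumes[svc.service_id][year] * share / workload
            if scenario.flags.apply_support_adjustment:
                total *= saaf
            by_year[year] = total
        out[cadre.cadre_id] = by_year
    return out


def oracle_supply(scenario) -> dict[str, dict[int, float]]:
    """Per-cadre effective supply by year via the explicit recursion."""
    out: dict[str, dict[int, float]] = {}
    for cadre in scenario.cadres:
        by_year: dict[int, float] = {}
        stock = cadre.baseline_stock
        for year in range(scenario.base_year, scenario.horizon_end + 1):
            if year > scenario.base_year:
                pipe = cadre.pipeline
                enrol = pipe.enrolment_by_year.get(year - pipe.training_duration, 0.0)
                inflow = (
                    enrol * (1.0 - pipe.dropout_rate) + pipe.immigration_by_year.get(year, 0.0)
                ) * pipe.pass_rate
                stock = stock * (1.0 - cadre.attrition_rate) + inflow
            by_year[year] = stock * cadre.participation_rate
        out[cadre.cadre_id] = by_year
    return out
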