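"""Needs engine: rates, status projection, service need, workloads, SAAF."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hwfplan.fixtures import SyntheticSpec, generate_synthetic_scenario
from hwfplan.needs_engine import (
    compute_awt,
    compute_saaf,
    compute_service_need,
    compute_service_volumes,
    compute_standard_workload,
    compute_workforce_requirement,
    estimate_rate_of_change,
    project_health_status,
)
from hwfplan.scenario_model import AwtComponents, HealthIndicator, SupportActivity

from .oracle import oracle_need, oracle_service_volumes


def _bisect_compound_rate(v1, v2, span):
    """Oracle: solve v1 (1+r)^span = v2 for r by bisection."""
    lo, hi = -0.999, 10.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if v1 * (1.0 + mid) ** span < v2:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


class TestRateOfChange:
    def test_no_change_gives_zero_rate(self):
        assert estimate_rate_of_change(0.10, 2007, 0.10, 2017, "geometric") == 0.0

    def test_geometric_doubling_over_a_decade(self):
        expected = _bisect_compound_rate(0.10, 0.20, 10)
        rate = estimate_rate_of_change(0.10, 2007, 0.20, 2017, "geometric")
        assert rate == pytest.approx(expected, abs=1e-12)
        assert rate == pytest.approx(0.07177, abs=5e-6)

    def test_continuous_doubling_over_a_decade(self):
        rate = estimate_rate_of_change(0.10, 2007, 0.20, 2017, "continuous")
        assert rate == pytest.approx(math.log(2.0) / 10.0, rel=1e-15)
        assert rate == pytest.approx(0.06931, abs=5e-6)

    def test_declining_indicator_gives_negative_rate(self):
        assert estimate_rate_of_change(0.2, 2010, 0.1, 2020) < 0.0

    def test_zero_baseline_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            estimate_rate_of_change(0.0, 2007, 0.2, 2017)

    def test_equal_years_rejected(self):
        with pytest.raises(ValueError, match="same year"):
            estimate_rate_of_change(0.1, 2017, 0.2, 2017)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        v1=st.floats(0.01, 1.0),
        rate=st.floats(-0.1, 0.2),
        span=st.integers(1, 30),
    )
    def test_geometric_recovers_simulated_rate_exactly(self, v1, rate, span):
        """Parameter recovery: the rate used to compound a series is recovered."""
        v2 = v1 * (1.0 + rate) ** span
        recovered = estimate_rate_of_change(v1, 2000, v2, 2000 + span)
        assert recovered == pytest.approx(rate, rel=1e-9, abs=1e-12)


class TestHealthStatusProjection:
    def _indicator(self, baseline, rate, year=2020):
        return HealthIndicator(
            indicator_id="h", baseline_value=baseline, baseline_year=year, rate_of_change=rate
        )

    def test_zero_rate_is_identity(self):
        series = project_health_status(self._indicator(0.2, 0.0), range(2020, 2026))
        assert all(v == 0.2 for v in series.values())

    def test_compounds_annually(self):
        series = project_health_status(self._indicator(0.2, 0.05), [2020, 2021, 2022])
        assert series[2022] == pytest.approx(0.2 * 1.05**2, rel=1e-12)
        assert series[2022] == pytest.approx(0.2205, abs=1e-12)

    def test_clamped_at_one(self):
        series = project_health_status(self._indicator(0.9, 0.2), [2020, 2021, 2022, 2023])
        assert series[2023] == 1.0

    def test_apply_rate_false_holds_baseline(self):
        series = project_health_status(self._indicator(0.37, 0.08), range(2020, 2031), apply_rate=False)
        assert set(series.values()) == {0.37}


class TestAwtAndWorkload:
    def test_wisn_available_time(self):
        awt = compute_awt(AwtComponents(
            possible_working_days=260, public_holidays=9, annual_leave=21,
            sick_leave=5, other_absences=4, hours_per_day=8))
        assert awt == 1768.0

    def test_no_absences(self):
        assert compute_awt(AwtComponents(possible_working_days=260, hours_per_day=8)) == 2080.0

    def test_negative_available_days_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            compute_awt(AwtComponents(
                possible_working_days=260, public_holidays=100, annual_leave=100,
                sick_leave=100, hours_per_day=8))

    @pytest.mark.parametrize(
        "awt, ss, expected", [(1768.0, 0.5, 3536.0), (1768.0, 1768.0, 1.0), (2080.0, 1.0, 2080.0)]
    )
    def test_standard_workload_is_awt_over_ss(self, awt, ss, expected):
        assert compute_standard_workload(awt, ss) == expected

    def test_nonpositive_service_standard_rejected(self):
        with pytest.raises(ValueError, match="service standard"):
            compute_standard_workload(1768.0, 0.0)


class TestSaaf:
    def test_published_midwife_support_allowances(self):
        saaf = compute_saaf([SupportActivity(name="a", sas=0.125), SupportActivity(name="b", sas=0.05)])
        assert saaf == pytest.approx(1.0 / 0.825, rel=1e-15)
        assert round(saaf, 3) == 1.212

    def test_published_specialist_adjustment(self):
        saaf = compute_saaf([SupportActivity(name="a", sas=0.15)])
        assert round((saaf - 1.0) * 100.0, 1) == 17.6

    def test_empty_list_gives_unity(self):
        assert compute_saaf([]) == 1.0

    def test_full_time_support_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            compute_saaf([SupportActivity(name="a", sas=0.6), SupportActivity(name="b", sas=0.5)])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 0.3), max_size=3))
    def test_saaf_at_least_one(self, shares):
        if sum(shares) >= 1.0:
            return
        acts = [SupportActivity(name=str(i), sas=s) for i, s in enumerate(shares)]
        assert compute_saaf(acts) >= 1.0


class TestServiceNeedAndRequirement:
    def test_single_stratum_product(self):
        scenario = generate_synthetic_scenario(SyntheticSpec(seed=0, horizon_years=2))
        svc = scenario.services[0]
        ind = scenario.get_indicator(svc.indicator_id)
        # pin inputs to a hand-checkable configuration
        ind.rate_of_change = 0.0
        ind.baseline_value = 0.1
        ind.stratum_selector.age_cohorts = [scenario.population[0].age_cohort]
        ind.stratum_selector.genders = [scenario.population[0].gender]
        ind.stratum_selector.locations = [scenario.population[0].location]
        scenario.population[0].counts_by_year = {y: 1000.0 for y in scenario.years}
        svc.frequency_per_person_in_need = 4.0
        assert compute_service_need(scenario, svc, scenario.base_year) == pytest.approx(400.0)

    def test_additivity_over_strata(self, known):
        scenario, _ = known
        svc = scenario.get_service("svc_a")
        ind = scenario.get_indicator("ind_a")
        ind.stratum_selector.age_cohorts = None  # now matches both strata
        ind.rate_of_change = 0.0
        ind.baseline_value = 0.1
        svc.frequency_per_person_in_need = 4.0
        scenario.population[0].counts_by_year[2020] = 1000.0
        scenario.population[1].counts_by_year[2020] = 500.0
        # 1000*0.1*4 + 500*0.1*4
        assert compute_service_need(scenario, svc, 2020) == pytest.approx(600.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_volumes_match_brute_force_loops(self, seed):
        scenario = generate_synthetic_scenario(
            SyntheticSpec(seed=seed, n_age_cohorts=5, n_locations=2, n_services=10, horizon_years=4)
        )
        expected = oracle_service_volumes(scenario)
        got = compute_service_volumes(scenario)
        assert got.keys() == expected.keys()
        for sid in expected:
            for year, value in expected[sid].items():
                assert got[sid][year] == pytest.approx(value, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_requirement_matches_brute_force_loops(self, seed):
        scenario = generate_synthetic_scenario(
            SyntheticSpec(seed=seed, n_age_cohorts=5, n_locations=2, n_services=10, horizon_years=4)
        )
        expected = oracle_need(scenario)
        for cadre_id, by_year in expected.items():
            for year, value in by_year.items():
                got = compute_workforce_requirement(scenario, cadre_id, year)
                assert got == pytest.approx(value, rel=1e-9)

    def test_requirement_identity_case(self, known):
        scenario, _ = known
        c = scenario.get_cadre("c1")
        c.support_activities = []
        svc_a = scenario.get_service("svc_a")
        svc_b = scenario.get_service("svc_b")
        # one service, volume == standard workload, full division -> 1 FTE
        svc_b.work_division = {"c1": 1.0}
        svc_b.frequency_per_person_in_need = 0.0
        ind = scenario.get_indicator("ind_a")
        ind.rate_of_change = 0.0
        svc_a.service_standard = 0.5  # SW = 1768/0.5 = 3536
        ind.baseline_value = 3536.0 / (4.0 * 1000.0)
        scenario.population[0].counts_by_year[2020] = 1000.0
        assert compute_workforce_requirement(scenario, "c1", 2020) == pytest.approx(1.0, rel=1e-12)
        # support activities inflate by exactly the SAAF
        c.support_activities = [SupportActivity(name="s", sas=0.175)]
        assert compute_workforce_requirement(scenario, "c1", 2020) == pytest.approx(
            1.0 / 0.825, rel=1e-12
        )

    def test_cadre_without_services_needs_nobody(self, known):
        scenario, _ = known
        spare = scenario.cadres[0].model_copy(deep=True)
        spare.cadre_id = "c2"  # appears in no service work division
        scenario.cadres.append(spare)
        assert compute_workforce_requirement(scenario, "c2", 2020) == 0.0


class TestNeedsProperties:
    def test_homogeneity_doubling_population_doubles_need(self):
        scenario = generate_synthetic_scenario(SyntheticSpec(seed=7, horizon_years=3))
        base_volumes = compute_service_volumes(scenario)
        base_need = {
            c.cadre_id: compute_workforce_requirement(scenario, c.cadre_id, scenario.horizon_end)
            for c in scenario.cadres
        }
        for stratum in scenario.population:
            stratum.counts_by_year = {y: 2.0 * v for y, v in stratum.counts_by_year.items()}
        doubled_volumes = compute_service_volumes(scenario)
        for sid in base_volumes:
            for year in base_volumes[sid]:
                assert doubled_volumes[sid][year] == pytest.approx(
                    2.0 * base_volumes[sid][year], rel=1e-12
                )
        for c in scenario.cadres:
            need = compute_workforce_requirement(scenario, c.cadre_id, scenario.horizon_end)
            assert need == pytest.approx(2.0 * base_need[c.cadre_id], rel=1e-12)

    def test_static_world_has_constant_need(self):
        scenario = generate_synthetic_scenario(SyntheticSpec(seed=11, horizon_years=6))
        scenario.flags.apply_rate_of_change = False
        for stratum in scenario.population:
            first = stratum.counts_by_year[scenario.base_year]
            stratum.counts_by_year = {y: first for y in scenario.years}
        for cadre in scenario.cadres:
            series = [
                compute_workforce_requirement(scenario, cadre.cadre_id, y) for y in scenario.years
            ]
            assert all(v == pytest.approx(series[0], rel=1e-12) for v in series)

    def test_increasing_rate_never_decreases_later_need(self):
        scenario = generate_synthetic_scenario(SyntheticSpec(seed=13, horizon_years=6))
        for ind in scenario.indicators:
            ind.rate_of_change = 0.01
        low = {
            (c.cadre_id, y): compute_workforce_requirement(scenario, c.cadre_id, y)
            for c in scenario.cadres
            for y in scenario.years
        }
        for ind in scenario.indicators:
            ind.rate_of_change = 0.03
        for (cadre_id, year), value in low.items():
            assert compute_workforce_requirement(scenario, cadre_id, year) >= value - 1e-12
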