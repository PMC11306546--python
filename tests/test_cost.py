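"""Cost engine: composition arithmetic, visit capacity, structural properties."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chwpay import (
    ServiceModel,
    StaffingPlan,
    ValidationError,
    labor_cost,
    monthly_visit_capacity,
    overhead_cost,
    supervision_cost,
    total_cost,
)
from chwpay.io import OverheadLedger

from conftest import make_geo

RN = StaffingPlan.rn()
HALF_TIME = StaffingPlan("RN", 8.0, 1040.0)

money = st.floats(min_value=0.01, max_value=500.0)
scale = st.floats(min_value=0.1, max_value=10.0)


class TestCostComposition:
    @pytest.mark.parametrize(
        "wage, plan, expected",
        [
            (23.51, RN, 48_900.80),
            (1.00, RN, 2_080.00),
            (20.00, HALF_TIME, 20_800.00),
        ],
    )
    def test_labor_is_wage_times_annual_hours(self, wage, plan, expected):
        assert labor_cost(wage, plan) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "wage, plan, expected",
        [
            (39.88, StaffingPlan("RN", 8, 2080), 10_368.80),
            (29.37, StaffingPlan("MSW", 6, 2080), 10_181.60),
            (31.00, StaffingPlan("RN", 1, 2080), 31.00 * 2080),
        ],
    )
    def test_supervision_is_allocated_across_the_team(self, wage, plan, expected):
        assert supervision_cost(wage, plan) == pytest.approx(expected)

    def test_overhead_annualises_each_component(self, national_geo):
        components = overhead_cost(national_geo.overhead, RN)
        assert sum(components.values()) == pytest.approx(43.65 * 2080)
        # the transportation share of overhead is preserved through annualisation
        share = components["transportation"] / sum(components.values())
        assert share == pytest.approx(28.42 / 43.65)
        assert share == pytest.approx(0.651, abs=1e-3)

    def test_zero_ledger_costs_nothing(self):
        zeros = OverheadLedger(0, 0, 0, 0, 0)
        assert all(v == 0 for v in overhead_cost(zeros, RN).values())

    def test_total_cost_sums_the_three_pieces(self, national_geo):
        cb = total_cost(national_geo, RN)
        assert cb.labor == pytest.approx(48_900.80)
        assert cb.supervision == pytest.approx(10_368.80)
        assert cb.total_annual == pytest.approx(150_061.60)
        assert cb.total_monthly == pytest.approx(12_505.13, abs=0.005)

    def test_degenerate_ledger_reduces_to_wage_bill(self):
        geo = make_geo(chw=(17.0, 0.0), rn=(1e-9 + 0.01, 0.0), overhead=(0, 0, 0, 0, 0))
        cb = total_cost(geo, StaffingPlan("RN", 1e9, 2080))
        assert cb.total_annual == pytest.approx(17.0 * 2080, rel=1e-6)

    def test_missing_supervisor_wage_is_a_config_error(self):
        geo = make_geo()
        geo = dataclasses.replace(geo, supervisor_wages={"RN": geo.supervisor_wages["RN"]})
        from chwpay import ConfigError

        with pytest.raises(ConfigError, match="MSW"):
            total_cost(geo, StaffingPlan.msw())

    @pytest.mark.parametrize("bad_wage", [0.0, -5.0])
    def test_non_positive_wage_rejected(self, bad_wage):
        with pytest.raises(ValidationError):
            labor_cost(bad_wage, RN)


class TestVisitCapacity:
    @pytest.mark.parametrize(
        "travel, expected",
        [(0.0, 346.67), (0.8, 247.62)],
    )
    def test_capacity_examples(self, travel, expected, service):
        cap = monthly_visit_capacity(service, travel, RN)
        assert cap == pytest.approx(expected, abs=0.005)

    def test_all_inperson_with_travel_equal_to_duration_halves_capacity(self):
        svc = ServiceModel(inperson_share=1.0)
        assert monthly_visit_capacity(svc, 0.5, RN) == pytest.approx(
            monthly_visit_capacity(svc, 0.0, RN) / 2
        )

    def test_zero_travel_capacity_is_exact(self):
        svc = ServiceModel(visit_duration=0.5, productive_fraction=0.8)
        assert monthly_visit_capacity(svc, 0.0, RN) == (2080 / 12 * 0.8) / 0.5

    def test_travel_opportunity_mode_ignores_travel_in_capacity(self, service):
        with_travel = monthly_visit_capacity(
            service, 1.5, RN, travel_opportunity_in_overhead=True
        )
        assert with_travel == monthly_visit_capacity(service, 0.0, RN)

    def test_travel_opportunity_mode_charges_wage_hours_to_ledger(self, service):
        geo = make_geo(travel=1.0)
        base = total_cost(geo, RN)
        moved = total_cost(geo, RN, svc=service, travel_opportunity_in_overhead=True)
        visits_per_year = 12 * monthly_visit_capacity(
            service, 0.0, RN, travel_opportunity_in_overhead=True
        )
        expected_extra = geo.chw_wage.mean * service.inperson_share * 1.0 * visits_per_year
        assert moved.total_annual - base.total_annual == pytest.approx(expected_extra)


class TestStructuralProperties:
    def test_breakdown_additivity_is_exact(self, national_geo):
        cb = total_cost(national_geo, RN)
        total = cb.labor + cb.supervision + sum(cb.overhead_by_component.values())
        assert abs(cb.total_annual - total) <= 1e-12 * total
        assert cb.total_monthly == cb.total_annual / 12.0

    @settings(derandomize=True, max_examples=50)
    @given(chw=money, rn=money, oh=money, k=scale)
    def test_total_cost_is_homogeneous_in_money(self, chw, rn, oh, k):
        """Scaling every $/h input by k scales the total by exactly k."""
        base = make_geo(chw=(chw, 0), rn=(rn, 0), overhead=(oh, oh, oh, oh, oh))
        scaled = make_geo(
            chw=(chw * k, 0), rn=(rn * k, 0),
            overhead=tuple([oh * k] * 5),
        )
        assert total_cost(scaled, RN).total_annual == pytest.approx(
            k * total_cost(base, RN).total_annual, rel=1e-12
        )

    @settings(derandomize=True, max_examples=50)
    @given(
        t1=st.floats(min_value=0, max_value=4),
        dt=st.floats(min_value=0.01, max_value=3),
        s=st.floats(min_value=0.05, max_value=1.0),
        pf=st.floats(min_value=0.1, max_value=0.99),
    )
    def test_capacity_monotonicity(self, t1, dt, s, pf):
        """Capacity falls with travel time and in-person share, rises with
        productive fraction."""
        svc = ServiceModel(inperson_share=s, productive_fraction=pf)
        assert monthly_visit_capacity(svc, t1 + dt, RN) < monthly_visit_capacity(svc, t1, RN)
        more_inperson = ServiceModel(inperson_share=min(1.0, s + 0.05), productive_fraction=pf)
        if t1 > 0:
            assert monthly_visit_capacity(more_inperson, t1, RN) < monthly_visit_capacity(
                svc, t1, RN
            ) + 1e-9
        fuller = ServiceModel(inperson_share=s, productive_fraction=min(1.0, pf + 0.01))
        assert monthly_visit_capacity(fuller, t1, RN) > monthly_visit_capacity(svc, t1, RN)

    def test_zero_visit_duration_rejected(self):
        with pytest.raises(ValidationError):
            ServiceModel(visit_duration=0.0)
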