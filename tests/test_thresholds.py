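"""Threshold engine: break-even rates, panel rescaling, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chwpay import (
    ServiceModel,
    StaffingPlan,
    ThresholdEstimate,
    ValidationError,
    aggregate,
    ffs_threshold,
    monthly_visit_capacity,
    pmpm_threshold,
    rescale_by_panel,
    total_cost,
)

from conftest import make_geo

money = st.floats(min_value=0.01, max_value=500.0)

SVC = ServiceModel()


def est(label, ffs, pmpm, panel=65.0):
    return ThresholdEstimate(label=label, ffs_rate=ffs, pmpm_rate=pmpm, panel_size=panel)


class TestBreakEvenRates:
    @pytest.mark.parametrize(
        "cost, panel, expected",
        [(9_111.70, 65, 140.18), (6_500.00, 65, 100.00), (777.77, 1, 777.77)],
    )
    def test_pmpm_spreads_cost_over_panel(self, cost, panel, expected):
        rate = pmpm_threshold(cost, panel)
        assert rate == pytest.approx(expected, abs=0.005)
        # revenue at the threshold covers the cost exactly
        assert rate * panel == pytest.approx(cost, rel=1e-12)

    @pytest.mark.parametrize(
        "cost, visits, expected",
        [(10_000.00, 200, 50.00), (9_111.70, 171.14, 53.24), (321.0, 1, 321.0)],
    )
    def test_ffs_spreads_cost_over_visits(self, cost, visits, expected):
        rate = ffs_threshold(cost, visits)
        assert rate == pytest.approx(expected, abs=0.005)
        assert rate * visits == pytest.approx(cost, rel=1e-12)

    @pytest.mark.parametrize("bad", [0, 0.5])
    def test_sub_unit_panel_rejected(self, bad):
        with pytest.raises(ValidationError):
            pmpm_threshold(100.0, bad)

    def test_zero_visits_rejected(self):
        with pytest.raises(ValidationError):
            ffs_threshold(100.0, 0.0)


class TestPanelRescaling:
    @pytest.mark.parametrize(
        "rate, new_panel, expected, tol",
        [
            # published panel-sweep values, from the panel-65 baselines
            (140.18, 100, 91.12, 0.005),
            (140.18, 15, 607.45, 0.005),
            (53.24, 100, 34.61, 0.005),
            (53.24, 15, 230.72, 0.02),  # cent-rounding of the printed baseline
        ],
    )
    def test_inverse_panel_law_reproduces_published_sweep(self, rate, new_panel, expected, tol):
        assert rescale_by_panel(rate, 65, new_panel) == pytest.approx(expected, abs=tol)

    def test_identity_at_same_panel(self):
        assert rescale_by_panel(123.45, 65, 65) == pytest.approx(123.45, rel=1e-15)

    @settings(derandomize=True, max_examples=50)
    @given(
        rate=money,
        p0=st.floats(min_value=1, max_value=500),
        p1=st.floats(min_value=1, max_value=500),
    )
    def test_rescaled_revenue_is_invariant(self, rate, p0, p1):
        """rate' x new_panel = rate x old_panel: same monthly cost recovered."""
        r1 = rescale_by_panel(rate, p0, p1)
        assert r1 * p1 == pytest.approx(rate * p0, rel=1e-12)
        if p1 > p0:
            assert r1 < rate

    def test_non_positive_arguments_rejected(self):
        with pytest.raises(ValidationError):
            rescale_by_panel(100.0, 65, 0)


class TestMonotonicity:
    @settings(derandomize=True, max_examples=30)
    @given(
        chw=money, rn=money, oh=money,
        bump=st.floats(min_value=0.01, max_value=100),
        travel=st.floats(min_value=0.0, max_value=4.0),
        dtravel=st.floats(min_value=0.01, max_value=2.0),
    )
    def test_thresholds_increase_in_costs_and_ffs_in_travel(
        self, chw, rn, oh, bump, travel, dtravel
    ):
        service = SVC
        plan = StaffingPlan.rn()
        base = make_geo(chw=(chw, 0), rn=(rn, 0), overhead=(oh, oh, oh, oh, oh), travel=travel)
        cost0 = total_cost(base, plan).total_monthly
        cap0 = monthly_visit_capacity(service, travel, plan)
        ffs0 = ffs_threshold(cost0, cap0)
        pmpm0 = pmpm_threshold(cost0, service.panel_size)
        # raise one wage component
        up = make_geo(chw=(chw + bump, 0), rn=(rn, 0), overhead=(oh, oh, oh, oh, oh), travel=travel)
        cost1 = total_cost(up, plan).total_monthly
        assert ffs_threshold(cost1, cap0) > ffs0
        assert pmpm_threshold(cost1, service.panel_size) > pmpm0
        # raise one overhead component
        up_oh = make_geo(
            chw=(chw, 0), rn=(rn, 0), overhead=(oh + bump, oh, oh, oh, oh), travel=travel
        )
        assert total_cost(up_oh, plan).total_monthly > cost0
        # longer travel strictly raises FFS (capacity falls, cost fixed)
        cap1 = monthly_visit_capacity(service, travel + dtravel, plan)
        assert ffs_threshold(cost0, cap1) > ffs0


class TestAggregation:
    def test_equal_weights_midpoint(self):
        out = aggregate([est("A", 40, 40), est("B", 60, 60)], label="M")
        assert out.ffs_rate == pytest.approx(50) and out.pmpm_rate == pytest.approx(50)

    def test_degenerate_weight_selects_one(self):
        out = aggregate([est("A", 40, 40), est("B", 60, 60)], weights=[1, 0])
        assert out.ffs_rate == pytest.approx(40)

    def test_singleton_identity(self):
        a = est("A", 47.1, 124.46)
        out = aggregate([a], weights=[3.0], label="A")
        assert out.ffs_rate == pytest.approx(a.ffs_rate)
        assert out.pmpm_rate == pytest.approx(a.pmpm_rate)

    def test_aggregate_of_identical_estimates_is_that_estimate(self):
        a = est("A", 55.5, 150.0)
        out = aggregate([a, a, a])
        assert out.ffs_rate == pytest.approx(a.ffs_rate, rel=1e-12)
        assert out.pmpm_ci_high == pytest.approx(a.pmpm_ci_high, rel=1e-12)

    def test_length_mismatch_and_zero_weights_rejected(self):
        pair = [est("A", 40, 40), est("B", 60, 60)]
        with pytest.raises(ValidationError):
            aggregate(pair, weights=[1.0])
        with pytest.raises(ValidationError):
            aggregate(pair, weights=[0.0, 0.0])

    def test_draw_level_aggregation_pools_pointwise(self):
        rng = np.random.default_rng(1)
        draws_a = rng.normal(40, 2, 1000) + 10  # keep positive
        draws_b = rng.normal(60, 2, 1000) + 10
        a = ThresholdEstimate(
            label="A", ffs_rate=float(draws_a.mean()), pmpm_rate=float(draws_a.mean()),
            ffs_ci_low=float(np.percentile(draws_a, 2.5)),
            ffs_ci_high=float(np.percentile(draws_a, 97.5)),
            pmpm_ci_low=float(np.percentile(draws_a, 2.5)),
            pmpm_ci_high=float(np.percentile(draws_a, 97.5)),
            ffs_draws=draws_a, pmpm_draws=draws_a, n_draws=1000,
        )
        b = ThresholdEstimate(
            label="B", ffs_rate=float(draws_b.mean()), pmpm_rate=float(draws_b.mean()),
            ffs_ci_low=float(np.percentile(draws_b, 2.5)),
            ffs_ci_high=float(np.percentile(draws_b, 97.5)),
            pmpm_ci_low=float(np.percentile(draws_b, 2.5)),
            pmpm_ci_high=float(np.percentile(draws_b, 97.5)),
            ffs_draws=draws_b, pmpm_draws=draws_b, n_draws=1000,
        )
        out = aggregate([a, b], label="M")
        np.testing.assert_allclose(out.ffs_draws, (draws_a + draws_b) / 2)
        # the mean of two independent streams is less dispersed than either
        assert out.ffs_ci_high - out.ffs_ci_low < a.ffs_ci_high - a.ffs_ci_low + 1e-9
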