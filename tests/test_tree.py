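"""Decision-tree arithmetic: path probabilities, expected surgeries and
costs, the IFMI add-on, and the two-anchor time-cost calibration."""

import pytest
from hypothesis import given, settings, strategies as st

from ifmiecon import (
    CostParameters,
    MarginModel,
    ParameterError,
    calibrate_time_cost,
    device_cost_per_surgery,
    expected_cost,
    expected_surgeries,
    ifmi_addon_cost,
    incremental,
    path_distribution,
    time_delta_cost,
)
from ifmiecon.tree import path_outcomes

probs = st.floats(0.0, 1.0)


class TestPathDistribution:
    def test_base_case_split(self):
        assert path_distribution(0.3, 0.1) == pytest.approx((0.70, 0.27, 0.03))

    def test_zero_first_surgery_risk_stops_after_one(self):
        assert path_distribution(0.0, 0.7) == (1.0, 0.0, 0.0)

    @settings(derandomize=True, max_examples=200)
    @given(p1=probs, p2=probs)
    def test_conservation(self, p1, p2):
        assert sum(path_distribution(p1, p2)) == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ParameterError):
            path_distribution(1.2, 0.1)


class TestExpectedSurgeries:
    @pytest.mark.parametrize("p1,p2,expected", [
        (0.3, 0.1, 1.33),   # ST base case
        (0.1, 0.1, 1.11),   # IFMI base case
        (0.0, 0.0, 1.0),
    ])
    def test_published_values(self, p1, p2, expected):
        assert expected_surgeries(p1, p2) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(p1=probs, p2=probs)
    def test_bounded_between_one_and_three(self, p1, p2):
        e = expected_surgeries(p1, p2)
        assert 1.0 <= e <= 3.0
        # equals the path-weighted surgery count
        probs_ = path_distribution(p1, p2)
        assert e == pytest.approx(sum(n * p for n, p in zip((1, 2, 3), probs_)))


class TestDeviceCost:
    def test_base_case_amortization_rounds_to_182(self):
        exact = device_cost_per_surgery(150_000, 0.10, 7, 200)
        assert exact == pytest.approx(182.142857, abs=1e-6)
        assert CostParameters().camera_cost == 182.0

    def test_free_device_costs_nothing(self):
        assert device_cost_per_surgery(0.0, 0.1, 7, 200) == 0.0

    def test_no_maintenance_leaves_depreciation_only(self):
        assert device_cost_per_surgery(150_000, 0.0, 7, 200) == pytest.approx(107.142857, abs=1e-6)

    def test_nonpositive_lifespan_raises(self):
        with pytest.raises(ParameterError):
            device_cost_per_surgery(150_000, 0.1, 0, 200)


class TestTimeDeltaAndAddon:
    def test_base_case_time_delta_is_a_saving(self):
        c = CostParameters()
        delta = time_delta_cost(10, 27, 0.64, c.cost_per_minute, c.fsa_fixed_saving)
        assert delta == pytest.approx(-588.62, abs=1e-9)

    def test_zero_rate_zero_saving_is_free(self):
        assert time_delta_cost(10, 27, 0.0, 0.0, 0.0) == 0.0

    def test_strictly_decreasing_in_staff_factor(self):
        c = CostParameters()
        vals = [time_delta_cost(10, 27, s, c.cost_per_minute, c.fsa_fixed_saving)
                for s in (0.0, 0.3, 0.64, 1.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_staff_factor_raises(self):
        with pytest.raises(ParameterError):
            time_delta_cost(10, 27, 1.5, 68.0, 0.0)

    def test_addon_base_case(self):
        # 500 + 182 + 23 + 107 - 588.62
        assert ifmi_addon_cost(CostParameters()) == pytest.approx(223.38, abs=1e-9)

    def test_addon_without_staff_saving(self):
        costs = CostParameters(staff_time_saving_factor=0.0)
        assert ifmi_addon_cost(costs) == pytest.approx(1402.38, abs=1e-9)


class TestExpectedCostAndIncrement:
    def test_published_expected_costs_truncate_correctly(self, base_params):
        m, c = base_params.margins, base_params.costs
        st_res = expected_cost("ST", m, c)
        ifmi_res = expected_cost("IFMI", m, c)
        assert st_res.expected_cost == pytest.approx(5358.57, abs=1e-9)
        assert st_res.expected_cost_eur == 5358
        assert ifmi_res.expected_cost == pytest.approx(4695.57, abs=1e-9)
        assert ifmi_res.expected_cost_eur == 4695

    def test_degenerate_margins_cost_one_surgery(self):
        m = MarginModel(p_pos_st=0.0, p_pos_ifmi=0.0, p_pos_second=0.0)
        c = CostParameters()
        assert expected_cost("ST", m, c).expected_cost == pytest.approx(c.lump_sum_per_surgery)

    def test_base_incremental_endpoints(self, base_params):
        inc = incremental(base_params.margins, base_params.costs)
        assert inc.delta_surgeries == pytest.approx(-0.22, abs=1e-12)
        assert inc.delta_cost == pytest.approx(-663.0, abs=1e-9)

    def test_equal_margins_leave_only_the_addon(self):
        m = MarginModel(p_pos_ifmi=0.3)  # rr = 1
        c = CostParameters()
        inc = incremental(m, c)
        assert inc.delta_surgeries == 0.0
        assert inc.delta_cost == pytest.approx(223.38, abs=1e-9)

    def test_path_outcome_probabilities_and_costs(self, base_params):
        outcomes = path_outcomes("ST", base_params.margins, base_params.costs)
        assert sum(o.probability for o in outcomes) == pytest.approx(1.0)
        assert [o.n_surgeries for o in outcomes] == [1, 2, 3]
        lump = base_params.costs.lump_sum_per_surgery
        assert [o.cost for o in outcomes] == pytest.approx([lump, 2 * lump, 3 * lump])

    def test_endpoints_affine_in_relative_risk(self, base_params):
        """Three collinear rr evaluations: midpoint equals the mean of the ends."""
        m, c = base_params.margins, base_params.costs
        def at(rr):
            inc = incremental(m.with_rr(rr), c)
            return inc.delta_surgeries, inc.delta_cost
        lo, mid, hi = at(0.2), at(0.45), at(0.7)
        for i in range(2):
            assert mid[i] == pytest.approx((lo[i] + hi[i]) / 2.0, abs=1e-9)


class TestCalibration:
    def test_published_anchors_give_calibrated_defaults(self):
        c, F = calibrate_time_cost((0.64, -663.0), (0.0, 516.0))
        assert c == pytest.approx(68.229, abs=0.001)
        assert F == pytest.approx(91.91, abs=0.005)
        defaults = CostParameters()
        assert c == pytest.approx(defaults.cost_per_minute, abs=1e-9)
        assert F == pytest.approx(defaults.fsa_fixed_saving, abs=1e-9)

    def test_calibration_reproduces_both_anchors_simultaneously(self, base_params):
        """Default (c, F) yields -663 at s=0.64 and 516 at s=0 at once."""
        inc = incremental(base_params.margins, base_params.costs)
        assert inc.delta_cost == pytest.approx(-663.0, abs=1e-9)
        ps0 = base_params.with_values(staff_time_saving_factor=0.0)
        inc0 = incremental(ps0.margins, ps0.costs)
        assert inc0.delta_cost == pytest.approx(516.0, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(c0=st.floats(10.0, 200.0), f0=st.floats(0.0, 500.0),
           s_a=st.floats(0.0, 1.0), s_b=st.floats(0.0, 1.0))
    def test_round_trip_recovers_known_time_costs(self, c0, f0, s_a, s_b):
        if abs(s_a - s_b) < 1e-3:
            return
        m = MarginModel()
        def delta(s):
            costs = CostParameters(
                staff_time_saving_factor=s, cost_per_minute=c0, fsa_fixed_saving=f0
            )
            return incremental(m, costs).delta_cost
        costs = CostParameters()
        c, F = calibrate_time_cost((s_a, delta(s_a)), (s_b, delta(s_b)), m, costs)
        assert c == pytest.approx(c0, rel=1e-7)
        assert F == pytest.approx(f0, rel=1e-6, abs=1e-6)

    def test_identical_anchor_factors_raise(self):
        with pytest.raises(ParameterError):
            calibrate_time_cost((0.5, -100.0), (0.5, 100.0))
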