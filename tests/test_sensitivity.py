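"""Relative-risk sweep, linear interpolation, tornado ranking, one-way
scenarios and the break-even staff-time-saving thresholds."""

import pytest

from ifmiecon import (
    ParameterError,
    interpolate,
    rr_sweep,
    run_scenario,
    threshold_staff_factor,
    tornado,
)


class TestSweep:
    def test_published_grid_points(self, base_params):
        sweep = rr_sweep(base_params, grid=(0.0, 1 / 3, 1.0), with_psa=False)
        by_rr = {round(p.rr, 3): p for p in sweep}
        assert by_rr[0.333].delta_surgeries == pytest.approx(-0.22)
        assert by_rr[1.0].delta_surgeries == pytest.approx(0.0)
        assert by_rr[0.0].delta_surgeries == pytest.approx(-0.33)  # -0.3 * 1.1

    def test_rr_outside_unit_interval_raises(self, base_params):
        with pytest.raises(ParameterError):
            rr_sweep(base_params, grid=(1.5,), with_psa=False)

    def test_interpolation_is_exact_for_affine_endpoints(self, base_params):
        """Point estimates are affine in rr, and with common random numbers
        the surgery interval bounds are too: interpolation matches direct
        evaluation."""
        sweep = rr_sweep(base_params, n=2000, seed=9)
        direct = rr_sweep(base_params, grid=(0.25,), n=2000, seed=9)[0]
        mid = interpolate(sweep, 0.25)
        assert mid.delta_surgeries == pytest.approx(direct.delta_surgeries, abs=1e-9)
        assert mid.delta_cost == pytest.approx(direct.delta_cost, abs=1e-9)
        assert mid.ci_surgeries[0] == pytest.approx(direct.ci_surgeries[0], abs=1e-9)
        assert mid.ci_surgeries[1] == pytest.approx(direct.ci_surgeries[1], abs=1e-9)
        # cost bounds carry addon noise per draw: approximate only
        assert mid.ci_cost[0] == pytest.approx(direct.ci_cost[0], abs=25.0)

    def test_interpolation_at_node_returns_the_node(self, base_params):
        sweep = rr_sweep(base_params, with_psa=False)
        node = sweep[2]
        got = interpolate(sweep, node.rr)
        assert got.delta_cost == pytest.approx(node.delta_cost)

    def test_midpoint_is_arithmetic_mean_of_neighbours(self, base_params):
        sweep = rr_sweep(base_params, grid=(0.2, 0.6), with_psa=False)
        mid = interpolate(sweep, 0.4)
        assert mid.delta_cost == pytest.approx(
            (sweep[0].delta_cost + sweep[1].delta_cost) / 2.0
        )

    def test_interpolation_outside_span_raises(self, base_params):
        sweep = rr_sweep(base_params, grid=(0.2, 0.6), with_psa=False)
        with pytest.raises(ParameterError):
            interpolate(sweep, 0.7)


class TestTornado:
    def test_published_inputs_at_quarter_variation(self, base_params):
        entries = {e.parameter: e for e in tornado(base_params)}
        assert entries["drg_cost"].low_input == pytest.approx(2631.0)
        assert entries["drg_cost"].high_input == pytest.approx(4385.0)
        assert entries["staff_time_saving_factor"].low_input == pytest.approx(0.48)
        assert entries["staff_time_saving_factor"].high_input == pytest.approx(0.8)
        assert entries["p_pos_ifmi"].low_input == pytest.approx(0.075)
        assert entries["p_pos_ifmi"].high_input == pytest.approx(0.125)

    def test_sorted_by_descending_range(self, base_params):
        entries = tornado(base_params)
        ranges = [e.range for e in entries]
        assert ranges == sorted(ranges, reverse=True)

    def test_margin_and_drg_parameters_lead_the_ranking(self, base_params):
        """The published diagram names the DRG costs, ST margin proportion,
        staff time saving factor and FSA duration as the key drivers."""
        top = {e.parameter for e in tornado(base_params)[:4]}
        assert top == {"drg_cost", "p_pos_st", "staff_time_saving_factor", "fsa_duration"}

    def test_zero_fraction_gives_zero_ranges(self, base_params):
        assert all(e.range == pytest.approx(0.0) for e in tornado(base_params, fraction=0.0))

    def test_drg_range_matches_analytic_slope(self, base_params):
        """Incremental cost is affine in the DRG lump sum (directly and via
        the derived cost per minute): range = |slope| * 0.5 * mean."""
        c = base_params.costs
        s, prol, fsa = c.staff_time_saving_factor, c.prolongation, c.fsa_duration
        slope = -0.22 + (prol - s * fsa) / c.st_duration
        expected = abs(slope) * 0.5 * c.drg_cost
        entry = {e.parameter: e for e in tornado(base_params)}["drg_cost"]
        assert entry.range == pytest.approx(expected, rel=1e-9)


class TestScenarios:
    def test_no_staff_saving_scenario_matches_published_cost(self, base_params):
        res = run_scenario(base_params, "staff_saving_0", with_psa=False)
        assert res.incremental.delta_cost == pytest.approx(516.0, abs=1e-9)
        assert res.incremental.delta_surgeries == pytest.approx(-0.22)

    def test_agent_price_rise_shifts_every_sweep_point_equally(self, base_params):
        res = run_scenario(base_params, {"agent_cost": 800.0}, with_psa=False, with_sweep=True)
        base_sweep = rr_sweep(base_params, with_psa=False)
        shifts = {
            round(a.delta_cost - b.delta_cost, 9)
            for a, b in zip(res.sweep, base_sweep)
        }
        assert shifts == {300.0}

    def test_empty_overrides_reproduce_base_analysis(self, base_params):
        res = run_scenario(base_params, None, with_psa=False)
        assert res.incremental.delta_cost == pytest.approx(-663.0, abs=1e-9)
        assert res.params == base_params

    def test_lower_st_margins_scenario_reties_relative_risk(self, base_params):
        res = run_scenario(base_params, "st_margins_low", with_psa=False)
        assert res.params.margins.p_pos_st == pytest.approx(0.183)
        assert res.params.margins.rr == pytest.approx(1 / 3)
        assert res.params.psa_specs["p_pos_st"].se == pytest.approx(0.035)

    def test_unknown_scenario_and_override_raise(self, base_params):
        with pytest.raises(ParameterError):
            run_scenario(base_params, "no_such_scenario")
        with pytest.raises(ParameterError):
            run_scenario(base_params, {"no_such_param": 1.0})


class TestThreshold:
    def test_point_threshold_is_the_closed_form_zero_crossing(self, base_params):
        res = threshold_staff_factor(base_params, "point")
        # delta_cost(s) = 516 - 27*c*s  =>  s* = 516/(27*c)
        c = base_params.costs.cost_per_minute
        assert res.s_star == pytest.approx(516.0 / (27.0 * c), abs=1e-9)
        assert res.s_star == pytest.approx(0.280, abs=0.001)
        assert not res.at_boundary

    def test_always_saving_configuration_reports_boundary(self, base_params):
        cheap = base_params.with_values(agent_cost=0.0, staff_addon_cost=0.0,
                                        camera_cost=0.0, draping_cost=0.0)
        res = threshold_staff_factor(cheap, "point")
        assert res.s_star == 0.0
        assert res.at_boundary

    def test_significance_threshold_exceeds_point_threshold(self, base_params):
        sig = threshold_staff_factor(base_params, "significance", seed=4, n=4000)
        pt = threshold_staff_factor(base_params, "point")
        assert sig.s_star >= pt.s_star
        assert not sig.at_boundary

    def test_significance_threshold_is_seed_reproducible(self, base_params):
        a = threshold_staff_factor(base_params, "significance", seed=8, n=2000)
        b = threshold_staff_factor(base_params, "significance", seed=8, n=2000)
        assert a.s_star == b.s_star
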