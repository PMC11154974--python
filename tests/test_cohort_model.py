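"""Decision tree and Markov cohort engine behaviour."""

import numpy as np
import pytest

from strokecea import (
    ValidationError,
    accrue_cycle,
    build_transition_matrix,
    discount_factor,
    evaluate_arm_horizons,
    recurrence_redistribution,
    run_decision_tree,
    run_markov,
)
from strokecea.cohort_model import HealthState
from strokecea.params import MRSDistribution

from _oracles import microsimulate_arm


def _no_recurrence(params):
    params.transitions.recurrence_annual = 0.0
    return params


class TestDecisionTree:
    def test_cost_is_direct_treatment_cost(self, base_params):
        assert run_decision_tree("evt", base_params).cost == 71329.86
        assert run_decision_tree("evt_ivt", base_params).cost == 108463.60

    def test_first_quarter_qaly_accrual(self, base_params):
        # cycle_length * sum(p_state * u_state) with the published inputs
        tree = run_decision_tree("evt", base_params)
        assert tree.qaly == pytest.approx(
            0.25 * (0.49 * 0.76 + 0.3519 * 0.21), abs=1e-12)
        assert tree.qaly == pytest.approx(0.111575, abs=1e-6)
        tree2 = run_decision_tree("evt_ivt", base_params)
        assert tree2.qaly == pytest.approx(
            0.25 * (0.5073 * 0.76 + 0.3443 * 0.21), abs=1e-12)

    def test_end_distribution_is_3_month_outcome(self, base_params):
        dist = run_decision_tree("evt", base_params).end_distribution
        assert (dist.p_good, dist.p_poor, dist.p_dead) == \
            (0.49, 0.3519, 0.1581)


class TestTransitionMatrix:
    def test_first_year_rows_without_recurrence(self, params):
        m = build_transition_matrix("evt", _no_recurrence(params),
                                    "first_year")
        assert m[HealthState.GOOD] == pytest.approx(
            [0.955, 0.024, 0.0, 0.021], abs=1e-12)
        assert m[HealthState.POOR] == pytest.approx(
            [0.029, 0.919, 0.0, 0.052], abs=1e-12)

    def test_post_first_year_poor_cannot_improve(self, params):
        m = build_transition_matrix("evt", _no_recurrence(params),
                                    "post_first_year")
        assert m[HealthState.POOR] == pytest.approx(
            [0.0, 0.948, 0.0, 0.052], abs=1e-12)
        # independent patients keep the first-occurrence row
        assert m[HealthState.GOOD] == pytest.approx(
            [0.955, 0.024, 0.0, 0.021], abs=1e-12)

    def test_dead_row_absorbing_and_rows_sum_to_one(self, base_params):
        for phase in ("first_year", "post_first_year"):
            m = build_transition_matrix("evt_ivt", base_params, phase)
            assert m[HealthState.DEAD] == pytest.approx([0, 0, 0, 1])
            assert m.sum(axis=1) == pytest.approx(np.ones(4), abs=1e-12)

    def test_recurrence_mass_and_tunnel_exit(self, base_params):
        r = 1.0 - 0.904 ** 0.25
        m = build_transition_matrix("evt", base_params, "first_year")
        assert m[HealthState.GOOD, HealthState.RECURRENT] == \
            pytest.approx(r, abs=1e-12)
        assert m[HealthState.RECURRENT] == pytest.approx(
            [0.49, 0.3519, 0.0, 0.1581], abs=1e-12)
        dist = recurrence_redistribution("evt_ivt", base_params)
        assert dist.as_array() == pytest.approx([0.5073, 0.3443, 0.1484])


class TestDiscounting:
    @pytest.mark.parametrize("years, rate, expected", [
        (0.0, 0.03, 1.0),
        (1.0, 0.03, 1.0 / 1.03),
        (0.25, 0.03, 1.03 ** -0.25),
    ])
    def test_discount_factor(self, years, rate, expected):
        assert discount_factor(years, rate) == pytest.approx(expected,
                                                             abs=1e-9)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            discount_factor(1.0, -0.01)


class TestAccrual:
    def test_all_good_cycle(self, base_params):
        acc = accrue_cycle([1.0, 0.0, 0.0, 0.0], "evt", base_params, 1)
        assert acc.cost_undiscounted == pytest.approx(0.25 * 7385.0)
        assert acc.qaly_undiscounted == pytest.approx(0.25 * 0.76)
        df = 1.03 ** -0.25
        assert acc.cost == pytest.approx(df * 0.25 * 7385.0)

    def test_all_dead_accrues_nothing(self, base_params):
        acc = accrue_cycle([0.0, 0.0, 0.0, 1.0], "evt", base_params, 5)
        assert acc.cost == 0.0
        assert acc.qaly == 0.0

    def test_recurrent_cycle_incurs_retreatment(self, base_params):
        acc = accrue_cycle([0.0, 0.0, 1.0, 0.0], "evt", base_params, 1)
        assert acc.cost_undiscounted == pytest.approx(71329.86)
        assert acc.qaly_undiscounted == pytest.approx(0.25 * 0.20)

    def test_death_increment_triggers_indirect_cost(self, base_params):
        with_deaths = accrue_cycle([0.9, 0.0, 0.0, 0.1], "evt", base_params,
                                   1, death_increment=0.05)
        without = accrue_cycle([0.9, 0.0, 0.0, 0.1], "evt", base_params, 1)
        df = 1.03 ** -0.25
        assert with_deaths.cost - without.cost == pytest.approx(
            df * 0.05 * 57595.37)

    def test_off_simplex_occupancy_rejected(self, base_params):
        with pytest.raises(ValidationError):
            accrue_cycle([0.5, 0.4, 0.2, 0.1], "evt", base_params, 1)


class TestMarkovRun:
    def test_two_cycle_hand_oracle(self, params):
        # r = 0, no discounting: one matrix multiplication by hand.
        _no_recurrence(params)
        params.economics.discount_annual = 0.0
        params.indirect_mode = "excluded"
        out = run_markov("evt", params, horizon=1)
        expected_qaly = 0.25 * (0.49 * 0.76 + 0.3519 * 0.21) + 0.25 * (
            0.49 * 0.955 * 0.76
            + (0.49 * 0.024 + 0.3519 * 0.919) * 0.21
            + 0.3519 * 0.029 * 0.76)
        assert out.qaly == pytest.approx(expected_qaly, abs=1e-12)
        g1 = 0.49 * 0.955 + 0.3519 * 0.029
        p1 = 0.49 * 0.024 + 0.3519 * 0.919
        expected_cost = 71329.86 + 0.25 * (g1 * 7385.0 + p1 * 11350.0)
        assert out.cost == pytest.approx(expected_cost, abs=1e-9)

    def test_all_dead_cohort_costs_treatment_only(self, params):
        params.evt.mrs_3m = MRSDistribution(0.0, 0.0, 1.0)
        out = run_markov("evt", params, "lifetime")
        assert out.cost == pytest.approx(71329.86)
        assert out.qaly == 0.0
        assert out.cycles_run == 0

    def test_lifetime_reaches_termination_mortality(self, base_params):
        for arm in ("evt", "evt_ivt"):
            out = run_markov(arm, base_params, "lifetime")
            assert out.terminated
            assert out.cumulative_mortality >= 0.99
            assert out.cycles_run <= base_params.economics.max_cycles

    def test_mass_conservation_and_monotone_mortality(self, base_params):
        trace = run_markov("evt", base_params, "lifetime").trace
        occ = np.asarray(trace.occupancy)
        assert occ.sum(axis=1) == pytest.approx(np.ones(len(occ)), abs=1e-9)
        assert np.all(occ >= -1e-12)
        dead = occ[:, HealthState.DEAD]
        assert np.all(np.diff(dead) >= -1e-12)

    def test_discounted_increments_bounded_by_undiscounted(self, base_params):
        trace = run_markov("evt", base_params, "lifetime").trace
        assert np.all(np.asarray(trace.cost_discounted) <=
                      np.asarray(trace.cost_undiscounted) + 1e-12)
        assert np.all(np.asarray(trace.qaly_discounted) <=
                      np.asarray(trace.qaly_undiscounted) + 1e-12)

    def test_zero_discount_equals_undiscounted(self, params):
        params.economics.discount_annual = 0.0
        out = run_markov("evt", params, "1y")
        trace = out.trace
        assert trace.cost_discounted == pytest.approx(
            trace.cost_undiscounted)
        assert out.cost >= run_markov(
            "evt", params.copy(), "1y").cost  # rate already 0; sanity

    def test_horizon_nesting(self, base_params):
        for arm in ("evt", "evt_ivt"):
            res = {h: run_markov(arm, base_params, h, keep_trace=False)
                   for h in ("3m", "1y", "lifetime")}
            assert res["3m"].cost <= res["1y"].cost <= res["lifetime"].cost
            assert res["3m"].qaly <= res["1y"].qaly <= res["lifetime"].qaly

    def test_identical_arms_have_identical_outcomes(self, params):
        params.evt_ivt.mrs_3m = params.evt.mrs_3m
        params.evt_ivt.direct_treatment = params.evt.direct_treatment
        params.evt_ivt.components = dict(params.evt.components)
        for h in ("3m", "1y", "lifetime"):
            a = run_markov("evt", params, h, keep_trace=False)
            b = run_markov("evt_ivt", params, h, keep_trace=False)
            assert b.cost == pytest.approx(a.cost, abs=1e-9)
            assert b.qaly == pytest.approx(a.qaly, abs=1e-12)

    def test_fast_path_matches_run_markov(self, base_params):
        for arm in ("evt", "evt_ivt"):
            fast = evaluate_arm_horizons(arm, base_params)
            for h in ("3m", "1y", "lifetime"):
                out = run_markov(arm, base_params, h, keep_trace=False)
                assert fast[h][0] == pytest.approx(out.cost, abs=1e-6)
                assert fast[h][1] == pytest.approx(out.qaly, abs=1e-9)

    def test_trace_dataframe_shape(self, base_params):
        out = run_markov("evt", base_params, "1y")
        df = out.trace.to_dataframe()
        assert len(df) == 4  # cycle 0 + three Markov cycles
        assert df["cumulative_mortality"].is_monotonic_increasing


class TestMicrosimulationOracle:
    def test_cohort_model_matches_individual_simulation(self, base_params):
        """Expected totals from 1e5 simulated patients reproduce the
        cohort model's discounted cost and QALY within 3 standard errors."""
        cohort = run_markov("evt", base_params, "lifetime",
                            keep_trace=False)
        mc_cost, mc_qaly, se_cost, se_qaly = microsimulate_arm(
            "evt", base_params, n_patients=100_000, seed=7,
            n_cycles=cohort.cycles_run)
        assert abs(mc_cost - cohort.cost) < 3 * se_cost
        assert abs(mc_qaly - cohort.qaly) < 3 * se_qaly
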