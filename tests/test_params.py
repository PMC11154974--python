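"""Parameter loading, validation and distribution-fitting behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strokecea import (
    ConfigurationError,
    ValidationError,
    annual_to_cycle_probability,
    beta_from_mean_ci,
    compute_indirect_cost,
    dirichlet_from_proportions,
    gamma_from_mean_ci,
    load_parameters,
    parameters_from_dict,
    residual_death_probability,
)
from strokecea.params import MRSDistribution


class TestLoadParameters:
    @pytest.mark.parametrize("accessor, expected", [
        (lambda p: p.evt.direct_treatment.mean, 71329.86),
        (lambda p: p.evt.direct_treatment.lo, 69890.76),
        (lambda p: p.evt.direct_treatment.hi, 72768.96),
        (lambda p: p.evt_ivt.direct_treatment.mean, 108463.60),
        (lambda p: p.evt.mrs_3m.p_good, 0.4900),
        (lambda p: p.evt.mrs_3m.p_poor, 0.3519),
        (lambda p: p.evt.mrs_3m.p_dead, 0.1581),
        (lambda p: p.evt_ivt.mrs_3m.p_good, 0.5073),
        (lambda p: p.evt_ivt.mrs_3m.p_poor, 0.3443),
        (lambda p: p.evt_ivt.mrs_3m.p_dead, 0.1484),
        (lambda p: p.transitions.p_good_to_good, 0.9550),
        (lambda p: p.transitions.p_good_to_poor, 0.0240),
        (lambda p: p.transitions.p_poor_to_good, 0.0290),
        (lambda p: p.transitions.p_poor_to_poor, 0.9190),
        (lambda p: p.transitions.recurrence_annual, 0.0960),
        (lambda p: p.costs.post_hosp_annual_good.mean, 7385.00),
        (lambda p: p.costs.post_hosp_annual_poor.mean, 11350.00),
        (lambda p: p.costs.indirect_total, 57595.37),
        (lambda p: p.costs.dalys, 7.95),
        (lambda p: p.utilities.u_good.mean, 0.76),
        (lambda p: p.utilities.u_poor.mean, 0.21),
        (lambda p: p.utilities.u_dead, 0.00),
        (lambda p: p.utilities.u_recurrent.mean, 0.20),
        (lambda p: p.economics.discount_annual, 0.03),
        (lambda p: p.economics.wtp_low, 90620),
        (lambda p: p.economics.wtp_high, 271860),
        (lambda p: p.evt.components["operative_materials"], 43751.21),
        (lambda p: p.evt_ivt.components["nursing"], 3035.45),
    ])
    def test_default_config_reproduces_published_inputs(
            self, base_params, accessor, expected):
        assert accessor(base_params) == pytest.approx(expected, abs=1e-12)

    def test_round_trip_is_lossless(self, base_params):
        rebuilt = parameters_from_dict(base_params.to_dict())
        assert rebuilt == base_params

    def test_missing_key_names_the_key(self, tmp_path, base_params):
        cfg = base_params.to_dict()
        del cfg["utilities"]["recurrent"]
        with pytest.raises(ConfigurationError, match="utilities.recurrent"):
            parameters_from_dict(cfg)

    def test_invalid_simplex_rejected(self, base_params):
        cfg = base_params.to_dict()
        cfg["arms"]["evt"]["mrs_3m"] = {"good": 0.5, "poor": 0.6,
                                        "dead": -0.1}
        with pytest.raises(ValidationError):
            parameters_from_dict(cfg)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(ConfigurationError):
            load_parameters(tmp_path / "nope.yaml")

    def test_value_per_daly_backsolved(self, base_params):
        co = base_params.costs
        assert co.value_per_daly * co.dalys == pytest.approx(
            co.indirect_total, abs=1e-9)


class TestProbabilityPlumbing:
    def test_annual_to_cycle_examples(self):
        assert annual_to_cycle_probability(0.0, 4) == 0.0
        assert annual_to_cycle_probability(0.5, 1) == 0.5
        assert annual_to_cycle_probability(0.096, 4) == pytest.approx(
            1.0 - 0.904 ** 0.25, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(p=st.floats(0.0, 0.95), n=st.integers(1, 12))
    def test_cycle_probability_compounds_back_to_annual(self, p, n):
        pc = annual_to_cycle_probability(p, n)
        assert (1.0 - pc) ** n == pytest.approx(1.0 - p, abs=1e-12)

    def test_annual_probability_domain(self):
        with pytest.raises(ValidationError):
            annual_to_cycle_probability(1.0, 4)
        with pytest.raises(ValidationError):
            annual_to_cycle_probability(-0.1, 4)

    def test_residual_death_from_published_rows(self):
        assert residual_death_probability((0.955, 0.024)) == pytest.approx(
            0.021, abs=1e-12)
        assert residual_death_probability((0.919, 0.029)) == pytest.approx(
            0.052, abs=1e-12)
        assert residual_death_probability((1.0,)) == 0.0
        with pytest.raises(ValidationError):
            residual_death_probability((0.9, 0.2))


class TestDistributionFits:
    def test_gamma_fit_matches_closed_form(self):
        spec = gamma_from_mean_ci(71329.86, 69890.76, 72768.96)
        sd = (72768.96 - 69890.76) / 3.92
        assert spec.parameters["shape"] == pytest.approx((71329.86 / sd) ** 2)
        assert spec.parameters["scale"] == pytest.approx(sd ** 2 / 71329.86)
        # spot values from the moment formulas
        assert spec.parameters["shape"] == pytest.approx(9437.9, rel=1e-3)
        assert spec.parameters["scale"] == pytest.approx(7.558, rel=1e-3)

    def test_gamma_fit_rejects_bad_intervals(self):
        with pytest.raises(ValidationError):
            gamma_from_mean_ci(1.0, 1.0 - 1.96, 1.5)
        with pytest.raises(ValidationError):
            gamma_from_mean_ci(10.0, 12.0, 14.0)

    @settings(derandomize=True, max_examples=100)
    @given(mean=st.floats(0.5, 1e6),
           rel_half=st.floats(0.001, 0.8))
    def test_gamma_moment_round_trip(self, mean, rel_half):
        lo, hi = mean * (1 - rel_half), mean * (1 + rel_half)
        spec = gamma_from_mean_ci(mean, lo, hi)
        assert spec.mean() == pytest.approx(mean, rel=1e-9)
        assert spec.sd() == pytest.approx((hi - lo) / 3.92, rel=1e-9)

    def test_beta_fit_published_utility(self):
        spec = beta_from_mean_ci(0.76, 0.69, 0.82)
        assert spec.parameters["alpha"] == pytest.approx(125.3, rel=1e-2)
        assert spec.parameters["beta"] == pytest.approx(39.6, rel=1e-2)
        assert spec.mean() == pytest.approx(0.76, abs=1e-12)

    def test_beta_fit_symmetric_and_mean_recovery(self):
        sym = beta_from_mean_ci(0.5, 0.49, 0.51)
        assert sym.parameters["alpha"] == pytest.approx(
            sym.parameters["beta"], rel=1e-12)
        spec = beta_from_mean_ci(0.21, 0.17, 0.26)
        a, b = spec.parameters["alpha"], spec.parameters["beta"]
        assert a / (a + b) == pytest.approx(0.21, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(mean=st.floats(0.05, 0.95), rel=st.floats(0.01, 0.3))
    def test_beta_moment_round_trip(self, mean, rel):
        lo, hi = mean * (1 - rel), min(mean * (1 + rel), 0.999)
        spec = beta_from_mean_ci(mean, lo, hi)
        assert spec.mean() == pytest.approx(mean, rel=1e-9)
        assert spec.sd() == pytest.approx((hi - lo) / 3.92, rel=1e-9)

    def test_beta_infeasible_variance_rejected(self):
        # interval nearly the whole unit line around a mean near 0:
        # (hi-lo)/3.92 squared exceeds mean*(1-mean)
        with pytest.raises(ValidationError):
            beta_from_mean_ci(0.01, 0.0005, 0.999)

    def test_dirichlet_concentrations_and_means(self):
        spec = dirichlet_from_proportions((0.49, 0.3519, 0.1581), 600)
        assert spec.parameters["concentration"] == pytest.approx(
            (294.0, 211.14, 94.86), abs=1e-9)
        assert spec.mean() == pytest.approx((0.49, 0.3519, 0.1581),
                                            abs=1e-12)

    def test_dirichlet_zero_component_floored(self):
        spec = dirichlet_from_proportions((1.0, 0.0, 0.0), 100)
        conc = spec.parameters["concentration"]
        assert conc[1] == pytest.approx(1e-4)
        assert conc[0] == pytest.approx(100.0)

    def test_dirichlet_sampled_means_converge(self):
        spec = dirichlet_from_proportions((0.5073, 0.3443, 0.1484), 600)
        rng = np.random.default_rng(0)
        draws = spec.sample(rng, size=100_000)
        assert draws.mean(axis=0) == pytest.approx(
            (0.5073, 0.3443, 0.1484), abs=0.003)

    def test_dirichlet_rejects_bad_inputs(self):
        with pytest.raises(ValidationError):
            dirichlet_from_proportions((0.5, 0.5, 0.0), 0)
        with pytest.raises(ValidationError):
            dirichlet_from_proportions((0.5, 0.2, 0.2), 100)

    def test_gamma_sampling_recovers_mean(self):
        spec = gamma_from_mean_ci(7385.0, 7157.0, 7619.0)
        assert spec.parameters["shape"] == pytest.approx(3925.6, rel=1e-3)
        rng = np.random.default_rng(0)
        draws = spec.sample(rng, size=1_000_000)
        assert draws.mean() == pytest.approx(7385.0, rel=1e-3)


class TestIndirectCost:
    def test_published_total_recovered(self):
        assert compute_indirect_cost(7.95, 57595.37 / 7.95, 0.0) == \
            pytest.approx(57595.37, abs=1e-9)

    def test_trivial_cases(self):
        assert compute_indirect_cost(0.0, 1234.0, 0.05) == 0.0
        assert compute_indirect_cost(1.0, 100.0, 0.0) == 100.0

    def test_discounting_reduces_value(self):
        undisc = compute_indirect_cost(7.95, 7244.70, 0.0)
        disc = compute_indirect_cost(7.95, 7244.70, 0.03)
        assert 0 < disc < undisc

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            compute_indirect_cost(-1.0, 100.0, 0.0)
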