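"""Core neuronal operations: magnesium switch, firing, drift, equilibrium."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import root

from nmda_dcm import (
    MicrocircuitParameters, ModelConfig, PopulationState, alpha_from_blockade,
    firing_rate, fixed_point, mg_switch, mg_switch_standard, population_drift,
)
from nmda_dcm.errors import InvalidParameterError, StructuralError
from nmda_dcm.microcircuit import drift_norm
from nmda_dcm.params import N_NODES


class TestBlockadeScale:
    @pytest.mark.parametrize("blk, expected", [
        (0.0, 1.0),
        (0.42, np.exp(0.42)),       # the drug-sized shift
        (-0.125, np.exp(-0.125)),   # the progression-sized shift
    ])
    def test_exponential_transform(self, blk, expected):
        assert alpha_from_blockade(blk) == pytest.approx(expected, rel=1e-12)

    def test_monotone_and_positive(self):
        blk = np.linspace(-3, 3, 41)
        a = alpha_from_blockade(blk)
        assert np.all(a > 0) and np.all(np.diff(a) > 0)

    @pytest.mark.parametrize("bad", [np.nan, np.inf, -np.inf])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            alpha_from_blockade(bad)


class TestMagnesiumSwitch:
    def test_saturation_modified(self):
        assert mg_switch(1e6, 0.0) == pytest.approx(1.50265, rel=1e-9)

    def test_saturation_standard(self):
        assert mg_switch_standard(1e6) == pytest.approx(1.5, rel=1e-9)

    def test_value_at_zero_voltage_independent_of_blockade(self):
        expected = 1.50265 / 1.33
        for blk in (-2.0, 0.0, 0.5, 4.0):
            assert mg_switch(0.0, blk) == pytest.approx(expected, rel=1e-12)

    def test_bounds_on_grid(self):
        V, B = np.meshgrid(np.linspace(-120, 60, 49), np.linspace(-2, 2, 25))
        m = mg_switch(V, B)
        assert np.all(m > 0) and np.all(m < 1.50265)

    def test_strictly_increasing_in_voltage(self):
        V = np.linspace(-100, 40, 141)
        for blk in (-1.0, 0.0, 2.0):
            assert np.all(np.diff(mg_switch(V, blk)) > 0)

    def test_blockade_reduces_output_at_hyperpolarised_voltage(self):
        out = mg_switch(-70.0, np.array([-1.0, 0.0, 1.0, 2.0, 4.0]))
        assert np.all(np.diff(out) < 0)

    def test_blockade_direction_flips_with_voltage_sign(self):
        blks = np.linspace(-1, 2, 13)
        assert np.all(np.diff(mg_switch(-20.0, blks)) < 0)
        assert np.all(np.diff(mg_switch(+20.0, blks)) > 0)

    def test_standard_form_matches_modified_at_prior_mean_up_to_numerator(self):
        V = np.linspace(-100, 50, 151)
        ratio = mg_switch(V, 0.0) / mg_switch_standard(V)
        assert np.allclose(ratio, 1.50265 / 1.5, rtol=1e-12)


class TestFiringRate:
    def test_midpoint(self):
        assert firing_rate(-40.0, slope=0.1, threshold=-40.0) == 0.5

    def test_saturation(self):
        assert firing_rate(-1e4) < 1e-10
        assert firing_rate(1e4) > 1 - 1e-10

    def test_steeper_slope_increases_suprathreshold_output(self):
        v = -20.0
        assert firing_rate(v, slope=0.2) > firing_rate(v, slope=0.1)

    @pytest.mark.parametrize("slope", [0.0, -1.0, np.nan])
    def test_bad_slope_rejected(self, slope):
        with pytest.raises(InvalidParameterError):
            firing_rate(0.0, slope=slope)


class TestPopulationState:
    def test_negative_conductance_rejected(self):
        g = np.zeros(N_NODES)
        bad = g.copy()
        bad[3] = -0.1
        with pytest.raises(InvalidParameterError):
            PopulationState(np.full(N_NODES, -70.0), bad, g, g, g)

    def test_wrong_shape_rejected(self):
        with pytest.raises(StructuralError):
            PopulationState(np.zeros(3), np.zeros(3), np.zeros(3),
                            np.zeros(3), np.zeros(3))

    def test_vector_round_trip(self, rng):
        y = np.abs(rng.normal(size=5 * N_NODES))
        y[:N_NODES] *= -1
        state = PopulationState.from_vector(y)
        assert np.array_equal(state.to_vector(), y)


class TestDrift:
    def test_leak_equilibrium_with_silent_network(self):
        zeros = tuple(tuple(0.0 for _ in range(4)) for _ in range(4))
        cfg = ModelConfig(intrinsic_exc=zeros, intrinsic_inh=zeros,
                          forward_gain=0.0, backward_gain=0.0)
        p = MicrocircuitParameters(cfg, {})
        g0 = np.zeros(N_NODES)
        state = PopulationState(np.full(N_NODES, cfg.v_leak), g0, g0, g0,
                                np.full(N_NODES, cfg.g_leak))
        d = population_drift(state, p, u=0.0)
        assert np.max(np.abs(d.to_vector())) < 1e-14

    def test_drift_vanishes_at_fixed_point(self, config):
        p = MicrocircuitParameters(config, {"b_l": -0.4, "b_r": -0.4})
        for condition in (0, 1):
            fp = fixed_point(p, condition)
            assert drift_norm(p, fp, condition) < 1e-8

    def test_fixed_point_agrees_with_root_finding_oracle(self, config):
        p = MicrocircuitParameters(config, {"blk_l": 0.2, "b_l": -0.4, "b_r": -0.4})
        fp = fixed_point(p, 0)

        def fun(y):
            return population_drift(
                PopulationState.from_vector(y, clip=True), p, 0.0, 0).to_vector()

        # start the oracle away from the implementation's answer
        y0 = fp.to_vector() + 0.5
        sol = root(fun, y0, method="hybr", tol=1e-12)
        assert sol.success
        assert np.max(np.abs(np.asarray(fun(sol.x)))) < 1e-8
        assert np.allclose(sol.x, fp.to_vector(), atol=1e-6)

    def test_small_perturbations_decay(self, config):
        from nmda_dcm import integrate_trial

        cfg = ModelConfig.from_dict({**config.to_dict(), "input_amplitude": 0.0})
        p = MicrocircuitParameters(cfg, {"b_l": -0.4, "b_r": -0.4})
        tr = integrate_trial(p, 0)
        # no input: trajectory stays at the equilibrium it started from
        assert np.max(np.abs(tr.voltage - tr.baseline)) < 1e-9

    def test_blockade_weakens_nmda_current_at_depolarised_state(self, config):
        g0 = np.zeros(N_NODES)
        gn = np.full(N_NODES, 0.5)
        state = PopulationState(np.full(N_NODES, -30.0), g0, g0, gn,
                                np.full(N_NODES, config.g_leak))
        d_low = population_drift(state, MicrocircuitParameters(config, {}), 0.0)
        high = MicrocircuitParameters(config, {"blk_l": 1.0, "blk_r": 1.0})
        d_high = population_drift(state, high, 0.0)
        # only the NMDA term differs; it is depolarising at V=-30, so the
        # voltage derivative must drop when the blockade increases
        assert np.all(d_high.V < d_low.V)


class TestNaturalScale:
    @given(st.lists(st.floats(-1.5, 1.5), min_size=11, max_size=11))
    def test_natural_parameters_strictly_positive(self, values):
        from nmda_dcm.params import LATENT_NAMES

        p = MicrocircuitParameters(ModelConfig(), dict(zip(LATENT_NAMES, values)))
        assert all(v > 0 for v in p.natural().values())

    def test_json_round_trip(self, tmp_path, config):
        p = MicrocircuitParameters(config, {"blk_l": 0.3, "b_r": -0.2})
        p.to_json(tmp_path / "p.json")
        q = MicrocircuitParameters.from_json(tmp_path / "p.json")
        assert q.latents == p.latents
        assert q.config.to_dict() == p.config.to_dict()
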