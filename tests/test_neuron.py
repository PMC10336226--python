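"""Unit tests for the single-population neuron dynamics."""

import numpy as np
import pytest

from ftsts import ModelParams
from ftsts.neuron import (PopulationState, apply_spike_reset, chloride_step,
                          conductance_step, membrane_step, nernst,
                          sample_spikes, threshold_step)


def _state(params, n=4, **overrides):
    s = PopulationState.resting(n, params)
    for key, val in overrides.items():
        getattr(s, key)[:] = val
    return s


class TestMembrane:
    def test_leak_equilibrium_is_fixed_point(self, params):
        s = _state(params)
        membrane_step(s, np.zeros(s.n), params)
        assert np.allclose(s.V, params.E_L)

    def test_capacitive_charging_rate(self, params):
        # 200 pA into 100 pF with conductances removed: dV/dt = 2 mV/ms
        p = ModelParams(g_L=0.0)
        s = _state(p)
        membrane_step(s, np.full(s.n, 200.0), p)
        assert np.allclose(s.V, p.E_L + 2.0 * p.dt)

    def test_balanced_leak_and_excitation_steady_state(self, params):
        # g_L = effective excitatory conductance = 4 nS: V* = (E_L+E_E)/2
        s = _state(params, g_E=4.0 / params.f_max)
        for _ in range(5000):
            membrane_step(s, np.zeros(s.n), params)
        assert np.allclose(s.V, (params.E_L + params.E_E) / 2.0)
        assert np.allclose(s.V, -28.5)

    def test_shape_mismatch_is_hard_error(self, params):
        s = _state(params)
        with pytest.raises(ValueError, match="shape"):
            membrane_step(s, np.zeros(s.n + 1), params)

    def test_nonfinite_voltage_names_step(self, params):
        s = _state(params)
        s.V[0] = np.inf
        with pytest.raises(FloatingPointError, match="step 3"):
            membrane_step(s, np.zeros(s.n), params, step=3)


class TestSpiking:
    def test_vanishing_rate_never_spikes(self, params):
        rng = np.random.default_rng(0)
        s = _state(params, V=-500.0)
        for k in range(200):
            assert not sample_spikes(s, params, rng, k * params.dt).any()

    def test_refractory_forbids_spiking(self, params):
        rng = np.random.default_rng(0)
        s = _state(params, V=100.0)  # astronomically suprathreshold
        s.t_last_spike[:] = 10.0 - 2.0  # spiked 2 ms ago
        assert not sample_spikes(s, params, rng, 10.0).any()
        # once tau_ref has elapsed the same state spikes with certainty
        assert sample_spikes(s, params, rng, 10.0 + 3.1).all()

    def test_empirical_rate_at_threshold_matches_f0(self, params):
        # V = phi held fixed: rate must be f0 = 2 Hz within 3 SE
        rng = np.random.default_rng(1234)
        n, steps = 200, 120000
        p = ModelParams(tau_ref=1e-9)  # isolate the Poisson sampling
        s = _state(p, n=n, V=p.phi0)
        count = 0
        for k in range(steps):
            count += int(sample_spikes(s, p, rng, k * p.dt).sum())
        total_time_s = n * steps * p.dt / 1000.0
        rate = count / total_time_s
        se = np.sqrt(count) / total_time_s
        assert abs(rate - p.f0) < 3.0 * se + 1e-9

    def test_spike_reset_averaging_rule(self, params):
        s = _state(params, V=-50.0)
        mask = np.array([True, False, False, False])
        apply_spike_reset(s, mask, params, t=7.0)
        assert s.V[0] == pytest.approx((40.0 - 50.0) / 2.0)  # -5 mV
        assert np.allclose(s.V[1:], -50.0)
        assert s.phi[0] == pytest.approx(params.phi0 + params.delta_phi)
        assert np.allclose(s.phi[1:], params.phi0)
        assert s.t_last_spike[0] == 7.0

    def test_averaging_fixed_point_at_40(self, params):
        s = _state(params, V=40.0)
        apply_spike_reset(s, np.ones(s.n, bool), params, t=0.0)
        assert np.allclose(s.V, 40.0)

    def test_reset_base_conventions(self):
        pre = ModelParams(reset_from_pre_average=True)
        post = ModelParams(reset_from_pre_average=False)
        for p, expected in ((pre, -50.0), (post, -5.0)):
            s = _state(p, V=-50.0)
            apply_spike_reset(s, np.ones(s.n, bool), p, t=0.0)
            assert np.allclose(s.v_spike, expected)


class TestThresholdAndConductances:
    def test_threshold_relaxes_to_phi0(self, params):
        s = _state(params, phi=-50.0)
        for _ in range(int(100.0 / params.dt)):  # 100 ms = tau_phi
            threshold_step(s, params)
        expected = params.phi0 + 5.0 * np.exp(-1.0)
        assert np.allclose(s.phi, expected, atol=0.05)

    def test_threshold_equilibrium(self, params):
        s = _state(params)
        threshold_step(s, params)
        assert np.allclose(s.phi, params.phi0)

    def test_threshold_monotone_decay(self, params):
        s = _state(params, phi=-40.0)
        prev = s.phi.copy()
        for _ in range(50):
            threshold_step(s, params)
            assert np.all(s.phi < prev)
            assert np.all(s.phi > params.phi0)
            prev = s.phi.copy()

    def test_synaptic_decay_matches_exponential(self, params):
        s = _state(params, g_E=10.0)
        none = np.zeros(s.n, bool)
        for _ in range(int(15.0 / params.dt)):  # one tau_syn
            conductance_step(s, 0.0, 0.0, none, params)
        assert np.allclose(s.g_E, 10.0 * np.exp(-1.0), rtol=0.02)

    def test_sahp_increment_is_delta_K_over_tau_K(self, params):
        s = _state(params)
        spikes = np.array([True, False, False, False])
        conductance_step(s, 0.0, 0.0, spikes, params)
        assert s.g_K[0] == pytest.approx(40.0 / 5000.0)
        assert np.allclose(s.g_K[1:], 0.0)

    def test_all_conductances_decay_to_zero(self, params):
        s = _state(params, g_E=5.0, g_I=5.0, g_K=5.0)
        none = np.zeros(s.n, bool)
        for _ in range(100000):  # 50 s = 10 tau_K
            conductance_step(s, 0.0, 0.0, none, params)
        assert np.all(s.g_E < 1e-6) and np.all(s.g_I < 1e-6)
        assert np.all(s.g_K < 1e-3)

    def test_negative_input_is_hard_error(self, params):
        s = _state(params)
        with pytest.raises(ValueError):
            conductance_step(s, np.full(s.n, -1.0), 0.0,
                             np.zeros(s.n, bool), params)


class TestChloride:
    def test_equal_concentrations_give_zero_reversal(self, params):
        assert nernst(np.array([params.Cl_out]), params)[0] == 0.0

    def test_equilibrium_reversal_value(self, params):
        # -26.7 ln(110/6) ~ -77.6 mV
        e = nernst(np.array([6.0]), params)[0]
        assert e == pytest.approx(-26.7 * np.log(110.0 / 6.0))
        assert e == pytest.approx(-77.6, abs=0.1)

    def test_log10_flag(self):
        p = ModelParams(nernst_natural_log=False)
        assert nernst(np.array([6.0]), p)[0] == pytest.approx(
            -26.7 * np.log10(110.0 / 6.0))

    def test_reversal_monotone_in_gradient(self, params):
        cl = np.linspace(2.0, 110.0, 50)
        e = nernst(cl, params)
        assert np.all(np.diff(e) > 0)  # shrinking ratio -> higher E_Cl

    def test_perturbation_relaxes_to_equilibrium(self, params):
        s = _state(params, Cl_in=12.0, g_I=0.0)
        for k in range(int(5 * params.tau_Cl / params.dt)):
            chloride_step(s, params)
        assert np.allclose(s.Cl_in, params.Cl_in_eq, atol=0.1)

    def test_depolarized_gaba_loads_chloride(self, params):
        s = _state(params, g_I=50.0, V=-20.0)
        cl0 = s.Cl_in.copy()
        chloride_step(s, params)
        assert np.all(s.Cl_in > cl0)
        assert np.all(s.E_Cl > -77.7)


def test_state_snapshot_round_trip(tmp_path, params):
    s = _state(params, V=-40.0, g_E=2.0)
    s.t_last_spike[:] = 3.0
    path = tmp_path / "state.npz"
    s.save(path)
    back = PopulationState.load(path)
    assert np.array_equal(back.V, s.V)
    assert np.array_equal(back.g_E, s.g_E)
    assert np.array_equal(back.t_last_spike, s.t_last_spike)
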