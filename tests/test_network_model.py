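"""Oscillator network: connectivity, drive, integration correctness."""

import numpy as np
import pytest
from dataclasses import replace

from oscistim.network_model import (
    IntegrationDivergedError,
    NetworkParams,
    StimulusProtocol,
    ablated,
    build_connectivity,
    ecog_recording,
    sigmoid_rate,
    simulate_network,
    stimulation_drive,
)


class TestConnectivity:
    def test_dense_limit_every_entry_is_one_over_n(self):
        conn = build_connectivity(50, 1.0, seed=0)
        for W in (conn.W_ee, conn.W_ei, conn.W_ie, conn.W_ii, conn.W1, conn.W2):
            np.testing.assert_allclose(W, 1.0 / 50)

    def test_nonzero_entries_share_the_scaled_value(self):
        conn = build_connectivity(80, 0.8, seed=1)
        nz = conn.W_ee[conn.W_ee != 0]
        np.testing.assert_allclose(nz, 1.0 / (0.8 * 80))

    def test_density_concentrates_around_rho(self):
        dens = [
            (build_connectivity(200, 0.8, seed=s).W_ee != 0).mean() for s in range(20)
        ]
        assert abs(np.mean(dens) - 0.8) < 0.03

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            build_connectivity(10, 1.5, seed=0)


class TestSigmoid:
    def test_midpoint(self):
        assert sigmoid_rate(np.array([-0.3]), h=-0.3)[0] == pytest.approx(0.5)

    def test_tenth_above_threshold(self):
        val = sigmoid_rate(np.array([0.1]), h=0.0)[0]
        assert val == pytest.approx(1.0 / (1.0 + np.exp(-3.5)), abs=1e-12)
        assert val == pytest.approx(0.9707, abs=1e-4)

    def test_point_symmetry_about_threshold(self):
        v = np.linspace(-2, 2, 41)
        h = 0.2
        np.testing.assert_allclose(
            sigmoid_rate(v, h) + sigmoid_rate(2 * h - v, h), 1.0, atol=1e-12
        )


class TestStimulationDrive:
    def setup_method(self):
        self.proto = StimulusProtocol(drive_mode="biphasic_exact")
        self.start = 5000.0  # ms

    def test_first_phase_is_positive(self):
        assert stimulation_drive(self.start + 0.1, self.proto) == pytest.approx(0.2)

    def test_second_phase_is_negative(self):
        assert stimulation_drive(self.start + 0.3, self.proto) == pytest.approx(-0.2)

    def test_zero_between_pulses_and_outside_epoch(self):
        assert stimulation_drive(self.start + 50.0, self.proto) == 0.0
        assert stimulation_drive(self.start - 1.0, self.proto) == 0.0
        assert stimulation_drive(self.start + 5000.0 + 1.0, self.proto) == 0.0

    def test_phases_must_fit_the_period(self):
        with pytest.raises(ValueError):
            StimulusProtocol(pulse_rate=10.0, phase_width=60_000.0)


def _leak_only(params: NetworkParams) -> NetworkParams:
    return replace(
        params, g_ee=0.0, g_ei=0.0, g_ie=0.0, g_ii=0.0, g1=0.0, g2=0.0, noise_D=0.0
    )


class TestIntegration:
    def test_linear_leak_fixed_point(self, small_net_kwargs):
        """Closed form: with pure leak dynamics V -> -(I_bias + I_state)/a."""
        params = _leak_only(small_net_kwargs["params"])
        proto = replace(small_net_kwargs["protocol"], amplitude=0.0)
        res = simulate_network(params, proto, "task", burn_in=1.0, keep_traces=True)
        expected = -(params.I_bias + 0.50) / params.a
        np.testing.assert_allclose(res.V_e[:, -1], expected, atol=1e-6)
        np.testing.assert_allclose(res.V_i[:, -1], 0.0, atol=1e-6)

    def test_ecog_is_population_average(self, small_net_kwargs):
        res = simulate_network(
            small_net_kwargs["params"], small_net_kwargs["protocol"], "eyes_open",
            keep_traces=True,
        )
        np.testing.assert_array_equal(res.ecog, (res.V_e + res.V_i).mean(axis=0))

    def test_seed_determinism(self, small_net_kwargs):
        a = simulate_network(small_net_kwargs["params"], small_net_kwargs["protocol"], "task")
        b = simulate_network(small_net_kwargs["params"], small_net_kwargs["protocol"], "task")
        np.testing.assert_array_equal(a.ecog, b.ecog)

    def test_unknown_state_rejected(self, small_net_kwargs):
        with pytest.raises(ValueError):
            simulate_network(small_net_kwargs["params"], small_net_kwargs["protocol"], "nap")

    def test_divergence_raises_with_step_index(self, small_net_kwargs):
        params = replace(small_net_kwargs["params"], g_ee=1e6, a=5.0, noise_D=0.0)
        with pytest.raises(IntegrationDivergedError, match="step"):
            simulate_network(params, small_net_kwargs["protocol"], "task", burn_in=0.5)

    @pytest.mark.parametrize("delay_name", ["D1", "D2"])
    def test_delay_onset_exactness(self, delay_name):
        """A perturbed initial condition propagates through a delayed loop
        only after exactly D/dt steps; before that the difference follows
        the pure-leak closed form."""
        dt = 0.5
        base = NetworkParams(N=4, dt=dt, noise_D=0.0, seed=3,
                             g_ee=0.0, g_ei=0.0, g_ie=0.0, g_ii=0.0,
                             g1=-0.5 if delay_name == "D1" else 0.0,
                             g2=0.0 if delay_name == "D1" else 0.85,
                             D1=20.0, D2=40.0)
        proto = StimulusProtocol(pre_duration=0.2, stim_duration=0.0, post_duration=0.0,
                                 amplitude=0.0)
        eps = 1e-3
        ref = simulate_network(base, proto, "eyes_closed", burn_in=0.0, keep_traces=True)
        per = simulate_network(base, proto, "eyes_closed", burn_in=0.0, keep_traces=True,
                               initial_v_e=np.full(4, eps))
        diff = per.V_e[0] - ref.V_e[0]
        d_steps = int((base.D1 if delay_name == "D1" else base.D2) / dt)
        decay = 1.0 + base.a * dt / base.tau_e
        expected = eps * decay ** np.arange(len(diff))
        # pure leak until the delayed feedback first sees the perturbation
        np.testing.assert_allclose(diff[: d_steps + 1], expected[: d_steps + 1], rtol=1e-9)
        assert abs(diff[d_steps + 1] - expected[d_steps + 1]) > 1e-12

    def test_ou_stationary_variance_matches_closed_form(self):
        """With all couplings silent each unit is an OU process with
        stationary variance D / (|a| tau)."""
        params = _leak_only(NetworkParams(N=4, dt=0.5, seed=8))
        params = replace(params, noise_D=0.01, I_bias=0.0)
        proto = StimulusProtocol(pre_duration=100.0, stim_duration=0.0, post_duration=0.0,
                                 amplitude=0.0)
        res = simulate_network(params, proto, "eyes_closed", burn_in=2.0, keep_traces=True)
        var = res.V_e[0].var()
        expected = params.noise_D / (abs(params.a) * params.tau_e)
        assert var == pytest.approx(expected, rel=0.10)


class TestHelpers:
    def test_ablation_variants(self):
        p = NetworkParams()
        assert ablated(p, "thalamic").g1 == 0.0
        assert ablated(p, "cortical").g2 == 0.0
        assert ablated(p, None) is p
        with pytest.raises(ValueError):
            ablated(p, "limbic")

    def test_ecog_recording_resamples_and_annotates(self, small_net_kwargs):
        res = simulate_network(small_net_kwargs["params"], small_net_kwargs["protocol"], "task")
        rec = ecog_recording(res, target_rate=800.0)
        assert rec.sample_rate == 800.0
        assert rec.n_samples == int(3.0 * 800)
        assert rec.trial_onsets[0] == int(1.0 * 800)

    def test_delays_must_be_divisible_by_dt(self):
        with pytest.raises(ValueError):
            NetworkParams(D1=0.35, dt=0.2)
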