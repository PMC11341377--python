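"""Simulators: closed-form rates, cascade response, coordinate maps, cross-model checks."""

import math

import numpy as np
import pytest

from qifks import (
    NetworkParams,
    QIFConfig,
    SynapticCascade,
    SynapticKernel,
    Trajectory,
    detect_spikes,
    gamma_kernel_value,
    map_coordinates,
    simulate_ks,
    simulate_qif,
    simulate_theta,
    simulate_winfree_phase,
    KSParams,
)

PERIOD = np.pi / np.sqrt(2)  # uncoupled Type I period at eta = 2


def _uncoupled(N=1, eta=2.0, nu=20):
    return NetworkParams(N=max(N, 2), eta=np.full(max(N, 2), eta), kappa=0.0,
                         nu=nu, kernel=SynapticKernel(0, 1.0))


class TestThetaNetwork:
    def test_uncoupled_firing_rate_matches_closed_form(self):
        traj, spikes = simulate_theta(_uncoupled(), np.array([0.0, 1.0]), T=100.0)
        isi = np.diff(spikes.of_neuron(0))
        assert isi.mean() == pytest.approx(PERIOD, abs=1e-3)
        assert len(spikes.of_neuron(0)) in (int(100 * np.sqrt(2) / np.pi), int(100 * np.sqrt(2) / np.pi) + 1)

    def test_spike_time_error_shrinks_with_step(self):
        # linear-interpolation spike timing is second order: halving dt
        # should shrink the error by >= 3.5x
        errs = []
        for dt in (0.02, 0.01):
            _, spikes = simulate_theta(_uncoupled(), np.array([0.0, 0.0]), dt=dt, T=40.0)
            t = spikes.of_neuron(0)
            k = np.arange(1, len(t) + 1)
            # theta(0)=0 is half a period before the first pi-crossing
            errs.append(np.abs(t - (k - 0.5) * PERIOD).max())
        assert errs[0] / errs[1] >= 3.5

    def test_trajectory_phases_are_wrapped(self):
        traj, _ = simulate_theta(_uncoupled(), np.array([0.0, 2.0]), T=10.0)
        assert np.all(traj.states > -np.pi) and np.all(traj.states <= np.pi)

    def test_delta_pulse_coupling_drives_cascade(self):
        p = NetworkParams(N=2, eta=np.array([2.0, 2.0]), kappa=-0.3, nu=math.inf,
                          kernel=SynapticKernel(1, 0.3))
        traj, spikes = simulate_theta(p, np.array([0.0, 1.0]), T=20.0)
        assert len(spikes) > 0
        assert traj.synaptic.max() > 0.0


class TestQIFNetwork:
    def test_uncoupled_interspike_interval(self):
        cfg = QIFConfig(network=_uncoupled(nu=math.inf), v_th=1e5, v_r=-1e5, T=60.0)
        _, spikes = simulate_qif(cfg, np.array([0.0, 1.0]))
        assert np.diff(spikes.of_neuron(0)).mean() == pytest.approx(PERIOD, abs=1e-3)

    def test_pass_through_mode_includes_transit_time(self):
        cfg = QIFConfig(network=_uncoupled(nu=math.inf), v_th=1e5, v_r=-1e5, T=60.0,
                        refractory_mode="pass_through")
        _, spikes = simulate_qif(cfg, np.array([0.0, 1.0]))
        assert np.diff(spikes.of_neuron(0)).mean() == pytest.approx(PERIOD, abs=1e-3)

    def test_excitable_regime_never_spikes(self):
        # eta < 0: rest state exists, no firing without input
        p = NetworkParams.__new__(NetworkParams)  # bypass eta>0 check deliberately
        object.__setattr__(p, "N", 2)
        object.__setattr__(p, "eta", np.array([-1.0, -0.5]))
        object.__setattr__(p, "kappa", 0.0)
        object.__setattr__(p, "nu", math.inf)
        object.__setattr__(p, "kernel", SynapticKernel(0, 1.0))
        cfg = QIFConfig(network=p, v_th=1e5, v_r=-1e5, T=50.0)
        _, spikes = simulate_qif(cfg, np.array([0.0, -0.9]))
        assert len(spikes) == 0

    def test_agrees_with_theta_network_spike_times(self):
        cfg = QIFConfig(network=_uncoupled(nu=math.inf), v_th=1e5, v_r=-1e5, T=120.0)
        _, sp_q = simulate_qif(cfg, np.array([0.0, 0.0]))
        _, sp_t = simulate_theta(_uncoupled(), np.array([0.0, 0.0]), T=120.0)
        n = min(50, len(sp_q.of_neuron(0)), len(sp_t.of_neuron(0)))
        gap = np.abs(sp_q.of_neuron(0)[:n] - sp_t.of_neuron(0)[:n])
        assert gap.max() <= 2 * 0.01 + 2 / 1e5

    def test_initial_voltage_above_threshold_rejected(self):
        cfg = QIFConfig(network=_uncoupled(nu=math.inf), v_th=100.0, v_r=-100.0, T=1.0)
        with pytest.raises(ValueError):
            simulate_qif(cfg, np.array([200.0, 0.0]))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            QIFConfig(network=_uncoupled(nu=math.inf), v_th=-1.0, v_r=-2.0)
        with pytest.raises(ValueError):
            QIFConfig(network=_uncoupled(nu=math.inf), refractory_mode="bogus")


class TestSynapticCascade:
    @pytest.mark.parametrize("q, tau", [(0, 0.5), (1, 0.3), (4, 0.15)])
    def test_impulse_response_reproduces_kernel(self, q, tau):
        N = 21
        kernel = SynapticKernel(q, tau)
        c = SynapticCascade(kernel, N)
        c.inject()
        dt = 0.002
        t = np.arange(0, 2.0 + dt / 2, dt)
        S = np.empty_like(t)
        S[0] = c.S
        for i in range(1, t.size):
            c.step(dt)
            S[i] = c.S
        assert np.abs(S - gamma_kernel_value(t, kernel) / N).max() < 1e-6

    def test_output_is_last_stage(self):
        c = SynapticCascade(SynapticKernel(3, 0.2), 5)
        assert c.stages.size == 4
        c.stages[-1] = 0.7
        assert c.S == 0.7


class TestWinfreePhaseModel:
    def test_uncoupled_rotates_uniformly(self):
        Om = 2.5
        eta = np.full(2, Om * Om / 4)  # zero detuning
        p = NetworkParams(N=2, eta=eta, kappa=0.0, nu=20, kernel=SynapticKernel(0, 1.0))
        phi0 = np.array([0.3, -2.0])
        traj = simulate_winfree_phase(p, Om, phi0, T=10.0)
        expected = np.angle(np.exp(1j * (phi0[:, None] + Om * traj.times[None, :])))
        assert np.abs(np.angle(np.exp(1j * (traj.states - expected)))).max() < 1e-9

    def test_identical_to_theta_model_at_omega_two(self):
        eta = np.array([1.0, 1.1, 0.9])  # Omega = 2 is the uncoupled frequency at eta=1
        p = NetworkParams(N=3, eta=eta, kappa=-0.2, nu=20, kernel=SynapticKernel(1, 0.4))
        x0 = np.array([0.5, -1.0, 2.5])
        traj_t, sp_t = simulate_theta(p, x0, T=30.0)
        traj_w = simulate_winfree_phase(p, 2.0, x0, T=30.0)
        dev = np.abs(np.angle(np.exp(1j * (traj_t.states - traj_w.states))))
        assert dev.max() < 1e-9
        sp_w = detect_spikes(traj_w)
        n = min(len(sp_t), len(sp_w))
        assert np.abs(sp_t.times[:n] - sp_w.times[:n]).max() <= 2 * 0.01


class TestKSModel:
    def test_attractive_pair_synchronizes(self):
        ks = KSParams(omega=np.zeros(2), K=1.0, alpha=0.0, Omega=2.6)
        traj = simulate_ks(ks, np.array([0.0, 2.0]), T=40.0)
        d = abs(np.angle(np.exp(1j * (traj.states[0, -1] - traj.states[1, -1]))))
        assert d < 1e-6

    def test_repulsive_pair_settles_antiphase(self):
        ks = KSParams(omega=np.zeros(2), K=-1.0, alpha=0.0, Omega=2.6)
        traj = simulate_ks(ks, np.array([0.0, 2.0]), T=40.0)
        d = abs(np.angle(np.exp(1j * (traj.states[0, -1] - traj.states[1, -1]))))
        assert d == pytest.approx(np.pi, abs=1e-6)

    def test_spike_reconstruction_uses_fast_rotation(self):
        ks = KSParams(omega=np.zeros(2), K=0.0, alpha=0.0, Omega=2.0)
        traj = simulate_ks(ks, np.array([0.0, 0.0]), T=10.0)
        spikes = detect_spikes(traj)
        # fast phase Omega*t crosses pi at t = pi/2 + k*pi
        expected = np.pi / 2 + np.pi * np.arange(3)
        got = spikes.of_neuron(0)[:3]
        assert got == pytest.approx(expected, abs=1e-9)


class TestDetectSpikes:
    def test_linear_ramp_crossing_is_exact(self):
        times = np.array([1.49, 1.51])
        states = np.array([[np.pi - 0.01, np.pi + 0.01]])  # crosses pi at t = 1.5
        traj = Trajectory(times=times, states=np.angle(np.exp(1j * states)),
                          synaptic=None, model_tag="theta")
        spikes = detect_spikes(traj)
        assert len(spikes) == 1
        assert spikes.times[0] == pytest.approx(1.5, abs=1e-6)

    def test_subthreshold_trace_is_empty(self):
        traj = Trajectory(times=np.linspace(0, 1, 11),
                          states=np.full((3, 11), 0.2), synaptic=None, model_tag="theta")
        assert len(detect_spikes(traj)) == 0

    def test_count_matches_closed_form_rate(self):
        traj, _ = simulate_theta(_uncoupled(), np.array([0.0, 0.0]), T=100.0)
        spikes = detect_spikes(traj)
        expected = int(100 * np.sqrt(2) / np.pi)
        assert abs(len(spikes.of_neuron(0)) - expected) <= 1

    def test_voltage_rule_on_qif_trajectory(self):
        cfg = QIFConfig(network=_uncoupled(nu=math.inf), v_th=1e5, v_r=-1e5, T=30.0)
        traj, online = simulate_qif(cfg, np.array([0.0, 0.0]))
        post = detect_spikes(traj, {"kind": "voltage", "v_th": 50.0})
        # threshold-50 crossings precede the v_th=1e5 spikes by ~1/50 time units
        n = min(len(online.of_neuron(0)), len(post.of_neuron(0)))
        assert n > 0
        assert np.all(post.of_neuron(0)[:n] <= online.of_neuron(0)[:n])
        assert np.abs(post.of_neuron(0)[:n] - online.of_neuron(0)[:n]).max() < 0.05


class TestCoordinateMaps:
    def test_fixed_points(self):
        assert map_coordinates(0.0, "v_to_theta") == 0.0
        assert map_coordinates(0.0, "theta_to_phi", 2.639) == 0.0
        assert map_coordinates(np.pi, "theta_to_phi", 2.639) == pytest.approx(np.pi)

    def test_identity_at_omega_two(self, rng):
        x = rng.uniform(-3, 3, 100)
        assert map_coordinates(x, "theta_to_phi", 2.0) == pytest.approx(x)
        assert map_coordinates(x, "phi_to_theta", 2.0) == pytest.approx(x)

    def test_round_trip(self, rng):
        phi = rng.uniform(-np.pi + 0.01, np.pi - 0.01, 200)
        back = map_coordinates(
            map_coordinates(phi, "phi_to_theta", 2.639), "theta_to_phi", 2.639
        )
        assert np.abs(back - phi).max() < 1e-12

    def test_branch_consistency_for_unwrapped_phases(self):
        # continuity across branch cuts: unwrapped input stays unwrapped
        phi = np.linspace(-3 * np.pi, 3 * np.pi, 1001)
        th = map_coordinates(phi, "phi_to_theta", 2.639)
        assert np.all(np.diff(th) > 0)
        assert np.abs(th - phi).max() < np.pi  # same branch throughout

    def test_infinity_sentinels(self):
        assert map_coordinates(np.inf, "v_to_theta") == pytest.approx(np.pi)
        assert map_coordinates(-np.inf, "v_to_theta") == pytest.approx(-np.pi)
        assert np.isposinf(map_coordinates(np.pi, "theta_to_v"))
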