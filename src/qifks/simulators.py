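"""Fixed-step simulators for the three model levels and the synaptic cascade.

Three descriptions of the same pulse-coupled network are integrated with a
shared classical 4th-order Runge-Kutta scheme (default dt = 0.01):

* the QIF network  dv_n/dt = v_n^2 + eta_n + kappa S(t)  with threshold
  reset, where the synaptic drive S(t) filters the population spike train;
* the theta-neuron network  dtheta_n/dt = (1 - cos theta_n)
  + (1 + cos theta_n)(eta_n + kappa S(t)), spiking when theta crosses pi;
* the Winfree-form phase model in the uniformly rotating coordinate phi,
  and the reduced Kuramoto-Sakaguchi (KS) model for the slow phases.

The gamma kernel is realised as its equivalent cascade of q+1 first-order
stages (tau u1' + u1 = input, tau u_{k+1}' + u_{k+1} = u_k, S = u_{q+1});
a delta spike enters as an instantaneous jump u1 += 1/(N tau), applied at
the end of the step containing the (interpolated) spike time.  This is the
exact Green's-function realisation of the kernel, with no convolution
storage.

QIF integration near threshold.  With v_th = 1e5 the quadratic blow-up
crosses the threshold faster than any fixed step resolves in v itself, so
whenever |v| exceeds a hand-off value the integrator follows the exact
inverse coordinate w = 1/v, whose dynamics

    dw/dt = -1 - (eta + kappa S) w^2

is smooth and nearly linear through the spike (w decreasing through 1/v_th,
then through 0 as v passes +/- infinity).  This is an exact change of
variables, not an approximation; spike times are read off by linear
interpolation of w, which is itself accurate to the same order.  The default
reset jumps to v_r at the interpolated crossing; ``refractory_mode =
"pass_through"`` instead lets w run on through the singularity, which takes
the transit time ~ 1/v_th + 1/|v_r| to reach v_r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kernels import SynapticKernel
from .pulses import pulse_value, transformed_pulse_value
from .reduction import KSParams, NetworkParams

__all__ = [
    "QIFConfig",
    "SpikeTrain",
    "Trajectory",
    "SynapticCascade",
    "simulate_qif",
    "simulate_theta",
    "simulate_winfree_phase",
    "simulate_ks",
    "detect_spikes",
    "map_coordinates",
]


@dataclass(frozen=True)
class QIFConfig:
    """Integration settings for the QIF network."""

    network: NetworkParams
    v_th: float = 1e5
    v_r: float = -1e5
    dt: float = 0.01
    T: float = 200.0
    refractory_mode: str = "none"  # or "pass_through"

    def __post_init__(self) -> None:
        if not (self.v_th > 0 > self.v_r):
            raise ValueError("require v_th > 0 > v_r")
        if self.refractory_mode not in ("none", "pass_through"):
            raise ValueError(f"unknown refractory_mode {self.refractory_mode!r}")
        if not (0 < self.dt < self.T):
            raise ValueError("require 0 < dt < T")


@dataclass(frozen=True)
class SpikeTrain:
    """Timestamped spike events of a network run."""

    neurons: np.ndarray  # int, sorted by time
    times: np.ndarray  # float, within [0, T]
    n_neurons: int

    @classmethod
    def from_events(cls, events: list[tuple[int, float]], n_neurons: int) -> "SpikeTrain":
        if events:
            ev = sorted(events, key=lambda e: e[1])
            neurons = np.array([e[0] for e in ev], dtype=int)
            times = np.array([e[1] for e in ev], dtype=float)
        else:
            neurons = np.empty(0, dtype=int)
            times = np.empty(0, dtype=float)
        return cls(neurons=neurons, times=times, n_neurons=n_neurons)

    def __len__(self) -> int:
        return self.times.size

    def of_neuron(self, n: int) -> np.ndarray:
        return self.times[self.neurons == n]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"neuron_id": self.neurons, "time": self.times})


@dataclass(frozen=True)
class Trajectory:
    """State time series of one model run.

    ``states`` has shape (N, n_samples): wrapped phases in (-pi, pi] for the
    phase models, membrane potentials for the QIF model, slow phases for the
    KS model (whose fast phase is Omega*t + state, with Omega recorded in
    ``omega_fast``).
    """

    times: np.ndarray
    states: np.ndarray
    synaptic: np.ndarray | None
    model_tag: str  # qif | theta | winfree_phase | ks
    omega_fast: float | None = None
    meta: dict = field(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd

        n, s = self.states.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, n),
                "neuron_id": np.tile(np.arange(n), s),
                "value": self.states.T.ravel(),
            }
        )


class SynapticCascade:
    """Cascade realisation of the gamma kernel: q+1 first-order stages.

    ``stages[-1]`` is the synaptic output S.  Continuous drive enters the
    first stage through :meth:`derivatives`; delta spikes enter through
    :meth:`inject` as jumps of 1/(N tau) each.  The unit impulse response of
    the cascade equals the gamma kernel itself.
    """

    def __init__(self, kernel: SynapticKernel, n_neurons: int):
        if not isinstance(kernel, SynapticKernel):
            raise TypeError(
                "simulators require a gamma-family kernel (the cascade is its "
                "exact realisation); tabulated kernels support the reduction only"
            )
        self.kernel = kernel
        self.n_neurons = n_neurons
        self.stages = np.zeros(kernel.q + 1)

    @property
    def S(self) -> float:
        return float(self.stages[-1])

    def derivatives(self, stages: np.ndarray, drive: float) -> np.ndarray:
        tau = self.kernel.tau
        du = np.empty_like(stages)
        du[0] = (drive - stages[0]) / tau
        if stages.size > 1:
            du[1:] = (stages[:-1] - stages[1:]) / tau
        return du

    def inject(self, n_spikes: int = 1) -> None:
        self.stages[0] += n_spikes / (self.n_neurons * self.kernel.tau)

    def step(self, dt: float, drive: float = 0.0) -> None:
        """One RK4 step with drive held constant over the step."""
        u = self.stages
        k1 = self.derivatives(u, drive)
        k2 = self.derivatives(u + 0.5 * dt * k1, drive)
        k3 = self.derivatives(u + 0.5 * dt * k2, drive)
        k4 = self.derivatives(u + dt * k3, drive)
        self.stages = u + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


def _wrap(x: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - x, 2 * np.pi)


def _spike_crossings(old: np.ndarray, new: np.ndarray, t: float, dt: float):
    """Upward crossings of pi + 2*pi*k between consecutive unwrapped samples."""
    k_old = np.floor((old - np.pi) / (2 * np.pi))
    k_new = np.floor((new - np.pi) / (2 * np.pi))
    events = []
    for n in np.nonzero(k_new > k_old)[0]:
        level = np.pi + 2 * np.pi * (k_old[n] + 1)
        ts = t + dt * (level - old[n]) / (new[n] - old[n])
        events.append((int(n), float(ts)))
    return events


def _phase_network_run(
    params: NetworkParams,
    initial: np.ndarray,
    dt: float,
    T: float,
    store_every: int,
    rhs_phase,
    drive_fn,
    model_tag: str,
    omega_fast: float | None,
):
    """Shared loop for the theta and Winfree-form simulators.

    ``rhs_phase(x, total_input)`` gives the phase velocities; ``drive_fn(x)``
    the cascade source (None selects the delta-pulse path with per-spike
    jumps into the cascade).
    """
    N, kernel, kappa = params.N, params.kernel, params.kappa
    x = np.asarray(initial, dtype=float).copy()
    if x.shape != (N,):
        raise ValueError(f"initial state must have shape ({N},)")
    cascade = SynapticCascade(kernel, N)
    tau = kernel.tau
    q1 = kernel.q + 1
    steps = int(round(T / dt))
    n_keep = steps // store_every + 1
    times = np.empty(n_keep)
    states = np.empty((N, n_keep))
    syn = np.empty(n_keep)
    times[0], states[:, 0], syn[0] = 0.0, _wrap(x), cascade.S
    events: list[tuple[int, float]] = []
    delta_input = drive_fn is None
    u = cascade.stages
    kept = 1
    for i in range(steps):
        t = i * dt

        def deriv(xv, uv):
            drive = 0.0 if delta_input else drive_fn(xv)
            du = np.empty(q1)
            du[0] = (drive - uv[0]) / tau
            if q1 > 1:
                du[1:] = (uv[:-1] - uv[1:]) / tau
            return rhs_phase(xv, uv[-1]), du

        k1x, k1u = deriv(x, u)
        k2x, k2u = deriv(x + 0.5 * dt * k1x, u + 0.5 * dt * k1u)
        k3x, k3u = deriv(x + 0.5 * dt * k2x, u + 0.5 * dt * k2u)
        k4x, k4u = deriv(x + dt * k3x, u + dt * k3u)
        x_new = x + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
        u = u + dt / 6.0 * (k1u + 2 * k2u + 2 * k3u + k4u)
        new_events = _spike_crossings(x, x_new, t, dt)
        if new_events:
            events.extend(new_events)
            if delta_input:
                u[0] += len(new_events) / (N * tau)
        x = x_new
        if (i + 1) % store_every == 0:
            times[kept] = (i + 1) * dt
            states[:, kept] = _wrap(x)
            syn[kept] = u[-1]
            kept += 1
    cascade.stages = u
    traj = Trajectory(
        times=times[:kept],
        states=states[:, :kept],
        synaptic=syn[:kept],
        model_tag=model_tag,
        omega_fast=omega_fast,
        meta={"dt": dt, "T": T, "kappa": kappa, "nu": params.nu,
              "q": kernel.q, "tau": kernel.tau},
    )
    spikes = SpikeTrain.from_events(events, N)
    return traj, spikes


def simulate_theta(
    params: NetworkParams,
    initial_theta: np.ndarray,
    *,
    dt: float = 0.01,
    T: float = 200.0,
    store_every: int = 1,
) -> tuple[Trajectory, SpikeTrain]:
    """Integrate the theta-neuron network.

    dtheta_n/dt = (1 - cos theta_n) + (1 + cos theta_n)(eta_n + kappa S),
    with S the cascade output driven by the population mean of the pulse
    P_nu(theta) (or by unit delta spikes at pi-crossings when nu = inf).
    Spike times are interpolated pi-crossings.
    """
    eta, kappa = params.eta, params.kappa

    def rhs(th, S):
        c = np.cos(th)
        return (1.0 - c) + (1.0 + c) * (eta + kappa * S)

    if math.isinf(params.nu):
        drive = None
    else:
        nu = int(params.nu)

        def drive(th):
            return float(pulse_value(_wrap(th), nu).mean())

    return _phase_network_run(
        params, initial_theta, dt, T, store_every, rhs, drive, "theta", None
    )


def simulate_winfree_phase(
    params: NetworkParams,
    Omega: float,
    initial_phi: np.ndarray,
    *,
    dt: float = 0.01,
    T: float = 200.0,
    store_every: int = 1,
) -> Trajectory:
    """Integrate the Winfree-form phase model in the rotating coordinate phi.

    dphi_n/dt = Omega + (2/Omega)(1 + cos phi_n)(eta_n - Omega^2/4 + kappa S),
    with S driven by the population mean of the transformed pulse Q_nu(phi).
    Exactly equivalent to the theta network under the coordinate map; the
    fast rotation is explicit, which is what the averaging exploits.
    """
    if not (Omega > 0):
        raise ValueError("Omega must be positive")
    eta, kappa = params.eta, params.kappa
    detuning = eta - Omega * Omega / 4.0

    def rhs(phi, S):
        return Omega + (2.0 / Omega) * (1.0 + np.cos(phi)) * (detuning + kappa * S)

    if math.isinf(params.nu):
        drive = None
    else:
        nu = int(params.nu)

        def drive(phi):
            return float(transformed_pulse_value(_wrap(phi), nu, Omega).mean())

    traj, _ = _phase_network_run(
        params, initial_phi, dt, T, store_every, rhs, drive, "winfree_phase", Omega
    )
    return traj


def simulate_ks(
    ks: KSParams,
    initial_phi: np.ndarray,
    *,
    dt: float = 0.01,
    T: float = 200.0,
    store_every: int = 1,
) -> Trajectory:
    """Integrate the reduced KS model for the slow phases.

    dphi_n/dt = omega_n + (K/N) sum sin(phi_n' - phi_n - alpha); the mean
    field is evaluated through the complex order parameter so each step is
    O(N).  The fast phase Omega*t + phi_n (used for spike reconstruction) is
    recovered through ``omega_fast`` recorded on the trajectory.
    """
    omega, K, alpha = ks.omega, ks.K, ks.alpha
    N = omega.size
    phi = np.asarray(initial_phi, dtype=float).copy()
    if phi.shape != (N,):
        raise ValueError(f"initial_phi must have shape ({N},)")
    steps = int(round(T / dt))
    n_keep = steps // store_every + 1
    times = np.empty(n_keep)
    states = np.empty((N, n_keep))
    times[0], states[:, 0] = 0.0, _wrap(phi)

    def rhs(p):
        R = np.exp(1j * p).mean()
        return omega + K * np.imag(R * np.exp(-1j * (p + alpha)))

    kept = 1
    for i in range(steps):
        k1 = rhs(phi)
        k2 = rhs(phi + 0.5 * dt * k1)
        k3 = rhs(phi + 0.5 * dt * k2)
        k4 = rhs(phi + dt * k3)
        phi += dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if (i + 1) % store_every == 0:
            times[kept] = (i + 1) * dt
            states[:, kept] = _wrap(phi)
            kept += 1
    return Trajectory(
        times=times[:kept],
        states=states[:, :kept],
        synaptic=None,
        model_tag="ks",
        omega_fast=ks.Omega,
        meta={"dt": dt, "T": T, "K": K, "alpha": alpha},
    )


def simulate_qif(
    config: QIFConfig,
    initial_v: np.ndarray,
    *,
    store_every: int = 1,
) -> tuple[Trajectory, SpikeTrain]:
    """Integrate the QIF network with threshold reset and delta-spike coupling.

    See the module docstring for the inverse-coordinate handling of the
    threshold region.  Each spike injects 1/(N tau) into the first cascade
    stage at the end of the step containing the interpolated crossing.
    """
    net = config.network
    eta, kappa, kernel, N = net.eta, net.kappa, net.kernel, net.N
    dt, T, v_th, v_r = config.dt, config.T, config.v_th, config.v_r
    pass_through = config.refractory_mode == "pass_through"
    tau = kernel.tau
    q1 = kernel.q + 1

    # hand-off |v| between direct and inverse coordinates: the transit time
    # 1/V_c from the hand-off to infinity must span several steps
    V_c = min(10.0, 0.1 / dt)
    if v_th <= V_c:
        raise ValueError(
            f"v_th={v_th:g} too small for the inverse-coordinate scheme at "
            f"dt={dt:g} (requires v_th > {V_c:g})"
        )
    w_th = 1.0 / v_th

    x = np.asarray(initial_v, dtype=float).copy()
    if x.shape != (N,):
        raise ValueError(f"initial_v must have shape ({N},)")
    if np.any(x >= v_th):
        raise ValueError("initial voltages must lie below v_th")
    inv = np.abs(x) > V_c
    x[inv] = 1.0 / x[inv]
    u = np.zeros(q1)

    def voltages(x, inv):
        v = x.copy()
        m = inv & (np.abs(x) > 1e-300)
        v[m] = 1.0 / x[m]
        v[inv & ~m] = v_th  # passing through the singularity this instant
        return v

    steps = int(round(T / dt))
    n_keep = steps // store_every + 1
    times = np.empty(n_keep)
    states = np.empty((N, n_keep))
    syn = np.empty(n_keep)
    times[0], states[:, 0], syn[0] = 0.0, voltages(x, inv), u[-1]
    events: list[tuple[int, float]] = []
    kept = 1
    for i in range(steps):
        t = i * dt

        def deriv(xv, uv):
            a = eta + kappa * uv[-1]
            d = np.where(inv, -1.0 - a * xv * xv, xv * xv + a)
            du = np.empty(q1)
            du[0] = -uv[0] / tau
            if q1 > 1:
                du[1:] = (uv[:-1] - uv[1:]) / tau
            return d, du

        k1x, k1u = deriv(x, u)
        k2x, k2u = deriv(x + 0.5 * dt * k1x, u + 0.5 * dt * k1u)
        k3x, k3u = deriv(x + 0.5 * dt * k2x, u + 0.5 * dt * k2u)
        k4x, k4u = deriv(x + dt * k3x, u + dt * k3u)
        x_old = x.copy()
        x = x + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
        u = u + dt / 6.0 * (k1u + 2 * k2u + 2 * k3u + k4u)
        if np.any(~inv & ~np.isfinite(x)) or np.any(~inv & (np.abs(x) > 10 * v_th)):
            raise RuntimeError(
                f"QIF integration blew up at t={t:g}; reduce dt "
                f"(dt={dt:g}, max|v| handled = {V_c:g})"
            )
        # spikes: w crossing 1/v_th downward while in the inverse coordinate
        crossed = inv & (x_old > w_th) & (x <= w_th)
        n_spikes = 0
        for n in np.nonzero(crossed)[0]:
            ts = t + dt * (x_old[n] - w_th) / (x_old[n] - x[n])
            events.append((int(n), float(ts)))
            n_spikes += 1
            if not pass_through:
                # jump to v_r at the crossing, then drift (dw/dt ~ -1) to step end
                x[n] = 1.0 / v_r - ((t + dt) - ts)
        # regime hand-offs
        leave = inv & (x <= -1.0 / V_c)
        x[leave] = 1.0 / x[leave]
        inv[leave] = False
        enter = ~inv & (np.abs(x) > V_c)
        x[enter] = 1.0 / x[enter]
        inv[enter] = True
        if n_spikes:
            u[0] += n_spikes / (N * tau)
        if (i + 1) % store_every == 0:
            times[kept] = (i + 1) * dt
            states[:, kept] = voltages(x, inv)
            syn[kept] = u[-1]
            kept += 1
    traj = Trajectory(
        times=times[:kept],
        states=states[:, :kept],
        synaptic=syn[:kept],
        model_tag="qif",
        meta={"dt": dt, "T": T, "v_th": v_th, "v_r": v_r,
              "refractory_mode": config.refractory_mode,
              "q": kernel.q, "tau": kernel.tau, "kappa": kappa},
    )
    return traj, SpikeTrain.from_events(events, N)


def detect_spikes(trajectory: Trajectory, threshold_rule: dict | None = None) -> SpikeTrain:
    """Post-hoc spike detection on a stored trajectory.

    Rules: ``{"kind": "voltage", "v_th": x}`` detects upward threshold
    crossings of the stored voltages; ``{"kind": "phase"}`` detects upward
    crossings of pi (mod 2*pi) of the stored phases, adding the fast rotation
    Omega*t for KS trajectories.  Event times use linear interpolation
    between the bracketing samples, exact for linear data.
    """
    if threshold_rule is None:
        if trajectory.model_tag == "qif":
            threshold_rule = {"kind": "voltage", "v_th": trajectory.meta.get("v_th", 1.0)}
        else:
            threshold_rule = {"kind": "phase"}
    times = trajectory.times
    dt_arr = np.diff(times)
    events: list[tuple[int, float]] = []
    if threshold_rule["kind"] == "voltage":
        v_th = threshold_rule["v_th"]
        v = trajectory.states
        below, above = v[:, :-1] < v_th, v[:, 1:] >= v_th
        for n, j in zip(*np.nonzero(below & above)):
            frac = (v_th - v[n, j]) / (v[n, j + 1] - v[n, j])
            events.append((int(n), float(times[j] + frac * dt_arr[j])))
    elif threshold_rule["kind"] == "phase":
        x = np.unwrap(trajectory.states, axis=1)
        if trajectory.model_tag == "ks" and trajectory.omega_fast is not None:
            x = x + trajectory.omega_fast * times[None, :]
        k = np.floor((x - np.pi) / (2 * np.pi))
        inc = k[:, 1:] > k[:, :-1]
        for n, j in zip(*np.nonzero(inc)):
            level = np.pi + 2 * np.pi * (k[n, j] + 1)
            frac = (level - x[n, j]) / (x[n, j + 1] - x[n, j])
            events.append((int(n), float(times[j] + frac * dt_arr[j])))
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    return SpikeTrain.from_events(events, trajectory.states.shape[0])


def map_coordinates(values, direction: str, Omega: float | None = None):
    """Branch-consistent coordinate maps between the three representations.

    ``v_to_theta``: theta = 2 arctan(v)  (infinities map to pi);
    ``theta_to_v``: v = tan(theta/2)  (theta = pi maps to +inf);
    ``theta_to_phi`` / ``phi_to_theta``: 2 tan(theta/2) = Omega tan(phi/2),
    applied branch-by-branch so unwrapped phase arrays stay continuous and
    +/- pi (+ 2*pi*k) are fixed points.
    """
    values = np.asarray(values, dtype=float)
    if direction == "v_to_theta":
        out = 2.0 * np.arctan(values)
        return np.where(np.isneginf(values), -np.pi, np.where(np.isposinf(values), np.pi, out))
    if direction == "theta_to_v":
        r = _wrap(values)
        with np.errstate(divide="ignore"):
            return np.where(r == np.pi, np.inf, np.tan(0.5 * r))
    if Omega is None or not (Omega > 0):
        raise ValueError(f"direction {direction!r} requires Omega > 0")
    k = np.floor((values + np.pi) / (2 * np.pi))
    r = values - 2 * np.pi * k  # (-pi, pi]
    if direction == "theta_to_phi":
        mapped = 2.0 * np.arctan(2.0 * np.tan(0.5 * r) / Omega)
    elif direction == "phi_to_theta":
        mapped = 2.0 * np.arctan(0.5 * Omega * np.tan(0.5 * r))
    else:
        raise ValueError(f"unknown direction {direction!r}")
    mapped = np.where(r == np.pi, np.pi, mapped)
    return mapped + 2 * np.pi * k
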