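"""Macroscopic and microscopic diagnostics and regime classification.

The collective state is summarised by the complex Kuramoto order parameters

    R_ell(t) = (1/N) sum_n exp(i ell phi_n(t)) = r_ell exp(i psi_ell),

where r_1 measures phase synchrony (1 = full sync) and r_2 cluster
coherence (r_2 = 0 on generalized splay manifolds).  The population firing
rate is a sliding-window spike count, rho(t) = count in (t - dt_w, t] /
(N dt_w).  Cluster structure is read off by single-linkage grouping on the
circle, and four qualitative regimes are distinguished:

* synchronized      - long-time mean r_1 above a threshold (default 0.95);
* generalized_splay - long-time mean r_1 below a threshold (default 0.1);
* cyclops           - two equal coherent clusters plus one solitary
                      oscillator, pattern (m, m, 1) persisting in time;
* other             - anything else (including weakly coherent states).

The thresholds are qualitative heuristics, configurable and recorded in
the report.  For cross-model comparisons all models are classified in the
common rotating coordinate phi (thetas are mapped through the coordinate
change, voltages through v = tan(theta/2) first); moduli of R_ell are
unaffected by the global rotation Omega*t, so KS slow phases are used
directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulators import Trajectory, SpikeTrain, map_coordinates

__all__ = [
    "OrderParameterSeries",
    "RegimeReport",
    "kuramoto_order_parameter",
    "order_parameters",
    "firing_rate",
    "detect_clusters",
    "classify_regime",
]


@dataclass(frozen=True)
class OrderParameterSeries:
    """First- and second-order Kuramoto order parameters over time."""

    times: np.ndarray
    r1: np.ndarray
    psi1: np.ndarray
    r2: np.ndarray
    psi2: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, "r1": self.r1, "psi1": self.psi1,
             "r2": self.r2, "psi2": self.psi2}
        )


@dataclass(frozen=True)
class RegimeReport:
    """Outcome of regime classification on the post-transient window."""

    label: str  # synchronized | generalized_splay | cyclops | other
    cluster_sizes: list[int]
    r1_longtime_mean: float
    r2_longtime_mean: float
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "cluster_sizes": list(map(int, self.cluster_sizes)),
            "r1_longtime_mean": self.r1_longtime_mean,
            "r2_longtime_mean": self.r2_longtime_mean,
            "settings": self.settings,
        }


def kuramoto_order_parameter(phases: np.ndarray, ell: int = 1) -> np.ndarray:
    """Complex R_ell(t) = mean over neurons of exp(i ell phi); phases (N,) or (N, T)."""
    phases = np.asarray(phases, dtype=float)
    return np.exp(1j * ell * phases).mean(axis=0)


def order_parameters(phases: np.ndarray, times: np.ndarray | None = None) -> OrderParameterSeries:
    """Moduli and arguments of R_1 and R_2 from a (N, T) phase matrix."""
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    r = [kuramoto_order_parameter(phases, ell) for ell in (1, 2)]
    if times is None:
        times = np.arange(phases.shape[1], dtype=float)
    return OrderParameterSeries(
        times=np.asarray(times, dtype=float),
        r1=np.abs(r[0]), psi1=np.angle(r[0]),
        r2=np.abs(r[1]), psi2=np.angle(r[1]),
    )


def firing_rate(spikes: SpikeTrain, window: float, times: np.ndarray) -> np.ndarray:
    """Population rate rho(t): spikes in (t - window, t] per neuron per time.

    ``window`` is the sliding-window width (a customary default is 0.05
    time units for pulse-resolved rates).
    """
    if not (window > 0):
        raise ValueError("window must be positive")
    times = np.asarray(times, dtype=float)
    st = np.sort(spikes.times)
    hi = np.searchsorted(st, times, side="right")
    lo = np.searchsorted(st, times - window, side="right")
    return (hi - lo) / (spikes.n_neurons * window)


def detect_clusters(phases: np.ndarray, tolerance: float = 0.05) -> list[int]:
    """Single-linkage phase clusters on the circle; sizes sorted descending.

    Oscillators closer than ``tolerance`` (circular distance, radians) to a
    neighbour chain into one cluster.
    """
    if not (tolerance > 0):
        raise ValueError("tolerance must be positive")
    x = np.sort(np.angle(np.exp(1j * np.asarray(phases, dtype=float))))
    n = x.size
    if n == 1:
        return [1]
    gaps = np.diff(x)
    wrap_gap = 2 * np.pi - (x[-1] - x[0])
    cuts = np.nonzero(gaps > tolerance)[0]
    if cuts.size == 0:
        return [n]
    sizes = np.diff(np.concatenate([[-1], cuts, [n - 1]])).tolist()
    if wrap_gap <= tolerance and len(sizes) > 1:
        sizes[0] += sizes.pop()  # first and last runs join across the wrap
    return sorted(map(int, sizes), reverse=True)


def _common_phase_coordinate(trajectory: Trajectory, Omega: float | None) -> np.ndarray:
    tag = trajectory.model_tag
    if tag in ("ks", "winfree_phase"):
        return trajectory.states
    if tag == "theta":
        if Omega is None:
            return trajectory.states
        return map_coordinates(trajectory.states, "theta_to_phi", Omega)
    if tag == "qif":
        theta = map_coordinates(trajectory.states, "v_to_theta")
        if Omega is None:
            return theta
        return map_coordinates(theta, "theta_to_phi", Omega)
    raise ValueError(f"unknown model_tag {tag!r}")


def classify_regime(
    trajectory: Trajectory,
    *,
    Omega: float | None = None,
    transient_frac: float = 0.5,
    sync_threshold: float = 0.95,
    splay_threshold: float = 0.1,
    cluster_tolerance: float = 0.05,
    persistence: float = 0.9,
    max_cluster_samples: int = 400,
) -> RegimeReport:
    """Classify the post-transient dynamics of a trajectory.

    The first ``transient_frac`` of the run is discarded; time-means of r_1
    and r_2 and the persistence of the (m, m, 1) cluster pattern are
    evaluated on the remainder.  Priority: synchronized, then cyclops (which
    can carry intermediate r_1), then generalized splay, else other.
    """
    phases = _common_phase_coordinate(trajectory, Omega)
    n_samples = phases.shape[1]
    start = int(transient_frac * n_samples)
    window = phases[:, start:]
    if window.shape[1] < 2:
        raise ValueError("trajectory too short for the requested transient fraction")
    ops = order_parameters(window, trajectory.times[start:])
    r1_mean = float(ops.r1.mean())
    r2_mean = float(ops.r2.mean())

    N = phases.shape[0]
    stride = max(1, window.shape[1] // max_cluster_samples)
    samples = window[:, ::stride]
    patterns = [tuple(detect_clusters(samples[:, j], cluster_tolerance))
                for j in range(samples.shape[1])]
    m = (N - 1) // 2
    cyclops_pattern = (m, m, 1)
    cyclops_frac = (
        float(np.mean([p == cyclops_pattern for p in patterns]))
        if N == 2 * m + 1 and m >= 2
        else 0.0
    )

    if r1_mean > sync_threshold:
        label = "synchronized"
    elif cyclops_frac >= persistence:
        label = "cyclops"
    elif r1_mean < splay_threshold:
        label = "generalized_splay"
    else:
        label = "other"
    return RegimeReport(
        label=label,
        cluster_sizes=list(patterns[-1]),
        r1_longtime_mean=r1_mean,
        r2_longtime_mean=r2_mean,
        settings={
            "transient_frac": transient_frac,
            "sync_threshold": sync_threshold,
            "splay_threshold": splay_threshold,
            "cluster_tolerance": cluster_tolerance,
            "persistence": persistence,
            "cyclops_fraction": cyclops_frac,
            "model_tag": trajectory.model_tag,
        },
    )
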