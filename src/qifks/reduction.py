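"""Reduction of pulse-coupled Type I neuron networks to the Kuramoto-Sakaguchi model.

A globally coupled network of N oscillatory theta neurons (or, equivalently,
QIF neurons at infinite threshold) with weak synaptic coupling is
approximated by the Kuramoto-Sakaguchi (KS) phase model

    dphi_n/dt = omega_n + (K/N) sum_n' sin(phi_n' - phi_n - alpha),

whose parameters are explicit functions of the network parameters:

    omega_n = 2 (eta_n - Omega^2/4 + kappa Q_nu0) / Omega
    K       = 2 kappa |G_1| Q_nu1 / Omega
    alpha   = -arg G_1 - pi/2

where Q_nu0, Q_nu1 are the first two Fourier coefficients of the transformed
synaptic pulse, G_1 the kernel coefficient at the fast frequency Omega, and
Omega the positive root of  <eta> - Omega^2/4 + kappa Q_nu0(Omega) = 0,
chosen so the reduced frequencies omega_n average to zero.  Because
Q_nu1 <= 0, the KS coupling K and the synaptic weight kappa have opposite
signs (for Omega > 0): inhibitory pulse coupling is effectively attractive.

Synchronization is favoured when K cos(alpha) > 0.  For the gamma kernel
this reduces (kappa < 0, Omega > 0) to sin((q+1) arctan(tau*Omega)) > 0,
which alternates with tau*Omega: slow synapses and latency flip the coupling
between attractive and repulsive, with floor(q/2)+1 attractive windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .kernels import SynapticKernel, TabulatedKernel, kernel_fourier
from .pulses import delta_limit_coefficient, pulse_fourier


@dataclass(frozen=True)
class NetworkParams:
    """Parameters of the pulse-coupled network (all-to-all topology).

    Parameters
    ----------
    N : int
        Number of neurons (>= 2).
    eta : ndarray
        Positive excitability currents eta_n; all neurons must be in the
        oscillatory regime for the phase reduction to apply.
    kappa : float
        Common synaptic weight (negative = inhibitory).
    nu : int or math.inf
        Pulse sharpness; ``inf`` selects the delta-pulse limit.
    kernel : SynapticKernel or TabulatedKernel
        Synaptic activation kernel.  The reduction accepts a tabulated
        kernel (transform taken by quadrature); the cascade-based
        simulators require the gamma family.
    """

    N: int
    eta: np.ndarray
    kappa: float
    nu: float
    kernel: SynapticKernel | TabulatedKernel

    def __post_init__(self) -> None:
        eta = np.asarray(self.eta, dtype=float)
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if eta.shape != (self.N,):
            raise ValueError(f"eta must have shape ({self.N},), got {eta.shape}")
        if np.any(eta <= 0):
            raise ValueError("all eta_n must be positive (oscillatory regime)")
        if not math.isinf(self.nu) and (int(self.nu) != self.nu or self.nu < 1):
            raise ValueError("nu must be a positive integer or inf")
        object.__setattr__(self, "eta", eta)

    @property
    def eta_mean(self) -> float:
        return float(self.eta.mean())


@dataclass(frozen=True)
class KSParams:
    """Reduced Kuramoto-Sakaguchi parameters of a network."""

    omega: np.ndarray  # natural frequencies, zero-mean by construction
    K: float  # coupling strength (opposite sign to kappa for Omega > 0)
    alpha: float  # Sakaguchi phase lag, wrapped to (-pi, pi]
    Omega: float  # fast rotation frequency

    @property
    def attractive(self) -> bool:
        return self.K * math.cos(self.alpha) > 0

    def to_dict(self) -> dict:
        return {
            "Omega": self.Omega,
            "K": self.K,
            "alpha": self.alpha,
            "omega_mean": float(self.omega.mean()),
            "omega_std": float(self.omega.std()),
            "attractive": bool(self.attractive),
        }


@dataclass(frozen=True)
class CouplingRegionMap:
    """Attractive/repulsive classification on a (eta, tau) grid at fixed q."""

    tau_grid: np.ndarray
    eta_grid: np.ndarray
    q: int
    attractive: np.ndarray  # bool, shape (len(eta_grid), len(tau_grid))
    valid: np.ndarray = field(default=None)  # False where the Omega solve failed

    def to_dataframe(self):
        """Long-format table with columns tau, eta, q, attractive."""
        import pandas as pd

        tt, ee = np.meshgrid(self.tau_grid, self.eta_grid)
        return pd.DataFrame(
            {
                "tau": tt.ravel(),
                "eta": ee.ravel(),
                "q": self.q,
                "attractive": self.attractive.ravel(),
                "valid": (np.ones_like(self.attractive) if self.valid is None else self.valid).ravel(),
            }
        )


def _q_nu0(nu: float, Omega: float) -> float:
    if math.isinf(nu):
        return delta_limit_coefficient(0, Omega).value
    return pulse_fourier(0, int(nu), Omega).value


def _q_nu1(nu: float, Omega: float) -> float:
    if math.isinf(nu):
        return delta_limit_coefficient(1, Omega).value
    return pulse_fourier(1, int(nu), Omega).value


def solve_omega(eta_mean: float, kappa: float, nu: float) -> float:
    """Self-consistent fast frequency Omega.

    Solves  eta_mean - Omega^2/4 + kappa * Q_nu0(Omega) = 0  for the positive
    root nearest the uncoupled value 2 sqrt(eta_mean); in the delta-pulse
    limit (nu = inf, Q_inf0 = Omega/2pi) the quadratic solves in closed form:

        Omega = (kappa + sqrt(kappa^2 + 4 pi^2 eta_mean)) / pi.
    """
    if not (eta_mean > 0):
        raise ValueError("eta_mean must be positive")
    if math.isinf(nu):
        return (kappa + math.sqrt(kappa**2 + 4 * math.pi**2 * eta_mean)) / math.pi

    def f(Om: float) -> float:
        return eta_mean - Om * Om / 4.0 + kappa * _q_nu0(nu, Om)

    lo, hi = 1e-6, 2.0 * math.sqrt(eta_mean) + 2.0 * abs(kappa) + 1.0
    grid = np.linspace(lo, hi, 200)
    vals = np.array([f(x) for x in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        raise RuntimeError(
            f"no sign change of the Omega equation on [{lo:g}, {hi:g}] "
            f"(eta_mean={eta_mean:g}, kappa={kappa:g}, nu={nu:g})"
        )
    target = 2.0 * math.sqrt(eta_mean)
    roots = [
        brentq(f, grid[i], grid[i + 1], xtol=1e-12) for i in sign_change
    ]
    return min(roots, key=lambda r: abs(r - target))


def reduce_to_ks(params: NetworkParams) -> KSParams:
    """Map network parameters to the reduced KS parameters (Omega, omega_n, K, alpha)."""
    Omega = solve_omega(params.eta_mean, params.kappa, params.nu)
    q0 = _q_nu0(params.nu, Omega)
    q1 = _q_nu1(params.nu, Omega)
    method = "quadrature" if isinstance(params.kernel, TabulatedKernel) else "closed_form"
    g1 = kernel_fourier(1, Omega, params.kernel, method=method).value
    omega = 2.0 * (params.eta - Omega**2 / 4.0 + params.kappa * q0) / Omega
    K = 2.0 * params.kappa * abs(g1) * q1 / Omega
    alpha = _wrap_angle(-np.angle(g1) - np.pi / 2.0)
    return KSParams(omega=omega, K=float(K), alpha=float(alpha), Omega=float(Omega))


def _wrap_angle(a: float) -> float:
    """Wrap to (-pi, pi]."""
    w = math.remainder(a, 2 * math.pi)
    return math.pi if w == -math.pi else w


def is_attractive(q: int, tau: float, Omega: float, kappa: float) -> bool:
    """Sign test for attractive coupling: sign(K) cos(alpha) > 0.

    Uses sign(K) = -sign(kappa) (exact for Omega > 0 since Q_nu1 <= 0) and
    cos(alpha) = sin((q+1) arctan(tau Omega)) from the gamma-kernel G_1.
    """
    if not (tau > 0 and Omega > 0):
        raise ValueError("tau and Omega must be positive")
    if kappa == 0:
        return False
    g1 = kernel_fourier(1, Omega, SynapticKernel(q=q, tau=tau)).value
    alpha = _wrap_angle(-np.angle(g1) - np.pi / 2.0)
    return (-math.copysign(1.0, kappa)) * math.cos(alpha) > 0


def attractive_intervals(q: int) -> list[tuple[float, float]]:
    """Maximal open intervals of x = tau*Omega > 0 with attractive coupling (kappa < 0).

    The condition sin((q+1) arctan x) > 0 changes sign at x = tan(k pi/(q+1)).
    Counting the formal negative branch of the axis as well, the total number
    of attractive windows is floor(q/2) + 1; only the physical positive-axis
    intervals are returned here.
    """
    if q < 0 or int(q) != q:
        raise ValueError("q must be a non-negative integer")
    n = q + 1
    bounds = [math.tan(k * math.pi / n) for k in range(1, n) if k * math.pi / n < math.pi / 2]
    edges = [0.0, *bounds, math.inf]
    intervals = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid = lo + 1.0 if math.isinf(hi) else 0.5 * (lo + hi)
        if math.sin(n * math.atan(mid)) > 0:
            intervals.append((lo, hi))
    return intervals


def region_map(
    q: int,
    kappa: float,
    nu: float,
    tau_grid,
    eta_grid,
) -> CouplingRegionMap:
    """Classify attractive vs repulsive coupling over a (tau, eta) grid.

    Omega depends on eta (and kappa, nu) but not on tau, so it is solved once
    per eta value and the tau sweep reuses it.  Cells where the Omega solve
    fails are marked invalid.
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    eta_grid = np.asarray(eta_grid, dtype=float)
    if tau_grid.size == 0 or eta_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(eta_grid <= 0) or np.any(tau_grid <= 0):
        raise ValueError("grids must be positive")
    att = np.zeros((eta_grid.size, tau_grid.size), dtype=bool)
    valid = np.ones_like(att)
    for i, eta in enumerate(eta_grid):
        try:
            Omega = solve_omega(float(eta), kappa, nu)
        except RuntimeError:
            valid[i, :] = False
            continue
        for j, tau in enumerate(tau_grid):
            att[i, j] = is_attractive(q, float(tau), Omega, kappa)
    return CouplingRegionMap(
        tau_grid=tau_grid, eta_grid=eta_grid, q=q, attractive=att, valid=valid
    )
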