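"""Synaptic activation kernels and their frequency-domain coefficients.

A presynaptic spike does not drive the postsynaptic cell instantaneously:
neurotransmitter release, diffusion and channel gating low-pass filter the
spike train.  This module represents that filter by the gamma-family kernel

    g(t) = (t/tau)^q  exp(-t/tau) / (q! tau),    t >= 0,

the Green's function of the (q+1)-st order linear operator
(tau d/dt + 1)^(q+1).  The integer order ``q`` sets the effective synaptic
latency (peak at t = q*tau) while ``tau`` sets the time scale; ``q = 0`` is
the classical exponential synapse and ``q = 1`` the alpha function.

The phase reduction needs the kernel only through its complex Fourier
coefficients at harmonics of the fast network frequency Omega,

    G_ell = integral_0^inf g(t) exp(-i ell Omega t) dt,

which for the gamma family have the closed form 1 / (1 + i ell Omega tau)^(q+1).
Arbitrary tabulated kernels are supported through the quadrature path only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import gammaln


@dataclass(frozen=True)
class SynapticKernel:
    """Gamma-family synaptic kernel with shape ``q`` and time constant ``tau``.

    Parameters
    ----------
    q : int
        Non-negative integer shape (delay) order.  Larger ``q`` delays the
        peak of the postsynaptic response.
    tau : float
        Positive synaptic time constant, in the network's time units.
    """

    q: int
    tau: float

    def __post_init__(self) -> None:
        if int(self.q) != self.q or self.q < 0:
            raise ValueError(f"q must be a non-negative integer, got {self.q}")
        if not (self.tau > 0):
            raise ValueError(f"tau must be positive, got {self.tau}")
        object.__setattr__(self, "q", int(self.q))
        object.__setattr__(self, "tau", float(self.tau))


@dataclass(frozen=True)
class TabulatedKernel:
    """Kernel sampled on a time grid; evaluated by interpolation.

    The samples should cover the kernel's support and integrate to ~1.
    Only the quadrature path of :func:`kernel_fourier` applies.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 2:
            raise ValueError("times and values must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def value(self, t):
        return np.interp(t, self.times, self.values, left=0.0, right=0.0)


@dataclass(frozen=True)
class KernelMoments:
    """Temporal statistics of a gamma kernel (peak latency, mean, spread)."""

    t_max: float
    t_mean: float
    variance: float
    skewness: float


@dataclass(frozen=True)
class KernelCoefficient:
    """One complex Fourier coefficient G_ell of a synaptic kernel."""

    ell: int
    value: complex

    @property
    def modulus(self) -> float:
        return abs(self.value)

    @property
    def argument(self) -> float:
        return float(np.angle(self.value))


def gamma_kernel_value(t, kernel: SynapticKernel):
    """Evaluate the gamma kernel g(t) = (t/tau)^q e^{-t/tau} / (q! tau).

    Vectorised over ``t``; returns 0 for t < 0 (causality).  Evaluated in
    log space so large ``q`` does not overflow.
    """
    q, tau = kernel.q, kernel.tau
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t)
    pos = t > 0
    if q == 0:
        valid = t >= 0
        out[valid] = np.exp(-t[valid] / tau) / tau
    else:
        x = t[pos] / tau
        out[pos] = np.exp(q * np.log(x) - x - gammaln(q + 1) - np.log(tau))
        # t == 0 contributes 0 for q >= 1
    return out[0] if scalar else out


def kernel_moments(kernel: SynapticKernel) -> KernelMoments:
    """Closed-form gamma-distribution statistics of the kernel.

    Peak latency q*tau, mean (q+1)*tau, variance (q+1)*tau^2 and skewness
    2/sqrt(q+1).  The mode is at the origin for the exponential case q = 0.
    """
    q, tau = kernel.q, kernel.tau
    return KernelMoments(
        t_max=q * tau,
        t_mean=(q + 1) * tau,
        variance=(q + 1) * tau**2,
        skewness=2.0 / np.sqrt(q + 1),
    )


def _quadrature_horizon(q: int) -> float:
    # mean + 12 standard deviations + a flat margin in the dimensionless
    # variable xi = t/tau; the margin matters at small q, where exp(-xi)
    # alone must push the truncated tail below the 1e-10 tolerance
    return (q + 1) + 12.0 * np.sqrt(q + 1) + 25.0


def kernel_fourier(
    ell: int,
    Omega: float,
    kernel: SynapticKernel | TabulatedKernel,
    method: str = "closed_form",
) -> KernelCoefficient:
    """Complex Fourier coefficient G_ell of a synaptic kernel at frequency Omega.

    For the gamma family the closed form is 1/(1 + i ell Omega tau)^(q+1),
    with modulus (1 + (ell Omega tau)^2)^(-(q+1)/2) and argument
    -(q+1) arctan(ell Omega tau).  ``method='quadrature'`` integrates the
    defining transform directly and is the only path for tabulated kernels.

    Parameters
    ----------
    ell : int
        Harmonic index (G_0 = 1 by normalization).
    Omega : float
        Positive fast rotation frequency, rad / time unit.
    """
    if not (Omega > 0):
        raise ValueError("Omega must be positive")
    if isinstance(kernel, TabulatedKernel):
        if method == "closed_form":
            raise ValueError("closed_form applies to gamma kernels only")
        t, v = kernel.times, kernel.values
        phase = np.exp(-1j * ell * Omega * t)
        return KernelCoefficient(ell=ell, value=complex(np.trapezoid(v * phase, t)))
    q, tau = kernel.q, kernel.tau
    if method == "closed_form":
        value = (1.0 + 1j * ell * Omega * tau) ** (-(q + 1))
        return KernelCoefficient(ell=ell, value=complex(value))
    if method != "quadrature":
        raise ValueError(f"unknown method {method!r}")
    # G_ell = int_0^inf xi^q e^{-xi} / q!  *  e^{-i ell Omega tau xi} dxi
    lognorm = gammaln(q + 1)
    w = ell * Omega * tau

    def integrand_re(xi):
        return np.exp(q * np.log(xi) - xi - lognorm) * np.cos(w * xi) if xi > 0 else (
            np.cos(0.0) if q == 0 else 0.0
        )

    def integrand_im(xi):
        return -np.exp(q * np.log(xi) - xi - lognorm) * np.sin(w * xi) if xi > 0 else 0.0

    hi = _quadrature_horizon(q)
    re, re_err = quad(integrand_re, 0.0, hi, epsabs=1e-11, limit=500)
    im, im_err = quad(integrand_im, 0.0, hi, epsabs=1e-11, limit=500)
    if re_err > 1e-7 or im_err > 1e-7:
        raise RuntimeError(
            f"kernel quadrature did not converge (ell={ell}, q={q}, "
            f"Omega*tau={Omega * tau:g}; error estimates {re_err:g}, {im_err:g})"
        )
    return KernelCoefficient(ell=ell, value=complex(re, im))
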