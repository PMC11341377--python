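"""Pulsatile synapse profiles and their Fourier coefficients.

The chemical synapse of a theta neuron is modelled by the smooth pulse

    P_nu(theta) = p_nu (1 - cos theta)^nu,

peaked at the spike phase theta = pi, whose sharpness grows with the
integer exponent ``nu``.  The normalization p_nu = 2^nu (nu!)^2 / (pi (2nu)!)
fixes the circle integral of P_nu to 2, so that in the limit nu -> inf the
pulse becomes a weight-2 Dirac comb at theta = pi and the drive received per
spike matches the unit-weight delta input of the integrate-and-fire picture
(the phase crosses pi at speed 2).

Under the uniform-rotation change of variables 2 tan(theta/2) = Omega
tan(phi/2) the pulse becomes Q_nu(phi) = P_nu(2 arctan(Omega tan(phi/2)/2)),
and the phase reduction uses its Fourier coefficients

    Q_nu_ell = (1/2pi) int_{-pi}^{pi} e^{-i ell phi} Q_nu(phi) dphi,

real and even in ell.  These have a closed form as a finite sum of Gauss
hypergeometric terms 2F1(., .; .; 1 - Omega^2/4); the quadrature of the
defining integral serves as an independent oracle for it.  All coefficients
converge to (-1)^ell * Omega/(2pi) as nu -> inf.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.special import betaln, gammaln, hyp2f1


def _log_pulse_norm(nu: int) -> float:
    """log of p_nu = 2^nu (nu!)^2 / (pi (2nu)!)."""
    return nu * math.log(2.0) + 2 * gammaln(nu + 1) - math.log(math.pi) - gammaln(2 * nu + 1)


def pulse_normalization(nu: int) -> float:
    """Normalization constant p_nu making the circle integral of P_nu equal 2."""
    _check_nu(nu)
    return math.exp(_log_pulse_norm(nu))


def _check_nu(nu) -> None:
    if math.isinf(nu):
        raise ValueError(
            "nu = inf is the delta-pulse limit; use delta_limit_coefficient / "
            "the simulators' delta-input path instead"
        )
    if int(nu) != nu or nu < 1:
        raise ValueError(f"nu must be a positive integer (or inf), got {nu}")


@dataclass(frozen=True)
class PulseShape:
    """Smooth synaptic pulse P_nu(theta) = p_nu (1 - cos theta)^nu."""

    nu: int

    def __post_init__(self) -> None:
        _check_nu(self.nu)
        object.__setattr__(self, "nu", int(self.nu))

    @property
    def p_nu(self) -> float:
        return pulse_normalization(self.nu)

    def __call__(self, theta):
        return pulse_value(theta, self.nu)


@dataclass(frozen=True)
class PulseCoefficient:
    """One (real) Fourier coefficient Q_nu_ell of the transformed pulse."""

    ell: int
    value: float


def pulse_value(theta, nu: int):
    """Evaluate P_nu(theta) = p_nu (1 - cos theta)^nu, vectorised over theta.

    Computed in log space: for sharp pulses (nu ~ 1e5) the direct power
    underflows everywhere except a ~1/sqrt(nu) neighbourhood of pi.
    """
    _check_nu(nu)
    theta = np.asarray(theta, dtype=float)
    scalar = theta.ndim == 0
    theta = np.atleast_1d(theta)
    x = 1.0 - np.cos(theta)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = np.exp(_log_pulse_norm(nu) + nu * np.log(x[pos]))
    return out[0] if scalar else out


def _theta_of_phi(phi, Omega: float):
    """Map phi -> theta per 2 tan(theta/2) = Omega tan(phi/2), branch-consistent.

    Works on unwrapped angles: each 2*pi branch maps onto itself, with
    phi = pi + 2*pi*k fixed points of the map.
    """
    phi = np.asarray(phi, dtype=float)
    k = np.floor((phi + np.pi) / (2 * np.pi))
    r = phi - 2 * np.pi * k  # in (-pi, pi]
    theta = 2.0 * np.arctan(0.5 * Omega * np.tan(0.5 * r))
    theta = np.where(r == np.pi, np.pi, theta)
    return theta + 2 * np.pi * k


def transformed_pulse_value(phi, nu: int, Omega: float):
    """Evaluate Q_nu(phi) = P_nu(2 arctan(Omega tan(phi/2) / 2)).

    2*pi-periodic and symmetric in phi; the identity Q_nu = P_nu holds at
    Omega = 2, where the change of variables is trivial.
    """
    if not (Omega > 0):
        raise ValueError("Omega must be positive")
    return pulse_value(_theta_of_phi(phi, Omega), nu)


def delta_limit_coefficient(ell: int, Omega: float) -> PulseCoefficient:
    """Fourier coefficient of the delta-pulse limit: (-1)^ell * Omega / (2 pi)."""
    if not (Omega > 0):
        raise ValueError("Omega must be positive")
    return PulseCoefficient(ell=ell, value=(-1) ** (ell % 2) * Omega / (2 * np.pi))


def _hyp2f1_stable(a: float, b: float, c: float, z: float) -> float:
    """Gauss 2F1 with a Pfaff transformation for z < 0.

    scipy's direct evaluation loses accuracy for strongly negative arguments
    at large c (sharp pulses with Omega > 2); mapping z -> z/(z-1) in (0, 1)
    restores a well-conditioned series.
    """
    if z < 0:
        return (1.0 - z) ** (-a) * hyp2f1(a, c - b, c, z / (z - 1.0))
    return hyp2f1(a, b, c, z)


def _pulse_fourier_hyp(ell: int, nu: int, Omega: float) -> float:
    """Closed-form Q_nu_ell: finite sum of 2F1 terms at argument 1 - Omega^2/4."""
    z = 1.0 - Omega * Omega / 4.0
    log_a = _log_pulse_norm(nu) + nu * math.log(2.0) - math.log(math.pi)
    total = 0.0
    for m in range(ell + 1):
        # C(2*ell, 2*m) via log-gamma to stay exact in the log domain
        log_binom = (
            gammaln(2 * ell + 1) - gammaln(2 * m + 1) - gammaln(2 * (ell - m) + 1)
        )
        log_term = (
            log_a
            + log_binom
            + (2 * (ell - m) + 1) * math.log(Omega / 2.0)
            + gammaln(nu + m + 0.5)
            + gammaln(ell - m + 0.5)
            - gammaln(nu + ell + 1)
        )
        h = _hyp2f1_stable(ell + 1, ell - m + 0.5, nu + ell + 1, z)
        total += (-1.0) ** m * math.exp(log_term) * h
    return total


def _pulse_fourier_quad(ell: int, nu: int, Omega: float) -> float:
    """Direct quadrature of the defining integral (independent oracle).

    By evenness the imaginary part vanishes and
    Q_nu_ell = (1/pi) int_0^pi cos(ell*phi) Q_nu(phi) dphi.  The integrand
    concentrates in a (2/Omega)/sqrt(nu) neighbourhood of pi for sharp
    pulses; a breakpoint there steers the adaptive rule.
    """

    def f(phi):
        return math.cos(ell * phi) * float(transformed_pulse_value(phi, nu, Omega))

    width = max(6.0 * (2.0 / Omega) / math.sqrt(nu), 1e-3)
    pts = [max(np.pi - width, 0.0)]
    val, err = quad(f, 0.0, np.pi, points=pts, limit=400, epsabs=1e-12, epsrel=1e-11)
    if err > 1e-8:
        raise RuntimeError(
            f"pulse quadrature did not converge (ell={ell}, nu={nu}, Omega={Omega:g}; "
            f"error estimate {err:g})"
        )
    return val / np.pi


def pulse_fourier(
    ell: int, nu: int, Omega: float, method: str = "hypergeometric"
) -> PulseCoefficient:
    """Fourier coefficient Q_nu_ell of the transformed pulse.

    The hypergeometric path evaluates the closed-form finite sum (exact for
    every ell >= 0, reducing to the elementary forms at Omega = 2); the
    quadrature path integrates the definition and is the ground truth the
    closed form is validated against.  A non-finite closed-form value (the
    2F1 argument approaches 1 as Omega -> 0) falls back to quadrature with
    a warning.
    """
    if not (Omega > 0):
        raise ValueError("Omega must be positive")
    _check_nu(nu)
    nu = int(nu)
    ell = abs(int(ell))  # Q_{nu,-ell} = Q_{nu,ell}
    if method == "quadrature":
        return PulseCoefficient(ell=ell, value=_pulse_fourier_quad(ell, nu, Omega))
    if method != "hypergeometric":
        raise ValueError(f"unknown method {method!r}")
    value = _pulse_fourier_hyp(ell, nu, Omega)
    if not math.isfinite(value):
        warnings.warn(
            f"hypergeometric evaluation failed for (ell={ell}, nu={nu}, "
            f"Omega={Omega:g}); falling back to quadrature",
            RuntimeWarning,
            stacklevel=2,
        )
        value = _pulse_fourier_quad(ell, nu, Omega)
    return PulseCoefficient(ell=ell, value=value)


def pulse_fourier_table(nu: int, Omega: float, ells=range(6)):
    """Coefficients Q_nu_ell for a set of harmonics, as a (ell, value) table."""
    import pandas as pd

    return pd.DataFrame(
        {"ell": list(ells),
         "value": [pulse_fourier(ell, nu, Omega).value for ell in ells]}
    )


def pulse_peak_value(nu: int) -> float:
    """Maximum of P_nu (at theta = pi): p_nu 2^nu = 2 / (pi B(1/2, nu + 1/2)).

    Grows like sqrt(nu) - the usual sharpening of a normalized bump.
    """
    _check_nu(nu)
    return 2.0 / math.pi * math.exp(-betaln(0.5, nu + 0.5) + math.log(math.pi))
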