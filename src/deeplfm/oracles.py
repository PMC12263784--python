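"""Brute-force quadrature oracles.

Every closed form in this package (response features, the analytic
convolutions of the exponential filter, the LFM covariance) is validated
against direct adaptive quadrature of the defining integral.  These
routines are deliberately slow and simple — they are the arbiters used by
the test suite, never part of a training path.

All oracles use absolute tolerance 1e-10 unless stated otherwise.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import dblquad, quad

__all__ = [
    "rfrf_quadrature",
    "lfm_kernel_oracle",
    "conv_cosine_quadrature",
    "conv_eq_quadrature",
    "filter_response_quadrature",
]

_ATOL = 1e-10


def rfrf_quadrature(t: float, gamma: float, omega: float) -> complex:
    """∫_0^t e^{-γ(t-τ)} e^{jωτ} dτ by adaptive quadrature (real and imag parts)."""
    re, _ = quad(lambda tau: np.exp(-gamma * (t - tau)) * np.cos(omega * tau),
                 0.0, t, epsabs=_ATOL, limit=400)
    im, _ = quad(lambda tau: np.exp(-gamma * (t - tau)) * np.sin(omega * tau),
                 0.0, t, epsabs=_ATOL, limit=400)
    return re + 1j * im


def lfm_kernel_oracle(t: float, t2: float, gamma: float, lengthscale: float,
                      gamma2: float | None = None, sensitivity: float = 1.0,
                      lower: float = 0.0) -> float:
    """LFM covariance S² ∫ G(t-τ) ∫ G(t'-τ') k(τ,τ') dτ' dτ by 2-D quadrature.

    ``lower`` is the shared lower integration limit (0 for the classic LFM,
    −∞-style truncation for the lower-tail convolution used by the
    inducing-point formulation — pass a sufficiently negative float).
    Raises if the quadrature error estimate exceeds 1e-6.
    """
    if gamma2 is None:
        gamma2 = gamma

    def integrand(tau2, tau):
        k = np.exp(-((tau - tau2) ** 2) / lengthscale**2)
        return np.exp(-gamma * (t - tau)) * np.exp(-gamma2 * (t2 - tau2)) * k

    val, err = dblquad(integrand, lower, t, lower, t2, epsabs=_ATOL)
    if err > 1e-6:
        raise RuntimeError(f"LFM kernel quadrature did not converge (err={err:.2e})")
    return sensitivity**2 * val


def conv_cosine_quadrature(gamma: float, theta: float, beta: float, x: float,
                           tail: float = 60.0) -> float:
    """∫_{-∞}^{x} e^{-γ(x-z)} cos(θz + β) dz, truncated where the filter underflows."""
    lo = x - max(tail / gamma, 60.0)
    val, _ = quad(lambda z: np.exp(-gamma * (x - z)) * np.cos(theta * z + beta),
                  lo, x, epsabs=_ATOL, limit=800)
    return val


def conv_eq_quadrature(gamma: float, ell: float, x: float, zm: float) -> float:
    """∫_{-∞}^{x} e^{-γ(x-z)} exp(-(z-z_m)²/ℓ²) dz, truncated far below all structure.

    The integrand can be a narrow spike (sharp kernel or near-delta filter)
    inside a wide truncated interval, so its known feature locations are
    passed to the adaptive rule as break points.
    """
    lo = min(x, zm) - max(30.0 / gamma, 30.0 * ell)
    features = [zm - 3 * ell, zm, zm + 3 * ell, x - 3.0 / gamma, x - 0.3 / gamma]
    pts = sorted({p for p in features if lo < p < x})
    val, _ = quad(lambda z: np.exp(-gamma * (x - z)) * np.exp(-((z - zm) ** 2) / ell**2),
                  lo, x, epsabs=_ATOL, limit=1000, points=pts or None)
    return val


def filter_response_quadrature(u, gamma: float, t: float) -> float:
    """∫_0^t e^{-γ(t-τ)} u(τ) dτ for an arbitrary callable force u."""
    val, _ = quad(lambda tau: np.exp(-gamma * (t - tau)) * u(tau),
                  0.0, t, epsabs=1e-12, limit=800)
    return val
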