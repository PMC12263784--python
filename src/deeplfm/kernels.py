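"""Green's functions, EQ latent kernels and random Fourier response features.

A latent force model (LFM) writes each output as a convolution of latent
Gaussian-process forces with the Green's function of a linear ODE.  For the
first-order system df/dt + γ f = Σ_q S_q u_q(t) the Green's function is the
exponential filter G(x) = e^{-γx}.  With an exponentiated-quadratic (EQ)
kernel k_q(τ, τ') = exp(-(τ-τ')²/ℓ_q²) on the forces, Bochner's theorem
yields random Fourier features with frequencies ω ~ N(0, 2/ℓ_q²), and
convolving those Fourier basis functions with G gives the *random Fourier
response features* (RFRFs)

    φ(t, γ, ω) = (e^{jωt} − e^{-γt}) / (γ + jω),

the complex-valued building block of every DLFM-RFF layer.  This module
holds the feature maps and the small value types they are built from; the
quadrature oracles they are tested against live in :mod:`deeplfm.oracles`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FirstOrderGreens",
    "LatentForceKernel",
    "eq_kernel",
    "rfrf_complex",
    "rfrf_realify",
    "rfrf_multidim",
    "rfrf_feature_matrix",
    "eq_rff",
    "lfm_kernel_rfrf_estimate",
]


@dataclass(frozen=True)
class FirstOrderGreens:
    """Exponential impulse response G(x) = e^{-γx} of df/dt + γf = u."""

    gamma: float

    def __post_init__(self):
        if not self.gamma > 0:
            raise ValueError(f"decay parameter must be positive, got {self.gamma}")

    def __call__(self, x):
        return np.exp(-self.gamma * np.asarray(x, dtype=float))


@dataclass(frozen=True)
class LatentForceKernel:
    """EQ kernel family over the Q latent forces.

    ``lengthscales`` holds ℓ_q for each force; ``variance`` is the marginal
    variance σ² used by the weight-space feature maps.  Frequencies are
    sampled from the spectral density N(0, 2/ℓ_q²) of
    k_q(τ, τ') = exp(-(τ-τ')²/ℓ_q²).
    """

    lengthscales: np.ndarray
    variance: float = 1.0

    def __post_init__(self):
        object.__setattr__(
            self, "lengthscales", np.atleast_1d(np.asarray(self.lengthscales, dtype=float))
        )
        if np.any(self.lengthscales <= 0):
            raise ValueError("lengthscales must be positive")
        if self.variance < 0:
            raise ValueError("variance must be nonnegative")

    @property
    def n_forces(self) -> int:
        return self.lengthscales.shape[0]

    def k(self, x, x2, q: int = 0):
        r = np.subtract.outer(np.asarray(x, float), np.asarray(x2, float))
        return np.exp(-(r**2) / self.lengthscales[q] ** 2)

    def sample_frequencies(self, n_rf: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ω_{q,s} ~ N(0, 2/ℓ_q²); shape (Q, n_rf)."""
        scale = np.sqrt(2.0) / self.lengthscales[:, None]
        return scale * rng.standard_normal((self.n_forces, n_rf))


def eq_kernel(x, x2, lengthscale: float) -> np.ndarray:
    """exp(-(x - x')²/ℓ²) for 1-D inputs (matrix over all pairs)."""
    r = np.subtract.outer(np.asarray(x, float), np.asarray(x2, float))
    return np.exp(-(r**2) / lengthscale**2)


# ------------------------------------------------------------------ RFRFs
def rfrf_complex(t, gamma: float, omega):
    """The first-order-ODE response feature φ(t, γ, ω) = (e^{jωt} − e^{-γt})/(γ + jω).

    Equals the convolution ∫_0^t e^{-γ(t-τ)} e^{jωτ} dτ; broadcasts over
    ``t`` and ``omega``; exactly zero at t = 0 and conjugate-symmetric in ω.
    """
    if not gamma > 0:
        raise ValueError("gamma must be positive")
    t = np.asarray(t, dtype=float)
    omega = np.asarray(omega, dtype=float)
    num = np.exp(1j * omega * t) - np.exp(-gamma * t)
    return num / (gamma + 1j * omega)


def rfrf_realify(phi_c: np.ndarray) -> np.ndarray:
    """Stack [Re(φ), Im(φ)] along the last axis, order preserved within halves."""
    phi_c = np.asarray(phi_c)
    return np.concatenate([phi_c.real, phi_c.imag], axis=-1)


def rfrf_multidim(x, gammas, omegas, sensitivities=None) -> np.ndarray:
    """Complex feature vector for a p-dimensional input.

    Per input dimension m, RFRFs φ(x_m, γ_m, ω_{m,q,s}) are computed and
    summed over m; the per-force scaling √(S_q²/N_RF) is applied exactly
    once, here.  ``omegas`` has shape (p, Q, N_RF); the result is the
    flattened (q, s)-lexicographic vector of length Q·N_RF.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    gammas = np.atleast_1d(np.asarray(gammas, dtype=float))
    omegas = np.asarray(omegas, dtype=float)
    if omegas.ndim != 3 or omegas.shape[0] != x.shape[0] or gammas.shape[0] != x.shape[0]:
        raise ValueError(
            f"expected one gamma and one (Q, N_RF) frequency block per input "
            f"dimension; got x:{x.shape}, gammas:{gammas.shape}, omegas:{omegas.shape}"
        )
    _, n_q, n_rf = omegas.shape
    if sensitivities is None:
        sensitivities = np.ones(n_q)
    sensitivities = np.asarray(sensitivities, dtype=float)
    acc = np.zeros((n_q, n_rf), dtype=complex)
    for m in range(x.shape[0]):
        acc += rfrf_complex(x[m], gammas[m], omegas[m])
    acc *= np.sqrt(sensitivities[:, None] ** 2 / n_rf)
    return acc.reshape(n_q * n_rf)


def rfrf_feature_matrix(F, gammas, omegas, sensitivities=None) -> np.ndarray:
    """Realified RFRF design matrix Φ_LFM(F) ∈ R^{N × 2QN_RF} (numpy path).

    This is the reference (non-autodiff) evaluation used by tests and by the
    shallow LFM-RFF; the trainable layers in :mod:`deeplfm.rff` rebuild the
    same expression from differentiable primitives.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    rows = [
        rfrf_realify(rfrf_multidim(F[n], gammas, omegas, sensitivities))
        for n in range(F.shape[0])
    ]
    return np.stack(rows, axis=0)


# ------------------------------------------------------------- EQ baseline
def eq_rff(F, Omega, sigma2: float) -> np.ndarray:
    """Plain EQ random features √(σ²/N_RF)[cos(FΩ), sin(FΩ)] (the DGP-RFF map)."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    F = np.atleast_2d(np.asarray(F, dtype=float))
    Omega = np.asarray(Omega, dtype=float)
    n_rf = Omega.shape[1]
    proj = F @ Omega
    return np.sqrt(sigma2 / n_rf) * np.concatenate([np.cos(proj), np.sin(proj)], axis=1)


def lfm_kernel_rfrf_estimate(t, t2, gamma: float, kernel: LatentForceKernel,
                             n_rf: int, rng: np.random.Generator,
                             sensitivities=None) -> float:
    """Feature-space estimate Σ_q (S_q²/N_RF) Σ_s φ(t, ω_{q,s}) φ*(t', ω_{q,s}).

    Monte-Carlo approximation of the LFM covariance for one (t, t') pair
    under a fresh spectral draw; used to check convergence to the
    double-integral oracle.
    """
    omegas = kernel.sample_frequencies(n_rf, rng)
    if sensitivities is None:
        sensitivities = np.ones(kernel.n_forces)
    total = 0.0
    for q in range(kernel.n_forces):
        phi_t = rfrf_complex(t, gamma, omegas[q])
        phi_t2 = rfrf_complex(t2, gamma, omegas[q])
        total += sensitivities[q] ** 2 / n_rf * np.real(np.sum(phi_t * np.conj(phi_t2)))
    return float(total)
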