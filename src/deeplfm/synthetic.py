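"""Synthetic data generators: the compositional toy ODE system, CHARIS-like
multi-output pulse signals, and the imputation/extrapolation split protocols.

The toy system chains two first-order filters driven by the same sinusoidal
latent force,

    f1(t)      = ∫_0^t  G1(t − τ)  u(τ)  dτ,        G_i(x) = e^{-γ_i x},
    f2(f1(t))  = ∫_0^{f1(t)} G2(f1(t) − τ') u(τ') dτ',
    y2(t)      = f2(t) + ε,

with default latent force u(t) = cos(0.5 t) + 6 sin(3 t), which produces a
pulse train with varying amplitude.  For sinusoidal forces both integrals
have elementary closed forms (used here and cross-checked against
quadrature in the tests); arbitrary callables fall back to adaptive
quadrature.

Default reconstruction choices (γ1 = γ2 = 1, t ∈ [0, 15] at 500 points,
noise sd = 5% of the clean signal's sd) are stated defaults of this
package, tuned only to reproduce the pulse-train morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ToySystemSpec",
    "SplitSpec",
    "simulate_toy",
    "simulate_charis_like",
    "make_split",
]


# --------------------------------------------------------------- toy system
def _filter_cos(t, gamma, w):
    """∫_0^t e^{-γ(t-τ)} cos(wτ) dτ (exact; valid for any real t)."""
    den = gamma**2 + w**2
    return (gamma * np.cos(w * t) + w * np.sin(w * t) - gamma * np.exp(-gamma * t)) / den


def _filter_sin(t, gamma, w):
    """∫_0^t e^{-γ(t-τ)} sin(wτ) dτ (exact; valid for any real t)."""
    den = gamma**2 + w**2
    return (gamma * np.sin(w * t) - w * np.cos(w * t) + w * np.exp(-gamma * t)) / den


@dataclass(frozen=True)
class ToySystemSpec:
    """Configuration of the two-stage toy dynamical system.

    ``cos_terms`` / ``sin_terms`` are (amplitude, frequency) pairs defining
    u(t) = Σ a·cos(wt) + Σ b·sin(wt); a general callable force can be given
    instead, at the cost of quadrature.  ``noise_sd`` of ``None`` means 5%
    of the empirical sd of the clean f2 signal.
    """

    cos_terms: tuple = ((1.0, 0.5),)
    sin_terms: tuple = ((6.0, 3.0),)
    force: object = None  # optional callable u(t); overrides the sinusoid terms
    gamma1: float = 1.0
    gamma2: float = 1.0
    noise_sd: float | None = None
    t_min: float = 0.0
    t_max: float = 15.0
    n_points: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.gamma1 <= 0 or self.gamma2 <= 0:
            raise ValueError("stage decays must be positive")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")

    def u(self, t):
        if self.force is not None:
            return self.force(t)
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for a, w in self.cos_terms:
            out = out + a * np.cos(w * t)
        for b, w in self.sin_terms:
            out = out + b * np.sin(w * t)
        return out

    def filter_response(self, s, gamma):
        """F(s) = ∫_0^s e^{-γ(s-τ)} u(τ) dτ, elementwise over ``s``."""
        s = np.asarray(s, dtype=float)
        if self.force is not None:
            from .oracles import filter_response_quadrature

            return np.array([filter_response_quadrature(self.force, gamma, si) for si in np.atleast_1d(s)]).reshape(s.shape)
        out = np.zeros_like(s)
        for a, w in self.cos_terms:
            out = out + a * _filter_cos(s, gamma, w)
        for b, w in self.sin_terms:
            out = out + b * _filter_sin(s, gamma, w)
        return out


def simulate_toy(spec: ToySystemSpec) -> pd.DataFrame:
    """Simulate the compositional system; returns columns (t, f1, f2, y2)."""
    t = np.linspace(spec.t_min, spec.t_max, spec.n_points)
    f1 = spec.filter_response(t, spec.gamma1)
    f2 = spec.filter_response(f1, spec.gamma2)
    sd = spec.noise_sd if spec.noise_sd is not None else 0.05 * float(np.std(f2))
    rng = np.random.default_rng(spec.seed)
    y2 = f2 + sd * rng.standard_normal(f2.shape)
    return pd.DataFrame({"t": t, "f1": f1, "f2": f2, "y2": y2})


# --------------------------------------------------- CHARIS-like pulse signals
def simulate_charis_like(n_outputs: int = 3, n_steps: int = 1000, seed: int = 0,
                         t_max: float = 10.0, q: int = 1, noise_sd: float = 0.05):
    """Correlated nonstationary multi-output pulse signals on a regular grid.

    Draws one prior sample from a two-layer inducing-point DLFM (M = 0, pure
    pathwise prior) whose outputs share latent forces, emulating the regular
    sampling and shared-drive structure of physiological recordings
    (ECG/ABP/ICP-like).  Sampling from the model family's own prior gives
    parameter-recovery tests a known ground truth.

    Returns ``(frame, latents)``: a DataFrame with columns t, f_1..f_D
    (clean) and y_1..y_D (noisy), plus the latent first-layer sample.
    """
    if n_steps < 100:
        raise ValueError("n_steps must be at least 100")
    from .vip import DLFMVIP

    t = np.linspace(0.0, t_max, n_steps)
    x = t[:, None]
    rng = np.random.default_rng(seed)
    model = DLFMVIP(
        layer_dims=[1, n_outputs, n_outputs],
        n_forces=q,
        n_inducing=0,
        n_basis=256,
        ell_init=1.0,
        gamma_init=2.0,
        input_range=(0.0, t_max),
        resample="full",
        seed=int(rng.integers(2**31 - 1)),
    )
    samples, per_layer = model.sample_layers(x, n_samples=1, seed=int(rng.integers(2**31 - 1)))
    clean = samples[0]  # (n_steps, n_outputs)
    # rescale each output to unit sd so channels are comparable
    scale = clean.std(axis=0)
    scale[scale == 0] = 1.0
    clean = clean / scale
    noisy = clean + noise_sd * rng.standard_normal(clean.shape)
    data = {"t": t}
    for d in range(n_outputs):
        data[f"f_{d + 1}"] = clean[:, d]
    for d in range(n_outputs):
        data[f"y_{d + 1}"] = noisy[:, d]
    frame = pd.DataFrame(data)
    latents = {"layer1": per_layer[0][0] / per_layer[0][0].std(axis=0)}
    return frame, latents


# ------------------------------------------------------------------- splits
@dataclass(frozen=True)
class SplitSpec:
    """Train/test split protocol.

    ``imputation`` removes ``n_blocks`` non-overlapping contiguous blocks of
    ``block_len`` points from each output; ``extrapolation`` holds out
    everything at or beyond ``boundary``; ``random`` holds out a uniform
    sample of ``block_len·n_blocks`` points per output.
    """

    mode: str = "imputation"
    block_len: int = 150
    n_blocks: int = 1
    boundary: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("imputation", "extrapolation", "random"):
            raise ValueError(f"unknown split mode {self.mode!r}")


def make_split(n_points: int, spec: SplitSpec, n_outputs: int = 1) -> np.ndarray:
    """Boolean test mask of shape (n_points, n_outputs); True marks test points."""
    rng = np.random.default_rng(spec.seed)
    mask = np.zeros((n_points, n_outputs), dtype=bool)
    if spec.mode == "extrapolation":
        if spec.boundary is None or not 0 < spec.boundary < n_points:
            raise ValueError("extrapolation split needs a boundary inside the series")
        mask[spec.boundary:, :] = True
        return mask
    total = spec.block_len * spec.n_blocks
    if total > n_points:
        raise ValueError(
            f"requested {total} removed points but the series has only {n_points}"
        )
    for d in range(n_outputs):
        if spec.mode == "random":
            idx = rng.choice(n_points, size=total, replace=False)
            mask[idx, d] = True
            continue
        # place non-overlapping blocks by sampling gaps around them
        free = n_points - total
        cuts = np.sort(rng.choice(free + 1, size=spec.n_blocks, replace=False))
        start = 0
        for i, c in enumerate(cuts):
            s = c + i * spec.block_len
            mask[s : s + spec.block_len, d] = True
            start = s + spec.block_len
        assert start <= n_points
    return mask
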