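"""Inducing-point deep latent force model (DLFM-VIP).

Each layer draws functional samples from its Q latent EQ Gaussian
processes by pathwise (Matheron) sampling,

    u_q^{(s)}(·) = Σ_i w_i φ_i(·) + k(·, z_q) K⁻¹ (v_q − Φ w),
    φ_i(x) = √(2/B) cos(θ_iᵀ x + β_i),   θ_i ~ N(0, 2/ℓ_q²),  β_i ~ U(0, 2π),

and maps them *analytically* through the exponential-filter convolution
with lower limit −∞,

    f_d(x) = Σ_q a_{d,q} ∫_{-∞}^{x} Π_p e^{-γ_{d,p}(x_p - z_p)} u_q^{(s)}(z) dz.

Both pieces of the sample admit closed-form convolutions: the cosine basis
through (γ cosφ + θ sinφ)/(γ² + θ²) (complex product across dimensions),
and the EQ canonical functions k(·, z_m) through a complementary-error-
function expression (evaluated through erfcx to avoid overflow; see
:func:`deeplfm._ad.conv_eq_canonical_op`).  Because the lower limit is −∞
the samples do not collapse to an initial condition at the origin.

Layers compose by feeding the multi-output sample of layer ℓ as evaluation
points of layer ℓ+1; training maximises the doubly stochastic bound

    L = Σ_i (1/S) Σ_s log p(y_i | F_i^{L,(s)}) − Σ_ℓ KL[q(Vℓ) ‖ p(Vℓ)],

with q(v_q) = N(μ_q, Σ_q) and prior p(v_q) = N(0, K_{u_q u_q}(z_q, z_q)).
"""

from __future__ import annotations

import numpy as np

from ._ad import (
    Tensor,
    astensor,
    concatenate,
    conv_eq_canonical_op,
    inv_psd,
    logdet_psd,
    parameter,
)
from .rff import softplus_inv

__all__ = ["conv_cosine", "conv_eq_canonical", "VIPLayer", "DLFMVIP"]

_SQRT2 = np.sqrt(2.0)
# Nugget folded into the prior covariance of the inducing variables, making
# p(V) = N(0, K + σ_n² I); keeps the KL term well conditioned when inducing
# inputs crowd within a lengthscale.
_PRIOR_NUGGET = 1e-4
# Initial sd of the variational distribution over inducing outputs: small,
# so that the posterior starts concentrated and no variance is carried in
# directions outside the numerical range of K.
_SIGMA_INIT_SD = 0.01


# --------------------------------------------------- convolution primitives
def conv_cosine(gamma, theta, beta, x):
    """∫_{-∞}^{x} e^{-γ(x-z)} cos(θz + β) dz = (γ cos(θx+β) + θ sin(θx+β))/(γ²+θ²).

    Plain-numpy closed form (the differentiable layers re-express it through
    autodiff primitives); broadcasts over all arguments.
    """
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma <= 0):
        raise ValueError("gamma must be positive")
    phase = np.asarray(theta) * np.asarray(x) + np.asarray(beta)
    return (gamma * np.cos(phase) + theta * np.sin(phase)) / (gamma**2 + theta**2)


def conv_eq_canonical(gamma, ell, x, zm):
    """∫_{-∞}^{x} e^{-γ(x-z)} exp(-(z-z_m)²/ℓ²) dz, overflow-safe closed form."""
    gamma = np.asarray(gamma, dtype=float)
    ell = np.asarray(ell, dtype=float)
    if np.any(gamma <= 0) or np.any(ell <= 0):
        raise ValueError("gamma and ell must be positive")
    return conv_eq_canonical_op(gamma, ell, x, zm).data


def _safe_inv_psd(k: Tensor):
    """Cholesky-based inverse with a condition-aware jitter ladder.

    When the kernel matrix is comfortably positive definite the solve uses
    no jitter at all, so the Matheron update interpolates the sampled
    inducing outputs to solver precision; when inducing inputs crowd within
    a lengthscale the eigenvalue floor engages and jitter escalates instead
    of letting K⁻¹ amplify round-off null-space junk.
    """
    lam = np.linalg.eigvalsh(0.5 * (k.data + k.data.T))
    if lam[-1] <= 0:
        raise np.linalg.LinAlgError("kernel matrix has no positive eigenvalues")
    if lam[0] > max(1e-10, 1e-7 * lam[-1]):
        return inv_psd(k, jitter=0.0), 0.0
    for jit in (1e-6, 1e-4, 1e-2):
        try:
            return inv_psd(k, jitter=jit), jit
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        "covariance of inducing variables not positive definite even at jitter 1e-2"
    )


# ------------------------------------------------------------------- layer
class VIPLayer:
    """One inducing-point DLFM layer (P inputs, D outputs, Q latent forces)."""

    def __init__(self, in_dim, out_dim, n_forces=1, n_inducing=20, n_basis=256,
                 rng=None, gamma_init=1.0, ell_init=1.0, z_low=-2.0, z_high=2.0,
                 trainable_z=True, resample="weights", identity_init=False,
                 index=0):
        if resample not in ("weights", "full"):
            raise ValueError(f"unknown basis resampling policy {resample!r}")
        rng = rng or np.random.default_rng()
        self.resample = resample
        self.identity_init = identity_init
        self.in_dim, self.out_dim = in_dim, out_dim
        self.n_forces, self.n_inducing, self.n_basis = n_forces, n_inducing, n_basis
        self.trainable_z = trainable_z
        self.index = index
        self.ell_raw = parameter(np.full(n_forces, softplus_inv(ell_init)))
        self.gamma_raw = parameter(np.full((out_dim, in_dim), softplus_inv(gamma_init)))
        self.a = parameter(np.ones((out_dim, n_forces)))
        self.z, self.mu, self.l_factor = [], [], []
        self._tril_mask = np.tril(np.ones((n_inducing, n_inducing)))
        for _ in range(n_forces):
            grid = np.linspace(z_low, z_high, max(n_inducing, 1))[:, None]
            z0 = np.repeat(grid, in_dim, axis=1)
            if in_dim > 1:  # decorrelate the per-dimension grids
                for p in range(1, in_dim):
                    z0[:, p] = rng.permutation(z0[:, p])
            zp = parameter(z0[:n_inducing])
            zp.requires_grad = trainable_z
            self.z.append(zp)
            q = len(self.mu)
            if identity_init and n_inducing > 0:
                # hidden layers start as a monotone map of one input
                # coordinate (u ≈ x at the inducing inputs) so that depth
                # does not collapse the input structure at initialisation
                self.mu.append(parameter(z0[:n_inducing, q % in_dim].copy()))
            else:
                self.mu.append(parameter(np.zeros(n_inducing)))
            self.l_factor.append(
                parameter(_SIGMA_INIT_SD * np.eye(n_inducing))
            )
        self._frozen = None  # optional fixed basis draws (see freeze_basis)
        # Fixed Fourier frequencies/phases for the default "weights" policy:
        # the sparse-spectrum basis is pinned per layer while the pathwise
        # weights w and inducing-value draws η stay fresh per sample, which
        # keeps the Matheron update and predictive spread honest but removes
        # basis-churn noise from the training gradients.
        self._fixed_angles = [
            dict(
                eps_theta=rng.standard_normal((1, n_basis, in_dim)),
                beta=rng.uniform(0.0, 2.0 * np.pi, (1, n_basis)),
            )
            for _ in range(n_forces)
        ]

    @staticmethod
    def _kernel_np(z, ell):
        d2 = ((z[:, None, :] - z[None, :, :]) ** 2).sum(-1)
        return np.exp(-d2 / ell**2)

    # ------------------------------------------------------------------ api
    def parameters(self):
        out = [self.ell_raw, self.gamma_raw, self.a]
        for q in range(self.n_forces):
            if self.trainable_z and self.n_inducing > 0:
                out.append(self.z[q])
            if self.n_inducing > 0:
                out += [self.mu[q], self.l_factor[q]]
        return out

    def freeze_basis(self, seed=0):
        """Fix the pathwise basis/weight draws (disables per-sample resampling)."""
        rng = np.random.default_rng(seed)
        self._frozen = self._draw_basis(rng, 1)

    def thaw_basis(self):
        self._frozen = None

    def _draw_basis(self, rng, n_samples):
        draws = []
        for q in range(self.n_forces):
            if self.resample == "full":
                angles = dict(
                    eps_theta=rng.standard_normal((n_samples, self.n_basis, self.in_dim)),
                    beta=rng.uniform(0.0, 2.0 * np.pi, (n_samples, self.n_basis)),
                )
            else:
                angles = dict(
                    eps_theta=np.repeat(self._fixed_angles[q]["eps_theta"], n_samples, axis=0),
                    beta=np.repeat(self._fixed_angles[q]["beta"], n_samples, axis=0),
                )
            draws.append(
                dict(
                    **angles,
                    w=rng.standard_normal((n_samples, self.n_basis)),
                    eta=rng.standard_normal((n_samples, self.n_inducing)),
                )
            )
        return draws

    def _kernel_graph(self, z: Tensor, ell: Tensor) -> Tensor:
        m = z.shape[0]
        za = z.reshape(m, 1, self.in_dim)
        zb = z.reshape(1, m, self.in_dim)
        d2 = ((za - zb) ** 2.0).sum(axis=2)
        return (-1.0 * d2 / (ell * ell)).exp()

    def _latent_state(self, q, draws, n_samples):
        """Per-force pathwise state: basis tensors and the Matheron update coefs."""
        ell = self.ell_raw[q].softplus()
        d = draws[q]
        theta = (_SQRT2 / ell) * Tensor(d["eps_theta"])  # (S, B, P)
        beta = Tensor(d["beta"])                          # (S, B)
        w = Tensor(d["w"])                                # (S, B)
        state = dict(ell=ell, theta=theta, beta=beta, w=w)
        if self.n_inducing == 0:
            return state
        z = self.z[q]
        # prior sample at the inducing inputs: (S, M, B) basis matrix
        proj = z @ theta.transpose(0, 2, 1)               # (S, M, B)
        phi_ind = np.sqrt(2.0 / self.n_basis) * (proj + beta.reshape(n_samples, 1, self.n_basis)).cos()
        prior_z = (phi_ind * w.reshape(n_samples, 1, self.n_basis)).sum(axis=2)  # (S, M)
        l_tril = self.l_factor[q] * self._tril_mask
        v = self.mu[q].reshape(1, self.n_inducing) + (
            l_tril @ Tensor(d["eta"]).reshape(n_samples, self.n_inducing, 1)
        ).reshape(n_samples, self.n_inducing)
        kmat = self._kernel_graph(z, ell)
        kinv, jit = _safe_inv_psd(kmat)
        alpha = (v - prior_z) @ kinv                      # (S, M), K symmetric
        state.update(z=z, v=v, alpha=alpha, kinv=kinv, kmat=kmat, l_tril=l_tril,
                     phi_ind=phi_ind)
        return state

    def latent_eval(self, state, x: Tensor, n_samples) -> Tensor:
        """Evaluate the pathwise latent sample u_q^{(s)} at points x (S, N, P)."""
        n = x.shape[1]
        b = self.n_basis
        proj = x @ state["theta"].transpose(0, 2, 1)      # (S, N, B)
        phi = np.sqrt(2.0 / b) * (proj + state["beta"].reshape(n_samples, 1, b)).cos()
        out = (phi * state["w"].reshape(n_samples, 1, b)).sum(axis=2)
        if self.n_inducing == 0:
            return out
        z, ell = state["z"], state["ell"]
        xa = x.reshape(n_samples, n, 1, self.in_dim)
        zb = z.reshape(1, 1, self.n_inducing, self.in_dim)
        d2 = ((xa - zb) ** 2.0).sum(axis=3)               # (S, N, M)
        kx = (-1.0 * d2 / (ell * ell)).exp()
        update = (kx * state["alpha"].reshape(n_samples, 1, self.n_inducing)).sum(axis=2)
        return out + update

    def _convolved_basis(self, state, gamma_d: Tensor, x: Tensor, n_samples):
        """Re{e^{jβ} Π_p e^{jθ_p x_p}/(γ_p + jθ_p)} for every basis term: (S, N, B)."""
        b = self.n_basis
        beta = state["beta"].reshape(n_samples, 1, b)
        re, im = beta.cos(), beta.sin()
        for p in range(self.in_dim):
            th = state["theta"][:, :, p].reshape(n_samples, 1, b)   # (S, 1, B)
            xp = x[:, :, p : p + 1]                                  # (S, N, 1)
            g = gamma_d[p]
            phase = xp * th
            cr, ci = phase.cos(), phase.sin()
            den = g * g + th * th
            fr = (cr * g + ci * th) / den
            fi = (ci * g - cr * th) / den
            re, im = re * fr - im * fi, re * fi + im * fr
        return re

    def output_sample(self, x: Tensor, draws, n_samples) -> Tensor:
        """Map pathwise latent samples through the analytic convolution.

        x has shape (S, N, P); returns (S, N, D).
        """
        states = [self._latent_state(q, draws, n_samples) for q in range(self.n_forces)]
        n = x.shape[1]
        cols = []
        for d in range(self.out_dim):
            gamma_d = self.gamma_raw[d].softplus()        # (P,)
            acc = None
            for q, state in enumerate(states):
                conv_re = self._convolved_basis(state, gamma_d, x, n_samples)
                part = np.sqrt(2.0 / self.n_basis) * (
                    conv_re * state["w"].reshape(n_samples, 1, self.n_basis)
                ).sum(axis=2)                              # (S, N)
                if self.n_inducing > 0:
                    prod = None
                    for p in range(self.in_dim):
                        term = conv_eq_canonical_op(
                            gamma_d[p],
                            state["ell"],
                            x[:, :, p].reshape(n_samples, n, 1),
                            state["z"][:, p].reshape(1, 1, self.n_inducing),
                        )
                        prod = term if prod is None else prod * term
                    part = part + (
                        prod * state["alpha"].reshape(n_samples, 1, self.n_inducing)
                    ).sum(axis=2)
                contrib = self.a[d, q] * part
                acc = contrib if acc is None else acc + contrib
            cols.append(acc.reshape(n_samples, n, 1))
        return cols[0] if self.out_dim == 1 else concatenate(cols, axis=2)

    def output_moments(self, x: Tensor, rng, n_samples):
        """Analytic per-point mean and variance of the layer output.

        Conditional on the basis angles and the evaluation points, the
        convolved pathwise sample is linear in the Gaussian draws (w, η),
        so its first two moments are available in closed form:

            f_d = Σ_q a_{d,q} [ C_w w_q + C_η η_q + (conv_can K⁻¹) μ_q ],
            C_w = conv_basis − (conv_can K⁻¹) Φ_ind,
            C_η = (conv_can K⁻¹) L_q.

        Marginalising the output layer this way (instead of sampling it)
        removes all final-layer Monte-Carlo noise from the likelihood term
        of the bound — the same variance reduction that doubly stochastic
        DGP inference obtains by analytically integrating the last GP.
        Returns (mean, var), each (S, N, D).
        """
        if self._frozen is not None:
            draws = [
                {k: np.repeat(v, n_samples, axis=0) for k, v in d.items()}
                for d in self._frozen
            ]
        else:
            draws = self._draw_basis(rng, n_samples)
        states = [self._latent_state(q, draws, n_samples) for q in range(self.n_forces)]
        n = x.shape[1]
        means, variances = [], []
        for d in range(self.out_dim):
            gamma_d = self.gamma_raw[d].softplus()
            mean_acc, var_acc = None, None
            for q, state in enumerate(states):
                conv_b = np.sqrt(2.0 / self.n_basis) * self._convolved_basis(
                    state, gamma_d, x, n_samples
                )  # (S, N, B)
                a_dq = self.a[d, q]
                if self.n_inducing == 0:
                    m_dq = Tensor(np.zeros((n_samples, n)))
                    v_dq = (conv_b * conv_b).sum(axis=2)
                else:
                    prod = None
                    for p in range(self.in_dim):
                        term = conv_eq_canonical_op(
                            gamma_d[p], state["ell"],
                            x[:, :, p].reshape(n_samples, n, 1),
                            state["z"][:, p].reshape(1, 1, self.n_inducing),
                        )
                        prod = term if prod is None else prod * term
                    u_part = prod @ state["kinv"]           # (S, N, M)
                    m_dq = (u_part @ self.mu[q].reshape(self.n_inducing, 1)).reshape(
                        n_samples, n
                    )
                    c_w = conv_b - u_part @ state["phi_ind"]  # (S, N, B)
                    c_eta = u_part @ state["l_tril"]          # (S, N, M)
                    v_dq = (c_w * c_w).sum(axis=2) + (c_eta * c_eta).sum(axis=2)
                mean_acc = a_dq * m_dq if mean_acc is None else mean_acc + a_dq * m_dq
                term_v = (a_dq * a_dq) * v_dq
                var_acc = term_v if var_acc is None else var_acc + term_v
            means.append(mean_acc.reshape(n_samples, n, 1))
            variances.append(var_acc.reshape(n_samples, n, 1))
        if self.out_dim == 1:
            return means[0], variances[0]
        return concatenate(means, axis=2), concatenate(variances, axis=2)

    def forward(self, x: Tensor, rng, n_samples) -> Tensor:
        if self._frozen is not None:
            # broadcast the single frozen draw across samples
            draws = [
                {k: np.repeat(v, n_samples, axis=0) for k, v in d.items()}
                for d in self._frozen
            ]
        else:
            draws = self._draw_basis(rng, n_samples)
        return self.output_sample(x, draws, n_samples)

    def pathwise_latent_sample(self, x, q=0, n_samples=1, rng=None):
        """Numpy convenience: evaluate pathwise samples of force q at x.

        Returns ``(u, v)`` where u has shape (S, N) and v holds the sampled
        inducing outputs (S, M), or None when the layer has no inducing set.
        """
        rng = rng or np.random.default_rng()
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        draws = self._draw_basis(rng, n_samples)
        state = self._latent_state(q, draws, n_samples)
        xt = astensor(np.broadcast_to(x[None], (n_samples,) + x.shape).copy())
        u = self.latent_eval(state, xt, n_samples)
        v = state["v"].data if self.n_inducing > 0 else None
        return u.data, v

    def kl(self) -> Tensor:
        """Σ_q KL[N(μ_q, Σ_q) ‖ N(0, K_q)] with Σ_q = L Lᵀ (full covariance)."""
        if self.n_inducing == 0:
            return Tensor(0.0)
        total = None
        m = self.n_inducing
        for q in range(self.n_forces):
            ell = self.ell_raw[q].softplus()
            kmat = self._kernel_graph(self.z[q], ell)
            kinv = inv_psd(kmat, jitter=_PRIOR_NUGGET)
            l_tril = self.l_factor[q] * self._tril_mask
            sigma = l_tril @ l_tril.T
            mu = self.mu[q].reshape(m, 1)
            trace = (kinv * sigma).sum()
            quad = (mu.T @ kinv @ mu).reshape(())
            term = 0.5 * (
                trace + quad - float(m)
                + logdet_psd(kmat, jitter=_PRIOR_NUGGET) - logdet_psd(sigma, jitter=1e-12)
            )
            total = term if total is None else total + term
        return total

    def prior_covariance(self, q: int = 0) -> np.ndarray:
        """Prior covariance K + σ_n² I of the inducing variables (numpy)."""
        ell = float(np.logaddexp(0.0, self.ell_raw.data[q]))
        k = self._kernel_np(self.z[q].data, ell)
        return k + _PRIOR_NUGGET * np.eye(self.n_inducing)

    # ----------------------------------------------------------- checkpoint
    def state(self, prefix):
        out = {
            f"{prefix}.ell_raw": self.ell_raw.data,
            f"{prefix}.gamma_raw": self.gamma_raw.data,
            f"{prefix}.a": self.a.data,
        }
        for q in range(self.n_forces):
            out[f"{prefix}.z{q}"] = self.z[q].data
            out[f"{prefix}.mu{q}"] = self.mu[q].data
            out[f"{prefix}.l{q}"] = self.l_factor[q].data
            out[f"{prefix}.eps_theta{q}"] = self._fixed_angles[q]["eps_theta"]
            out[f"{prefix}.beta{q}"] = self._fixed_angles[q]["beta"]
        return out

    def load(self, prefix, arrays):
        self.ell_raw.data = arrays[f"{prefix}.ell_raw"].copy()
        self.gamma_raw.data = arrays[f"{prefix}.gamma_raw"].copy()
        self.a.data = arrays[f"{prefix}.a"].copy()
        for q in range(self.n_forces):
            self.z[q].data = arrays[f"{prefix}.z{q}"].copy()
            self.mu[q].data = arrays[f"{prefix}.mu{q}"].copy()
            self.l_factor[q].data = arrays[f"{prefix}.l{q}"].copy()
            self._fixed_angles[q]["eps_theta"] = arrays[f"{prefix}.eps_theta{q}"].copy()
            self._fixed_angles[q]["beta"] = arrays[f"{prefix}.beta{q}"].copy()


# ------------------------------------------------------------------- model
class DLFMVIP:
    """Stacked inducing-point LFM layers with a Gaussian likelihood."""

    family = "vip"

    def __init__(self, layer_dims, n_forces=1, n_inducing=20, n_basis=128,
                 noise_init=0.1, gamma_init=10.0, ell_init=0.1, input_range=(0.0, 1.0),
                 inner_range=(-2.0, 2.0), trainable_z=False, resample="weights",
                 train_inner_covariance=False, seed=0):
        if len(layer_dims) < 2:
            raise ValueError("need at least input and output dimensions")
        self.layer_dims = list(layer_dims)
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.layers = []
        for i in range(len(layer_dims) - 1):
            lo, hi = input_range if i == 0 else inner_range
            # extend the grid below the evaluation range by the filter
            # memory ≈ 6/γ so the convolution tail is covered by inducing
            # points (otherwise the unconstrained prior mass there, amplified
            # by the sensitivities, inflates the likelihood noise for every
            # point near the lower edge)
            lo = lo - min(6.0 / gamma_init, 1.0 * (hi - lo))
            self.layers.append(
                VIPLayer(
                    layer_dims[i], layer_dims[i + 1], n_forces=n_forces,
                    n_inducing=n_inducing, n_basis=n_basis, rng=rng,
                    gamma_init=gamma_init, ell_init=ell_init,
                    z_low=lo, z_high=hi, trainable_z=trainable_z,
                    resample=resample,
                    identity_init=i < len(layer_dims) - 2,
                    index=i,
                )
            )
            self.layers[-1]._init_range = (lo, hi)
        self.noise_raw = parameter(softplus_inv(noise_init))
        # Restricted variational family for hidden layers: their covariance
        # factors stay at the small initial value unless asked otherwise,
        # which keeps hidden-layer samples concentrated and the doubly
        # stochastic gradients informative (the bound remains a valid ELBO
        # over the restricted family).
        if not train_inner_covariance:
            for layer in self.layers[:-1]:
                for lf in layer.l_factor:
                    lf.requires_grad = False
        self._initialized = False
        self._calibrate_amplitudes(np.random.default_rng((seed, 1)))

    def initialize_from_data(self, x, n_draws=6):
        """Data-dependent initialisation of inducing grids and amplitudes.

        Propagates the training inputs through the layers once, placing each
        layer's inducing inputs evenly over the empirical range of its
        incoming activations (extended below by the filter memory ≈ 3/γ so
        the convolution tail stays covered), re-seating the identity-like
        means of hidden layers on the new grid, and rescaling sensitivities
        so every layer emits unit-scale activations for the actual data.
        Deterministic given the model seed; called automatically by
        :func:`deeplfm.training.fit`.
        """
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        rng = np.random.default_rng((self.seed, 2))
        f = np.broadcast_to(x[None], (n_draws,) + x.shape).copy()
        for layer in self.layers:
            gamma = np.logaddexp(0.0, layer.gamma_raw.data)      # (D, P)
            lo = f.min(axis=(0, 1))
            hi = f.max(axis=(0, 1))
            span = np.where(hi > lo, hi - lo, 1.0)
            tail = np.minimum(6.0 / gamma.min(axis=0), 1.0 * span)
            if layer.n_inducing > 0:
                for q in range(layer.n_forces):
                    grid = np.stack(
                        [
                            np.linspace(lo[p] - tail[p], hi[p], layer.n_inducing)
                            for p in range(layer.in_dim)
                        ],
                        axis=1,
                    )
                    for p in range(1, layer.in_dim):
                        grid[:, p] = rng.permutation(grid[:, p])
                    layer.z[q].data = grid
                    if layer.identity_init:
                        layer.mu[q].data = grid[:, q % layer.in_dim].copy()
                    else:
                        layer.mu[q].data = np.zeros(layer.n_inducing)
            layer.a.data = np.ones_like(layer.a.data)
            xt = astensor(f)
            out = layer.forward(xt, rng, n_draws).data           # (S, N, D)
            sd = out.reshape(-1, layer.out_dim).std(axis=0)
            sd[sd == 0] = 1.0
            layer.a.data /= sd[:, None]
            f = out / sd[None, None, :]
        self._initialized = True

    def _calibrate_amplitudes(self, rng, n_grid=40, n_draws=8):
        """Scale each layer's sensitivities so prior outputs have unit sd.

        The exponential filter attenuates by roughly 1/γ, which would leave
        deep compositions with vanishing signal at initialisation; this
        one-time rescaling of a_{d,q} makes every layer's prior marginal
        variance ≈ 1 on its initial input range.
        """
        for layer in self.layers:
            lo, hi = layer._init_range
            grid = rng.uniform(lo, hi, size=(n_grid, layer.in_dim))
            grid[:, 0] = np.sort(grid[:, 0])
            xt = astensor(np.broadcast_to(grid[None], (n_draws,) + grid.shape).copy())
            out = layer.forward(xt, rng, n_draws).data  # (S, N, D)
            sd = out.reshape(-1, layer.out_dim).std(axis=0)
            sd[sd == 0] = 1.0
            layer.a.data /= sd[:, None]

    @property
    def noise_variance(self) -> Tensor:
        return self.noise_raw.softplus()

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()] + [self.noise_raw]

    def parameter_groups(self):
        """Variational parameters vs point-estimated hyperparameters."""
        variational, hyper = [], [self.noise_raw]
        for layer in self.layers:
            hyper += [layer.ell_raw, layer.gamma_raw, layer.a]
            for q in range(layer.n_forces):
                if layer.n_inducing > 0:
                    variational += [layer.mu[q], layer.l_factor[q]]
                    if layer.trainable_z:
                        hyper.append(layer.z[q])
        return {"variational": variational, "hyper": hyper}

    def forward(self, x, rng, n_samples=1) -> Tensor:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        xt = astensor(np.broadcast_to(x[None], (n_samples,) + x.shape).copy())
        f = xt
        for layer in self.layers:
            f = layer.forward(f, rng, n_samples)
        return f

    def sample_layers(self, x, n_samples=1, seed=0):
        """Per-layer sample tensors (numpy); returns (final, [layer outputs])."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        rng = np.random.default_rng((self.seed, seed))
        f = astensor(np.broadcast_to(x[None], (n_samples,) + x.shape).copy())
        per_layer = []
        for layer in self.layers:
            f = layer.forward(f, rng, n_samples)
            per_layer.append(f.data.copy())
        return per_layer[-1], per_layer

    def kl(self) -> Tensor:
        total = self.layers[0].kl()
        for layer in self.layers[1:]:
            total = total + layer.kl()
        return total

    def elbo(self, x, y, n_total=None, mask=None, n_samples=1, rng=None) -> Tensor:
        """Doubly stochastic bound: minibatch-scaled likelihood minus layer KLs."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if x.shape[0] == 0:
            raise ValueError("empty minibatch")
        if n_samples < 1:
            raise ValueError("need at least one sample")
        rng = rng or np.random.default_rng()
        n_batch = x.shape[0]
        n_total = n_total if n_total is not None else n_batch
        obs = np.ones_like(y, dtype=bool) if mask is None else mask
        y_filled = np.where(obs, y, 0.0)
        sigma2 = self.noise_variance
        # propagate samples through the hidden layers, marginalise the last
        f = astensor(np.broadcast_to(x[None], (n_samples,) + x.shape).copy())
        for layer in self.layers[:-1]:
            f = layer.forward(f, rng, n_samples)
        mean, var = self.layers[-1].output_moments(f, rng, n_samples)
        resid2 = (Tensor(y_filled[None]) - mean) ** 2.0
        ll = (
            (-0.5) * (resid2 + var) / sigma2
            - 0.5 * sigma2.log()
            - 0.5 * np.log(2.0 * np.pi)
        )
        lik = (ll * obs[None].astype(float)).sum() * (1.0 / n_samples)
        lik = lik * (n_total / n_batch)
        return lik - self.kl()

    def predict(self, x, n_samples=50, seed=0) -> np.ndarray:
        """S end-to-end pathwise samples, shape (S, N, D)."""
        if n_samples < 1:
            raise ValueError("need at least one sample")
        rng = np.random.default_rng((self.seed, seed))
        f = self.forward(x, rng, n_samples=n_samples)
        return f.data

    def set_inducing_range(self, low, high):
        """Re-initialise first-layer inducing inputs evenly over [low, high]."""
        layer = self.layers[0]
        for q in range(layer.n_forces):
            if layer.n_inducing == 0:
                continue
            grid = np.linspace(low, high, layer.n_inducing)[:, None]
            layer.z[q].data = np.repeat(grid, layer.in_dim, axis=1)

    # ----------------------------------------------------------- checkpoint
    def state_dict(self):
        arrays = {"noise_raw": self.noise_raw.data}
        for i, layer in enumerate(self.layers):
            arrays.update(layer.state(f"layer{i}"))
        meta = {
            "format": 1,
            "family": self.family,
            "layer_dims": self.layer_dims,
            "seed": self.seed,
            "n_forces": self.layers[0].n_forces,
            "n_inducing": self.layers[0].n_inducing,
            "n_basis": self.layers[0].n_basis,
        }
        return meta, arrays

    def load_state_dict(self, arrays):
        self.noise_raw.data = np.asarray(arrays["noise_raw"]).copy()
        for i, layer in enumerate(self.layers):
            layer.load(f"layer{i}", arrays)
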