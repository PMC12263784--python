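# Methods

## Model

A deep latent force model (DLFM) is a deep Gaussian process in which every
layer is a first-order-ODE latent force model. Each layer receives an input
vector x and returns outputs

    f_d(x) = Σ_q S_{d,q} ∫ G_d(x − z) u_q(z) dz,      G(x) = e^{−γx},

where the latent forces u_q are independent GPs with exponentiated-quadratic
(EQ) kernels k_q(τ, τ') = exp(−(τ−τ')²/ℓ_q²) and γ is the decay of the ODE
df/dt + γf = Σ_q S_q u_q. Layers compose: the outputs of layer ℓ are the
evaluation points of layer ℓ+1. The Green's function acts as a learnable
low-pass filter per layer; as γ → ∞ it approaches a Dirac impulse with mass
1/γ and the layer degenerates to its latent EQ GP, so the model can turn its
mechanistic bias off where the data do not support it.

Two inference formulations are implemented.

**Weight-space (`DLFMRFF`).** The convolution of EQ random Fourier features
with the Green's function over [0, t] has the closed form
φ(t, γ, ω) = (e^{jωt} − e^{−γt})/(γ + jω) — the random Fourier *response*
feature. Features are realified as [Re, Im], summed over input dimensions
for multivariate inputs, scaled by √(S_q²/N_RF), and followed by a linear
weight layer plus a learnable bias c_d (the initial condition: every sample
satisfies y_d(0) = c_d). Variational Gaussians are placed over weights (prior
N(0,1)) and spectral frequencies (prior N(0, 2/ℓ²)); the frequency noise
draws are fixed once at construction and reused for every iteration
(VAR-FIXED), so frequencies move only through their variational mean and
scale. Training uses the local reparameterization trick; at prediction time
reparameterization can be disabled, making the S predictive draws a
deterministic function of the variational state and the seed. When enabled
at test time, the spectral frequencies are additionally resampled from the
variational posterior rather than anchored at the fixed draws, which widens
the predictive spread; local reparameterization on its own leaves per-point
predictive marginals unchanged in distribution, so the extra Ω-sampling is
what actually carries the "noisier predictions" behaviour.

Setting `feature_type="eq"` replaces the response features by the plain
cos/sin map √(σ²/N_RF)[cos(FΩ), sin(FΩ)], recovering the standard DGP with
random feature expansions inside the identical architecture, bound and
optimiser — the matched non-physics baseline used in the experiments.

**Inducing-point (`DLFMVIP`).** Each latent force carries M inducing inputs
z_q with a full-covariance variational Gaussian q(v_q) = N(μ_q, Σ_q),
Σ_q = L Lᵀ. Functional samples follow Matheron's rule: a sparse-spectrum
prior sample Σ_i w_i √(2/B) cos(θ_iᵀx + β_i) plus the update
k(·, z) K⁻¹ (v − Φw). Both parts pass through the convolution with lower
limit −∞ analytically:

* cosine basis: ∫_{−∞}^{x} e^{−γ(x−z)} cos(θz+β) dz
  = (γ cos(θx+β) + θ sin(θx+β)) / (γ² + θ²); for P input dimensions the
  separable filter gives a complex product of per-dimension factors
  e^{jθ_p x_p}/(γ_p + jθ_p);
* EQ canonical functions: completing the square gives
  ∫_{−∞}^{x} e^{−γ(x−z)} e^{−(z−z_m)²/ℓ²} dz
  = (√π ℓ/2) · erfcx(γℓ/2 − r/ℓ) · e^{−r²/ℓ²}, r = x − z_m, evaluated
  through the scaled complement erfcx so no overflow occurs at large γℓ
  (a two-branch form handles the far right tail). Both forms are validated
  against adaptive quadrature to 1e−7 across logarithmic parameter grids.

Because the lower limit is −∞, samples near the origin are unconstrained —
there is no initial-condition collapse, unlike the weight-space family.

The bound is the doubly stochastic ELBO
Σ_i (1/S) Σ_s log p(y_i|F_i^{L,(s)}) − Σ_ℓ KL[q(Vℓ)‖p(Vℓ)], with
p(Vℓ) = N(0, K + σ_n²I) (σ_n² = 1e−4; the tiny nugget keeps the KL well
conditioned when inducing points crowd within a lengthscale) and a Gaussian
likelihood with shared variance σ_y².

## Variance control in the inducing-point bound

Naive Monte-Carlo estimation of the likelihood term proved too noisy for
desk-scale budgets (the gradient signal-to-noise for the covariance factors
was ~0.01). Four measures, all of which preserve the bound's validity:

1. **Analytic output layer.** Conditional on the basis angles and the
   incoming sample, the pathwise output is linear in the Gaussian draws
   (w, η), so its per-point mean and variance are closed-form
   (`VIPLayer.output_moments`); the likelihood term uses the exact Gaussian
   expectation instead of sampling the final layer. Hidden layers remain
   sampled — the estimator is still doubly stochastic, just Rao-
   Blackwellised at the top, mirroring how doubly stochastic DGP inference
   integrates its final GP analytically.
2. **Fixed sparse-spectrum basis.** By default θ_i, β_i are drawn once per
   layer and pinned; the pathwise weights w and inducing-value draws η stay
   fresh per sample. This is the classic sparse-spectrum GP approximation;
   full per-sample redrawing (`resample="full"`) is retained and used in
   the prior-covariance tests, but pinning removes basis churn from the
   training gradients. B = 128 basis functions bound the prior
   approximation error at O(B^{-1/2}).
3. **Restricted family for hidden layers.** Hidden-layer covariance factors
   stay at their small initial value (sd 0.01) unless
   `train_inner_covariance=True`; optimisation is then over a sub-family of
   variational distributions and the objective remains a valid ELBO. Without
   this, the KL pulls hidden q(V) toward the prior faster than the noisy
   likelihood gradient can push back, hidden activations noise up, and the
   whole fit collapses to the mean.
4. **Learning-rate split.** Kernel hyperparameters, sensitivities, inducing
   inputs and the noise variance train at 0.05× the variational learning
   rate. With equal rates the lengthscale occasionally took a destabilising
   step from which the bound did not recover.

## Initialisation

* Positivity (γ, ℓ, σ², σ_y²) via softplus; γ init 1.0 (weight-space) or
  10.0 (inducing-point), ℓ init 0.1, σ_y² init 0.1. Inputs are min-max
  scaled to [0, 1] and targets standardised per output on the training
  split, so ℓ = 0.1 means "a tenth of the observed input range" — a neutral
  default for series with a handful of oscillations.
* Sensitivities are rescaled once at construction so each layer's prior
  output has unit standard deviation (the filter attenuates by ≈ 1/γ, which
  would otherwise leave deep compositions with vanishing signal).
* `DLFMVIP.initialize_from_data` (called automatically by `fit`) propagates
  the training inputs through the layers, places each layer's inducing grid
  evenly over the empirical range of its incoming activations — extended
  below by 6/γ so the convolution tail is covered by inducing points (the
  unconstrained prior mass in an uncovered tail otherwise inflates the
  likelihood noise near the lower edge) — and re-seats hidden-layer means
  on an identity-like map (μ = z at the inducing inputs) so depth preserves
  input structure at initialisation.
* Inducing inputs are not trained by default (`trainable_z=False`): under
  Adam they drift and collide, degrading the conditioning of K. The flag
  remains available.
* Solves against K use no jitter when K's smallest eigenvalue is comfortably
  positive — this is what makes the Matheron update interpolate the sampled
  inducing outputs to ~1e−9 — and escalate through 1e−6 … 1e−2 otherwise.

## Optimiser

AdamW (decoupled weight decay, default 0; lr 0.01, betas 0.9/0.999)
implemented over the package's own reverse-mode autodiff engine
(`deeplfm._ad`): a numpy `Tensor` graph with broadcasting-aware
vector-Jacobian products, PSD inverse/log-determinant primitives whose
backward passes reuse the forward Cholesky, and a dedicated primitive for
the erfcx convolution whose four partial derivatives close over the output
itself. Every VJP is checked against central finite differences in the test
suite. All randomness flows through explicitly seeded generators; fits are
bit-reproducible.

## Synthetic data

`simulate_toy` chains two first-order filters driven by
u(t) = cos(0.5t) + 6 sin(3t): f1 = G1∗u on [0, t], f2 = G2∗u on [0, f1(t)],
y2 = f2 + ε. For sinusoidal forces both stages use the exact elementary
antiderivatives (validated against quadrature to 1e−8); arbitrary callables
fall back to quadrature. Defaults — γ1 = γ2 = 1, t ∈ [0, 15] at 500 points,
noise sd 5% of the clean signal's sd — are this package's reconstruction of
the source experiment's unpublished settings, chosen to reproduce the
pulse-train morphology. Note the composition roughly doubles the effective
oscillation rate of y2 relative to u.

`simulate_charis_like` draws one prior sample from a two-layer
inducing-point DLFM whose outputs share a latent force, yielding correlated
nonstationary pulse-like channels on a regular grid (ECG/ABP/ICP-like in
sampling structure and shared drive, *not* in physiological waveform shape).
Because the generator is the model family's own prior, parameter-recovery
tests have exact ground truth; passing them says nothing about model
misspecification on real physiological data.

Split protocols: `imputation` removes non-overlapping contiguous blocks per
output; `extrapolation` holds out everything beyond a boundary index. The
reference toy protocols in `deeplfm.experiments` use 4 blocks of 8 points
(each ≈ 0.24 time units, below the signal's correlation length — a
single-output series carries no cross-channel information to bridge longer
gaps) and an extrapolation boundary of 475/500 (short-range, proportional
to the 975/1000 protocol used on the physiological benchmark). At desk
scale the standard problem sizes are N_RF = 100 or M = 48 / B = 128, two
layers, one latent force per layer, 5000 AdamW iterations.

## Degenerate inputs and numerical edges

* Response features at t = 0 are exactly zero; layer outputs at zero input
  equal the bias c exactly.
* Non-finite features (extreme γ·input products at hidden layers) raise
  with the offending layer index rather than propagating NaNs.
* NMSE refuses zero-variance test targets; moment-matched MNLL refuses a
  degenerate total variance; the mixture-of-Gaussians MNLL variant is
  available behind a flag.
* Checkpoints (`.npz` + JSON metadata) round-trip bit-exactly, including
  the fixed VAR-FIXED draws and the pinned basis angles.

## Known limitations

* Single-threaded determinism only; BLAS threading can perturb floating-
  point reduction order.
* The inducing-point family underperforms the weight-space family on
  extrapolation (consistent with the local nature of inducing-point
  approximations); neither family extrapolates reliably beyond a fraction
  of the signal's quasi-period.
* Hidden-layer posterior covariances are frozen by default (see above); on
  problems where hidden-layer uncertainty matters, enable
  `train_inner_covariance` and budget considerably more iterations.
* Second-order ODE kernels, periodic latent processes, non-Gaussian
  likelihoods and variational treatment of kernel hyperparameters are out
  of scope.
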