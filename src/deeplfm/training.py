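"""Shared optimisation loop, task metrics and predictive summaries.

Both model families expose an ``elbo`` estimator and a ``predict`` sampler;
:func:`fit` maximises the bound with AdamW over minibatches, and the
metrics below follow the conventions used throughout the multi-output GP
literature:

* NMSE — mean squared error divided by the variance of the *test* targets,
  so the trivial test-mean predictor scores 1;
* MNLL — negative log density of each test target under the moment-matched
  Gaussian (sample mean, sample variance + σ²_y), averaged over points;
* RMSE — root mean squared error over all points and outputs.

Targets are standardised per output on the training split and inputs
min-max scaled to [0, 1] before fitting; metrics are always reported on
the original scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .optim import AdamW

__all__ = [
    "PredictiveSummary",
    "FitReport",
    "Preprocessor",
    "fit",
    "nmse",
    "mnll",
    "rmse",
    "save_checkpoint",
    "load_checkpoint",
]


# ------------------------------------------------------------------ metrics
def nmse(y_true, y_pred_mean, axis=0):
    """Normalised MSE per output; the test-set mean predictor scores 1."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred_mean = np.asarray(y_pred_mean, dtype=float)
    if y_true.shape[axis] < 2:
        raise ValueError("NMSE needs at least 2 test points")
    var = y_true.var(axis=axis)
    if np.any(var == 0):
        raise ValueError("zero-variance test targets")
    return ((y_true - y_pred_mean) ** 2).mean(axis=axis) / var


def rmse(y_true, y_pred_mean):
    y_true = np.asarray(y_true, dtype=float)
    y_pred_mean = np.asarray(y_pred_mean, dtype=float)
    return float(np.sqrt(((y_true - y_pred_mean) ** 2).mean()))


def mnll(y_true, samples, noise_variance, axis_points=0, mixture=False):
    """Mean negative log-likelihood per output.

    ``samples`` has shape (S, N, ...); by default each point's predictive
    distribution is the moment-matched Gaussian N(sample mean,
    sample variance + σ²_y).  ``mixture=True`` instead scores the equally
    weighted Gaussian mixture over samples.
    """
    y_true = np.asarray(y_true, dtype=float)
    samples = np.asarray(samples, dtype=float)
    if samples.shape[0] < 2 and not mixture:
        raise ValueError("moment-matched MNLL needs at least 2 samples")
    mean = samples.mean(axis=0)
    if mixture:
        var = np.full_like(mean, float(noise_variance))
        comp = (
            -0.5 * np.log(2.0 * np.pi * var)
            - (y_true[None] - samples) ** 2 / (2.0 * var)
        )
        lse = np.logaddexp.reduce(comp, axis=0) - np.log(samples.shape[0])
        return (-lse).mean(axis=axis_points)
    var = samples.var(axis=0) + float(noise_variance)
    if np.any(var <= 0):
        raise ValueError("degenerate predictive variance")
    nll = 0.5 * np.log(2.0 * np.pi * var) + (y_true - mean) ** 2 / (2.0 * var)
    return nll.mean(axis=axis_points)


@dataclass
class PredictiveSummary:
    """Per-point sample set reduced to mean and ±2σ bands."""

    samples: np.ndarray  # (S, N, D)
    noise_variance: float

    @property
    def mean(self):
        return self.samples.mean(axis=0)

    @property
    def std(self):
        return self.samples.std(axis=0)

    @property
    def lower(self):
        return self.mean - 2.0 * self.std

    @property
    def upper(self):
        return self.mean + 2.0 * self.std

    def nmse(self, y_true, mask=None):
        return _masked_metric(nmse, y_true, self.mean, mask)

    def mnll(self, y_true, mask=None):
        y_true = np.asarray(y_true, dtype=float)
        if mask is None:
            return mnll(y_true, self.samples, self.noise_variance)
        out = []
        for d in range(y_true.shape[1]):
            sel = mask[:, d]
            out.append(
                float(mnll(y_true[sel, d], self.samples[:, sel, d], self.noise_variance))
            )
        return np.array(out)


def _masked_metric(metric, y_true, y_pred, mask):
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if mask is None:
        return metric(y_true, y_pred)
    out = []
    for d in range(y_true.shape[1]):
        sel = mask[:, d]
        out.append(float(metric(y_true[sel, d], y_pred[sel, d])))
    return np.array(out)


# -------------------------------------------------------------- preprocessing
@dataclass
class Preprocessor:
    """Per-output target standardisation + [0, 1] min-max input scaling.

    Fitted on the training split only; the inverse transform is exact and
    the fitted constants are recorded in checkpoints.
    """

    x_min: np.ndarray = None
    x_range: np.ndarray = None
    y_mean: np.ndarray = None
    y_std: np.ndarray = None

    def fit(self, x, y, mask=None):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        self.x_min = x.min(axis=0)
        rng = x.max(axis=0) - self.x_min
        rng[rng == 0] = 1.0
        self.x_range = rng
        if mask is None:
            mask = np.ones_like(y, dtype=bool)
        means, stds = [], []
        for d in range(y.shape[1]):
            vals = y[mask[:, d], d]
            means.append(vals.mean())
            sd = vals.std()
            stds.append(sd if sd > 0 else 1.0)
        self.y_mean = np.array(means)
        self.y_std = np.array(stds)
        return self

    def transform_x(self, x):
        return (np.asarray(x, dtype=float) - self.x_min) / self.x_range

    def transform_y(self, y):
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_std

    def inverse_y(self, y):
        return np.asarray(y, dtype=float) * self.y_std + self.y_mean

    def inverse_noise_variance(self, noise_variance):
        return float(noise_variance) * self.y_std**2

    def state(self):
        return {
            "pre.x_min": self.x_min,
            "pre.x_range": self.x_range,
            "pre.y_mean": self.y_mean,
            "pre.y_std": self.y_std,
        }

    def load(self, arrays):
        self.x_min = arrays["pre.x_min"].copy()
        self.x_range = arrays["pre.x_range"].copy()
        self.y_mean = arrays["pre.y_mean"].copy()
        self.y_std = arrays["pre.y_std"].copy()
        return self


# ------------------------------------------------------------------ fitting
@dataclass
class FitReport:
    elbo_trace: np.ndarray
    n_iterations: int
    seed: int
    final_noise_variance: float
    config: dict = field(default_factory=dict)


def fit(model, x, y, mask=None, n_iterations=5000, learning_rate=0.01,
        hyper_lr_scale=0.05, lr_schedule="cosine", weight_decay=0.0,
        batch_size=None, n_mc=1, seed=0, local_reparam=True,
        callback=None) -> FitReport:
    """Maximise the model family's ELBO by AdamW; deterministic given seeds.

    Variational parameters train at ``learning_rate``; kernel
    hyperparameters, sensitivities, inducing inputs and the noise variance
    train at ``learning_rate * hyper_lr_scale`` (fast steps on the stiff
    hyperparameters destabilise the bound).  ``lr_schedule`` is "cosine"
    (annealed to zero over the run — damps the late-training drift of the
    stochastic bound) or "constant".  ``mask`` marks observed entries of y
    (True = observed).  A non-finite bound aborts with the offending
    iteration.  ``callback(i, elbo)`` runs every iteration.
    """
    if lr_schedule not in ("cosine", "constant"):
        raise ValueError(f"unknown lr schedule {lr_schedule!r}")
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n_total = x.shape[0]
    if hasattr(model, "initialize_from_data") and not model._initialized:
        model.initialize_from_data(x)
    groups = model.parameter_groups()
    opt = AdamW(
        [
            {"params": groups["variational"], "lr": learning_rate},
            {"params": groups["hyper"], "lr": learning_rate * hyper_lr_scale},
        ],
        lr=learning_rate,
        weight_decay=weight_decay,
    )
    base_lrs = list(opt._lrs)
    rng = np.random.default_rng(seed)
    trace = np.empty(n_iterations)
    for i in range(n_iterations):
        if lr_schedule == "cosine" and n_iterations > 1:
            factor = 0.5 * (1.0 + np.cos(np.pi * i / (n_iterations - 1)))
            opt._lrs = [lr * factor for lr in base_lrs]
        if batch_size is None or batch_size >= n_total:
            xb, yb, mb = x, y, mask
        else:
            idx = rng.choice(n_total, size=batch_size, replace=False)
            xb, yb = x[idx], y[idx]
            mb = None if mask is None else mask[idx]
        if model.family == "rff":
            bound = model.elbo(xb, yb, n_total=n_total, mask=mb, n_mc=n_mc,
                               rng=rng, local_reparam=local_reparam)
        else:
            bound = model.elbo(xb, yb, n_total=n_total, mask=mb, n_samples=n_mc,
                               rng=rng)
        val = bound.item()
        if not np.isfinite(val):
            raise FloatingPointError(f"ELBO diverged (non-finite) at iteration {i}")
        trace[i] = val
        opt.zero_grad()
        (-1.0 * bound).backward()
        opt.step()
        if callback is not None:
            callback(i, val)
    return FitReport(
        elbo_trace=trace,
        n_iterations=n_iterations,
        seed=seed,
        final_noise_variance=float(model.noise_variance.data),
        config=dict(
            learning_rate=learning_rate, weight_decay=weight_decay,
            batch_size=batch_size, n_mc=n_mc, local_reparam=local_reparam,
        ),
    )


# -------------------------------------------------------------- checkpoints
def save_checkpoint(path, model, preprocessor=None):
    """Versioned parameter archive; save → load → predict is bit-exact."""
    meta, arrays = model.state_dict()
    if preprocessor is not None:
        arrays.update(preprocessor.state())
        meta["has_preprocessor"] = True
    arrays = {k: np.asarray(v) for k, v in arrays.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path):
    """Rebuild the model (and preprocessor, if stored) from an archive."""
    from .rff import DLFMRFF
    from .vip import DLFMVIP

    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    meta = json.loads(bytes(arrays.pop("__meta__")).decode())
    if meta["family"] == "rff":
        model = DLFMRFF(
            meta["layer_dims"], n_forces=meta["n_forces"], n_rf=meta["n_rf"],
            feature_type=meta["feature_type"],
            per_output_final=meta["per_output_final"], seed=meta["seed"],
        )
    else:
        model = DLFMVIP(
            meta["layer_dims"], n_forces=meta["n_forces"],
            n_inducing=meta["n_inducing"], n_basis=meta["n_basis"],
            seed=meta["seed"],
        )
    model.load_state_dict(arrays)
    pre = None
    if meta.get("has_preprocessor"):
        pre = Preprocessor().load(arrays)
    return model, pre, meta
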