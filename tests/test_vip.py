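"""Inducing-point DLFM: convolution primitives, pathwise sampling, bound."""

import numpy as np
import pytest

from deeplfm._ad import astensor
from deeplfm.oracles import conv_cosine_quadrature, conv_eq_quadrature, lfm_kernel_oracle
from deeplfm.rff import softplus_inv
from deeplfm.vip import DLFMVIP, VIPLayer, conv_cosine, conv_eq_canonical


class TestConvCosine:
    def test_constant_input_integrates_filter_mass(self):
        assert conv_cosine(2.0, 0.0, 0.0, 5.0) == pytest.approx(0.5)

    def test_spot_value(self):
        assert conv_cosine(1.0, 1.0, 0.0, 0.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("gamma", [0.1, 1.0, 10.0])
    @pytest.mark.parametrize("theta", [0.3, 3.0])
    def test_matches_quadrature_on_grid(self, gamma, theta):
        for beta in (0.0, 1.2):
            for x in (-1.0, 0.0, 2.5):
                closed = conv_cosine(gamma, theta, beta, x)
                numeric = conv_cosine_quadrature(gamma, theta, beta, x)
                assert abs(closed - numeric) < 1e-7

    def test_rejects_nonpositive_decay(self):
        with pytest.raises(ValueError):
            conv_cosine(0.0, 1.0, 0.0, 1.0)


class TestConvEQCanonical:
    def test_vanishes_far_left(self):
        assert abs(conv_eq_canonical(1.0, 1.0, -20.0, 0.0)) < 1e-8

    @pytest.mark.parametrize("gamma", [0.1, 1.0, 50.0])
    @pytest.mark.parametrize("ell", [0.3, 1.0, 3.0])
    def test_matches_quadrature_on_grid(self, gamma, ell):
        for x in (-1.0, 0.0, 1.5):
            closed = conv_eq_canonical(gamma, ell, x, 0.2)
            numeric = conv_eq_quadrature(gamma, ell, x, 0.2)
            assert abs(closed - numeric) < 1e-7

    def test_near_delta_limit_recovers_scaled_kernel(self):
        """γ → ∞: the filter integrates to 1/γ, so the convolution at the
        kernel centre approaches k(0)/γ."""
        val = conv_eq_canonical(200.0, 1.0, 0.0, 0.0)
        assert val == pytest.approx(1.0 / 200.0, rel=0.01)

    def test_no_overflow_at_extreme_decay_lengthscale_products(self):
        out = conv_eq_canonical(1e3, 10.0, 5.0, 0.0)
        assert np.isfinite(out)


class TestPathwiseSampling:
    def make_layer(self, m=8, b=64, ell=0.8, seed=3):
        layer = VIPLayer(1, 1, n_inducing=m, n_basis=b,
                         rng=np.random.default_rng(seed), gamma_init=1.0,
                         ell_init=ell, z_low=0.0, z_high=5.0)
        return layer

    def test_matheron_interpolation_at_inducing_inputs(self):
        layer = self.make_layer()
        u, v = layer.pathwise_latent_sample(layer.z[0].data, n_samples=5,
                                            rng=np.random.default_rng(0))
        assert np.abs(u - v).max() < 1e-8

    def test_prior_mode_without_inducing_set(self):
        layer = VIPLayer(1, 1, n_inducing=0, n_basis=64,
                         rng=np.random.default_rng(0), ell_init=1.0,
                         resample="full")
        u, v = layer.pathwise_latent_sample(np.linspace(0, 3, 7), n_samples=4,
                                            rng=np.random.default_rng(1))
        assert v is None and u.shape == (4, 7)

    def test_prior_covariance_matches_eq_kernel(self):
        """Empirical covariance of pathwise prior samples at 5 points matches
        the EQ kernel within Monte-Carlo error at B = 1024."""
        layer = VIPLayer(1, 1, n_inducing=0, n_basis=1024,
                         rng=np.random.default_rng(0), ell_init=1.0,
                         resample="full")
        x = np.linspace(0.0, 3.0, 5)
        u, _ = layer.pathwise_latent_sample(x, n_samples=4000,
                                            rng=np.random.default_rng(2))
        emp = np.cov(u.T)
        kern = np.exp(-np.subtract.outer(x, x) ** 2 / 1.0**2)
        mc_se = 3.0 / np.sqrt(4000)
        assert np.abs(emp - kern).max() < 3 * mc_se + 0.05


class TestOutputSampling:
    def test_far_left_update_contribution_vanishes(self):
        """Far below all inducing structure the data-dependent update term
        carries no mass: shifting the inducing outputs by a huge constant
        leaves the output unchanged (only the stationary prior part remains)."""
        layer = VIPLayer(1, 1, n_inducing=6, n_basis=32,
                         rng=np.random.default_rng(1), gamma_init=1.0,
                         ell_init=1.0, z_low=0.0, z_high=4.0)
        x = astensor(np.full((2, 3, 1), -60.0))
        draws = layer._draw_basis(np.random.default_rng(0), 2)
        base = layer.output_sample(x, draws, 2).data
        layer.mu[0].data[:] = 1e4
        shifted = layer.output_sample(x, draws, 2).data
        np.testing.assert_allclose(base, shifted, atol=1e-6)

    def test_single_basis_term_reduces_to_conv_cosine(self):
        layer = VIPLayer(1, 1, n_inducing=0, n_basis=1,
                         rng=np.random.default_rng(2), gamma_init=1.5,
                         ell_init=1.0)
        layer.a.data[:] = 1.0
        draws = layer._draw_basis(np.random.default_rng(5), 1)
        theta = np.sqrt(2.0) / float(np.logaddexp(0, layer.ell_raw.data[0]))
        theta = theta * draws[0]["eps_theta"][0, 0, 0]
        beta = draws[0]["beta"][0, 0]
        w = draws[0]["w"][0, 0]
        x = np.array([[0.3], [1.1]])
        out = layer.output_sample(astensor(x[None]), draws, 1)
        expected = np.sqrt(2.0) * w * conv_cosine(1.5, theta, beta, x[:, 0])
        np.testing.assert_allclose(out.data[0, :, 0], expected, atol=1e-10)

    def test_delta_limit_output_tracks_latent(self):
        """As γ grows the filter approaches a delta (mass 1/γ): correlation
        between normalised output and latent samples rises, >0.99 at γ=200."""
        x = np.linspace(0.0, 4.0, 120)
        cors = []
        for gamma in (0.01, 1.0, 200.0):
            layer = VIPLayer(1, 1, n_inducing=0, n_basis=256,
                             rng=np.random.default_rng(4), gamma_init=gamma,
                             ell_init=1.0)
            draws = layer._draw_basis(np.random.default_rng(9), 1)
            out = layer.output_sample(astensor(x[None, :, None]), draws, 1).data[0, :, 0]
            state = layer._latent_state(0, draws, 1)
            u = layer.latent_eval(state, astensor(x[None, :, None]), 1).data[0]
            cors.append(np.corrcoef(out, u)[0, 1])
        assert cors[0] < cors[1] < cors[2]
        assert cors[2] > 0.99

    def test_layer_compose_shapes_and_single_layer_equivalence(self):
        model = DLFMVIP([1, 2, 1], n_inducing=6, n_basis=32, seed=0)
        x = np.linspace(0, 1, 9)
        final, per_layer = model.sample_layers(x, n_samples=3, seed=1)
        assert per_layer[0].shape == (3, 9, 2)
        assert per_layer[1].shape == (3, 9, 1)
        np.testing.assert_array_equal(final, per_layer[-1])
        one = DLFMVIP([1, 1], n_inducing=6, n_basis=32, seed=0)
        f, layers = one.sample_layers(x, n_samples=2, seed=1)
        assert len(layers) == 1
        np.testing.assert_array_equal(f, layers[0])


class TestMoments:
    def test_analytic_moments_match_empirical(self):
        layer = VIPLayer(1, 1, n_inducing=8, n_basis=48,
                         rng=np.random.default_rng(3), gamma_init=3.0,
                         ell_init=0.5, z_low=0.0, z_high=1.0)
        rng = np.random.default_rng(5)
        layer.mu[0].data = rng.standard_normal(8)
        layer.l_factor[0].data = 0.3 * np.tril(rng.standard_normal((8, 8)))
        x = np.linspace(0, 1, 7)[:, None]
        xt = astensor(np.broadcast_to(x[None], (1,) + x.shape).copy())
        m, v = layer.output_moments(xt, np.random.default_rng(0), 1)
        S = 20000
        xs = astensor(np.broadcast_to(x[None], (S,) + x.shape).copy())
        out = layer.forward(xs, np.random.default_rng(1), S).data
        np.testing.assert_allclose(m.data[0, :, 0], out.mean(0)[:, 0], rtol=0.02,
                                   atol=0.05)
        np.testing.assert_allclose(v.data[0, :, 0], out.var(0)[:, 0], rtol=0.1,
                                   atol=0.02)


class TestVIPELBO:
    def test_kl_zero_when_posterior_equals_prior(self):
        layer = VIPLayer(1, 1, n_inducing=5, n_basis=16,
                         rng=np.random.default_rng(0), ell_init=1.0,
                         z_low=0.0, z_high=4.0)
        from scipy.linalg import cholesky
        layer.mu[0].data[:] = 0.0
        layer.l_factor[0].data = cholesky(layer.prior_covariance(0), lower=True)
        assert abs(layer.kl().item()) < 1e-8

    def test_kl_positive_otherwise(self):
        layer = VIPLayer(1, 1, n_inducing=5, n_basis=16,
                         rng=np.random.default_rng(0), ell_init=1.0,
                         z_low=0.0, z_high=4.0)
        layer.mu[0].data[:] = 1.0
        assert layer.kl().item() > 0.0

    def test_perfect_single_datum_likelihood(self):
        """Deterministic model (Σ→0, basis collapsed) predicting the datum
        exactly: the bound's likelihood term is −½ln(2πσ²)."""
        model = DLFMVIP([1, 1], n_inducing=4, n_basis=8, seed=0)
        layer = model.layers[0]
        for q in range(layer.n_forces):
            layer.mu[q].data[:] = 0.0
            layer.l_factor[q].data[:] = 0.0
        layer.a.data[:] = 0.0  # output exactly zero, no variance
        kl = model.kl().item()
        sigma2 = float(model.noise_variance.data)
        got = model.elbo(np.array([[0.5]]), np.array([[0.0]]),
                         rng=np.random.default_rng(0), n_samples=1).item()
        assert got + kl == pytest.approx(-0.5 * np.log(2 * np.pi * sigma2), abs=1e-9)

    def test_sample_count_does_not_bias_the_bound(self):
        model = DLFMVIP([1, 1], n_inducing=6, n_basis=32, seed=0)
        x = np.linspace(0, 1, 12)[:, None]
        y = np.sin(5 * x)
        small, large = [], []
        for s in range(60):
            small.append(model.elbo(x, y, rng=np.random.default_rng(s),
                                    n_samples=1).item())
            large.append(model.elbo(x, y, rng=np.random.default_rng(1000 + s),
                                    n_samples=8).item())
        se = np.sqrt(np.var(small) / 60 + np.var(large) / 60)
        assert abs(np.mean(small) - np.mean(large)) < 4 * se + 1e-6

    def test_frozen_deterministic_layers_give_identical_samples(self):
        model = DLFMVIP([1, 1], n_inducing=4, n_basis=16, seed=0)
        layer = model.layers[0]
        for q in range(layer.n_forces):
            layer.l_factor[q].data[:] = 0.0
        layer.freeze_basis(seed=3)
        s = model.predict(np.linspace(0, 1, 5), n_samples=4, seed=0)
        assert np.allclose(s[0], s[1]) and np.allclose(s[1], s[3])
        layer.thaw_basis()
        s2 = model.predict(np.linspace(0, 1, 5), n_samples=4, seed=0)
        assert not np.allclose(s2[0], s2[1])


class TestPriorMomentsOfOutput:
    def test_one_layer_prior_output_covariance_matches_adapted_oracle(self):
        """M = 0 output samples have mean ≈ 0 and covariance matching the
        LFM double-integral oracle with lower limit −∞ (truncated)."""
        layer = VIPLayer(1, 1, n_inducing=0, n_basis=512,
                         rng=np.random.default_rng(0), gamma_init=1.0,
                         ell_init=1.0, resample="full")
        layer.a.data[:] = 1.0
        x = np.array([1.0, 2.0])
        S = 4000
        xt = astensor(np.broadcast_to(x[None, :, None], (S, 2, 1)).copy())
        out = layer.forward(xt, np.random.default_rng(3), S).data[:, :, 0]
        target = lfm_kernel_oracle(x[0], x[1], 1.0, 1.0, lower=-30.0)
        var0 = lfm_kernel_oracle(x[0], x[0], 1.0, 1.0, lower=-30.0)
        assert abs(out.mean()) < 4 * np.sqrt(var0 / S) + 0.05
        emp = np.cov(out[:, 0], out[:, 1])[0, 1]
        assert abs(emp - target) < 0.1 * var0

    def test_origin_samples_are_unconstrained(self):
        """Lower limit −∞: samples at x = 0 have sd bounded away from zero
        (no initial-condition collapse, unlike the weight-space family)."""
        layer = VIPLayer(1, 1, n_inducing=0, n_basis=256,
                         rng=np.random.default_rng(1), gamma_init=1.0,
                         ell_init=1.0, resample="full")
        layer.a.data[:] = 1.0
        S = 500
        xt = astensor(np.zeros((S, 1, 1)))
        out = layer.forward(xt, np.random.default_rng(2), S).data
        assert out.std() > 0.1
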