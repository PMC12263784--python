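"""Weight-space DLFM: layers, variational machinery, bound and predictions."""

import numpy as np
import pytest

from deeplfm._ad import astensor
from deeplfm.kernels import LatentForceKernel, eq_rff, lfm_kernel_rfrf_estimate
from deeplfm.oracles import lfm_kernel_oracle
from deeplfm.rff import DLFMRFF, RFFLayer, kl_gaussian, softplus_inv


def make_layer(**kw):
    defaults = dict(in_dim=1, out_dim=2, n_forces=1, n_rf=16,
                    rng=np.random.default_rng(0))
    defaults.update(kw)
    return RFFLayer(**defaults)


class TestLayerForward:
    def test_zero_input_returns_bias(self):
        layer = make_layer()
        for b in layer.blocks:
            b.c.data = np.array([1.5, -0.5])
        out = layer.forward(astensor(np.zeros((4, 1))), np.random.default_rng(0))
        np.testing.assert_allclose(out.data, np.tile([1.5, -0.5], (4, 1)), atol=1e-12)

    def test_zero_weights_and_bias_give_zero(self):
        layer = make_layer()
        for b in layer.blocks:
            b.m_w.data[:] = 0.0
            b.s_w_raw.data[:] = softplus_inv(1e-14)
        out = layer.forward(astensor(np.ones((3, 1))), np.random.default_rng(0))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_single_feature_block_matches_hand_computation(self):
        """One force, one feature: the layer output is the realified response
        feature times the weight, reproducible by direct arithmetic."""
        layer = make_layer(out_dim=1, n_rf=1)
        b = layer.blocks[0]
        b.s_w_raw.data[:] = softplus_inv(1e-14)
        b.m_w.data = np.array([[2.0], [3.0]])
        t = 0.7
        gamma = float(np.logaddexp(0, b.gamma_raw.data[0]))
        omega = float(b.m_omega.data[0, 0, 0]
                      + np.logaddexp(0, b.s_omega_raw.data[0, 0, 0]) * b.epsilon[0, 0, 0])
        phi = (np.exp(1j * omega * t) - np.exp(-gamma * t)) / (gamma + 1j * omega)
        expected = (phi.real * 2.0 + phi.imag * 3.0) * np.sqrt(
            float(b.sens.data[0]) ** 2 / 1
        )
        out = layer.forward(astensor(np.array([[t]])), np.random.default_rng(0))
        assert np.isclose(out.data[0, 0], expected, atol=1e-10)

    def test_nonfinite_features_report_layer_index(self):
        layer = make_layer(index=3)
        with pytest.raises(FloatingPointError, match="layer 3"):
            layer.forward(astensor(np.array([[-1e6]])), np.random.default_rng(0))


class TestPerOutputFinalLayer:
    def test_tied_blocks_match_shared_layer(self):
        rng_a = np.random.default_rng(42)
        shared = RFFLayer(1, 2, n_rf=8, rng=rng_a, per_output=False)
        per = RFFLayer(1, 2, n_rf=8, rng=np.random.default_rng(7), per_output=True)
        # tie: copy the shared block's parameters into both per-output blocks
        src = shared.blocks[0]
        for d, blk in enumerate(per.blocks):
            blk.epsilon = src.epsilon
            blk.gamma_raw.data = src.gamma_raw.data.copy()
            blk.ell_raw.data = src.ell_raw.data.copy()
            blk.sens.data = src.sens.data.copy()
            blk.m_omega.data = src.m_omega.data.copy()
            blk.s_omega_raw.data = src.s_omega_raw.data.copy()
            blk.m_w.data = src.m_w.data[:, d : d + 1].copy()
            blk.s_w_raw.data[:] = softplus_inv(1e-14)
            blk.c.data = src.c.data[d : d + 1].copy()
        src.s_w_raw.data[:] = softplus_inv(1e-14)
        x = astensor(np.linspace(0, 1, 5)[:, None])
        a = shared.forward(x, np.random.default_rng(0))
        b = per.forward(x, np.random.default_rng(0))
        np.testing.assert_allclose(a.data, b.data, atol=1e-9)

    def test_output_columns_depend_only_on_own_block(self):
        layer = RFFLayer(1, 2, n_rf=8, rng=np.random.default_rng(1), per_output=True)
        layer.blocks[0].m_w.data[:] = 0.0
        layer.blocks[0].s_w_raw.data[:] = softplus_inv(1e-14)
        layer.blocks[1].s_w_raw.data[:] = softplus_inv(1e-14)
        out = layer.forward(astensor(np.ones((3, 1))), np.random.default_rng(0))
        assert np.allclose(out.data[:, 0], layer.blocks[0].c.data[0], atol=1e-10)
        assert not np.allclose(out.data[:, 1], layer.blocks[1].c.data[0])


class TestKLGaussian:
    def test_identity_is_zero(self):
        assert kl_gaussian(1.3, 0.7, 1.3, 0.7).item() == pytest.approx(0.0)

    def test_closed_form_values(self):
        assert kl_gaussian(1.0, 1.0, 0.0, 1.0).item() == pytest.approx(0.5)
        assert kl_gaussian(0.0, 4.0, 0.0, 1.0).item() == pytest.approx(
            0.5 * (4 - 1 - np.log(4))
        )

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m1, m2 = rng.standard_normal(2)
            v1, v2 = rng.uniform(0.1, 5, 2)
            assert kl_gaussian(m1, v1, m2, v2).item() >= 0.0


class TestVariationalSampling:
    def test_degenerate_variances_return_means(self):
        model = DLFMRFF([1, 1], n_rf=8, seed=0)
        for layer in model.layers:
            for b in layer.blocks:
                b.s_w_raw.data[:] = softplus_inv(1e-14)
        x = np.linspace(0, 1, 6)[:, None]
        a = model.predict(x, n_samples=3, seed=0)
        assert np.allclose(a[0], a[1], atol=1e-10) and np.allclose(a[1], a[2], atol=1e-10)

    def test_test_time_determinism_without_reparam(self):
        model = DLFMRFF([1, 2, 1], n_rf=8, seed=0)
        x = np.linspace(0, 1, 6)[:, None]
        a = model.predict(x, n_samples=4, reparam=False, seed=0)
        b = model.predict(x, n_samples=4, reparam=False, seed=0)
        np.testing.assert_array_equal(a, b)

    def test_local_reparam_matches_direct_sampling_moments(self):
        """Pre-activation mean/variance under the local reparameterization
        agree with direct weight sampling over many draws."""
        layer = make_layer(out_dim=1, n_rf=8)
        x = astensor(np.array([[0.4]]))
        direct, local = [], []
        rng = np.random.default_rng(0)
        for _ in range(4000):
            direct.append(layer.forward(x, rng, local_reparam=False).data[0, 0])
            local.append(layer.forward(x, rng, local_reparam=True).data[0, 0])
        assert np.isclose(np.mean(direct), np.mean(local), atol=0.01)
        assert np.isclose(np.std(direct), np.std(local), rtol=0.1)

    def test_reparam_at_test_time_increases_sample_variance(self):
        model = DLFMRFF([1, 1, 1], n_rf=16, seed=0)
        x = np.linspace(0, 1, 20)[:, None]
        off = model.predict(x, n_samples=30, reparam=False, seed=1)
        on = model.predict(x, n_samples=30, reparam=True, seed=1)
        assert on.std(axis=0).mean() > off.std(axis=0).mean()


class TestELBO:
    def test_full_batch_scaling_is_identity(self):
        model = DLFMRFF([1, 1], n_rf=8, seed=0)
        x = np.linspace(0, 1, 10)[:, None]
        y = np.sin(x)
        a = model.elbo(x, y, n_total=10, rng=np.random.default_rng(0),
                       local_reparam=False)
        b = model.elbo(x, y, rng=np.random.default_rng(0), local_reparam=False)
        assert a.item() == pytest.approx(b.item())

    def test_perfect_single_datum_likelihood(self):
        """With q = p (zero KL by construction) and exact prediction, the
        bound reduces to the Gaussian log-normaliser −½ln(2πσ²)."""
        model = DLFMRFF([1, 1], n_rf=4, seed=0)
        for layer in model.layers:
            for b in layer.blocks:
                b.m_w.data[:] = 0.0
                b.s_w_raw.data[:] = softplus_inv(1.0)   # q(W) = N(0,1) = prior
                b.m_omega.data[:] = 0.0
                prior_sd = np.sqrt(2.0) / float(np.logaddexp(0, b.ell_raw.data[0]))
                b.s_omega_raw.data[:] = softplus_inv(prior_sd)
                b.c.data[:] = 0.7                        # prediction = bias
        sigma2 = float(model.noise_variance.data)
        got = model.elbo(np.array([[0.0]]), np.array([[0.7]]),
                         rng=np.random.default_rng(0), local_reparam=False)
        assert got.item() == pytest.approx(-0.5 * np.log(2 * np.pi * sigma2), abs=1e-8)

    def test_minibatch_estimator_is_unbiased(self):
        model = DLFMRFF([1, 1], n_rf=8, seed=0)
        rng0 = np.random.default_rng(0)
        x = rng0.uniform(0, 1, (24, 1))
        y = np.sin(3 * x)
        full = model.elbo(x, y, rng=np.random.default_rng(1), local_reparam=False,
                          n_mc=1).item()
        ests = []
        for s in range(300):
            rng = np.random.default_rng(100 + s)
            idx = rng.choice(24, size=6, replace=False)
            ests.append(
                model.elbo(x[idx], y[idx], n_total=24, rng=rng,
                           local_reparam=False).item()
            )
        se = np.std(ests) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - full) < 4 * se + 1e-6

    def test_empty_minibatch_and_bad_mc_rejected(self):
        model = DLFMRFF([1, 1], n_rf=4, seed=0)
        with pytest.raises(ValueError):
            model.elbo(np.zeros((0, 1)), np.zeros((0, 1)))
        with pytest.raises(ValueError):
            model.elbo(np.zeros((2, 1)), np.zeros((2, 1)), n_mc=0)


class TestShallowPriorCovariance:
    def test_one_layer_prior_matches_lfm_kernel_oracle(self):
        """MC covariance of a 1-layer weight-space prior at two points
        approaches the double-integral LFM covariance (shallow limit)."""
        rng = np.random.default_rng(0)
        kern = LatentForceKernel(lengthscales=[1.0])
        gamma, t1, t2 = 1.0, 1.2, 0.6
        target = lfm_kernel_oracle(t1, t2, gamma, 1.0)
        ests = [
            lfm_kernel_rfrf_estimate(t1, t2, gamma, kern, 200, rng)
            for _ in range(60)
        ]
        se = np.std(ests) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - target) < 4 * se + 0.02 * abs(target)

    def test_eq_feature_type_reproduces_dgp_rff_features(self):
        """With shared frequencies the 'eq' layer equals the plain cos/sin map."""
        layer = make_layer(out_dim=1, n_rf=8, feature_type="eq")
        b = layer.blocks[0]
        f = np.linspace(0, 1, 5)[:, None]
        omega = (b.m_omega.data + np.logaddexp(0, b.s_omega_raw.data) * b.epsilon)
        expected = eq_rff(f, omega.reshape(1, 8), float(np.logaddexp(0, b.sigma2_raw.data)))
        got = layer._features(astensor(f), b)
        np.testing.assert_allclose(got.data, expected, atol=1e-12)
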