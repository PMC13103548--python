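"""Half-split crossover sparse autoencoder."""
import numpy as np
import pytest

from mdefusion.hcsae import (HCSAE, HCSAEConfig, abstract_features,
                             decode_reconstruct, dropout_sparsify,
                             half_split_crossover, hcsae_forward,
                             tanh_activation, tree_fuse)
from mdefusion.nn.autograd import Tensor
from mdefusion.types import ConfigurationError, FeatureSet, ParameterError


class TestTanh:
    def test_zero_maps_to_zero(self):
        assert tanh_activation(np.array(0.0)) == 0.0

    def test_odd_symmetry(self, rng):
        x = rng.normal(size=20)
        assert np.allclose(tanh_activation(x), -tanh_activation(-x))

    def test_saturation(self):
        assert 1.0 - tanh_activation(np.array(20.0)) < 1e-8
        assert np.all(np.abs(tanh_activation(np.array([50.0, -50.0]))) <= 1.0)


class TestDropout:
    def test_q_zero_is_identity(self, rng):
        f = rng.normal(size=(10, 10))
        assert np.array_equal(dropout_sparsify(f, 0.0, training=True, seed=0), f)

    def test_inference_is_identity(self, rng):
        f = rng.normal(size=(10, 10))
        assert np.array_equal(dropout_sparsify(f, 0.5, training=False, seed=0), f)

    def test_expectation_preserved(self):
        """E[mask/(1-q) * f] = f: empirical mean over 10^4 draws within 2%."""
        f = np.full(10_000, 3.0)
        out = dropout_sparsify(f, 0.3, training=True, seed=42)
        assert abs(out.mean() - 3.0) / 3.0 < 0.02

    def test_zeroed_fraction_binomial(self):
        f = np.ones(10_000)
        out = dropout_sparsify(f, 0.5, training=True, seed=7)
        assert abs((out == 0).mean() - 0.5) < 0.02

    @pytest.mark.parametrize("q", [0.1, 0.3, 0.5])
    def test_variance_matches_bernoulli(self, q):
        """Var[f_d] = q/(1-q) * f^2 for the inverted-dropout mask."""
        f = 2.0
        out = dropout_sparsify(np.full(200_000, f), q, training=True, seed=3)
        expect = q / (1 - q) * f ** 2
        assert out.var() == pytest.approx(expect, rel=0.05)

    def test_q_one_rejected(self):
        with pytest.raises(ParameterError):
            dropout_sparsify(np.ones(3), 1.0)


class TestCrossover:
    def test_self_crossover_identity(self, rng):
        A = rng.normal(size=(4, 6))
        P, Q = half_split_crossover(A, A.copy())
        assert np.array_equal(P, A) and np.array_equal(Q, A)

    def test_multiset_conservation(self, rng):
        A, B = rng.normal(size=(2, 8, 5))
        P, Q = half_split_crossover(A, B)
        assert np.array_equal(np.sort(np.concatenate([P, Q]).ravel()),
                              np.sort(np.concatenate([A, B]).ravel()))

    def test_channel_bookkeeping(self):
        A = np.stack([np.full(3, v) for v in [1, 2, 3, 4]])
        B = np.stack([np.full(3, v) for v in [5, 6, 7, 8]])
        P, Q = half_split_crossover(A, B)
        assert [p[0] for p in P] == [1, 2, 7, 8]
        assert [q[0] for q in Q] == [5, 6, 3, 4]

    def test_odd_channels_rejected(self, rng):
        A = rng.normal(size=(3, 4))
        with pytest.raises(ConfigurationError):
            half_split_crossover(A, A)

    def test_tensor_path_matches_numpy(self, rng):
        A, B = rng.normal(size=(2, 6, 4)).astype(np.float32)
        Pn, Qn = half_split_crossover(A, B)
        Pt, Qt = half_split_crossover(Tensor(A), Tensor(B))
        assert np.allclose(Pt.data, Pn) and np.allclose(Qt.data, Qn)


@pytest.fixture
def tiny_net():
    cfg = HCSAEConfig(abstract_channels=4, n_1x3_layers=1, dropout_q=0.0,
                      latent_channels=6, seed=1)
    return HCSAE(5, 3, cfg)


class TestAbstract:
    def test_channel_and_time_contract(self, tiny_net, rng):
        A, B = abstract_features(rng.normal(size=(5, 12)),
                                 rng.normal(size=(3, 12)), tiny_net)
        assert A.shape == (4, 12) and B.shape == (4, 12)

    def test_fixed_weight_oracle(self, rng):
        """With 1x1 weights = identity rows and zero 1x3 kernels, the stream
        reduces to tanh(tanh(selected channels))."""
        cfg = HCSAEConfig(abstract_channels=2, n_1x3_layers=1, dropout_q=0.0,
                          latent_channels=2, seed=0)
        net = HCSAE(2, 2, cfg)
        net.in1.w.data[:] = np.eye(2, dtype=np.float32)[:, :, None]
        net.in1.b.data[:] = 0
        net.deep1[0].w.data[:] = 0
        net.deep1[0].w.data[0, 0, 1] = 1.0   # center tap identity
        net.deep1[0].w.data[1, 1, 1] = 1.0
        net.deep1[0].b.data[:] = 0
        x = rng.normal(size=(2, 6))
        A, _ = abstract_features(x, np.zeros((2, 6)), net)
        assert np.allclose(A, np.tanh(np.tanh(x)), atol=1e-6)


class TestTreeFuse:
    def test_latent_channel_contract(self, tiny_net, rng):
        P = rng.normal(size=(4, 10))
        z = tree_fuse(P, P, tiny_net)
        assert z.shape == (6, 10)
        assert np.all(np.abs(z) < 1.0)     # tanh output range

    def test_zero_inputs_zero_latent(self, tiny_net):
        z = tree_fuse(np.zeros((4, 5)), np.zeros((4, 5)), tiny_net)
        assert np.allclose(z, 0.0)         # zero biases at init, tanh(0)=0

    def test_hand_computed_forward(self):
        """2-channel inputs of length 3 with fixed small weights, against a
        pencil-and-paper pass: z = tanh(W2 @ concat(tanh(Wp P), tanh(Wq Q)))."""
        cfg = HCSAEConfig(abstract_channels=2, n_1x3_layers=0, dropout_q=0.0,
                          latent_channels=1, seed=0)
        net = HCSAE(2, 2, cfg)
        net.fuse_p.w.data[:] = np.array([[0.5, 0.0], [0.0, 0.5]],
                                        dtype=np.float32)[:, :, None]
        net.fuse_q.w.data[:] = np.array([[0.0, 1.0], [1.0, 0.0]],
                                        dtype=np.float32)[:, :, None]
        net.fuse_top.w.data[:] = np.array([[0.25, -0.25, 0.5, -0.5]],
                                          dtype=np.float32)[:, :, None]
        for layer in (net.fuse_p, net.fuse_q, net.fuse_top):
            layer.b.data[:] = 0
        P = np.array([[1.0, -1.0, 0.5], [0.0, 2.0, -0.5]])
        Q = np.array([[0.2, 0.0, 1.0], [-0.2, 0.4, 0.0]])
        lp = np.tanh(0.5 * P)
        lq = np.tanh(np.array([Q[1], Q[0]]))
        expect = np.tanh(0.25 * lp[0] - 0.25 * lp[1] + 0.5 * lq[0] - 0.5 * lq[1])
        z = tree_fuse(P, Q, net)
        assert np.allclose(z[0], expect, atol=1e-6)


class TestDecode:
    def test_reconstruction_error_nonnegative(self, tiny_net, rng):
        z = rng.normal(size=(6, 10))
        ab = rng.normal(size=(8, 10))
        rec = decode_reconstruct(z, ab, tiny_net)
        assert rec.recon_error >= 0
        assert rec.output.shape == (8, 5)   # restored width, halved time

    def test_perfect_copy_toy_zero_error(self, tiny_net, rng):
        """If the (pooled) target equals the decoder output, error is zero."""
        z = rng.normal(size=(6, 10)).astype(np.float32)
        from mdefusion.nn.autograd import Tensor, conv1d, no_grad
        with no_grad():
            pre = conv1d(Tensor(z[None]), tiny_net.decode_conv.w,
                         tiny_net.decode_conv.b).tanh().data[0]
        # hand the decoder a target whose pooled form it reproduces exactly
        rec = decode_reconstruct(z, pre, tiny_net)
        assert rec.recon_error == pytest.approx(0.0, abs=1e-12)

    def test_mse_matches_oracle(self, tiny_net, rng):
        z = rng.normal(size=(6, 10))
        ab = rng.normal(size=(8, 10))
        rec = decode_reconstruct(z, ab, tiny_net)
        target = ab.reshape(8, 5, 2).max(axis=2)
        expect = ((rec.output - target) ** 2).mean()
        assert rec.recon_error == pytest.approx(expect, rel=1e-6)


class TestForward:
    def _fs(self, rng):
        return FeatureSet(F1=rng.normal(size=(5, 2, 12)),
                          F2=rng.normal(size=(3, 12)))

    def test_inference_deterministic(self, rng):
        cfg = HCSAEConfig(abstract_channels=4, n_1x3_layers=1, dropout_q=0.5,
                          latent_channels=6, seed=1)
        net = HCSAE(10, 3, cfg)
        fs = self._fs(rng)
        z1, _ = hcsae_forward(fs, net, training=False)
        z2, _ = hcsae_forward(fs, net, training=False)
        assert np.array_equal(z1, z2)

    def test_training_reproducible_under_seed(self, rng):
        cfg = HCSAEConfig(abstract_channels=4, n_1x3_layers=1, dropout_q=0.5,
                          latent_channels=6, seed=1)
        net = HCSAE(10, 3, cfg)
        fs = self._fs(rng)
        z1, _ = hcsae_forward(fs, net, training=True, seed=11)
        z2, _ = hcsae_forward(fs, net, training=True, seed=11)
        assert np.array_equal(z1, z2)

    def test_shape_contract(self, rng):
        cfg = HCSAEConfig(abstract_channels=4, n_1x3_layers=1, dropout_q=0.0,
                          latent_channels=6, seed=1)
        net = HCSAE(10, 3, cfg)
        fs = self._fs(rng)
        z, rec = hcsae_forward(fs, net)
        assert z.shape == (6, 12)           # latent keeps the time length
        assert rec.output.shape[-1] == 6    # one pooling halves time

    def test_odd_abstract_channels_rejected(self):
        with pytest.raises(ConfigurationError):
            HCSAEConfig(abstract_channels=5).validate()


def test_gradient_flow_matches_finite_differences(rng):
    """Autodiff gradient of the reconstruction error w.r.t. a decoder weight
    agrees with central differences within 1e-4 relative (float64 probe)."""
    cfg = HCSAEConfig(abstract_channels=4, n_1x3_layers=1, dropout_q=0.0,
                      latent_channels=6, seed=0)
    net = HCSAE(5, 3, cfg)
    for p in net.parameters():
        p.data = p.data.astype(np.float64)
    F1 = Tensor(rng.normal(size=(2, 5, 8)))
    F2 = Tensor(rng.normal(size=(2, 3, 8)))
    _, _, err = net.forward(F1, F2)
    err.backward()
    w = net.decode_conv.w
    g_auto = w.grad[0, 0, 0]
    eps = 1e-6

    def at(delta):
        w.data[0, 0, 0] += delta
        _, _, e = net.forward(F1, F2)
        w.data[0, 0, 0] -= delta
        return float(e.data)

    g_fd = (at(eps) - at(-eps)) / (2 * eps)
    assert abs(g_auto - g_fd) / max(abs(g_fd), 1e-12) < 1e-4
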