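"""Variational GP autoencoder: losses, limits, training behavior."""

import numpy as np
import pytest

from stvgp.autograd import Tensor
from stvgp.gp_core import Kernel, gp_conditional, knn_graph
from stvgp.metrics import ari
from stvgp.synthetic import SynthConfig, make_stack
from stvgp.vgp_model import (
    GaussianDecoder,
    GaussianEncoder,
    VGPConfig,
    _build_prior,
    cluster_domains,
    crossmodal_losses,
    elbo_expression,
    encode,
    mmd,
    train,
)

_LOG2PI = np.log(2 * np.pi)


class TestEncoder:
    def test_zero_initialized_heads(self):
        enc = GaussianEncoder(5, (8,), 3, np.random.default_rng(0))
        m, lv = encode(np.random.default_rng(1).random((4, 5)), enc)
        np.testing.assert_array_equal(m, 0.0)
        np.testing.assert_array_equal(lv, -2.0)

    def test_identical_rows_identical_outputs_and_chunking(self):
        enc = GaussianEncoder(6, (8,), 3, np.random.default_rng(2))
        for W, _, _, _ in enc.mean_head.layers:
            W.data = np.random.default_rng(3).standard_normal(W.shape) * 0.1
        x = np.random.default_rng(4).random((10, 6))
        x[3] = x[7]
        m, lv = encode(x, enc)
        np.testing.assert_array_equal(m[3], m[7])
        m_a, _ = encode(x[:4], enc)
        np.testing.assert_allclose(m[:4], m_a, atol=1e-12)

    def test_dim_mismatch_fatal(self):
        enc = GaussianEncoder(6, (8,), 3, np.random.default_rng(5))
        with pytest.raises(ValueError, match="dim"):
            encode(np.ones((2, 4)), enc)


class TestMMD:
    def test_identical_samples_give_exact_zero(self):
        A = np.random.default_rng(0).random((15, 4))
        assert mmd(A, A.copy()) == 0.0

    def test_single_point_closed_form(self):
        x, y = np.array([[0.0, 0.0]]), np.array([[1.0, 1.0]])
        sigma = 2.0
        val = mmd(x, y, bandwidths=[sigma])
        kappa = np.exp(-2.0 / (2 * sigma**2))
        assert abs(val - 2 * (1 - kappa)) < 1e-12

    def test_shifted_distribution_exceeds_null(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            A = rng.standard_normal((200, 2))
            B = rng.standard_normal((200, 2)) + 5.0
            A2 = rng.standard_normal((200, 2))
            hits += mmd(A, B) > mmd(A, A2)
        assert hits == 20

    def test_symmetric_and_nonnegative(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            A, B = rng.random((8, 3)), rng.random((12, 3))
            assert mmd(A, B) >= 0
            assert abs(mmd(A, B) - mmd(B, A)) < 1e-12


class TestCrossmodal:
    def test_equal_latents_give_zero_losses(self):
        H = np.random.default_rng(7).random((20, 4))
        graph = knn_graph(np.random.default_rng(8).random((20, 2)), 4)
        gd, sld, cl = crossmodal_losses(H, H.copy(), graph)
        assert gd == 0 and sld == 0 and cl == 0

    def test_opposite_latents_guarded(self):
        H = np.random.default_rng(9).random((10, 3)) + 1.0
        graph = knn_graph(np.random.default_rng(10).random((10, 2)), 3)
        _, _, cl = crossmodal_losses(H, -H, graph)
        assert np.isfinite(cl) and cl > 1e3

    def test_sld_matches_per_neighborhood_oracle(self):
        rng = np.random.default_rng(11)
        H1, H2 = rng.random((20, 3)), rng.random((20, 3))
        coords = rng.random((20, 2))
        graph = knn_graph(coords, 4)
        bw = [0.7, 1.3]
        _, sld, _ = crossmodal_losses(H1, H2, graph, bandwidths=bw)
        oracle = np.mean(
            [mmd(H1[graph.nei[k]], H2[graph.nei[k]], bw) for k in range(20)]
        )
        assert abs(sld - oracle) < 1e-10

    def test_absent_second_modality_returns_zeros(self):
        graph = knn_graph(np.random.default_rng(0).random((5, 2)), 2)
        assert crossmodal_losses(np.ones((5, 2)), None, graph) == (0.0, 0.0, 0.0)


def plain_vae_elbo(x, mu, logvar, sample, xhat, log_noise):
    """Independent textbook VAE ELBO: Gaussian decoder, N(0, I) prior,
    closed-form KL, single-sample reconstruction."""
    var_g = np.exp(log_noise)
    recon = -0.5 * (_LOG2PI + log_noise + (x - xhat) ** 2 / var_g).sum()
    kl = -0.5 * (1 + logvar - mu**2 - np.exp(logvar)).sum()
    return recon - kl


class TestELBO:
    def _setup(self, seed=0, n=12, g=7, L=3):
        rng = np.random.default_rng(seed)
        x = rng.random((n, g))
        enc = GaussianEncoder(g, (8,), L, rng)
        for W, _, _, _ in enc.mean_head.layers:
            W.data = rng.standard_normal(W.shape) * 0.3
        dec = GaussianDecoder(L, (8,), g, rng)
        dec.log_noise.data = rng.standard_normal(g) * 0.2
        mu, lv = enc(Tensor(x))
        h = mu + (lv * 0.5).exp() * Tensor(rng.standard_normal(mu.shape))
        return x, enc, dec, mu, lv, h, rng

    def test_vae_limit_matches_independent_implementation(self):
        """K = 0 and zero batch means reduce the model to a plain VAE."""
        x, enc, dec, mu, lv, h, rng = self._setup()
        coords = rng.random((len(x), 2))
        kernel = Kernel(lengthscale=1.0, variance=1.0)
        prior = _build_prior(coords, kernel, knn_graph(coords, 0))
        val = elbo_expression(
            x, mu, lv, h, dec, prior, Tensor(np.zeros(mu.shape))
        ).item()
        xhat = dec(h).data
        expected = plain_vae_elbo(x, mu.data, lv.data, h.data, xhat, dec.log_noise.data)
        assert abs(val - expected) < 1e-6

    def test_kl_term_matches_dense_gaussian_oracle(self):
        """Neighbor-conditioned KL on a 4-spot toy vs closed-form KL against
        the GP conditional evaluated spot by spot."""
        x, enc, dec, mu, lv, h, rng = self._setup(seed=1, n=4)
        coords = rng.random((4, 2))
        kernel = Kernel(lengthscale=0.7, variance=1.2)
        graph = knn_graph(coords, 2)
        prior = _build_prior(coords, kernel, graph)
        val = elbo_expression(x, mu, lv, h, dec, prior, Tensor(np.zeros(mu.shape))).item()
        # oracle: recon + sum_j KL(N(mu_j, s_j^2) || N(m_j, v_j))
        xhat = dec(h).data
        var_g = np.exp(dec.log_noise.data)
        recon = -0.5 * (_LOG2PI + dec.log_noise.data + (x - xhat) ** 2 / var_g).sum()
        kl = 0.0
        for j in range(4):
            nei = graph.nei[j]
            m, c = gp_conditional(coords[j], coords[nei], mu.data[nei], kernel)
            v = kernel.variance - (
                kernel(coords[j], coords[nei])[0]
                @ np.linalg.solve(
                    kernel(coords[nei], coords[nei]) + kernel.jitter * np.eye(len(nei)),
                    kernel(coords[nei], coords[j])[:, 0],
                )
            )
            s2 = np.exp(lv.data[j])
            kl += 0.5 * (
                np.log(v) - lv.data[j] + (s2 + (mu.data[j] - m[0]) ** 2) / v - 1.0
            ).sum()
        assert abs(val - (recon - kl)) < 1e-6

    def test_perfect_decoder_maximizes_reconstruction(self):
        x = np.random.default_rng(2).random((6, 3))
        var_g = np.full(3, 1e-4)
        recon_perfect = -0.5 * (_LOG2PI + np.log(var_g)).sum() * 6
        recon_bad = -0.5 * ((_LOG2PI + np.log(var_g)) + (0.5**2) / var_g).sum() * 6
        assert recon_perfect > recon_bad


def _tiny_stack(seed=0, n_slices=2, spots=80, genes=30):
    cfg = SynthConfig(
        n_slices=n_slices, spots_per_slice=spots, n_genes=genes, seed=seed,
        rotation_deg=0.0, markers_per_domain=5,
    )
    return make_stack(cfg)


class TestTraining:
    def test_same_seed_bit_identical_history(self):
        stack, _ = _tiny_stack()
        cfg = VGPConfig(latent_dim=4, hidden=(16,), epochs=5, seed=3)
        _, h1, _ = train(stack, cfg)
        _, h2, _ = train(stack, cfg)
        assert h1.total == h2.total
        assert h1.L_exp == h2.L_exp

    def test_loss_decreases_on_synthetic_stack(self):
        stack, _ = _tiny_stack(seed=1)
        cfg = VGPConfig(latent_dim=8, hidden=(32,), epochs=60, seed=0)
        _, hist, _ = train(stack, cfg)
        assert hist.L_exp[-1] < hist.L_exp[0]

    def test_loss_report_total_identity(self):
        stack, _ = _tiny_stack(seed=2)
        cfg = VGPConfig(latent_dim=4, hidden=(16,), epochs=3, seed=0,
                        use_images=True, lambda1=0.5)
        _, hist, _ = train(stack, cfg)
        for i in range(len(hist.total)):
            expected = (
                hist.L_exp[i]
                + hist.L_img[i]
                + cfg.lambda_batch * hist.L_batch[i]
                + cfg.lambda1 * (hist.L_CL[i] + hist.L_align_GD[i] + hist.L_align_SLD[i])
            )
            assert abs(hist.total[i] - expected) < 1e-6 * max(1, abs(expected))

    def test_checkpoint_round_trip(self, tmp_path):
        stack, _ = _tiny_stack(seed=3)
        cfg = VGPConfig(latent_dim=4, hidden=(16,), epochs=3, seed=0)
        latent, _, model = train(stack, cfg)
        model.save(tmp_path / "m")
        from stvgp.vgp_model import VGPModel

        back = VGPModel.load(tmp_path / "m")
        x = stack.slices[0].expr
        np.testing.assert_array_equal(
            model.encode_expr(x)[0], back.encode_expr(x)[0]
        )


class TestClustering:
    def test_two_blobs_perfectly_recovered(self):
        rng = np.random.default_rng(4)
        Z = np.concatenate([rng.normal(0, 0.1, (40, 3)), rng.normal(5, 0.1, (40, 3))])
        truth = np.repeat([0, 1], 40)
        for method in ("kmeans", "leiden"):
            labels = cluster_domains(Z, method=method, n_domains=2, resolution=0.5, seed=0)
            assert ari(truth, labels) == 1.0

    def test_kmeans_k1_single_label(self):
        Z = np.random.default_rng(5).random((10, 2))
        assert len(np.unique(cluster_domains(Z, "kmeans", 1, seed=0))) == 1

    def test_too_many_domains_fatal(self):
        with pytest.raises(ValueError):
            cluster_domains(np.ones((3, 2)), "kmeans", 5, seed=0)


def test_negative_binomial_likelihood_trains_on_counts():
    from stvgp.io_preprocess import normalize

    cfg = SynthConfig(n_slices=2, spots_per_slice=60, n_genes=20, seed=50,
                      counts=True, rotation_deg=0.0, markers_per_domain=3)
    stack, _ = make_stack(cfg)
    stack = normalize(stack)
    _, hist, _ = train(
        stack, VGPConfig(latent_dim=4, hidden=(16,), epochs=30,
                         likelihood="nb", seed=0)
    )
    assert hist.L_exp[-1] < hist.L_exp[0]
    assert np.all(np.isfinite(hist.total))
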