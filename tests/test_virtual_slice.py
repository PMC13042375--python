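"""Virtual-slice prediction: GP posterior, Monte-Carlo decoding, masking."""

import numpy as np
import pytest

from stvgp.gp_core import Kernel
from stvgp.synthetic import SynthConfig, make_stack
from stvgp.vgp_model import VGPConfig, train
from stvgp.virtual_slice import (
    generate_slice,
    predict_from_images,
    predict_latent,
    predict_masked_slice,
)


@pytest.fixture(scope="module")
def trained_small():
    cfg = SynthConfig(n_slices=3, spots_per_slice=100, n_genes=40, seed=41,
                      rotation_deg=0.0, markers_per_domain=6)
    stack, truth = make_stack(cfg)
    mcfg = VGPConfig(latent_dim=8, hidden=(64, 32), epochs=500, seed=0)
    latent, _, model = train(stack, mcfg)
    coords3d = np.concatenate(
        [np.column_stack([s.coords, np.full(s.n_spots, s.z)]) for s in stack.slices]
    )
    return stack, truth, latent, model, coords3d


class TestPredictLatent:
    def test_query_at_real_spot_k1_recovers_latent(self, trained_small):
        _, _, latent, _, coords3d = trained_small
        kern = Kernel(lengthscale=1.0, variance=1.0, jitter_frac=1e-14)
        mean, var, nei = predict_latent(
            coords3d[5], coords3d, latent.mean1, kern, K=1
        )
        np.testing.assert_allclose(mean[0], latent.mean1[5], atol=1e-5)
        assert var[0] < 1e-5

    def test_midpoint_between_equal_latents_long_lengthscale(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        v = np.array([[1.5, -0.5], [1.5, -0.5]])
        kern = Kernel(lengthscale=1e4, variance=1.0)
        mean, _, _ = predict_latent([[1.0, 0.0, 0.0]], coords, v, kern, K=2)
        np.testing.assert_allclose(mean[0], [1.5, -0.5], atol=1e-4)

    def test_matches_dense_gp_oracle(self):
        rng = np.random.default_rng(0)
        coords = rng.random((6, 3))
        vals = rng.standard_normal((6, 4))
        q = rng.random((2, 3))
        kern = Kernel(lengthscale=0.8, variance=1.1)
        mean, var, _ = predict_latent(q, coords, vals, kern, K=6)
        K_nn = kern(coords, coords) + kern.jitter * np.eye(6)
        for i in range(2):
            K_qn = kern(q[i], coords)
            exp_mean = K_qn @ np.linalg.solve(K_nn, vals)
            exp_var = kern.variance - (K_qn @ np.linalg.solve(K_nn, K_qn.T))[0, 0]
            np.testing.assert_allclose(mean[i], exp_mean[0], atol=1e-8)
            assert abs(var[i] - max(exp_var, 0)) < 1e-8

    def test_k0_returns_prior_with_warning(self, trained_small):
        _, _, latent, _, coords3d = trained_small
        with pytest.warns(UserWarning, match="prior"):
            mean, var, _ = predict_latent(
                coords3d[:3], coords3d, latent.mean1, Kernel(1.0, 1.0), K=0
            )
        np.testing.assert_array_equal(mean, 0.0)
        np.testing.assert_array_equal(var, 1.0)


class TestGenerateSlice:
    def test_deterministic_per_seed_and_mc_convergence(self, trained_small):
        stack, _, latent, model, coords3d = trained_small
        kw = dict(aligned_coords=coords3d, latent_means=latent.mean1, model=model)
        a = generate_slice(0.5, n_mc=5, seed=3, **kw)
        b = generate_slice(0.5, n_mc=5, seed=3, **kw)
        np.testing.assert_array_equal(a.expr_mean, b.expr_mean)
        # across-seed scatter of the MC mean shrinks with more samples
        def spread(n_mc):
            means = [
                generate_slice(0.5, n_mc=n_mc, seed=s, **kw).expr_mean
                for s in range(4)
            ]
            return np.std(np.stack(means), axis=0).mean()

        assert spread(32) < spread(2)

    def test_midpoint_prediction_between_slices(self, trained_small):
        stack, _, latent, model, coords3d = trained_small
        vs = generate_slice(0.5, coords3d, latent.mean1, model, n_mc=10, seed=0)
        # grid copied from the nearest real plane
        assert vs.expr_mean.shape == (100, stack.n_genes)
        assert np.all(vs.query_coords[:, 2] == 0.5)
        # neighbors come mostly from the two adjacent planes
        z_nei = coords3d[vs.neighbor_idx.ravel(), 2]
        assert np.mean(np.isin(z_nei, [0.0, 1.0])) > 0.8

    def test_extrapolation_warns(self, trained_small):
        _, _, latent, model, coords3d = trained_small
        with pytest.warns(UserWarning, match="extrapolation"):
            generate_slice(10.0, coords3d, latent.mean1, model, n_mc=2, seed=0)

    def test_self_consistency_at_a_real_plane(self, trained_small):
        stack, truth, latent, model, coords3d = trained_small
        vs = generate_slice(1.0, coords3d, latent.mean1, model, n_mc=20, seed=0)
        from stvgp.metrics import expression_report

        rep = expression_report(vs.expr_mean, stack.slices[1].expr, stack.genes)
        markers = [g for gs in truth["marker_genes"].values() for g in gs]
        assert rep.loc[markers, "pearson_r"].median() > 0.5


class TestMasking:
    def test_out_of_range_fatal(self, trained_small):
        stack, *_ = trained_small
        with pytest.raises(IndexError):
            predict_masked_slice(stack, 99, VGPConfig(epochs=1))

    def test_boundary_mask_warns_and_runs(self):
        cfg = SynthConfig(n_slices=3, spots_per_slice=60, n_genes=20, seed=42,
                          rotation_deg=0.0, markers_per_domain=3)
        stack, _ = make_stack(cfg)
        with pytest.warns(UserWarning, match="boundary"):
            vs, rep = predict_masked_slice(
                stack, 0, VGPConfig(latent_dim=4, hidden=(16,), epochs=10), seed=0
            )
        assert vs.expr_mean.shape == (60, 20)

    def test_masked_expression_never_leaks(self):
        """Predictions are bit-identical whether the masked slice's
        expression is zeroed or left intact."""
        cfg = SynthConfig(n_slices=3, spots_per_slice=60, n_genes=20, seed=43,
                          rotation_deg=0.0, markers_per_domain=3)
        stack, _ = make_stack(cfg)
        mcfg = VGPConfig(latent_dim=4, hidden=(16,), epochs=15)
        vs1, rep1 = predict_masked_slice(stack, 1, mcfg, seed=0)
        stack.slices[1].expr = np.zeros_like(stack.slices[1].expr)
        stack.slices[1].raw = np.zeros_like(stack.slices[1].raw)
        vs2, _ = predict_masked_slice(stack, 1, mcfg, seed=0)
        np.testing.assert_array_equal(vs1.expr_mean, vs2.expr_mean)


class TestCrossModal:
    def test_unimodal_model_has_no_image_head(self, trained_small):
        _, _, _, model, _ = trained_small
        with pytest.raises(ValueError, match="cross-modal"):
            predict_from_images(np.ones((5, 8)), model)

    def test_same_embeddings_same_predictions(self):
        cfg = SynthConfig(n_slices=2, spots_per_slice=60, n_genes=20, seed=44,
                          rotation_deg=0.0, markers_per_domain=3, img_dim=16)
        stack, _ = make_stack(cfg)
        mcfg = VGPConfig(latent_dim=4, hidden=(16,), epochs=15, use_images=True)
        _, _, model = train(stack, mcfg)
        emb = stack.slices[0].img_emb
        np.testing.assert_array_equal(
            predict_from_images(emb, model), predict_from_images(emb, model)
        )
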