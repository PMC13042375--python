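"""Landmarks, rigid fitting, STN and fusion."""

import numpy as np
import pytest

from stvgp.align3d import (
    AlignConfig,
    STN,
    align_pair,
    align_stack,
    compute_landmarks,
    fit_rigid,
    fuse,
    LandmarkSet,
)
from stvgp.io_preprocess import Slice
from stvgp.metrics import alignment_distance, alignment_score
from stvgp.svg_selection import select_svgs
from stvgp.synthetic import SynthConfig, make_stack


def _swap_coords(s, coords):
    return Slice(expr=s.expr, coords=coords, genes=s.genes, img_emb=s.img_emb,
                 labels=s.labels, batch_id=s.batch_id, z=s.z, name=s.name)


@pytest.fixture(scope="module")
def svg_stack():
    stack, truth = make_stack(
        SynthConfig(n_slices=2, spots_per_slice=200, n_genes=60, seed=21,
                    rotation_deg=0.0)
    )
    svg = select_svgs(stack, top_k=30)
    return stack, truth, svg


class TestLandmarks:
    def test_single_spot_genes_land_on_those_spots(self):
        from stvgp.svg_selection import MoranResult

        rng = np.random.default_rng(12)
        coords = rng.random((10, 2)) * 5
        expr = np.zeros((10, 3))
        spots = [7, 2, 4]
        for g, sp in enumerate(spots):
            expr[sp, g] = 5.0
        s = Slice(expr=expr, coords=coords, genes=["a", "b", "c"])
        svg = MoranResult(I=np.zeros((3, 1)), variance=np.ones(3),
                          selected=["a", "b", "c"], genes=["a", "b", "c"])
        lm = compute_landmarks(s, s, svg, m=3)
        np.testing.assert_allclose(lm.coords_template, coords[spots])

    def test_uniform_expression_gives_unweighted_centroid(self, svg_stack):
        stack, _, svg = svg_stack
        s = stack.slices[0]
        mod = _swap_coords(s, s.coords)
        mod.expr = np.ones_like(s.expr)
        lm = compute_landmarks(mod, mod, svg, m=3)
        np.testing.assert_allclose(lm.coords_template[0], s.coords.mean(0))

    def test_two_spot_weighted_mean(self):
        s = Slice(expr=np.array([[1.0], [3.0]]),
                  coords=np.array([[0.0, 0.0], [4.0, 0.0]]), genes=["g"])
        from stvgp.svg_selection import MoranResult

        svg = MoranResult(I=np.zeros((1, 1)), variance=np.ones(1),
                          selected=["g"], genes=["g"])
        with pytest.raises(ValueError):  # only 1 gene -> < 3 landmarks
            compute_landmarks(s, s, svg, m=3)
        # the centroid itself: (0*1 + 4*3) / 4 = 3
        from stvgp.align3d import _weighted_centroid

        assert _weighted_centroid(s.coords, s.expr[:, 0])[0] == 3.0

    def test_landmark_set_needs_three(self):
        with pytest.raises(ValueError, match=">= 3"):
            LandmarkSet(["a", "b"], np.zeros((2, 2)), np.zeros((2, 2)))


class TestRigid:
    def _rotate(self, coords, deg):
        th = np.deg2rad(deg)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return coords @ R.T

    def test_rotation_recovery(self):
        rng = np.random.default_rng(0)
        lm_t = rng.random((20, 2)) * 10
        lm_m = self._rotate(lm_t, -30.0)  # moving = template rotated
        lm = LandmarkSet([f"g{i}" for i in range(20)], lm_t, lm_m)
        f = fit_rigid(lm, AlignConfig(rigid_epochs=50, seed=0))
        rmse = np.sqrt(((f(lm_m) - lm_t) ** 2).mean())
        diameter = np.linalg.norm(lm_t.max(0) - lm_t.min(0))
        assert rmse < 0.01 * diameter

    def test_identity_and_translation(self):
        rng = np.random.default_rng(1)
        lm_t = rng.random((15, 2)) * 5
        lm = LandmarkSet([f"g{i}" for i in range(15)], lm_t, lm_t.copy())
        f = fit_rigid(lm, AlignConfig(rigid_epochs=30, seed=0))
        assert np.abs(f(lm_t) - lm_t).max() < 1e-3
        lm2 = LandmarkSet([f"g{i}" for i in range(15)], lm_t, lm_t + [5.0, -2.0])
        f2 = fit_rigid(lm2, AlignConfig(rigid_epochs=30, seed=0))
        assert np.abs(f2(lm_t + [5.0, -2.0]) - lm_t).max() < 1e-3

    def test_collinear_landmarks_fall_back_with_warning(self):
        lm_t = np.column_stack([np.arange(5.0), np.zeros(5)])
        lm = LandmarkSet([f"g{i}" for i in range(5)], lm_t, lm_t.copy())
        with pytest.warns(UserWarning, match="degenerate"):
            fit_rigid(lm, AlignConfig(rigid_epochs=5, seed=0))


class TestSTN:
    def test_identity_at_zero_init(self):
        rng = np.random.default_rng(2)
        coords = rng.random((40, 2)) * 8
        stn = STN(40, coords, AlignConfig(), rng)
        np.testing.assert_allclose(stn.forward_np(coords), coords, atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        coords = rng.random((30, 2))
        cfg = AlignConfig(k_schedule=(8, 4, 2))
        stn = STN(30, coords, cfg, np.random.default_rng(4))
        # give it non-trivial weights
        for p in stn.params:
            p.data = np.random.default_rng(5).standard_normal(p.data.shape) * 0.3
        out = stn.forward_np(coords)
        perm = rng.permutation(30)
        stn_p = STN(30, coords[perm], cfg, np.random.default_rng(4))
        for p, q in zip(stn_p.params, stn.params):
            p.data = q.data.copy()
        out_p = stn_p.forward_np(coords[perm])
        np.testing.assert_allclose(out_p, out[perm], atol=1e-8)

    def test_schedule_must_strictly_decrease(self):
        rng = np.random.default_rng(6)
        coords = rng.random((40, 2))
        stn = STN(40, coords, AlignConfig(k_schedule=(32, 16, 8)), rng)
        assert stn.k_schedule == (32, 16, 8)
        with pytest.raises(ValueError, match="decreasing"):
            STN(40, coords, AlignConfig(k_schedule=(8, 16)), rng)


class TestFusion:
    def test_zero_attention_gives_midpoint(self):
        rng = np.random.default_rng(7)
        zr, zn = rng.random((10, 2)), rng.random((10, 2))
        alpha, zhat = fuse(zr, zn, np.zeros((2, 1)), rng.standard_normal((2, 2)),
                           np.zeros(2))
        np.testing.assert_allclose(alpha, 0.5)
        np.testing.assert_allclose(zhat, 0.5 * (zr + zn))

    def test_alpha_rows_sum_to_one(self):
        rng = np.random.default_rng(8)
        alpha, _ = fuse(rng.random((20, 2)), rng.random((20, 2)),
                        rng.standard_normal((2, 1)), rng.standard_normal((2, 2)),
                        rng.standard_normal(2))
        np.testing.assert_allclose(alpha.sum(1), 1.0, atol=1e-12)
        assert np.all((alpha > 0) & (alpha < 1))

    def test_consensus_coordinates_unchanged(self):
        rng = np.random.default_rng(9)
        z = rng.random((10, 2))
        _, zhat = fuse(z, z.copy(), rng.standard_normal((2, 1)),
                       rng.standard_normal((2, 2)), rng.standard_normal(2))
        np.testing.assert_allclose(zhat, z, atol=1e-12)


class TestPairAndStack:
    def test_identical_slices_align_to_near_zero_loss(self, svg_stack):
        stack, _, svg = svg_stack
        a = stack.slices[0]
        b = _swap_coords(a, a.coords.copy())
        b.z = a.z + 1
        tr = align_pair(a, b, svg, AlignConfig(epochs=100, seed=0))
        assert np.abs(tr.Z_hat - a.coords).mean() < 0.2

    def test_rotated_warped_slice_recovers(self):
        cfg = SynthConfig(n_slices=2, spots_per_slice=250, n_genes=100, seed=31,
                          rotation_deg=(0.0, 60.0), warp_amplitude=1.2)
        stack, _ = make_stack(cfg)
        svg = select_svgs(stack, top_k=40)
        a, b = stack.slices
        pre = np.nanmean(alignment_distance(a, b))
        tr = align_pair(a, b, svg, AlignConfig(seed=0, epochs=300))
        b2 = _swap_coords(b, tr.Z_hat)
        post = np.nanmean(alignment_distance(a, b2))
        assert post < 0.5 * pre
        assert alignment_score(a, b2) > alignment_score(a, b)

    def test_single_slice_stack_rejected(self, svg_stack):
        stack, _, svg = svg_stack
        from stvgp.io_preprocess import SliceStack

        single = SliceStack([stack.slices[0]], stack.genes)
        with pytest.raises(ValueError, match=">=2"):
            align_stack(single, svg)

    def test_identical_slices_stack_is_prism(self, svg_stack):
        stack, _, svg = svg_stack
        transforms = align_stack(stack, svg, AlignConfig(epochs=60, seed=0))
        assert len(transforms) == 2
        np.testing.assert_array_equal(transforms[0].Z_hat, stack.slices[0].coords)
        np.testing.assert_allclose(transforms[0].alpha.sum(1), 1.0)
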