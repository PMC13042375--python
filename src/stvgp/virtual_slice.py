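"""Virtual slices: latent GP prediction at unsampled 3D locations.

A query location's latent posterior is the GP predictive conditional over
its K nearest aligned real spots, with the neighbors' variational posterior
means plugged in (mean-field approximation of the predictive integral).
Expression is then obtained by Monte-Carlo: sample latents from the query
posterior, decode each with the expression decoder, and average the decoded
samples.

Also provides the leave-one-slice-out protocol (mask a real slice, retrain
on the rest, predict the masked slice's expression at its coordinates) and
cross-modal prediction of expression from histology-image embeddings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .gp_core import Kernel, gp_conditional
from .io_preprocess import SliceStack
from .metrics import expression_report
from .vgp_model import VGPConfig, VGPModel, train

__all__ = [
    "VirtualSlice",
    "predict_latent",
    "generate_slice",
    "predict_masked_slice",
    "predict_from_images",
]


@dataclass
class VirtualSlice:
    query_coords: np.ndarray  # (q, 3)
    latent_mean: np.ndarray  # (q, L)
    latent_var: np.ndarray  # (q,) GP conditional variance per query
    expr_mean: np.ndarray  # (q, G) Monte-Carlo average of decoded samples
    expr_samples: np.ndarray | None  # (S, q, G) when retained
    neighbor_idx: np.ndarray  # (q, K) indices into the aligned spots


def _kernel_3d(aligned_coords: np.ndarray, variance: float) -> Kernel:
    """Kernel for 3D queries: lengthscale = median distance to the nearest
    spot on a *different* z-plane, so neighbors on adjacent slices retain
    meaningful weight (the in-plane spacing is much finer than the
    inter-slice gap)."""
    zs = aligned_coords[:, 2]
    planes = np.unique(np.round(zs, 9))
    if len(planes) < 2:
        return Kernel.from_coords(aligned_coords, variance=variance)
    cross = []
    for p in planes:
        own = np.isclose(zs, p)
        if own.all() or (~own).sum() == 0:
            continue
        d, _ = cKDTree(aligned_coords[~own]).query(aligned_coords[own])
        cross.append(np.median(d))
    ls = float(np.median(cross)) if cross else 1.0
    return Kernel(lengthscale=max(ls, 1e-12), variance=variance)


def predict_latent(
    query_coords: np.ndarray,
    aligned_coords: np.ndarray,
    latent_means: np.ndarray,
    kernel: Kernel | None = None,
    K: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Latent posterior at 3D query points from K nearest aligned spots.

    Returns (mean (q, L), var (q,), neighbor_idx (q, K)). K = 0 returns the
    prior N(0, variance) with a warning.
    """
    query_coords = np.atleast_2d(np.asarray(query_coords, dtype=float))
    aligned_coords = np.asarray(aligned_coords, dtype=float)
    latent_means = np.asarray(latent_means, dtype=float)
    if kernel is None:
        kernel = _kernel_3d(aligned_coords, 1.0)
    q = len(query_coords)
    L = latent_means.shape[1]
    if K == 0:
        warnings.warn("K=0: returning the GP prior at every query")
        return (
            np.zeros((q, L)),
            np.full(q, kernel.variance),
            np.zeros((q, 0), dtype=np.intp),
        )
    K = min(K, len(aligned_coords))
    _, nei = cKDTree(aligned_coords).query(query_coords, k=K)
    nei = np.atleast_2d(nei)
    if K == 1:
        nei = nei.reshape(-1, 1)
    mean = np.zeros((q, L))
    var = np.zeros(q)
    for i in range(q):
        m, c = gp_conditional(
            query_coords[i], aligned_coords[nei[i]], latent_means[nei[i]], kernel
        )
        mean[i] = m[0]
        var[i] = max(c[0, 0], 0.0)
    return mean, var, nei


def generate_slice(
    z_query: float,
    aligned_coords: np.ndarray,
    latent_means: np.ndarray,
    model: VGPModel,
    grid: np.ndarray | None = None,
    slice_z: np.ndarray | None = None,
    K: int = 10,
    n_mc: int = 30,
    seed: int = 0,
    keep_samples: bool = False,
) -> VirtualSlice:
    """Decode a virtual slice at depth `z_query`.

    Query (x, y) positions default to the layout of the nearest real slice
    (`slice_z` gives each aligned spot's z so the nearest plane can be
    found); pass `grid` for a custom layout. A z beyond one inter-slice gap
    outside the sampled range triggers an extrapolation warning.
    """
    aligned_coords = np.asarray(aligned_coords, dtype=float)
    zs = np.unique(np.round(aligned_coords[:, 2], 9)) if slice_z is None else np.unique(slice_z)
    gap = np.diff(zs).max() if len(zs) > 1 else 1.0
    if z_query < zs.min() - gap or z_query > zs.max() + gap:
        warnings.warn(f"z={z_query} is an extrapolation beyond the sampled range")
    if grid is None:
        nearest_z = zs[np.argmin(np.abs(zs - z_query))]
        mask = np.isclose(aligned_coords[:, 2], nearest_z)
        grid = aligned_coords[mask, :2]
    query = np.column_stack([grid, np.full(len(grid), float(z_query))])

    kernel = _kernel_3d(aligned_coords, model.config.kernel_variance)
    mean, var, nei = predict_latent(query, aligned_coords, latent_means, kernel, K)

    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n_mc):
        h = mean + np.sqrt(var)[:, None] * rng.standard_normal(mean.shape)
        samples.append(model.decode_expr(h))
    S = np.stack(samples)
    return VirtualSlice(
        query_coords=query,
        latent_mean=mean,
        latent_var=var,
        expr_mean=S.mean(0),
        expr_samples=S if keep_samples else None,
        neighbor_idx=nei,
    )


def predict_masked_slice(
    stack: SliceStack,
    mask_index: int,
    model_config: VGPConfig | None = None,
    seed: int = 0,
    align: bool = False,
    K: int = 10,
    n_mc: int = 30,
    svg_top_k: int = 50,
):
    """Leave-one-slice-out: retrain without the masked slice and predict its
    expression at its own coordinates.

    The masked slice contributes only coordinates, z and (for scoring) its
    held-out expression; its expression never enters training. Returns
    (VirtualSlice, per-gene DataFrame with pearson_r and rmse). With
    `align=True` the remaining slices are registered first; leave it False
    when slices are already in a shared frame.
    """
    if not 0 <= mask_index < stack.n_slices:
        raise IndexError(f"mask_index {mask_index} out of range")
    if mask_index in (0, stack.n_slices - 1):
        warnings.warn("masking a boundary slice: prediction extrapolates in z")
    model_config = model_config or VGPConfig()
    model_config.seed = seed
    rest = stack.drop_slice(mask_index)

    latent, _, model = train(rest, model_config)
    if align and rest.n_slices >= 2:
        from .align3d import AlignConfig, align_stack, aligned_coords_3d
        from .svg_selection import select_svgs

        svg = select_svgs(rest, top_k=svg_top_k)
        sizes = np.cumsum([0] + [s.n_spots for s in rest.slices])
        lats = [latent.corrected[sizes[i]: sizes[i + 1]] for i in range(rest.n_slices)]
        transforms = align_stack(rest, svg, AlignConfig(seed=seed), lats)
        coords3d = aligned_coords_3d(rest, transforms)
    else:
        coords3d = np.concatenate(
            [
                np.column_stack([s.coords, np.full(s.n_spots, s.z)])
                for s in rest.slices
            ]
        )

    masked = stack.slices[mask_index]
    vs = generate_slice(
        masked.z,
        coords3d,
        latent.mean1,
        model,
        grid=masked.coords,
        K=K,
        n_mc=n_mc,
        seed=seed,
    )
    report = expression_report(vs.expr_mean, masked.expr, stack.genes)
    return vs, report


def predict_from_images(img_emb: np.ndarray, model: VGPModel) -> np.ndarray:
    """Cross-modal prediction: image embeddings -> expression.

    Embeddings are encoded with the image encoder and the posterior mean is
    decoded with the *expression* decoder; training's cross-modal alignment
    losses make the two latent distributions interchangeable.
    """
    mean2, _ = model.encode_img(np.asarray(img_emb, dtype=float))
    return model.decode_expr(mean2)
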