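"""Hybrid rigid + non-rigid slice registration into a shared 3D frame.

Registration of a moving slice onto a template proceeds in three stages:

1. **Rigid stage** — each highly spatial gene (by Moran's-I variance) yields
   one landmark per slice: its expression-weighted center of mass. A
   similarity transform (rotation/translation/scale, Procrustes) seeds an
   MLP that refines the landmark-to-landmark mapping; the composed map is
   applied to every spot.
2. **Non-rigid stage** — a spatial transformer: a stack of single-head
   attention layers over spot coordinates, each restricted to a shrinking
   k-nearest-neighbor footprint, with residual feed-forward refinement.
   Zero-initialized value/output projections make the STN the identity map
   at initialization.
3. **Fusion** — a per-spot attention gate blends the rigid and non-rigid
   coordinates; gate weights are a softmax over a shared scorer, so they
   are positive and sum to one.

The STN and fusion parameters are trained jointly to minimize the Frobenius
distance between fused coordinates and each moving spot's matched template
coordinate, where matching is nearest-neighbor in an expression-derived
latent space (trained model latents when available, else PCA).

Stacking appends each slice's z position as the third coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from . import autograd as ag
from .autograd import Tensor
from .gp_core import knn_graph
from .io_preprocess import Slice, SliceStack
from .svg_selection import MoranResult

__all__ = [
    "AlignConfig",
    "LandmarkSet",
    "Transform3D",
    "STN",
    "compute_landmarks",
    "fit_rigid",
    "stn_forward",
    "fuse",
    "align_pair",
    "align_stack",
]


@dataclass
class AlignConfig:
    m_landmarks: int = 30
    rigid_hidden: tuple = (64, 64)
    rigid_epochs: int = 300
    stn_layers: int = 3
    k_schedule: tuple | None = None  # default (min(32, N-1), 16, 8)
    ffn_hidden: int = 32
    clip_bound: float = 5.0
    epochs: int = 500
    lr: float = 1e-2
    seed: int = 0
    correspondence_dim: int = 20  # PCA dims for expression matching
    template_index: int = 0


@dataclass
class LandmarkSet:
    genes: list[str]
    coords_template: np.ndarray  # (m, 2)
    coords_moving: np.ndarray  # (m, 2)

    def __post_init__(self):
        if len(self.coords_template) != len(self.coords_moving):
            raise ValueError("landmark matrices must pair the same genes")
        if len(self.coords_template) < 3:
            raise ValueError("need >= 3 landmarks for a well-posed 2D mapping")


@dataclass
class Transform3D:
    Z_rigid: np.ndarray
    Z_nonrigid: np.ndarray
    alpha: np.ndarray  # (N, 2) fusion weights, rows sum to 1
    Z_hat: np.ndarray
    z: float
    final_loss: float = np.nan
    converged: bool = True


# --------------------------------------------------------------------------
# landmarks + rigid stage


def _weighted_centroid(coords: np.ndarray, weights: np.ndarray,
                       literal_formula: bool = False) -> np.ndarray:
    if literal_formula:
        # coordinate-sum normalizer, as an alternative convention
        return (coords * weights[:, None]).sum(0) / coords.sum(0)
    total = weights.sum()
    return (coords * weights[:, None]).sum(0) / total


def compute_landmarks(
    template: Slice,
    moving: Slice,
    svg: MoranResult,
    m: int = 30,
    literal_formula: bool = False,
) -> LandmarkSet:
    """Expression-weighted gene centroids on both slices, top-m spatial genes.

    Genes with zero total expression on either slice are dropped and
    back-filled from the ranking.
    """
    genes, ct, cm = [], [], []
    for g in svg.selected:
        gi_t = template.genes.index(g)
        gi_m = moving.genes.index(g)
        wt = template.expr[:, gi_t]
        wm = moving.expr[:, gi_m]
        if wt.sum() <= 0 or wm.sum() <= 0:
            continue
        genes.append(g)
        ct.append(_weighted_centroid(template.coords, wt, literal_formula))
        cm.append(_weighted_centroid(moving.coords, wm, literal_formula))
        if len(genes) == m:
            break
    if len(genes) < 3:
        raise ValueError("fewer than 3 usable landmark genes")
    return LandmarkSet(genes, np.asarray(ct), np.asarray(cm))


def _procrustes_similarity(src: np.ndarray, dst: np.ndarray):
    """Closed-form similarity transform (scale * rotation + translation)
    minimizing ||s R src + t - dst||^2. Returns (s, R, t) or None when the
    source landmarks are degenerate (collinear/coincident)."""
    mu_s, mu_d = src.mean(0), dst.mean(0)
    xs, xd = src - mu_s, dst - mu_d
    cov = xd.T @ xs / len(src)
    var_s = (xs**2).sum() / len(src)
    if var_s < 1e-12:
        return None
    U, D, Vt = np.linalg.svd(cov)
    if np.linalg.matrix_rank(cov) < 2:
        return None
    S = np.eye(2)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[1, 1] = -1.0
    R = U @ S @ Vt
    s = np.trace(np.diag(D) @ S) / var_s
    t = mu_d - s * R @ mu_s
    return s, R, t


class RigidMap:
    """Procrustes seed composed with a residual MLP refinement."""

    def __init__(self, s: float, R: np.ndarray, t: np.ndarray,
                 mlp, center: np.ndarray, scale: float):
        self.s, self.R, self.t = s, R, t
        self.mlp = mlp
        self.center, self.scale = center, scale

    def __call__(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        base = self.s * coords @ self.R.T + self.t
        if self.mlp is None:
            return base
        z = (coords - self.center) / self.scale
        return base + self.mlp.forward_np(z)


def fit_rigid(landmarks: LandmarkSet, config: AlignConfig | None = None) -> RigidMap:
    """Procrustes-seeded MLP mapping moving coordinates onto the template.

    The MLP (tanh, zero-initialized output) learns a residual on top of the
    closed-form similarity transform, minimizing landmark MSE. Degenerate
    (collinear) landmarks fall back to an identity seed with a warning.
    """
    config = config or AlignConfig()
    rng = np.random.default_rng(config.seed)
    res = _procrustes_similarity(landmarks.coords_moving, landmarks.coords_template)
    if res is None:
        warnings.warn("degenerate landmarks; identity rigid seed")
        s, R, t = 1.0, np.eye(2), np.zeros(2)
    else:
        s, R, t = res

    src = landmarks.coords_moving
    center = src.mean(0)
    scale = max(float(np.abs(src - center).max()), 1e-9)
    mlp = _TanhMLP([2, *config.rigid_hidden, 2], rng)
    base = s * src @ R.T + t
    target = Tensor(landmarks.coords_template - base)
    zin = Tensor((src - center) / scale)
    opt = ag.Adam(mlp.params, lr=1e-2)
    # when the Procrustes seed already fits, stop: Adam rescales even
    # vanishing gradients to lr-sized steps and would wander off the optimum
    tol = 1e-10 * max(1.0, float(landmarks.coords_template.var()))
    for _ in range(config.rigid_epochs):
        opt.zero_grad()
        resid = mlp(zin) - target
        loss = (resid * resid).mean()
        if loss.item() < tol:
            break
        loss.backward()
        opt.step()
    return RigidMap(s, R, t, mlp, center, scale)


class _TanhMLP:
    def __init__(self, sizes, rng):
        self.params = []
        self.layers = []
        for i, (fi, fo) in enumerate(zip(sizes[:-1], sizes[1:])):
            last = i == len(sizes) - 2
            scale = 0.0 if last else np.sqrt(1.0 / fi)
            W = Tensor(rng.standard_normal((fi, fo)) * scale, requires_grad=True)
            b = Tensor(np.zeros(fo), requires_grad=True)
            self.params += [W, b]
            self.layers.append((W, b, last))

    def __call__(self, x: Tensor) -> Tensor:
        for W, b, last in self.layers:
            x = x @ W + b
            if not last:
                x = x.tanh()
        return x

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        return self(Tensor(np.asarray(x, dtype=float))).data


# --------------------------------------------------------------------------
# spatial transformer


class STN:
    """Attention stack deforming spot coordinates; identity at init."""

    def __init__(self, n_spots: int, coords: np.ndarray,
                 config: AlignConfig, rng: np.random.Generator):
        ks = config.k_schedule
        if ks is None:
            base = (32, 16, 8)[: config.stn_layers]
            built = []
            prev = n_spots  # cap at N-1 and force strict decrease
            for k in base:
                k = max(1, min(k, n_spots - 1, prev - 1))
                built.append(k)
                prev = k
            ks = tuple(built)
        ks = tuple(int(k) for k in ks)
        if any(b >= a for a, b in zip(ks, ks[1:])):
            raise ValueError("neighbor schedule k_i must be strictly decreasing")
        self.k_schedule = ks
        self.clip_bound = config.clip_bound
        self.params: list[Tensor] = []
        self.layers = []
        # neighbor masks from the (fixed) input geometry, log-domain additive
        coords = np.asarray(coords, dtype=float)
        for k in ks:
            graph = knn_graph(coords, min(k, n_spots - 1))
            mask = np.full((n_spots, n_spots), -1e9)
            rows = np.repeat(np.arange(n_spots), graph.K)
            mask[rows, graph.nei.ravel()] = 0.0
            mask[np.arange(n_spots), np.arange(n_spots)] = 0.0
            Wq = Tensor(rng.standard_normal((2, 2)) * 0.5, requires_grad=True)
            Wk = Tensor(rng.standard_normal((2, 2)) * 0.5, requires_grad=True)
            Wv = Tensor(np.zeros((2, 2)), requires_grad=True)  # zero: identity init
            g = Tensor(np.ones(2), requires_grad=True)
            c = Tensor(np.zeros(2), requires_grad=True)
            W1 = Tensor(
                rng.standard_normal((2, config.ffn_hidden)) * np.sqrt(0.5),
                requires_grad=True,
            )
            b1 = Tensor(np.zeros(config.ffn_hidden), requires_grad=True)
            W2 = Tensor(np.zeros((config.ffn_hidden, 2)), requires_grad=True)
            b2 = Tensor(np.zeros(2), requires_grad=True)
            self.params += [Wq, Wk, Wv, g, c, W1, b1, W2, b2]
            self.layers.append(
                {"mask": mask, "Wq": Wq, "Wk": Wk, "Wv": Wv, "ln": (g, c),
                 "ffn": (W1, b1, W2, b2)}
            )

    def __call__(self, coords: Tensor) -> Tensor:
        y = coords
        for lyr in self.layers:
            Q = y @ lyr["Wq"]
            K = y @ lyr["Wk"]
            V = y @ lyr["Wv"]
            scores = (Q @ K.T) * 0.5
            scores = scores.clip(-self.clip_bound, self.clip_bound) + Tensor(lyr["mask"])
            E = ag.softmax(scores, axis=-1)
            y = y + E @ V
            normed = ag.layer_norm(y, *lyr["ln"])
            W1, b1, W2, b2 = lyr["ffn"]
            y = y + (normed @ W1 + b1).tanh() @ W2 + b2
        return y

    def forward_np(self, coords: np.ndarray) -> np.ndarray:
        return self(Tensor(np.asarray(coords, dtype=float))).data


def stn_forward(coords: np.ndarray, stn: STN) -> np.ndarray:
    """Apply the spatial transformer to coordinates (numpy in/out)."""
    return stn.forward_np(coords)


# --------------------------------------------------------------------------
# fusion


class FusionGate:
    def __init__(self, rng: np.random.Generator):
        self.W = Tensor(rng.standard_normal((2, 2)) * 0.5, requires_grad=True)
        self.b = Tensor(np.zeros(2), requires_grad=True)
        self.W_att = Tensor(np.zeros((2, 1)), requires_grad=True)
        self.params = [self.W, self.b, self.W_att]

    def __call__(self, zr: Tensor, zn: Tensor) -> tuple[Tensor, Tensor]:
        logit_r = (zr @ self.W + self.b).tanh() @ self.W_att  # (N, 1)
        logit_n = (zn @ self.W + self.b).tanh() @ self.W_att
        alpha = ag.softmax(ag.concat([logit_r, logit_n], axis=1), axis=1)
        a1 = alpha[:, 0:1]
        a2 = alpha[:, 1:2]
        return alpha, a1 * zr + a2 * zn


def fuse(Z_rigid, Z_nonrigid, W_att, W, b) -> tuple[np.ndarray, np.ndarray]:
    """Attention fusion: per-spot softmax weights over the two candidates.

    alpha = softmax over {W_att^T tanh(W z + b)} for z in (rigid, nonrigid);
    Z_hat = alpha_1 * Z_rigid + alpha_2 * Z_nonrigid. W_att = 0 gives equal
    weights and the midpoint.
    """
    gate = FusionGate(np.random.default_rng(0))
    gate.W.data = np.asarray(W, dtype=float)
    gate.b.data = np.asarray(b, dtype=float).ravel()
    gate.W_att.data = np.asarray(W_att, dtype=float).reshape(2, 1)
    alpha, zhat = gate(Tensor(np.asarray(Z_rigid, float)), Tensor(np.asarray(Z_nonrigid, float)))
    return alpha.data, zhat.data


# --------------------------------------------------------------------------
# pairwise + stack alignment


def _correspondence_targets(
    template: Slice,
    moving: Slice,
    config: AlignConfig,
    latent_template: np.ndarray | None,
    latent_moving: np.ndarray | None,
) -> np.ndarray:
    """Template coordinate matched to each moving spot, by nearest neighbor
    in latent space (trained model latents if given, else joint PCA)."""
    if latent_template is None or latent_moving is None:
        joint = np.concatenate([template.expr, moving.expr], axis=0)
        k = min(config.correspondence_dim, joint.shape[1], joint.shape[0] - 1)
        pca = PCA(n_components=k, random_state=config.seed)
        Z = pca.fit_transform(joint - joint.mean(0))
        latent_template = Z[: template.n_spots]
        latent_moving = Z[template.n_spots:]
    from scipy.spatial import cKDTree

    _, idx = cKDTree(latent_template).query(latent_moving)
    return template.coords[idx]


def align_pair(
    template: Slice,
    moving: Slice,
    svg: MoranResult,
    config: AlignConfig | None = None,
    latent_template: np.ndarray | None = None,
    latent_moving: np.ndarray | None = None,
) -> Transform3D:
    """Register `moving` onto `template`: rigid fit (frozen), then joint
    STN + fusion optimization of the Frobenius alignment loss against
    latent-matched template coordinates."""
    config = config or AlignConfig()
    rng = np.random.default_rng(config.seed)
    landmarks = compute_landmarks(template, moving, svg, config.m_landmarks)
    rigid = fit_rigid(landmarks, config)
    Z_rigid = rigid(moving.coords)

    target = _correspondence_targets(
        template, moving, config, latent_template, latent_moving
    )
    # normalize the optimization frame for conditioning
    scale = max(float(np.abs(template.coords - template.coords.mean(0)).max()), 1e-9)

    stn = STN(moving.n_spots, moving.coords, config, rng)
    gate = FusionGate(rng)
    params = stn.params + gate.params
    opt = ag.Adam(params, lr=config.lr)
    zr = Tensor(Z_rigid)
    zin = Tensor(moving.coords)
    tgt = Tensor(target)
    best = np.inf
    for _ in range(config.epochs):
        opt.zero_grad()
        zn = stn(zin)
        _, zhat = gate(zr, zn)
        resid = (zhat - tgt) * (1.0 / scale)
        loss = (resid * resid).sum()
        loss.backward()
        opt.step()
        best = min(best, loss.item())
    zn = stn(zin)
    alpha, zhat = gate(zr, zn)
    final = float((((zhat.data - target) / scale) ** 2).sum())
    return Transform3D(
        Z_rigid=Z_rigid,
        Z_nonrigid=zn.data,
        alpha=alpha.data,
        Z_hat=zhat.data,
        z=moving.z,
        final_loss=final,
        converged=np.isfinite(final),
    )


def align_stack(
    stack: SliceStack,
    svg: MoranResult,
    config: AlignConfig | None = None,
    latents: list[np.ndarray] | None = None,
) -> list[Transform3D]:
    """Sequentially chain pairwise alignments: slice i is registered onto
    the already-aligned slice i-1; the template keeps its own coordinates.
    Returns one Transform3D per slice (identity for the template)."""
    config = config or AlignConfig()
    if stack.n_slices < 2:
        raise ValueError(">=2 slices required for alignment")
    if config.template_index != 0:
        raise NotImplementedError("chained alignment starts from slice 0")
    transforms: list[Transform3D] = []
    t0 = stack.slices[0]
    n0 = t0.n_spots
    transforms.append(
        Transform3D(
            Z_rigid=t0.coords.copy(),
            Z_nonrigid=t0.coords.copy(),
            alpha=np.full((n0, 2), 0.5),
            Z_hat=t0.coords.copy(),
            z=t0.z,
            final_loss=0.0,
        )
    )
    prev_aligned = t0
    for i in range(1, stack.n_slices):
        moving = stack.slices[i]
        lt = latents[i - 1] if latents is not None else None
        lm = latents[i] if latents is not None else None
        tr = align_pair(prev_aligned, moving, svg, config, lt, lm)
        transforms.append(tr)
        prev_aligned = Slice(
            expr=moving.expr,
            coords=tr.Z_hat,
            genes=moving.genes,
            img_emb=moving.img_emb,
            labels=moving.labels,
            batch_id=moving.batch_id,
            z=moving.z,
            raw=moving.raw,
            name=moving.name,
        )
    return transforms


def aligned_coords_3d(stack: SliceStack, transforms: list[Transform3D]) -> np.ndarray:
    """Concatenate fused 2D coordinates with each slice's z position."""
    parts = []
    for s, tr in zip(stack.slices, transforms):
        parts.append(np.column_stack([tr.Z_hat, np.full(s.n_spots, s.z)]))
    return np.concatenate(parts, axis=0)
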