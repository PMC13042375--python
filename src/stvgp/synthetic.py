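"""Synthetic multi-slice stacks with known ground truth.

The generator emulates the structure the model targets: serial Visium-like
sections sharing layered (or blob) spatial domains, domain marker genes on
a smooth spatially correlated background, per-slice additive batch shifts
in log space, per-slice rigid rotations/translations plus smooth sinusoidal
warps of the coordinates, and low-dimensional image embeddings whose signal
fraction is correlated with domain identity.

Expression is produced directly in log space (the layer the model
consumes); a negative-binomial count mode is available for exercising the
normalization path. Every quantity needed to score downstream stages
(domain labels, true transforms, noise-free expression) is returned as
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_preprocess import Slice, SliceStack

__all__ = ["SynthConfig", "make_stack", "hex_grid"]


@dataclass
class SynthConfig:
    n_slices: int = 3
    spots_per_slice: int = 300
    n_genes: int = 200
    n_domains: int = 4
    domain_geometry: str = "layers"  # or "blobs"
    markers_per_domain: int = 15
    marker_strength: float = 1.2  # log-fold bump of a marker inside its domain
    batch_shift_sd: float = 0.3  # sd of per-slice per-gene additive log shift
    rotation_deg: tuple | float | None = None  # default: 30 deg increments
    translation: tuple | None = None  # per-slice (dx, dy)
    warp_amplitude: float = 0.0  # sinusoidal warp, coordinate units
    warp_frequency: float = 1.0  # cycles across the slice extent
    boundary_drift: float = 0.3  # per-slice domain-boundary wobble
    smooth_sd: float = 0.1  # amplitude of the smooth spatial background
    noise: dict = field(default_factory=lambda: {"gaussian_sd": 0.3})
    z_spacing: float = 1.0
    img_dim: int = 64
    img_signal_frac: float = 0.8
    counts: bool = False  # emit NB counts instead of log-space expression
    seed: int = 0

    def __post_init__(self):
        if min(self.n_slices, self.spots_per_slice, self.n_genes, self.n_domains) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.img_signal_frac <= 1.0:
            raise ValueError("img_signal_frac must lie in [0, 1]")


def hex_grid(n_spots: int, spacing: float = 1.0) -> np.ndarray:
    """Approximately n_spots points on a hexagonal lattice (Visium-like)."""
    n_cols = int(np.ceil(np.sqrt(n_spots)))
    n_rows = int(np.ceil(n_spots / n_cols))
    pts = []
    for r in range(n_rows):
        for c in range(n_cols):
            x = (c + 0.5 * (r % 2)) * spacing
            y = r * spacing * np.sqrt(3) / 2
            pts.append((x, y))
    return np.asarray(pts[:n_spots], dtype=float)


def _smooth_field(coords: np.ndarray, rng: np.random.Generator, n_centers: int = 8,
                  n_out: int = 4) -> np.ndarray:
    """Smooth low-rank spatial functions: Gaussian bumps at random centers."""
    lo, hi = coords.min(0), coords.max(0)
    centers = rng.uniform(lo, hi, size=(n_centers, 2))
    width = 0.35 * float(np.max(hi - lo))
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    basis = np.exp(-0.5 * d2 / width**2)
    W = rng.standard_normal((n_centers, n_out))
    F = basis @ W
    F = (F - F.mean(0)) / (F.std(0) + 1e-12)
    return F


def _assign_domains(coords: np.ndarray, cfg: SynthConfig,
                    rng: np.random.Generator, drift_phase: float) -> np.ndarray:
    lo, hi = coords.min(0), coords.max(0)
    if cfg.domain_geometry == "layers":
        width = hi[0] - lo[0]
        wobble = cfg.boundary_drift * np.sin(
            2 * np.pi * (coords[:, 0] - lo[0]) / max(width, 1e-9) + drift_phase
        )
        frac = (coords[:, 1] + wobble - lo[1]) / max(hi[1] - lo[1], 1e-9)
        labels = np.clip((frac * cfg.n_domains).astype(int), 0, cfg.n_domains - 1)
    elif cfg.domain_geometry == "blobs":
        centers = rng.uniform(lo, hi, size=(cfg.n_domains, 2))
        d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        labels = d2.argmin(1)
    else:
        raise ValueError(f"unknown domain_geometry '{cfg.domain_geometry}'")
    return labels


def _rigid(coords: np.ndarray, deg: float, trans: np.ndarray) -> np.ndarray:
    th = np.deg2rad(deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    center = coords.mean(0)
    return (coords - center) @ R.T + center + trans


def _warp(coords: np.ndarray, amplitude: float, frequency: float) -> np.ndarray:
    if amplitude == 0.0:
        return coords.copy()
    lo, hi = coords.min(0), coords.max(0)
    span = np.maximum(hi - lo, 1e-9)
    out = coords.copy()
    out[:, 0] += amplitude * np.sin(2 * np.pi * frequency * (coords[:, 1] - lo[1]) / span[1])
    out[:, 1] += amplitude * np.sin(2 * np.pi * frequency * (coords[:, 0] - lo[0]) / span[0])
    return out


def make_stack(cfg: SynthConfig) -> tuple[SliceStack, dict]:
    """Generate a stack plus its ground truth.

    Returns
    -------
    stack : SliceStack
        Observed slices (transformed coordinates, noisy batched expression).
    truth : dict
        'labels' (per-slice arrays), 'template_coords' (untransformed),
        'rotation_deg', 'translation', 'clean_expr' (noise-free, batch-free
        log expression), 'marker_genes' ({domain: [gene names]}),
        'batch_shift' (per-slice per-gene offsets).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"gene{i:04d}" for i in range(cfg.n_genes)]

    rot = cfg.rotation_deg
    if rot is None:
        rot = tuple(30.0 * i for i in range(cfg.n_slices))
    elif np.isscalar(rot):
        rot = tuple(float(rot) * i for i in range(cfg.n_slices))
    trans = cfg.translation
    if trans is None:
        trans = tuple((0.0, 0.0) for _ in range(cfg.n_slices))

    baseline = rng.uniform(0.5, 2.0, size=cfg.n_genes)
    marker_genes: dict[int, list[str]] = {}
    marker_matrix = np.zeros((cfg.n_domains, cfg.n_genes))
    for d in range(cfg.n_domains):
        idx = np.arange(d * cfg.markers_per_domain, (d + 1) * cfg.markers_per_domain)
        idx = idx[idx < cfg.n_genes]
        marker_matrix[d, idx] = cfg.marker_strength
        marker_genes[d] = [genes[i] for i in idx]

    # shared gene loadings for the smooth background so it is spatially
    # structured but domain-independent
    smooth_load = rng.standard_normal((4, cfg.n_genes)) * cfg.smooth_sd

    base_coords = hex_grid(cfg.spots_per_slice)
    base_coords = base_coords + rng.uniform(-0.08, 0.08, size=base_coords.shape)

    slices, labels_all, clean_all, shifts = [], [], [], []
    for i in range(cfg.n_slices):
        coords_t = base_coords  # template frame shared across slices
        labels = _assign_domains(coords_t, cfg, rng, drift_phase=0.5 * i)
        F = _smooth_field(coords_t, np.random.default_rng(cfg.seed + 1))  # shared field
        clean = baseline[None, :] + marker_matrix[labels] + F @ smooth_load
        shift = rng.normal(0.0, cfg.batch_shift_sd, size=cfg.n_genes)
        expr = clean + shift[None, :]
        sd = float(cfg.noise.get("gaussian_sd", 0.0))
        if sd > 0:
            expr = expr + rng.normal(0.0, sd, size=expr.shape)
        if cfg.counts:
            mu = np.exp(expr)
            disp = float(cfg.noise.get("nb_dispersion", 10.0))
            p = disp / (disp + mu)
            expr = rng.negative_binomial(disp, p).astype(float)

        observed = _warp(
            _rigid(coords_t, rot[i], np.asarray(trans[i], dtype=float)),
            cfg.warp_amplitude,
            cfg.warp_frequency,
        )

        img = None
        if cfg.img_dim > 0:
            onehot = np.eye(cfg.n_domains)[labels]
            Wd = np.random.default_rng(cfg.seed + 2).standard_normal(
                (cfg.n_domains, cfg.img_dim)
            )
            Wf = np.random.default_rng(cfg.seed + 3).standard_normal((4, cfg.img_dim))
            signal = onehot @ Wd + 0.5 * (F @ Wf)
            signal = (signal - signal.mean(0)) / (signal.std(0) + 1e-12)
            noise_img = rng.standard_normal((cfg.spots_per_slice, cfg.img_dim))
            img = cfg.img_signal_frac * signal + (1.0 - cfg.img_signal_frac) * noise_img

        slices.append(
            Slice(
                expr=expr,
                coords=observed,
                genes=list(genes),
                img_emb=img,
                labels=np.array([f"D{l}" for l in labels]),
                batch_id=str(i),
                z=i * cfg.z_spacing,
                raw=expr.copy(),
                name=f"synth{i}",
            )
        )
        labels_all.append(labels)
        clean_all.append(clean)
        shifts.append(shift)

    stack = SliceStack(slices, list(genes), {"normalized": True, "seed": cfg.seed})
    truth = {
        "labels": labels_all,
        "template_coords": base_coords,
        "rotation_deg": rot,
        "translation": trans,
        "clean_expr": clean_all,
        "marker_genes": marker_genes,
        "batch_shift": shifts,
    }
    return stack, truth
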