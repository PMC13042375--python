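"""Spatially variable gene selection by subspace Moran's I variance.

Each slice is partitioned into an equal-width grid of spatial subspaces.
Within every sufficiently populated subspace, Moran's I is computed per
gene against a k-nearest-neighbor spatial weight matrix; genes are then
ranked by the variance of their Moran's I values across all subspaces and
slices. Genes whose autocorrelation swings strongly between regions are
the spatially informative ones.

An optional prefilter keeps, per subspace, only genes differentially
expressed between the subspace and the rest of the slice (two-sided
Wilcoxon rank-sum with Benjamini-Hochberg control at FDR 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .gp_core import knn_graph
from .io_preprocess import Slice, SliceStack

__all__ = ["SubspaceGrid", "MoranResult", "build_grid", "morans_i", "select_svgs"]


@dataclass
class SubspaceGrid:
    n_intervals_x: int
    n_intervals_y: int
    assignments: np.ndarray  # per-spot flat subspace index
    counts: np.ndarray  # spots per subspace (m_j)


@dataclass
class MoranResult:
    I: np.ndarray  # gene x subspace-instance matrix (NaN where undefined)
    variance: np.ndarray  # per-gene variance of defined I values
    selected: list[str]  # top-k gene names, descending variance
    genes: list[str]

    def rank_of(self, gene: str) -> int:
        return self.selected.index(gene)


def build_grid(slc: Slice, n_intervals: int) -> SubspaceGrid:
    """Equal-width bins on x and y over the slice bounding box.

    Cells are half-open with the last cell closed, so boundary spots fall in
    the lower-index bin.
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    coords = slc.coords
    lo, hi = coords.min(0), coords.max(0)
    span = np.maximum(hi - lo, 1e-12)
    ix = np.minimum((coords[:, 0] - lo[0]) / span[0] * n_intervals, n_intervals - 1e-9)
    iy = np.minimum((coords[:, 1] - lo[1]) / span[1] * n_intervals, n_intervals - 1e-9)
    flat = ix.astype(int) * n_intervals + iy.astype(int)
    counts = np.bincount(flat, minlength=n_intervals**2)
    return SubspaceGrid(n_intervals, n_intervals, flat, counts)


def morans_i(x: np.ndarray, W: np.ndarray) -> float:
    """Moran's I: (m / sum W) * sum_ab w_ab (x_a - xbar)(x_b - xbar) / sum (x_a - xbar)^2.

    NaN when the signal is constant (zero variance) or the weights sum to 0.
    """
    x = np.asarray(x, dtype=float)
    W = np.asarray(W, dtype=float)
    m = len(x)
    if m < 2:
        raise ValueError("Moran's I needs at least 2 spots")
    s0 = W.sum()
    if s0 == 0:
        warnings.warn("zero total spatial weight; Moran's I undefined")
        return np.nan
    xc = x - x.mean()
    denom = (xc**2).sum()
    if denom == 0:
        return np.nan
    return float(m / s0 * (xc @ (W @ xc)) / denom)


def _subspace_weights(coords: np.ndarray, k: int) -> np.ndarray:
    """Binary kNN weights symmetrized by max (w_ab = 1 if a->b or b->a)."""
    m = len(coords)
    graph = knn_graph(coords, min(k, m - 1))
    W = np.zeros((m, m))
    for a in range(m):
        W[a, graph.nei[a]] = 1.0
    return np.maximum(W, W.T)


def _morans_all_genes(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Vectorized Moran's I across gene columns; NaN for constant genes."""
    m = X.shape[0]
    s0 = W.sum()
    Xc = X - X.mean(0, keepdims=True)
    num = np.einsum("ig,ig->g", Xc, W @ Xc)
    den = np.einsum("ig,ig->g", Xc, Xc)
    with np.errstate(divide="ignore", invalid="ignore"):
        I = m / s0 * num / den
    I[den == 0] = np.nan
    return I


def _de_prefilter(X_sub: np.ndarray, X_rest: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """BH-controlled two-sided Wilcoxon rank-sum mask of DE genes."""
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = mannwhitneyu(X_sub, X_rest, alternative="two-sided", axis=0)
    p = np.where(np.isfinite(p), p, 1.0)
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def select_svgs(
    stack: SliceStack,
    n_intervals: int = 4,
    top_k: int = 50,
    prefilter: bool = True,
    min_spots: int = 10,
    knn_k: int = 6,
    min_defined: int = 3,
) -> MoranResult:
    """Rank genes by variance of per-subspace Moran's I across the stack.

    Subspaces with fewer than `min_spots` spots are skipped; genes with
    fewer than `min_defined` defined I values are excluded from the ranking.
    Ties are broken by gene order.
    """
    genes = stack.genes
    G = len(genes)
    if top_k > G:
        warnings.warn(f"top_k={top_k} > {G} genes; clamping")
        top_k = G
    cols = []
    for slc in stack.slices:
        grid = build_grid(slc, n_intervals)
        for j in np.flatnonzero(grid.counts >= min_spots):
            mask = grid.assignments == j
            X_sub = slc.expr[mask]
            W = _subspace_weights(slc.coords[mask], knn_k)
            I = _morans_all_genes(X_sub, W)
            if prefilter:
                keep = _de_prefilter(X_sub, slc.expr[~mask])
                I = np.where(keep, I, np.nan)
            cols.append(I)
    if not cols:
        raise ValueError("no subspace met the min_spots threshold")
    I_mat = np.stack(cols, axis=1)  # gene x subspace-instance

    n_def = np.sum(~np.isnan(I_mat), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        var = np.nanvar(I_mat, axis=1)
    var = np.where(n_def >= min_defined, var, np.nan)

    order = sorted(
        range(G),
        key=lambda g: (-(var[g]) if np.isfinite(var[g]) else np.inf, g),
    )
    ranked = [g for g in order if np.isfinite(var[g])]
    selected = [genes[g] for g in ranked[:top_k]]
    return MoranResult(I=I_mat, variance=var, selected=selected, genes=list(genes))
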