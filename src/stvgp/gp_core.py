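"""Spatial kernels, neighbor graphs and Gaussian-process conditionals.

These primitives are shared by the spatial prior of the variational
autoencoder, the image-modality prior, and the virtual-slice predictive
posterior. Scalability comes from conditioning each spot only on its K
nearest neighbors (a Vecchia-style factorization) instead of the full
N x N covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["Kernel", "NeighborGraph", "knn_graph", "gp_conditional", "gp_prior_logpdf"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class Kernel:
    """RBF kernel k(z, z') = variance * exp(-||z - z'||^2 / (2 lengthscale^2)).

    Parameters
    ----------
    lengthscale
        Spatial decay scale in coordinate units. A sensible default is the
        median nearest-neighbor distance of the spot layout.
    variance
        Prior marginal variance of each latent dimension.
    jitter_frac
        Diagonal jitter added before factorization, as a fraction of
        `variance`; doubled up to 3 times if a solve fails.
    """

    lengthscale: float = 1.0
    variance: float = 1.0
    jitter_frac: float = 1e-5

    def __post_init__(self):
        if self.lengthscale <= 0 or self.variance <= 0:
            raise ValueError("kernel lengthscale and variance must be positive")

    @property
    def jitter(self) -> float:
        return self.jitter_frac * self.variance

    def __call__(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        a = np.atleast_2d(np.asarray(a, dtype=float))
        b = np.atleast_2d(np.asarray(b, dtype=float))
        d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
        return self.variance * np.exp(-0.5 * d2 / self.lengthscale**2)

    @classmethod
    def from_coords(cls, coords: np.ndarray, variance: float = 1.0) -> "Kernel":
        """Kernel with lengthscale = median nearest-neighbor distance."""
        coords = np.asarray(coords, dtype=float)
        if len(coords) < 2:
            return cls(1.0, variance)
        d, _ = cKDTree(coords).query(coords, k=2)
        ls = float(np.median(d[:, 1]))
        return cls(max(ls, 1e-12), variance)


@dataclass
class NeighborGraph:
    """Exact K-nearest-neighbor lists (no self-neighbors)."""

    K: int
    nei: np.ndarray  # (N, K) int array; K may be 0 -> shape (N, 0)
    scope: str = "2d"

    @property
    def n_spots(self) -> int:
        return self.nei.shape[0]


def knn_graph(coords: np.ndarray, K: int, scope: str | None = None) -> NeighborGraph:
    """Exact Euclidean K-NN; ties broken by lower spot index.

    K >= N is clamped to N - 1 with a warning; K = 0 yields empty lists
    (the model then degenerates to a plain VAE).
    """
    coords = np.asarray(coords, dtype=float)
    n, d = coords.shape
    if scope is None:
        scope = f"{d}d"
    if K < 0:
        raise ValueError("K must be >= 0")
    if K >= n:
        warnings.warn(f"K={K} >= N={n}; clamping to N-1")
        K = n - 1
    if K == 0:
        return NeighborGraph(0, np.zeros((n, 0), dtype=np.intp), scope)
    # stable lexicographic tie-break: sort on (distance, index)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1) if n <= 2048 else None
    if d2 is not None:
        np.fill_diagonal(d2, np.inf)
        order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), d2), axis=1)
        nei = order[:, :K]
    else:
        dist, idx = cKDTree(coords).query(coords, k=K + 1)
        nei = np.empty((n, K), dtype=np.intp)
        for i in range(n):
            cand = [j for j in idx[i] if j != i][:K]
            nei[i] = cand
    return NeighborGraph(K, np.asarray(nei, dtype=np.intp), scope)


def _solve_with_jitter(K_nn: np.ndarray, rhs: np.ndarray, kernel: Kernel) -> np.ndarray:
    jitter = kernel.jitter
    A = K_nn + jitter * np.eye(len(K_nn))
    for _ in range(4):
        try:
            np.linalg.cholesky(A)  # PD probe; raises LinAlgError when not
            return np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            jitter *= 2.0
            A = K_nn + jitter * np.eye(len(K_nn))
    cond = np.linalg.cond(K_nn)
    raise np.linalg.LinAlgError(
        f"GP neighbor covariance singular despite jitter (cond={cond:.3e})"
    )


def gp_conditional(
    query_coords: np.ndarray,
    nei_coords: np.ndarray,
    nei_values: np.ndarray,
    kernel: Kernel,
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean GP predictive conditional, shared across latent dimensions.

    Returns
    -------
    mean : (q, L) array
        K_qn (K_nn + jitter I)^-1 V per latent dimension.
    cov : (q, q) array
        K_qq - K_qn (K_nn + jitter I)^-1 K_nq (identical for every latent
        dimension since the kernel is shared); diagonal clamped at 0.
    """
    query_coords = np.atleast_2d(query_coords)
    nei_coords = np.atleast_2d(nei_coords)
    nei_values = np.asarray(nei_values, dtype=float)
    if nei_values.ndim == 1:
        nei_values = nei_values[:, None]
    K_qn = kernel(query_coords, nei_coords)
    K_nn = kernel(nei_coords, nei_coords)
    K_qq = kernel(query_coords, query_coords)
    sol = _solve_with_jitter(K_nn, np.concatenate([nei_values, K_qn.T], axis=1), kernel)
    L = nei_values.shape[1]
    mean = K_qn @ sol[:, :L]
    cov = K_qq - K_qn @ sol[:, L:]
    cov = 0.5 * (cov + cov.T)
    diag = np.diag(cov).copy()
    np.fill_diagonal(cov, np.maximum(diag, 0.0))
    return mean, cov


def gp_prior_logpdf(
    values: np.ndarray,
    coords: np.ndarray,
    kernel: Kernel,
    graph: NeighborGraph,
) -> float:
    """Log density of the neighbor-factorized GP prior.

    The joint p(H) = p(h_1) prod_j p(h_j | h_nei(j) restricted to earlier
    spots), each factor a GP predictive conditional, evaluated in data order.
    The jitter acts as a nugget: the prior covariance is K(X, X) + jitter*I,
    so with full neighborhoods the factorized density equals the dense
    multivariate-normal log density under that covariance exactly (chain
    rule); with K = 0 it is a product of independent N(0, variance + jitter)
    marginals.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    coords = np.asarray(coords, dtype=float)
    n, L = values.shape
    total = 0.0
    for j in range(n):
        pred = graph.nei[j][graph.nei[j] < j]
        if j == 0 or len(pred) == 0:
            var = kernel(coords[j], coords[j])[0, 0] + kernel.jitter
            resid = values[j]
        else:
            mean, cov = gp_conditional(coords[j], coords[pred], values[pred], kernel)
            var = cov[0, 0] + kernel.jitter
            resid = values[j] - mean[0]
        total += -0.5 * L * (_LOG2PI + np.log(var)) - 0.5 * (resid**2).sum() / var
    return float(total)
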