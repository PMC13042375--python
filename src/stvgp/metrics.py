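"""Alignment score/distance and expression-recovery reporting.

The alignment score asks, for every spot of a target slice B, whether its
Euclidean nearest neighbor in the template slice A carries the same region
label; the label-match fraction over B is the score (0..1). The alignment
distance is the per-B-spot distance to the nearest A spot *sharing* its
label. Both are computed on 2D coordinates by default (adjacent-pair
evaluation); pass `use_3d=True` for full 3D distances. Note the score is
asymmetric in (A, B) by construction.

ARI/NMI and per-gene Pearson/RMSE wrappers round out the evaluation kit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

__all__ = [
    "AlignmentReport",
    "alignment_score",
    "alignment_distance",
    "expression_report",
    "ari",
    "nmi",
]


@dataclass
class AlignmentReport:
    score: float
    distances: np.ndarray
    mean_distance: float
    median_distance: float


def _coords_labels(slc, use_3d: bool):
    coords = np.asarray(slc.coords, dtype=float)
    if use_3d:
        coords = np.column_stack([coords, np.full(len(coords), slc.z)])
    if slc.labels is None:
        raise ValueError(f"slice '{slc.name}' carries no region labels")
    return coords, np.asarray(slc.labels)


def alignment_score(template, target, use_3d: bool = False) -> float:
    """Label-match fraction of each target spot's nearest template spot.

    Nearest-neighbor ties are broken by lowest template spot index.
    """
    A, la = _coords_labels(template, use_3d)
    B, lb = _coords_labels(target, use_3d)
    d2 = ((B[:, None, :] - A[None, :, :]) ** 2).sum(-1)
    nn = d2.argmin(axis=1)  # argmin returns the first (lowest) index on ties
    return float(np.mean(la[nn] == lb))


def alignment_distance(template, target, use_3d: bool = False) -> np.ndarray:
    """Per-target-spot distance to the nearest same-label template spot.

    Labels absent from the template yield NaN with a warning.
    """
    A, la = _coords_labels(template, use_3d)
    B, lb = _coords_labels(target, use_3d)
    out = np.full(len(B), np.nan)
    for lab in np.unique(lb):
        sel_b = lb == lab
        sel_a = la == lab
        if not sel_a.any():
            warnings.warn(f"label '{lab}' absent from template; NaN distances")
            continue
        d, _ = cKDTree(A[sel_a]).query(B[sel_b])
        out[sel_b] = d
    return out


def alignment_report(template, target, use_3d: bool = False) -> AlignmentReport:
    dist = alignment_distance(template, target, use_3d)
    return AlignmentReport(
        score=alignment_score(template, target, use_3d),
        distances=dist,
        mean_distance=float(np.nanmean(dist)),
        median_distance=float(np.nanmedian(dist)),
    )


def expression_report(
    pred: np.ndarray, truth: np.ndarray, genes: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene Pearson r (NaN when either vector is constant) and RMSE."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must share a spots x genes shape")
    pc = pred - pred.mean(0)
    tc = truth - truth.mean(0)
    sp = np.sqrt((pc**2).sum(0))
    st = np.sqrt((tc**2).sum(0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (pc * tc).sum(0) / (sp * st)
    r[(sp == 0) | (st == 0)] = np.nan
    rmse = np.sqrt(((pred - truth) ** 2).mean(0))
    idx = genes if genes is not None else [f"g{i}" for i in range(pred.shape[1])]
    return pd.DataFrame({"pearson_r": r, "rmse": rmse}, index=idx)


def ari(labels_true, labels_pred) -> float:
    return float(adjusted_rand_score(labels_true, labels_pred))


def nmi(labels_true, labels_pred) -> float:
    return float(normalized_mutual_info_score(labels_true, labels_pred))
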