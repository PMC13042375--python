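"""Slice containers, readers/writers and normalization.

A `Slice` is one 2D spatial-transcriptomics section: a spot x gene
expression matrix, 2D spot coordinates in the file's native units, and
optionally per-spot histology-image embeddings and region labels. A
`SliceStack` is an ordered set of slices sharing one gene vocabulary, with
a z position per slice (cumulative section spacing along the sampling axis).

Supported on-disk forms: AnnData h5ad (coordinates in an obsm key, default
"spatial"), MatrixMarket MTX + barcodes/features TSV + coordinate CSV, and
a plain CSV pair (spots x genes matrix, coords CSV with x,y columns).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "Slice",
    "SliceStack",
    "read_stack",
    "write_stack",
    "normalize",
    "embed_image_tiles",
]


@dataclass
class Slice:
    """One 2D section.

    expr is spots x genes (counts or normalized); coords is spots x 2.
    `raw` keeps the original counts when `normalize` replaces expr.
    """

    expr: np.ndarray
    coords: np.ndarray
    genes: list[str]
    img_emb: np.ndarray | None = None
    labels: np.ndarray | None = None
    batch_id: str = "0"
    z: float = 0.0
    raw: np.ndarray | None = None
    name: str = "slice"

    def __post_init__(self):
        self.expr = np.asarray(self.expr, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.validate()

    @property
    def n_spots(self) -> int:
        return self.expr.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expr.shape[1]

    def validate(self) -> None:
        if self.expr.shape[0] != self.coords.shape[0]:
            raise ValueError(
                f"slice '{self.name}': expression has {self.expr.shape[0]} spots "
                f"but coordinates have {self.coords.shape[0]}"
            )
        if self.coords.shape[1] != 2:
            raise ValueError(f"slice '{self.name}': coordinates must be spots x 2")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"slice '{self.name}': non-finite coordinate")
        if len(np.unique(self.coords, axis=0)) != len(self.coords):
            raise ValueError(f"slice '{self.name}': duplicated (x, y) coordinate pair")
        if self.img_emb is not None and len(self.img_emb) != self.n_spots:
            raise ValueError(
                f"slice '{self.name}': image embeddings rows != spot count"
            )
        if self.labels is not None and len(self.labels) != self.n_spots:
            raise ValueError(f"slice '{self.name}': labels length != spot count")
        if len(self.genes) != self.n_genes:
            raise ValueError(f"slice '{self.name}': gene list length != columns")

    def subset_genes(self, genes: list[str]) -> "Slice":
        idx = [self.genes.index(g) for g in genes]
        return Slice(
            expr=self.expr[:, idx],
            coords=self.coords,
            genes=list(genes),
            img_emb=self.img_emb,
            labels=self.labels,
            batch_id=self.batch_id,
            z=self.z,
            raw=None if self.raw is None else self.raw[:, idx],
            name=self.name,
        )


@dataclass
class SliceStack:
    """Ordered slices over an identical gene list, plus model configuration."""

    slices: list[Slice]
    genes: list[str]
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        for s in self.slices:
            if s.genes != self.genes:
                raise ValueError(f"slice '{s.name}' gene list differs from stack")
        zs = [s.z for s in self.slices]
        if len(zs) > 1 and not np.all(np.diff(zs) > 0):
            raise ValueError("slice z positions must be strictly increasing")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_spots(self) -> int:
        return sum(s.n_spots for s in self.slices)

    def subset_genes(self, genes: list[str]) -> "SliceStack":
        return SliceStack(
            [s.subset_genes(genes) for s in self.slices], list(genes), dict(self.config)
        )

    def drop_slice(self, index: int) -> "SliceStack":
        keep = [s for i, s in enumerate(self.slices) if i != index]
        return SliceStack(keep, list(self.genes), dict(self.config))


# --------------------------------------------------------------------------
# readers


def _read_one(path: Path, coord_key: str) -> Slice:
    path = Path(path)
    if path.suffix == ".h5ad":
        adata = ad.read_h5ad(path)
        if coord_key not in adata.obsm:
            raise ValueError(f"{path.name}: missing coordinates obsm['{coord_key}']")
        X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
        labels = None
        for key in ("label", "layer", "domain", "region"):
            if key in adata.obs:
                labels = adata.obs[key].to_numpy()
                break
        img = adata.obsm.get("img_emb")
        return Slice(
            expr=np.asarray(X, dtype=float),
            coords=np.asarray(adata.obsm[coord_key], dtype=float)[:, :2],
            genes=list(adata.var_names),
            img_emb=None if img is None else np.asarray(img, dtype=float),
            labels=labels,
            name=path.stem,
        )
    if path.suffix == ".mtx":
        X = scipy.io.mmread(path).toarray().astype(float)
        genes = pd.read_csv(path.with_name("features.tsv"), sep="\t", header=None)[0]
        coords = pd.read_csv(path.with_name("coords.csv"))
        return Slice(
            expr=X,
            coords=coords[["x", "y"]].to_numpy(float),
            genes=list(genes.astype(str)),
            name=path.stem,
        )
    if path.suffix == ".csv":
        expr = pd.read_csv(path, index_col=0)
        coord_path = path.with_name(path.stem + "_coords.csv")
        if not coord_path.exists():
            raise ValueError(f"{path.name}: missing coordinates file {coord_path.name}")
        coords = pd.read_csv(coord_path)
        return Slice(
            expr=expr.to_numpy(float),
            coords=coords[["x", "y"]].to_numpy(float),
            genes=list(expr.columns.astype(str)),
            name=path.stem,
        )
    raise ValueError(f"unsupported slice format: {path}")


def read_stack(
    paths: list,
    coord_key: str = "spatial",
    z_spacing: list[float] | None = None,
    z_values: list[float] | None = None,
    config: dict | None = None,
) -> SliceStack:
    """Read slices, harmonize genes by intersection, assign z positions.

    Gene order follows the first slice's ordering restricted to the shared
    set. z positions are cumulative from `z_spacing` (first slice at 0)
    unless explicit `z_values` are given.
    """
    slices = [_read_one(Path(p), coord_key) for p in paths]
    return build_stack(slices, z_spacing=z_spacing, z_values=z_values, config=config)


def build_stack(
    slices: list[Slice],
    z_spacing: list[float] | None = None,
    z_values: list[float] | None = None,
    config: dict | None = None,
) -> SliceStack:
    """Assemble already-loaded slices into a stack (intersection of genes)."""
    if not slices:
        raise ValueError("no slices given")
    shared = set(slices[0].genes)
    for s in slices[1:]:
        shared &= set(s.genes)
    if not shared:
        raise ValueError("empty gene intersection across slices")
    genes = [g for g in slices[0].genes if g in shared]

    zs = _resolve_z(len(slices), z_spacing, z_values)
    out = []
    for i, s in enumerate(slices):
        sl = s.subset_genes(genes)
        sl.z = zs[i]
        sl.batch_id = sl.batch_id if sl.batch_id != "0" else str(i)
        out.append(sl)
    return SliceStack(out, genes, config or {})


def _resolve_z(n: int, z_spacing, z_values) -> np.ndarray:
    if z_values is not None:
        if len(z_values) != n:
            raise ValueError("z_values length must equal number of slices")
        return np.asarray(z_values, dtype=float)
    if z_spacing is not None:
        if len(z_spacing) != n - 1:
            raise ValueError("z_spacing needs one entry per inter-slice gap")
        return np.concatenate([[0.0], np.cumsum(np.asarray(z_spacing, dtype=float))])
    return np.arange(n, dtype=float)


# --------------------------------------------------------------------------
# writers


def write_stack(stack: SliceStack, path) -> None:
    """Write the stack as one h5ad with per-slice obs annotation."""
    to_anndata(stack).write_h5ad(Path(path))


def to_anndata(stack: SliceStack) -> ad.AnnData:
    X = np.concatenate([s.expr for s in stack.slices], axis=0)
    obs = pd.DataFrame(
        {
            "slice": np.concatenate(
                [[s.name] * s.n_spots for s in stack.slices]
            ).astype(str),
            "batch": np.concatenate(
                [[s.batch_id] * s.n_spots for s in stack.slices]
            ).astype(str),
            "z": np.concatenate([[s.z] * s.n_spots for s in stack.slices]),
        }
    )
    obs.index = [f"spot{i}" for i in range(len(obs))]
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=stack.genes))
    adata.obsm["spatial"] = np.concatenate([s.coords for s in stack.slices], axis=0)
    if all(s.labels is not None for s in stack.slices):
        adata.obs["label"] = np.concatenate(
            [np.asarray(s.labels, dtype=object) for s in stack.slices]
        ).astype(str)
    if all(s.img_emb is not None for s in stack.slices):
        adata.obsm["img_emb"] = np.concatenate(
            [s.img_emb for s in stack.slices], axis=0
        )
    if all(s.raw is not None for s in stack.slices):
        adata.layers["raw"] = np.concatenate([s.raw for s in stack.slices], axis=0)
    return adata


def from_anndata(adata: ad.AnnData, config: dict | None = None) -> SliceStack:
    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X, dtype=float)
    genes = list(adata.var_names)
    slices = []
    names = adata.obs["slice"].astype(str)
    for name in pd.unique(names):
        m = (names == name).to_numpy()
        slices.append(
            Slice(
                expr=X[m],
                coords=np.asarray(adata.obsm["spatial"])[m, :2],
                genes=genes,
                img_emb=(
                    np.asarray(adata.obsm["img_emb"])[m]
                    if "img_emb" in adata.obsm
                    else None
                ),
                labels=(
                    adata.obs["label"].to_numpy()[m] if "label" in adata.obs else None
                ),
                batch_id=str(adata.obs["batch"].to_numpy()[m][0]),
                z=float(adata.obs["z"].to_numpy()[m][0]),
                raw=adata.layers["raw"][m] if "raw" in adata.layers else None,
                name=str(name),
            )
        )
    return SliceStack(slices, genes, config or {})


# --------------------------------------------------------------------------
# image-embedding helper


def embed_image_tiles(image: np.ndarray, coords: np.ndarray, extractor,
                      tile_size: int = 32) -> np.ndarray:
    """Tile a registered histology image per spot and embed each tile.

    `image` is an H x W (x C) array in the same coordinate frame as
    `coords` (pixel units); `extractor` is any callable mapping a tile of
    shape (tile_size, tile_size[, C]) to a 1-D feature vector — e.g. a
    pretrained CNN wrapped by the caller. Tiles at the border are padded by
    edge replication. Convenience only; the model consumes whatever
    per-spot embedding matrix it is given.
    """
    image = np.asarray(image)
    coords = np.asarray(coords)
    half = tile_size // 2
    pad = [(half, half), (half, half)] + [(0, 0)] * (image.ndim - 2)
    padded = np.pad(image, pad, mode="edge")
    out = []
    for x, y in coords:
        r, c = int(round(y)) + half, int(round(x)) + half
        tile = padded[r - half: r - half + tile_size, c - half: c - half + tile_size]
        out.append(np.asarray(extractor(tile), dtype=float).ravel())
    return np.stack(out)


# --------------------------------------------------------------------------
# normalization


def normalize(
    stack: SliceStack, target_sum: float = 1e4, log1p: bool = True
) -> SliceStack:
    """Per-spot library-size scaling to `target_sum`, then log1p.

    Original counts are retained in each slice's `raw` attribute. All-zero
    spots are left as zeros with a warning.
    """
    out_slices = []
    for s in stack.slices:
        if np.any(s.expr < 0):
            raise ValueError(f"slice '{s.name}': negative expression values")
        lib = s.expr.sum(axis=1, keepdims=True)
        zero = lib[:, 0] == 0
        if np.any(zero):
            warnings.warn(
                f"slice '{s.name}': {int(zero.sum())} all-zero spot(s) left unchanged"
            )
        scale = np.where(lib > 0, target_sum / np.maximum(lib, 1e-300), 0.0)
        X = s.expr * scale
        if log1p:
            X = np.log1p(X)
        out_slices.append(
            Slice(
                expr=X,
                coords=s.coords,
                genes=s.genes,
                img_emb=s.img_emb,
                labels=s.labels,
                batch_id=s.batch_id,
                z=s.z,
                raw=s.expr.copy(),
                name=s.name,
            )
        )
    return SliceStack(out_slices, list(stack.genes), dict(stack.config))
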