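"""Training-tile extraction and dataset assembly.

Tiles are sampled from annotated regions with a point-counting-stereology
grid: a lattice of 64x64 squares anchored at the image origin is laid over
the slide and a square is kept iff every one of its pixels carries the
requested class label (the tile is completely inside an annotated region).

Per class, tiles are then pruned by computing all pairwise Euclidean
distances between flattened RGB tiles, embedding them with classical
(Torgerson) multidimensional scaling, and discarding points far from the
embedding's robust center.  Finally, leave-one-slide-out folds pair each
slide with a training set of all the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .formats_io import ImageRaster, LabelMask, LABEL_VALUES

__all__ = [
    "Tile",
    "TileDataset",
    "FoldSpec",
    "sample_tiles",
    "pairwise_distances",
    "mds_embed",
    "remove_outliers",
    "prune_tiles_mds",
    "make_loocv_folds",
]

TILE_SIZE = 64


@dataclass
class Tile:
    """A 64x64 RGB patch with provenance and class label."""

    pixels: np.ndarray
    slide_id: str
    origin: tuple[int, int]  # (row, col) of the top-left pixel
    label: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (TILE_SIZE, TILE_SIZE, 3):
            raise ValueError(f"tile must be {TILE_SIZE}x{TILE_SIZE}x3, got {self.pixels.shape}")
        if self.label not in LABEL_VALUES:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class TileDataset:
    """A labelled tile collection with per-slide, per-class bookkeeping."""

    tiles: list[Tile] = field(default_factory=list)

    def counts(self) -> pd.DataFrame:
        """Tile counts indexed by (slide_id, label)."""
        rows = [(t.slide_id, t.label) for t in self.tiles]
        df = pd.DataFrame(rows, columns=["slide_id", "label"])
        return df.groupby(["slide_id", "label"]).size().rename("n_tiles").reset_index()

    def count(self, label: str | None = None, slide_id: str | None = None) -> int:
        return sum(
            1
            for t in self.tiles
            if (label is None or t.label == label)
            and (slide_id is None or t.slide_id == slide_id)
        )

    @property
    def slide_ids(self) -> list[str]:
        return sorted({t.slide_id for t in self.tiles})

    def subset(self, slide_ids) -> "TileDataset":
        wanted = set(slide_ids)
        return TileDataset(tiles=[t for t in self.tiles if t.slide_id in wanted])

    def manifest(self) -> pd.DataFrame:
        """CSV-ready manifest: slide_id, row, col, label."""
        return pd.DataFrame(
            [
                {"slide_id": t.slide_id, "row": t.origin[0], "col": t.origin[1], "label": t.label}
                for t in self.tiles
            ]
        )

    def pixel_array(self) -> np.ndarray:
        """All tiles stacked as an (n, 64, 64, 3) array."""
        return np.stack([t.pixels for t in self.tiles])

    def labels(self) -> list[str]:
        return [t.label for t in self.tiles]


@dataclass(frozen=True)
class FoldSpec:
    """A leave-one-slide-out fold: one held-out slide, the rest train."""

    held_out_slide: str
    train_slides: tuple[str, ...]


def sample_tiles(
    mask: LabelMask,
    image: ImageRaster,
    label: str,
    tile_size: int = TILE_SIZE,
    grid_stride: int = TILE_SIZE,
) -> list[Tile]:
    """Grid-sample tiles of one class from an annotated slide.

    The grid is anchored at (0, 0) with the given stride; a grid square is
    extracted iff all ``tile_size**2`` of its pixels carry ``label``.  With
    ``grid_stride >= tile_size`` the tiles are disjoint.
    """
    if grid_stride < 1:
        raise ValueError("grid_stride must be >= 1")
    h, w = mask.shape
    if mask.shape != image.shape:
        raise ValueError("mask and image shapes differ")
    if tile_size > min(h, w):
        raise ValueError("tile_size larger than image")
    value = LABEL_VALUES[label]
    hit = mask.labels == value
    tiles = []
    for r in range(0, h - tile_size + 1, grid_stride):
        for c in range(0, w - tile_size + 1, grid_stride):
            if hit[r : r + tile_size, c : c + tile_size].all():
                tiles.append(
                    Tile(
                        pixels=image.pixels[r : r + tile_size, c : c + tile_size].copy(),
                        slide_id=image.slide_id,
                        origin=(r, c),
                        label=label,
                    )
                )
    return tiles


def _tile_matrix(tiles) -> np.ndarray:
    if isinstance(tiles, TileDataset):
        tiles = tiles.tiles
    arrs = [np.asarray(t.pixels if isinstance(t, Tile) else t, dtype=float) for t in tiles]
    shapes = {a.shape for a in arrs}
    if len(shapes) > 1:
        raise ValueError(f"tiles have mismatched shapes: {shapes}")
    return np.stack([a.ravel() for a in arrs])


def pairwise_distances(tiles) -> np.ndarray:
    """Symmetric matrix of Euclidean distances between flattened RGB tiles.

    Distances are computed on the raw 8-bit intensities, without any
    normalization.
    """
    x = _tile_matrix(tiles)
    if len(x) < 2:
        raise ValueError("need at least 2 tiles")
    return squareform(pdist(x, metric="euclidean"))


def mds_embed(distances: np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers ``-D**2 / 2`` and takes the top ``dims`` eigenpairs;
    negative eigenvalues (non-Euclidean residue) are clipped to zero, so an
    exactly Euclidean distance matrix is reproduced up to rigid motion.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if dims > n - 1:
        raise ValueError(f"dims={dims} exceeds n-1={n - 1}")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1][:dims]
    lam = np.clip(eigvals[order], 0.0, None)
    x = eigvecs[:, order] * np.sqrt(lam)
    # fix the reflection ambiguity for reproducibility
    for k in range(x.shape[1]):
        col = x[:, k]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            x[:, k] = -col
    return x


def remove_outliers(embedding: np.ndarray, k: float = 3.0, max_fraction: float = 0.1) -> np.ndarray:
    """Indices of embedded points to keep after a robust radius cut.

    A point is an outlier when its distance to the component-wise median
    exceeds ``median + k * MAD`` of those distances (MAD scaled by 1.4826 to
    be consistent with a Gaussian sigma).  Never discards more than
    ``max_fraction`` of the points: if the cut would, only the most distant
    ones up to the cap go.
    """
    x = np.asarray(embedding, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    center = np.median(x, axis=0)
    dist = np.linalg.norm(x - center, axis=1)
    med = np.median(dist)
    mad = 1.4826 * np.median(np.abs(dist - med))
    if mad == 0:  # degenerate cloud (e.g. all points identical): keep all
        return np.arange(n)
    outlier = dist > med + k * mad
    cap = int(np.floor(max_fraction * n))
    if outlier.sum() > cap:
        worst = np.argsort(dist)[::-1][:cap]
        outlier = np.zeros(n, dtype=bool)
        outlier[worst] = True
    return np.flatnonzero(~outlier)


def prune_tiles_mds(
    dataset: TileDataset,
    dims: int = 2,
    k: float = 3.0,
    max_tiles: int = 2000,
    seed: int = 0,
) -> TileDataset:
    """Per-class MDS outlier elimination over a whole dataset.

    For each class, pairwise distances across all slides are embedded with
    classical MDS and outliers removed by :func:`remove_outliers`.  When a
    class exceeds ``max_tiles``, the distance computation runs on a seeded
    uniform subsample and only tiles in that subsample can be discarded
    (distance matrices are quadratic in n).
    """
    rng = np.random.default_rng(seed)
    keep: list[Tile] = []
    for label in sorted({t.label for t in dataset.tiles}):
        tiles = [t for t in dataset.tiles if t.label == label]
        if len(tiles) < 3:
            keep.extend(tiles)
            continue
        idx = np.arange(len(tiles))
        if len(tiles) > max_tiles:
            idx = np.sort(rng.choice(len(tiles), size=max_tiles, replace=False))
        sub = [tiles[i] for i in idx]
        kept_local = remove_outliers(mds_embed(pairwise_distances(sub), dims=dims), k=k)
        dropped = set(idx) - set(idx[kept_local])
        keep.extend(t for i, t in enumerate(tiles) if i not in dropped)
    return TileDataset(tiles=keep)


def make_loocv_folds(slide_ids) -> list[FoldSpec]:
    """One leave-one-slide-out fold per slide."""
    ids = list(slide_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate slide ids")
    if len(ids) < 2:
        raise ValueError("need at least 2 slides")
    return [
        FoldSpec(held_out_slide=s, train_slides=tuple(t for t in ids if t != s)) for s in ids
    ]
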