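"""Spatial-omics ingestion: filtering, normalization, gene selection,
and rasterization of spot data into continuous images.

Spot-level count matrices (Visium-style: a spot x gene integer matrix
plus 2-D spot coordinates) are filtered (spots with fewer than 200
detected genes, genes present in fewer than 3 spots — iterated to a
fixed point), depth-normalized to the median spot total and log1p
transformed.  For training on expression channels, discriminative
genes are selected per sample by Leiden clustering on a PCA
neighborhood graph followed by a per-cluster two-sample t-statistic,
and the per-sample selections are intersected.  Selected channels are
min-max scaled and Delaunay-interpolated onto a raster grid; stacks of
many channels can be reduced to three display channels with PCA over
foreground pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import griddata
from sklearn.decomposition import PCA

from .augment import background_mask

__all__ = [
    "SpotTable",
    "filter_spots_genes",
    "normalize_log",
    "select_genes",
    "rasterize_spots",
    "raster_transform",
    "pca_rgb",
    "read_spot_csv",
    "read_spot_mtx",
    "read_coordinates_csv",
]


@dataclass
class SpotTable:
    """Spot coordinates plus a spot x gene non-negative count matrix."""

    spot_ids: np.ndarray
    coordinates: np.ndarray  # (N, 2) xy
    counts: np.ndarray  # (N, G) integer
    gene_ids: np.ndarray

    def __post_init__(self):
        self.spot_ids = np.asarray(self.spot_ids)
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.counts = np.asarray(self.counts)
        self.gene_ids = np.asarray(self.gene_ids)
        n, g = self.counts.shape
        if self.spot_ids.shape[0] != n or self.coordinates.shape != (n, 2):
            raise ValueError("spot_ids/coordinates/counts sizes disagree")
        if self.gene_ids.shape[0] != g:
            raise ValueError("gene_ids does not match counts columns")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(np.unique(self.spot_ids)) != n:
            raise ValueError("duplicate spot ids")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


def filter_spots_genes(
    table: SpotTable, min_genes_per_spot: int = 200, min_spots_per_gene: int = 3
) -> SpotTable:
    """Drop under-detected spots, then under-represented genes.

    "Detected" means count > 0.  Spots are filtered first, then genes;
    because each pass can expose new violations, the two passes iterate
    to a fixed point (the result is idempotent).  Raises if everything
    is filtered away.
    """
    counts = table.counts
    spot_keep = np.ones(table.n_spots, dtype=bool)
    gene_keep = np.ones(table.n_genes, dtype=bool)
    while True:
        sub = counts[np.ix_(spot_keep, gene_keep)]
        genes_per_spot = (sub > 0).sum(axis=1)
        bad_spots = genes_per_spot < min_genes_per_spot
        if bad_spots.any():
            idx = np.flatnonzero(spot_keep)[bad_spots]
            spot_keep[idx] = False
            continue
        spots_per_gene = (sub > 0).sum(axis=0)
        bad_genes = spots_per_gene < min_spots_per_gene
        if bad_genes.any():
            idx = np.flatnonzero(gene_keep)[bad_genes]
            gene_keep[idx] = False
            continue
        break
    if not spot_keep.any() or not gene_keep.any():
        raise ValueError(
            "filtering removed every spot or gene; thresholds "
            f"({min_genes_per_spot} genes/spot, {min_spots_per_gene} spots/gene) "
            "are too strict for this table"
        )
    return SpotTable(
        spot_ids=table.spot_ids[spot_keep],
        coordinates=table.coordinates[spot_keep],
        counts=counts[np.ix_(spot_keep, gene_keep)],
        gene_ids=table.gene_ids[gene_keep],
    )


def normalize_log(table: SpotTable) -> np.ndarray:
    """Median-total depth normalization followed by log(1 + x).

    Each spot's counts are scaled so its total equals the median spot
    total; zeros stay exactly zero.
    """
    counts = table.counts.astype(np.float64)
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("spots with zero total counts cannot be normalized")
    target = float(np.median(totals))
    return np.log1p(counts * (target / totals)[:, None])


def _welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-gene Welch two-sample t statistic of a (n1,G) vs b (n2,G)."""
    n1, n2 = a.shape[0], b.shape[0]
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1 = a.var(axis=0, ddof=1) if n1 > 1 else np.zeros(a.shape[1])
    v2 = b.var(axis=0, ddof=1) if n2 > 1 else np.zeros(b.shape[1])
    denom = np.sqrt(v1 / max(n1, 1) + v2 / max(n2, 1))
    return (m1 - m2) / np.maximum(denom, 1e-12)


def _leiden_labels(expr: np.ndarray, resolution: float, seed: int) -> np.ndarray:
    import anndata as ad_
    import scanpy as sc

    adata = ad_.AnnData(X=expr.astype(np.float32))
    n_comps = int(min(30, expr.shape[0] - 1, expr.shape[1] - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.pca(adata, n_comps=max(n_comps, 1), random_state=seed)
        sc.pp.neighbors(adata, random_state=seed)
        sc.tl.leiden(
            adata,
            resolution=resolution,
            random_state=seed,
            flavor="leidenalg",
        )
    return adata.obs["leiden"].astype(int).to_numpy()


def select_genes(
    samples,
    n_top: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
    cluster_labels=None,
) -> list:
    """Discriminative genes shared by all samples.

    Per sample: Leiden communities on a PCA neighborhood graph of the
    normalized expression (or caller-supplied ``cluster_labels``), then
    for each cluster the Welch t-statistic of every gene (cluster vs
    rest) ranked by magnitude; the per-cluster top-``n_top`` gene sets
    are unioned.  The final list is the intersection across samples,
    sorted lexicographically.  A sample whose clustering yields a
    single community contributes its global top-``n_top`` genes by
    expression variance (cluster-vs-rest is undefined there).
    """
    if not samples:
        raise ValueError("need at least one sample")
    per_sample: list[set] = []
    for si, table in enumerate(samples):
        expr = normalize_log(table)
        if cluster_labels is not None:
            labels = np.asarray(cluster_labels[si])
        else:
            labels = _leiden_labels(expr, resolution, seed)
        chosen: set = set()
        uniq = np.unique(labels)
        if len(uniq) < 2:
            order = np.argsort(expr.var(axis=0))[::-1][:n_top]
            chosen.update(table.gene_ids[order])
        else:
            for lab in uniq:
                mask = labels == lab
                t = _welch_t(expr[mask], expr[~mask])
                order = np.argsort(np.abs(t))[::-1][:n_top]
                chosen.update(table.gene_ids[order])
        per_sample.append(chosen)
    common = set.intersection(*per_sample)
    if not common:
        raise ValueError(
            "no gene was selected in every sample; increase n_top or relax "
            "the clustering resolution"
        )
    return sorted(common)


def raster_transform(coordinates: np.ndarray, grid_size: int, margin: float = 0.02):
    """Affine from spot coordinates to raster pixel coordinates.

    The grid spans the spot bounding box plus a relative margin;
    returns ``(origin, spacing)`` such that pixel = (coord - origin) /
    spacing, with isotropic spacing (the larger axis fits exactly).
    """
    coords = np.asarray(coordinates, dtype=np.float64)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    span = hi - lo
    pad = margin * np.maximum(span, 1e-12)
    lo, hi = lo - pad, hi + pad
    spacing = float(max(hi - lo) / (grid_size - 1))
    center = (lo + hi) / 2.0
    origin = center - spacing * (grid_size - 1) / 2.0
    return origin, spacing


def rasterize_spots(
    table: SpotTable, values, grid_size: int = 128, margin: float = 0.02
) -> np.ndarray:
    """Linear interpolation of per-spot values onto a square raster.

    ``values`` is (N,) or (N, C).  Each channel is min-max scaled to
    [0, 1] BEFORE interpolation (a zero-range channel maps to all
    zeros); pixels outside the spot convex hull are 0.
    """
    vals = np.asarray(values, dtype=np.float64)
    if vals.ndim == 1:
        vals = vals[:, None]
    if vals.shape[0] != table.n_spots:
        raise ValueError("one value row per spot required")
    coords = table.coordinates
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 spots to interpolate")
    span = coords - coords.mean(axis=0)
    if np.linalg.svd(span, compute_uv=False)[-1] < 1e-9:
        raise ValueError("all spots are collinear; cannot interpolate an image")
    lo = vals.min(axis=0)
    rng_ = vals.max(axis=0) - lo
    scaled = np.where(rng_ > 0, (vals - lo) / np.maximum(rng_, 1e-300), 0.0)
    origin, spacing = raster_transform(coords, grid_size, margin)
    px = (coords - origin) / spacing
    xs, ys = np.meshgrid(np.arange(grid_size, dtype=float), np.arange(grid_size, dtype=float))
    out = np.empty((grid_size, grid_size, scaled.shape[1]))
    for c in range(scaled.shape[1]):
        interp = griddata(px, scaled[:, c], (xs, ys), method="linear", fill_value=np.nan)
        out[:, :, c] = np.nan_to_num(interp, nan=0.0)
    return out


def pca_rgb(image, threshold: float = 0.1) -> np.ndarray:
    """Reduce a multi-channel raster to 3 display channels with PCA.

    All foreground pixels (any channel >= threshold) are treated as
    samples; the first three principal components are min-max scaled to
    [0, 1] with the sign fixed so each loading vector sums positive;
    background pixels stay 0.  If the pixel matrix has rank < 3 the
    missing components are zero-padded with a warning.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError("pca_rgb needs an (H, W, C>=3) image")
    fg = ~background_mask(arr, threshold)
    if fg.sum() < 3:
        raise ValueError("need at least 3 foreground pixels")
    pixels = arr[fg]
    n_comp = int(min(3, np.linalg.matrix_rank(pixels - pixels.mean(axis=0))))
    pca = PCA(n_components=n_comp, svd_solver="full")
    comps = pca.fit_transform(pixels)
    # deterministic sign: each loading vector sums positive
    signs = np.where(pca.components_.sum(axis=1) >= 0, 1.0, -1.0)
    comps = comps * signs[None, :]
    out = np.zeros((arr.shape[0], arr.shape[1], 3))
    for c in range(n_comp):
        v = comps[:, c]
        rng_ = v.max() - v.min()
        out[:, :, c][fg] = (v - v.min()) / rng_ if rng_ > 0 else 0.0
    if n_comp < 3:
        warnings.warn(
            f"pixel matrix has rank {n_comp} < 3; missing components zero-padded",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


# --------------------------------------------------------------------------
# readers
# --------------------------------------------------------------------------

def read_coordinates_csv(path) -> pd.DataFrame:
    """Read a spot coordinate table with columns spot_id, x, y."""
    df = pd.read_csv(path)
    missing = {"spot_id", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"coordinate CSV lacks columns {sorted(missing)}")
    return df


def read_spot_csv(counts_path, coordinates_path) -> SpotTable:
    """Read a spots x genes CSV (first column spot ids) plus coordinates."""
    counts = pd.read_csv(counts_path, index_col=0)
    coords = read_coordinates_csv(coordinates_path).set_index("spot_id")
    coords = coords.loc[counts.index]
    return SpotTable(
        spot_ids=counts.index.to_numpy(),
        coordinates=coords[["x", "y"]].to_numpy(float),
        counts=counts.to_numpy(),
        gene_ids=counts.columns.to_numpy(),
    )


def read_spot_mtx(matrix_path, genes_path, barcodes_path, coordinates_path) -> SpotTable:
    """Read MatrixMarket counts (genes x spots) with TSV row/column names."""
    from scipy.io import mmread

    mat = np.asarray(mmread(matrix_path).todense())
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].to_numpy()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].to_numpy()
    if mat.shape != (len(genes), len(barcodes)):
        raise ValueError("MTX shape does not match genes/barcodes files")
    coords = read_coordinates_csv(coordinates_path).set_index("spot_id")
    coords = coords.loc[barcodes]
    return SpotTable(
        spot_ids=barcodes,
        coordinates=coords[["x", "y"]].to_numpy(float),
        counts=mat.T,
        gene_ids=genes,
    )
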