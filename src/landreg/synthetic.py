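"""Synthetic tissue generator with exact ground truth.

Every generator renders from an analytic latent description — a smooth
Fourier-boundary foreground on a dark background with Gaussian internal
structures whose centers serve as ground-truth landmarks — so any point
can be mapped between frames to machine precision.  Inter-section and
inter-modality geometry is a composition of a random affine and a
smooth elastic field defined on coarse knots, applied FORWARD to
points and inverted per pixel (fixed-point iteration) when rendering,
which keeps image and point ground truth exactly consistent.

Emulated features of real serial-section data: tissue-shaped foreground
with black background, elastic + affine deformation between sections,
monotone per-section intensity batch effects (gamma + gain, preserving
zero background), paired modalities rendered from one latent tissue via
different channel mixtures, and hex-grid spot tables with spatially
smooth Poisson count patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .omics import SpotTable

__all__ = [
    "SyntheticSpec",
    "Deformation",
    "make_tissue",
    "make_section_pair",
    "make_stack",
    "make_multimodal_pair",
    "make_spot_table",
]


@dataclass
class SyntheticSpec:
    """Conditions of the synthetic study.

    Geometric units are pixels of the rendered image.  The defaults
    describe a desk-scale serial-section experiment: 64 px sections, six
    internal structures, inter-section deformations of a few pixels and
    visible but monotone batch effects.
    """

    image_size: int = 64
    n_channels: int = 3
    n_structures: int = 6
    boundary_harmonics: int = 3
    boundary_amplitude: float = 0.12
    base_radius_frac: float = 0.36
    blob_sigma_frac: float = 0.08
    edge_width: float = 1.5
    base_level: float = 0.35
    # inter-section deformation
    rotation_deg: float = 10.0
    translation_px: float = 2.0
    scale_jitter: float = 0.05
    elastic_grid_points: int = 4
    elastic_sigma: float = 2.0
    # per-section intensity batch effect
    batch_gamma_range: tuple = (0.7, 1.4)
    batch_gain_range: tuple = (0.85, 1.15)
    # stack / omics sizes
    n_sections: int = 12
    drift_px: float = 4.0
    n_spots: int = 200
    n_genes: int = 30
    count_depth: float = 50.0
    seed: int = 0

    def __post_init__(self):
        for name in ("image_size", "n_channels", "n_structures", "n_sections", "n_spots", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _rng_of(spec: SyntheticSpec, rng) -> np.random.Generator:
    if rng is None:
        return np.random.default_rng(spec.seed)
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


# --------------------------------------------------------------------------
# latent tissue
# --------------------------------------------------------------------------

@dataclass
class _Tissue:
    center: np.ndarray  # (2,)
    radius: float
    fourier_cos: np.ndarray  # (H,)
    fourier_sin: np.ndarray
    structure_centers: np.ndarray  # (S, 2)
    structure_amps: np.ndarray  # (S, C)
    blob_sigma: float
    base_level: float
    n_channels: int
    edge_width: float

    def boundary_radius(self, theta: np.ndarray) -> np.ndarray:
        out = np.ones_like(theta)
        for k, (a, b) in enumerate(zip(self.fourier_cos, self.fourier_sin), start=1):
            out = out + a * np.cos(k * theta) + b * np.sin(k * theta)
        return self.radius * out

    def foreground(self, points: np.ndarray) -> np.ndarray:
        rel = points - self.center
        r = np.hypot(rel[:, 0], rel[:, 1])
        theta = np.arctan2(rel[:, 1], rel[:, 0])
        return 1.0 / (1.0 + np.exp(-(self.boundary_radius(theta) - r) / self.edge_width))

    def features(self, points: np.ndarray) -> np.ndarray:
        """Per-point latent feature vector [foreground, blob_1..blob_S]."""
        mask = self.foreground(points)
        feats = [mask]
        for c in self.structure_centers:
            d2 = ((points - c) ** 2).sum(axis=1)
            feats.append(mask * np.exp(-d2 / (2.0 * self.blob_sigma**2)))
        return np.stack(feats, axis=1)

    def render_at(self, points: np.ndarray) -> np.ndarray:
        feats = self.features(points)
        vals = self.base_level * feats[:, :1] + feats[:, 1:] @ self.structure_amps
        return np.clip(vals, 0.0, 1.0)


def _sample_tissue(spec: SyntheticSpec, rng: np.random.Generator) -> _Tissue:
    size = spec.image_size
    center = (size - 1) / 2.0 + rng.uniform(-0.03, 0.03, size=2) * size
    ks = np.arange(1, spec.boundary_harmonics + 1)
    fc = rng.normal(0.0, spec.boundary_amplitude / ks)
    fs = rng.normal(0.0, spec.boundary_amplitude / ks)
    radius = spec.base_radius_frac * size
    # structure centers: polar sampling well inside the boundary
    theta = rng.uniform(0, 2 * np.pi, size=spec.n_structures)
    rfrac = 0.25 + 0.5 * np.sqrt(rng.uniform(size=spec.n_structures))
    tissue = _Tissue(
        center=center,
        radius=radius,
        fourier_cos=fc,
        fourier_sin=fs,
        structure_centers=np.zeros((spec.n_structures, 2)),
        structure_amps=rng.uniform(0.25, 0.65, size=(spec.n_structures, spec.n_channels)),
        blob_sigma=spec.blob_sigma_frac * size,
        base_level=spec.base_level,
        n_channels=spec.n_channels,
        edge_width=spec.edge_width,
    )
    bnd = tissue.boundary_radius(theta)
    tissue.structure_centers = center + np.stack(
        [rfrac * bnd * np.cos(theta), rfrac * bnd * np.sin(theta)], axis=1
    )
    return tissue


def _pixel_grid(size: int) -> np.ndarray:
    xs, ys = np.meshgrid(np.arange(size, dtype=float), np.arange(size, dtype=float))
    return np.stack([xs.ravel(), ys.ravel()], axis=1)


def _render_image(tissue: _Tissue, size: int, points=None) -> np.ndarray:
    pts = _pixel_grid(size) if points is None else points
    vals = tissue.render_at(pts)
    return vals.reshape(size, size, tissue.n_channels)


# --------------------------------------------------------------------------
# analytic forward deformations
# --------------------------------------------------------------------------

class Deformation:
    """Affine followed by a smooth elastic displacement, forward semantics.

    ``forward(p) = q + e(q)`` with ``q = A p`` and ``e`` a spline
    through coarse knot displacements.  ``inverse`` solves the fixed
    point ``q = y - e(q)`` and returns ``A^{-1} q``.
    """

    def __init__(self, affine: np.ndarray, knots: np.ndarray | None, size: int):
        self.affine = np.asarray(affine, dtype=np.float64)
        self.size = size
        self.knots = knots
        if knots is not None and np.any(knots != 0):
            g = knots.shape[0]
            kpos = np.linspace(0, size - 1, g)
            deg = min(3, g - 1)
            self._splines = [
                RectBivariateSpline(kpos, kpos, knots[:, :, c], kx=deg, ky=deg, s=0)
                for c in range(2)
            ]
        else:
            self._splines = None

    def _elastic(self, q: np.ndarray) -> np.ndarray:
        if self._splines is None:
            return np.zeros_like(q)
        return np.stack(
            [self._splines[c](q[:, 1], q[:, 0], grid=False) for c in range(2)], axis=1
        )

    def forward(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        homo = np.hstack([pts, np.ones((pts.shape[0], 1))])
        q = (homo @ self.affine.T)[:, :2]
        return q + self._elastic(q)

    def inverse(self, points: np.ndarray, n_iter: int = 30) -> np.ndarray:
        y = np.asarray(points, dtype=np.float64)
        q = y.copy()
        for _ in range(n_iter):
            q = y - self._elastic(q)
        homo = np.hstack([q, np.ones((q.shape[0], 1))])
        return (homo @ np.linalg.inv(self.affine).T)[:, :2]

    @staticmethod
    def identity(size: int) -> "Deformation":
        return Deformation(np.eye(3), None, size)


def _sample_deformation(
    spec: SyntheticSpec, rng: np.random.Generator, strength: float = 1.0
) -> Deformation:
    size = spec.image_size
    c = (size - 1) / 2.0
    theta = np.deg2rad(rng.uniform(-spec.rotation_deg, spec.rotation_deg) * strength)
    s = 1.0 + rng.uniform(-spec.scale_jitter, spec.scale_jitter) * strength
    t = rng.uniform(-spec.translation_px, spec.translation_px, size=2) * strength
    rot = s * np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    affine = np.eye(3)
    affine[:2, :2] = rot
    affine[:2, 2] = t + [c, c] - rot @ [c, c]
    g = spec.elastic_grid_points
    knots = rng.normal(0.0, spec.elastic_sigma * strength, size=(g, g, 2))
    return Deformation(affine, knots, size)


def _batch_effect(image: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator):
    """Monotone gamma + gain intensity jitter; zero background stays zero."""
    gamma = rng.uniform(*spec.batch_gamma_range)
    gain = rng.uniform(*spec.batch_gain_range)
    return np.clip(gain * np.power(image, gamma), 0.0, 1.0)


def _render_deformed(tissue: _Tissue, deform: Deformation, size: int) -> np.ndarray:
    grid = _pixel_grid(size)
    latent_pts = deform.inverse(grid)
    return _render_image(tissue, size, points=latent_pts)


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def make_tissue(spec: SyntheticSpec, rng=None):
    """One latent tissue image plus its ground-truth landmarks.

    Returns ``(image (H, W, C) in [0, 1], landmarks (S, 2))`` where the
    landmarks are the internal structure centers.
    """
    rng = _rng_of(spec, rng)
    tissue = _sample_tissue(spec, rng)
    return _render_image(tissue, spec.image_size), tissue.structure_centers.copy()


def make_section_pair(spec: SyntheticSpec, rng=None, deform: bool = True, batch: bool = True):
    """Two views of one tissue with exact point correspondence.

    B is a deformed (affine + elastic) and batch-perturbed rendering of
    the same latent tissue as A.  The returned correspondence maps
    A-frame points to their partner in B (``corr["map"]`` callable,
    ``corr["dense"]`` the (H, W, 2) forward field at every A pixel,
    ``corr["deform"]`` the full Deformation).
    """
    rng = _rng_of(spec, rng)
    tissue = _sample_tissue(spec, rng)
    img_a = _render_image(tissue, spec.image_size)
    d = _sample_deformation(spec, rng) if deform else Deformation.identity(spec.image_size)
    img_b = _render_deformed(tissue, d, spec.image_size)
    if batch:
        img_b = _batch_effect(img_b, spec, rng)
    grid = _pixel_grid(spec.image_size)
    dense = d.forward(grid).reshape(spec.image_size, spec.image_size, 2)
    corr = {"map": d.forward, "dense": dense, "deform": d}
    return img_a, img_b, corr


@dataclass
class StackTruth:
    """A synthetic z-stack with its exact geometric ground truth."""

    sections: list  # N images (H, W, C)
    target_points: np.ndarray  # (N, S, 2) per-section positions of the anchors
    deformations: list  # N Deformation objects, latent -> section i

    def pair_map(self, i: int, j: int, points: np.ndarray) -> np.ndarray:
        """Exact correspondence of section-i points into section j."""
        return self.deformations[j].forward(self.deformations[i].inverse(points))


def make_stack(spec: SyntheticSpec, rng=None) -> StackTruth:
    """Serial-section stack with drifting geometry and batch effects.

    Section i is the latent tissue pushed through a deformation that
    accumulates a smooth drift along the stack plus per-section jitter;
    blob intensities also drift, so consecutive sections resemble each
    other more than distant ones.  Each section carries the ground-truth
    positions of the structure centers (>= 4 target points per
    consecutive pair when ``n_structures >= 4``).
    """
    rng = _rng_of(spec, rng)
    tissue = _sample_tissue(spec, rng)
    n = spec.n_sections
    size = spec.image_size
    g = spec.elastic_grid_points
    # smooth drift: a fixed random direction field traversed along the stack
    drift_knots = rng.normal(0.0, spec.drift_px, size=(g, g, 2))
    drift_angle = np.deg2rad(rng.uniform(-spec.rotation_deg, spec.rotation_deg))
    amp_drift = rng.normal(0.0, 0.1, size=tissue.structure_amps.shape)
    c = (size - 1) / 2.0
    sections, points, deforms = [], [], []
    for i in range(n):
        f = i / max(n - 1, 1)
        jitter = _sample_deformation(spec, rng, strength=0.4)
        theta = drift_angle * f
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        affine = np.eye(3)
        affine[:2, :2] = rot @ jitter.affine[:2, :2]
        affine[:2, 2] = rot @ jitter.affine[:2, 2] + [c, c] - rot @ [c, c]
        knots = f * drift_knots + (jitter.knots if jitter.knots is not None else 0.0)
        d = Deformation(affine, knots, size)
        # intensity drift changes appearance without moving the geometry
        amps = np.clip(tissue.structure_amps * (1.0 + f * amp_drift), 0.05, 1.0)
        ti = replace(tissue, structure_amps=amps)
        img = _render_deformed(ti, d, size)
        img = _batch_effect(img, spec, rng)
        sections.append(img)
        points.append(d.forward(tissue.structure_centers))
        deforms.append(d)
    return StackTruth(
        sections=sections,
        target_points=np.stack(points),
        deformations=deforms,
    )


def make_multimodal_pair(
    spec: SyntheticSpec,
    rng=None,
    mixing_a: np.ndarray | None = None,
    mixing_b: np.ndarray | None = None,
    deform: bool = True,
    noise: float = 0.02,
):
    """One latent tissue rendered as two modalities.

    Latent per-pixel features [foreground, blob_1..blob_S] are mixed
    through modality-specific non-negative matrices (3 x (S+1)) and
    perturbed by small independent deformations and Gaussian noise.
    Returns ``(img_a, img_b, corr)`` with ``corr["map"]`` the exact
    A-frame -> B-frame point correspondence.
    """
    rng = _rng_of(spec, rng)
    tissue = _sample_tissue(spec, rng)
    s = spec.n_structures
    if mixing_a is None:
        mixing_a = rng.uniform(0.1, 0.8, size=(3, s + 1))
    if mixing_b is None:
        mixing_b = rng.uniform(0.1, 0.8, size=(3, s + 1))
    d_a = _sample_deformation(spec, rng, strength=0.3) if deform else Deformation.identity(spec.image_size)
    d_b = _sample_deformation(spec, rng, strength=0.3) if deform else Deformation.identity(spec.image_size)
    grid = _pixel_grid(spec.image_size)

    def render(mix, d, noise_rng):
        feats = tissue.features(d.inverse(grid))
        img = np.clip(feats @ np.asarray(mix).T, 0.0, 1.0)
        if noise > 0:
            img = np.clip(img + noise_rng.normal(0.0, noise, size=img.shape), 0.0, 1.0)
        return img.reshape(spec.image_size, spec.image_size, 3)

    img_a = render(mixing_a, d_a, rng)
    img_b = render(mixing_b, d_b, rng)

    def a_to_b(points):
        return d_b.forward(d_a.inverse(points))

    corr = {"map": a_to_b, "deform_a": d_a, "deform_b": d_b,
            "mixing_a": np.asarray(mixing_a), "mixing_b": np.asarray(mixing_b),
            "features": lambda pts: tissue.features(pts)}
    return img_a, img_b, corr


def make_spot_table(spec: SyntheticSpec, rng=None):
    """Hex-grid spot table with smooth Poisson expression patterns.

    Spots lie on a hexagonal lattice restricted to the tissue
    foreground; per-gene rates are smooth Gaussian spatial fields scaled
    to a mean depth of ``count_depth / n_genes`` per spot and gene.
    Returns ``(SpotTable, rates (N, G))`` with the exact Poisson rates.
    """
    rng = _rng_of(spec, rng)
    tissue = _sample_tissue(spec, rng)
    size = spec.image_size
    # hex lattice pitch targeting ~n_spots inside the foreground
    area = np.pi * tissue.radius**2
    pitch = max(1.0, np.sqrt(area / spec.n_spots / 0.866))
    pts = []
    row = 0
    y = 0.0
    while y < size:
        offset = 0.5 * pitch if row % 2 else 0.0
        x = offset
        while x < size:
            pts.append((x, y))
            x += pitch
        y += pitch * 0.866
        row += 1
    pts = np.asarray(pts)
    inside = tissue.foreground(pts) > 0.5
    coords = pts[inside]
    n = coords.shape[0]
    centers = tissue.center + rng.uniform(-0.6, 0.6, size=(spec.n_genes, 2)) * tissue.radius
    widths = rng.uniform(0.15, 0.4, size=spec.n_genes) * size
    rates = np.empty((n, spec.n_genes))
    for gi in range(spec.n_genes):
        d2 = ((coords - centers[gi]) ** 2).sum(axis=1)
        field = 0.1 + np.exp(-d2 / (2.0 * widths[gi] ** 2))
        rates[:, gi] = field
    rates *= spec.count_depth / spec.n_genes / rates.mean()
    counts = rng.poisson(rates)
    table = SpotTable(
        spot_ids=np.array([f"spot_{i:04d}" for i in range(n)]),
        coordinates=coords,
        counts=counts,
        gene_ids=np.array([f"gene_{g:03d}" for g in range(spec.n_genes)]),
    )
    return table, rates
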