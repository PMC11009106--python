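"""Input standardization and training-time augmentations.

Augmentations are the source of the self-supervision signal: a section
and a deformed copy of itself form a registration pair with a known
answer.  The pipeline is rotation (uniform in +-max_rotation_deg, with
an isotropic shrink keeping the foreground inside the frame) followed
by elastic deformation (a coarse grid of i.i.d. Normal(0, sigma^2)
pixel displacements upsampled to a dense smooth field).  Every
operation returns the exact transform it applied so ground-truth
landmark coordinates can be propagated alongside the image.

"Cropping" of black background is implemented as union-masking to
zero: pixels whose channels all fall strictly below the threshold in
either image of a pair are zeroed in both, preserving shape so the
losses always see equal-sized inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RectBivariateSpline
from scipy.ndimage import map_coordinates
from skimage.transform import resize_local_mean

__all__ = [
    "AugmentConfig",
    "resize_to_training",
    "random_rotation_scale",
    "elastic_deform",
    "background_mask",
    "joint_background_suppress",
    "apply_affine_to_points",
    "apply_field_to_points",
    "random_augment",
]


@dataclass
class AugmentConfig:
    """Augmentation parameters.

    elastic_sigma_range and elastic_grid_range are inclusive (lo, hi)
    ranges sampled per draw; pass equal endpoints for a fixed value
    (sigma 3 suits face-style benchmarks, 5.5 the tissue experiments).
    """

    target_size: int = 128
    max_rotation_deg: float = 15.0
    elastic_grid_range: tuple = (3, 5)
    elastic_sigma_range: tuple = (3.0, 3.0)
    background_threshold: float = 0.1

    def __post_init__(self):
        if not 0.0 < self.background_threshold < 1.0:
            raise ValueError("background_threshold must be in (0, 1)")
        if self.max_rotation_deg < 0:
            raise ValueError("max_rotation_deg must be >= 0")
        if self.elastic_grid_range[0] < 2:
            raise ValueError("elastic grid needs at least 2 points per axis")


def _as_hwc(image) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return arr


def resize_to_training(image, target_size: int = 128) -> np.ndarray:
    """Box-average (area-style) resampling to target_size x target_size.

    Aspect ratio is not preserved: training uses a fixed square shape.
    """
    arr = _as_hwc(image)
    squeeze = np.asarray(image).ndim == 2
    if arr.shape[0] == target_size and arr.shape[1] == target_size:
        out = arr.copy()
    else:
        out = resize_local_mean(arr, (target_size, target_size, arr.shape[2]))
    out = np.clip(out, 0.0, 1.0)
    return out[:, :, 0] if squeeze else out


def background_mask(image, threshold: float = 0.1) -> np.ndarray:
    """True where every channel is strictly below the threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    arr = _as_hwc(image)
    return np.all(arr < threshold, axis=2)


def joint_background_suppress(image_a, image_b, threshold: float = 0.1):
    """Zero the union of both backgrounds in BOTH images."""
    a, b = _as_hwc(image_a), _as_hwc(image_b)
    if a.shape[:2] != b.shape[:2]:
        raise ValueError("images must share spatial shape")
    union = background_mask(a, threshold) | background_mask(b, threshold)
    a, b = a.copy(), b.copy()
    a[union] = 0.0
    b[union] = 0.0
    if np.asarray(image_a).ndim == 2:
        a = a[:, :, 0]
    if np.asarray(image_b).ndim == 2:
        b = b[:, :, 0]
    return a, b


def apply_affine_to_points(affine: np.ndarray, points) -> np.ndarray:
    """Apply a 3x3 homogeneous affine to (K, 2) xy points."""
    pts = np.asarray(points, dtype=np.float64)
    homo = np.hstack([pts, np.ones((pts.shape[0], 1))])
    out = homo @ np.asarray(affine, float).T
    return out[:, :2]


def random_rotation_scale(image, config: AugmentConfig, rng, angle_deg=None):
    """Rotate about the image center with a foreground-preserving shrink.

    The angle is Uniform(-max_rotation_deg, +max_rotation_deg) unless
    ``angle_deg`` forces it (test hook).  The isotropic scale is chosen
    so the rotated bounding box of the foreground stays inside the
    frame.  Returns ``(augmented image, affine)`` where the 3x3
    homogeneous ``affine`` maps original pixel (x, y) to augmented
    pixel coordinates.
    """
    arr = _as_hwc(image)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if angle_deg is None:
        angle_deg = float(rng.uniform(-config.max_rotation_deg, config.max_rotation_deg))
    theta = np.deg2rad(angle_deg)
    h, w = arr.shape[:2]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0

    fg = ~background_mask(arr, config.background_threshold)
    if fg.any():
        ys, xs = np.nonzero(fg)
        x0, x1 = xs.min(), xs.max()
        y0, y1 = ys.min(), ys.max()
    else:
        x0, x1, y0, y1 = 0, w - 1, 0, h - 1
    corners = np.array(
        [[x0, y0], [x0, y1], [x1, y0], [x1, y1]], dtype=float
    ) - [cx, cy]
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    rotated = corners @ rot.T
    half_w, half_h = (w - 1) / 2.0, (h - 1) / 2.0
    with np.errstate(divide="ignore"):
        sx = np.where(np.abs(rotated[:, 0]) > 0, half_w / np.abs(rotated[:, 0]), np.inf)
        sy = np.where(np.abs(rotated[:, 1]) > 0, half_h / np.abs(rotated[:, 1]), np.inf)
    scale = float(min(1.0, sx.min(), sy.min()))

    affine = np.eye(3)
    affine[:2, :2] = scale * rot
    affine[:2, 2] = [cx, cy] - scale * rot @ [cx, cy]

    inv = np.linalg.inv(affine)
    xs_g, ys_g = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    src = apply_affine_to_points(inv, np.stack([xs_g.ravel(), ys_g.ravel()], axis=1))
    out = np.stack(
        [
            map_coordinates(
                arr[:, :, c],
                [src[:, 1].reshape(h, w), src[:, 0].reshape(h, w)],
                order=1,
                mode="constant",
                cval=0.0,
            )
            for c in range(arr.shape[2])
        ],
        axis=2,
    )
    if np.asarray(image).ndim == 2:
        out = out[:, :, 0]
    return out, affine


def _dense_field(coarse: np.ndarray, h: int, w: int) -> np.ndarray:
    """Upsample a (g, g, 2) knot grid to a dense (H, W, 2) field.

    Knots sit on a uniform grid spanning the full image; the spline
    interpolates the knot displacements exactly.
    """
    g = coarse.shape[0]
    ky = np.linspace(0, h - 1, g)
    kx = np.linspace(0, w - 1, g)
    deg = min(3, g - 1)
    field = np.empty((h, w, 2))
    ys, xs = np.arange(h, dtype=float), np.arange(w, dtype=float)
    for c in range(2):
        spl = RectBivariateSpline(ky, kx, coarse[:, :, c], kx=deg, ky=deg, s=0)
        field[:, :, c] = spl(ys, xs)
    return field


def knot_coordinates(shape, grid_points: int) -> np.ndarray:
    """Pixel (x, y) locations of the elastic deformation knots."""
    h, w = shape[:2]
    ky = np.linspace(0, h - 1, grid_points)
    kx = np.linspace(0, w - 1, grid_points)
    gx, gy = np.meshgrid(kx, ky)
    return np.stack([gx.ravel(), gy.ravel()], axis=1)


def elastic_deform(image, grid_points: int, sigma: float, rng):
    """Smooth elastic deformation from a coarse Gaussian displacement grid.

    A (grid_points, grid_points, 2) grid of i.i.d. Normal(0, sigma^2)
    pixel displacements is spline-upsampled to a dense field ``d`` and
    applied by backward warping: output pixel q samples the input at
    ``q + d(q)``.  Returns ``(warped image, dense field)`` with the
    field stored x-displacement first.
    """
    if grid_points < 2:
        raise ValueError("grid_points must be >= 2 per axis")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    arr = _as_hwc(image)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    h, w = arr.shape[:2]
    coarse = rng.normal(0.0, sigma, size=(grid_points, grid_points, 2))
    if sigma == 0:
        field = np.zeros((h, w, 2))
        out = arr.copy()
    else:
        field = _dense_field(coarse, h, w)
        xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        out = np.stack(
            [
                map_coordinates(
                    arr[:, :, c],
                    [ys + field[:, :, 1], xs + field[:, :, 0]],
                    order=1,
                    mode="constant",
                    cval=0.0,
                )
                for c in range(arr.shape[2])
            ],
            axis=2,
        )
    if np.asarray(image).ndim == 2:
        out = out[:, :, 0]
    return out, field


def apply_field_to_points(field: np.ndarray, points, n_iter: int = 25) -> np.ndarray:
    """Forward-map input-frame points through a backward displacement field.

    The field gives, for each OUTPUT pixel q, the input sample location
    q + d(q); the forward image of an input point p is the fixed point
    q = p - d(q), found by iteration (converges for smooth fields with
    |Jacobian of d| < 1).
    """
    pts = np.asarray(points, dtype=np.float64)
    h, w = field.shape[:2]

    def interp_d(q):
        return np.stack(
            [
                map_coordinates(field[:, :, c], [q[:, 1], q[:, 0]], order=1, mode="nearest")
                for c in range(2)
            ],
            axis=1,
        )

    q = pts.copy()
    for _ in range(n_iter):
        q = pts - interp_d(q)
    return q


def random_augment(image, config: AugmentConfig, rng):
    """Full augmentation pipeline: rotation+scale, then elastic.

    The rng stream order (rotation first, elastic second) is fixed for
    reproducibility.  Returns ``(augmented, info)`` where ``info``
    carries the affine, the dense elastic field, and the sampled
    (angle-implied) parameters; ``transform_points(info, pts)`` maps
    original-frame points into the augmented frame.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rotated, affine = random_rotation_scale(image, config, rng)
    grid = int(rng.integers(config.elastic_grid_range[0], config.elastic_grid_range[1] + 1))
    sigma = float(rng.uniform(*config.elastic_sigma_range))
    out, field = elastic_deform(rotated, grid, sigma, rng)
    return out, {"affine": affine, "field": field, "grid_points": grid, "sigma": sigma}


def transform_points(info: dict, points) -> np.ndarray:
    """Map original-frame points through a ``random_augment`` transform."""
    pts = apply_affine_to_points(info["affine"], points)
    return apply_field_to_points(info["field"], pts)
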