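"""Analytic landmark-based 2-D transforms.

Thin-plate splines (TPS) interpolate one ordered landmark set onto
another with the minimum-bending-energy map

    f(x, y) = a1 + ax*x + ay*y + sum_i w_i U(||(x_i, y_i) - (x, y)||)

with radial kernel ``U(r) = r^2 log2(r)`` and separate coefficient sets
per output axis.  The kernel weights satisfy the side conditions
``sum w_i = sum w_i x_i = sum w_i y_i = 0``, imposed through the
standard augmented linear system

    [[K + lam*I, P], [P^T, 0]] [w; a] = [q; 0]

which is solved exactly (no iterative optimization).  Coordinates are
normalized to [-1, 1] per axis before fitting so the system is scale
invariant; pixel coordinates are 0-based ``(x, y) = (column, row)`` with
pixel centers at integers.

Rigid / similarity alignment uses the closed-form Kabsch-Umeyama
solution with reflection excluded.

All operations accept plain numpy arrays; the TPS fit and warp also
accept autodiff :class:`~landreg._autodiff.Tensor` inputs, in which case
gradients flow through the linear solve and the bilinear sampling (used
by the training regimes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml

from . import _autodiff as ad
from ._autodiff import Tensor

__all__ = [
    "TPSModel",
    "RigidTransform",
    "tps_kernel",
    "tps_fit",
    "tps_transform_points",
    "tps_warp_image",
    "rigid_fit",
    "rigid_transform_points",
    "rigid_warp_image",
    "area_change",
    "save_transform",
    "load_transform",
]

_LN2 = math.log(2.0)
_EPS_SQ = 1e-30  # squared-distance cutoff below which U is its limit 0


# --------------------------------------------------------------------------
# small polymorphic helpers (numpy array or autodiff Tensor)
# --------------------------------------------------------------------------

def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _any_tensor(*xs) -> bool:
    return any(_is_tensor(x) for x in xs)


def _concat(parts, axis=0):
    if _any_tensor(*parts):
        return ad.concat([ad.as_tensor(p) for p in parts], axis=axis)
    return np.concatenate(parts, axis=axis)


def _solve(a, b):
    if _any_tensor(a, b):
        return ad.solve(ad.as_tensor(a), ad.as_tensor(b))
    return np.linalg.solve(a, b)


def _u_from_sq(s):
    """TPS kernel from SQUARED distance: U = s*log2(s)/2, U(0)=0.

    Working in squared distances avoids the non-differentiable sqrt at
    the kernel diagonal (r = 0).
    """
    if _is_tensor(s):
        mask = s.data > _EPS_SQ
        safe = ad.where(mask, s, 1.0)
        return ad.where(mask, safe * safe.log() * (0.5 / _LN2), 0.0)
    s = np.asarray(s, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(s > _EPS_SQ, s * np.log(np.where(s > _EPS_SQ, s, 1.0)), 0.0)
    return out * (0.5 / _LN2)


def _pairwise_sq(a, b):
    """Squared distances between rows of a (M,2) and b (K,2)."""
    if _any_tensor(a, b):
        a, b = ad.as_tensor(a), ad.as_tensor(b)
        ax = a[:, 0].reshape(-1, 1)
        ay = a[:, 1].reshape(-1, 1)
        bx = b[:, 0].reshape(1, -1)
        by = b[:, 1].reshape(1, -1)
        return (ax - bx) ** 2 + (ay - by) ** 2
    diff = a[:, None, :] - b[None, :, :]
    return (diff**2).sum(axis=2)


# --------------------------------------------------------------------------
# kernel
# --------------------------------------------------------------------------

def tps_kernel(r):
    """Radial TPS kernel ``U(r) = r^2 log2(r)``, with ``U(0) = 0``.

    Accepts scalars or arrays; negative radii are invalid.
    """
    arr = np.asarray(r, dtype=np.float64)
    if np.any(arr < 0):
        raise ValueError("tps_kernel requires r >= 0")
    out = _u_from_sq(arr**2)
    if np.isscalar(r) or arr.ndim == 0:
        return float(out)
    return out


# --------------------------------------------------------------------------
# TPS model
# --------------------------------------------------------------------------

@dataclass
class TPSModel:
    """Fitted thin-plate spline mapping source landmarks onto targets.

    ``affine`` rows are (a1, ax, ay) per output axis (columns x, y);
    ``weights`` holds one kernel weight per control point and output
    axis.  ``bounds`` records the normalization box (xmin, xmax, ymin,
    ymax) in source coordinate units.  Coefficient arrays may be
    autodiff Tensors inside a training graph.
    """

    control_points: object  # (K, 2) normalized source points
    affine: object  # (3, 2) rows (a1, ax, ay), columns (x, y)
    weights: object  # (K, 2)
    regularization: float = 0.0
    bounds: tuple = (-1.0, 1.0, -1.0, 1.0)

    @property
    def affine_x(self):
        a = self.affine.data if _is_tensor(self.affine) else self.affine
        return np.asarray(a)[:, 0]

    @property
    def affine_y(self):
        a = self.affine.data if _is_tensor(self.affine) else self.affine
        return np.asarray(a)[:, 1]

    @property
    def weights_x(self):
        w = self.weights.data if _is_tensor(self.weights) else self.weights
        return np.asarray(w)[:, 0]

    @property
    def weights_y(self):
        w = self.weights.data if _is_tensor(self.weights) else self.weights
        return np.asarray(w)[:, 1]


def _normalize(points, bounds):
    xmin, xmax, ymin, ymax = bounds
    sx = 2.0 / (xmax - xmin)
    sy = 2.0 / (ymax - ymin)
    if _is_tensor(points):
        x = (points[:, 0] - xmin) * sx - 1.0
        y = (points[:, 1] - ymin) * sy - 1.0
        return ad.stack([x, y], axis=1)
    out = np.empty_like(np.asarray(points, dtype=np.float64))
    out[:, 0] = (points[:, 0] - xmin) * sx - 1.0
    out[:, 1] = (points[:, 1] - ymin) * sy - 1.0
    return out


def _denormalize(points, bounds):
    xmin, xmax, ymin, ymax = bounds
    hx = (xmax - xmin) / 2.0
    hy = (ymax - ymin) / 2.0
    if _is_tensor(points):
        x = (points[:, 0] + 1.0) * hx + xmin
        y = (points[:, 1] + 1.0) * hy + ymin
        return ad.stack([x, y], axis=1)
    out = np.empty_like(np.asarray(points, dtype=np.float64))
    out[:, 0] = (points[:, 0] + 1.0) * hx + xmin
    out[:, 1] = (points[:, 1] + 1.0) * hy + ymin
    return out


def _default_bounds(source, target):
    pts = np.vstack([np.asarray(source, float), np.asarray(target, float)])
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)
    # guard degenerate (zero-extent) boxes
    if xmax - xmin < 1e-12:
        xmin, xmax = xmin - 0.5, xmax + 0.5
    if ymax - ymin < 1e-12:
        ymin, ymax = ymin - 0.5, ymax + 0.5
    return (float(xmin), float(xmax), float(ymin), float(ymax))


def _check_nondegenerate(src: np.ndarray) -> None:
    k = src.shape[0]
    d2 = _pairwise_sq(src, src)
    dup = np.argwhere(np.triu(d2 < 1e-16, k=1))
    if dup.size:
        i, j = dup[0]
        raise np.linalg.LinAlgError(
            f"duplicate control points {int(i)} and {int(j)}: {src[i].tolist()}"
        )
    centered = src - src.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[-1] < 1e-10 * max(svals[0], 1.0):
        raise np.linalg.LinAlgError(
            f"control points are collinear (singular values {svals.tolist()}); "
            "a TPS fit with lambda=0 is singular"
        )


def tps_fit(source, target, lam: float = 0.0, bounds=None) -> TPSModel:
    """Fit a TPS sending ``source`` landmarks onto ``target`` landmarks.

    Parameters
    ----------
    source, target : (K, 2) arrays or Tensors, K >= 3
        Corresponding point sets, ordered so index i pairs with index i.
    lam : float
        Non-negative bending regularization added to the kernel
        diagonal; ``lam = 0`` interpolates exactly.
    bounds : optional (xmin, xmax, ymin, ymax)
        Normalization box.  Defaults to the joint bounding box of both
        point sets (numpy inputs only; Tensor inputs must pass bounds so
        the normalization is a fixed linear map).
    """
    tensor_mode = _any_tensor(source, target)
    src_arr = source.data if _is_tensor(source) else np.asarray(source, float)
    tgt_arr = target.data if _is_tensor(target) else np.asarray(target, float)
    if src_arr.ndim != 2 or src_arr.shape[1] != 2 or src_arr.shape != tgt_arr.shape:
        raise ValueError(
            f"source/target must be matching (K, 2) arrays, got "
            f"{src_arr.shape} and {tgt_arr.shape}"
        )
    k = src_arr.shape[0]
    if k < 3:
        raise ValueError(f"TPS needs at least 3 control points, got {k}")
    if lam < 0:
        raise ValueError("regularization must be non-negative")
    if bounds is None:
        if tensor_mode:
            raise ValueError("Tensor inputs require explicit bounds")
        bounds = _default_bounds(src_arr, tgt_arr)

    src_n = _normalize(source, bounds)
    tgt_n = _normalize(target, bounds)
    src_n_arr = src_n.data if tensor_mode else src_n
    if lam == 0.0:
        _check_nondegenerate(np.asarray(src_n_arr))

    kmat = _u_from_sq(_pairwise_sq(src_n, src_n))
    if lam:
        kmat = kmat + lam * np.eye(k)
    if tensor_mode:
        ones = Tensor(np.ones((k, 1)))
        p = ad.concat([ones, ad.as_tensor(src_n)], axis=1)  # (K, 3)
        top = ad.concat([kmat, p], axis=1)
        bottom = ad.concat([p.transpose(1, 0), Tensor(np.zeros((3, 3)))], axis=1)
        lmat = ad.concat([top, bottom], axis=0)
        rhs = ad.concat([ad.as_tensor(tgt_n), Tensor(np.zeros((3, 2)))], axis=0)
    else:
        p = np.hstack([np.ones((k, 1)), src_n])
        lmat = np.zeros((k + 3, k + 3))
        lmat[:k, :k] = kmat
        lmat[:k, k:] = p
        lmat[k:, :k] = p.T
        rhs = np.vstack([tgt_n, np.zeros((3, 2))])
        cond = np.linalg.cond(lmat)
        if not np.isfinite(cond) or cond > 1e13:
            raise np.linalg.LinAlgError(
                f"TPS system is singular or ill-conditioned (cond={cond:.3g}); "
                "check for coincident or collinear control points"
            )
    coef = _solve(lmat, rhs)
    return TPSModel(
        control_points=src_n,
        affine=coef[k:],
        weights=coef[:k],
        regularization=float(lam),
        bounds=tuple(bounds),
    )


def tps_transform_points(model: TPSModel, points):
    """Evaluate the fitted spline at ``points`` ((M, 2), same units as fit)."""
    pts_n = _normalize(points, model.bounds)
    u = _u_from_sq(_pairwise_sq(pts_n, model.control_points))  # (M, K)
    if _any_tensor(pts_n, model.weights):
        pts_n = ad.as_tensor(pts_n)
        ones = Tensor(np.ones((pts_n.shape[0], 1)))
        pmat = ad.concat([ones, pts_n], axis=1)
        out_n = ad.as_tensor(u) @ model.weights + pmat @ model.affine
    else:
        pmat = np.hstack([np.ones((pts_n.shape[0], 1)), pts_n])
        out_n = u @ model.weights + pmat @ model.affine
    return _denormalize(out_n, model.bounds)


def tps_warp_image(model: TPSModel, image, out_shape=None):
    """Backward-warp ``image`` through a TPS fitted target -> source.

    Each output pixel (x, y) samples the source image bilinearly at the
    model-mapped location; samples outside the source fill with 0.  The
    model must therefore map OUTPUT (target-frame) pixel coordinates to
    SOURCE pixel coordinates.  ``image`` is (H, W) or (H, W, C); Tensor
    images of shape (C, H, W) keep gradients.
    """
    tensor_mode = _is_tensor(image)
    if tensor_mode:
        img_chw = image
        h, w = image.shape[1], image.shape[2]
    else:
        arr = np.asarray(image, dtype=np.float64)
        if arr.size == 0:
            raise ValueError("cannot warp an empty image")
        squeeze = arr.ndim == 2
        if squeeze:
            arr = arr[:, :, None]
        h, w = arr.shape[:2]
        img_chw = Tensor(np.moveaxis(arr, 2, 0))
    if out_shape is None:
        out_h, out_w = h, w
    else:
        out_h, out_w = out_shape
    xs, ys = np.meshgrid(np.arange(out_w, dtype=float), np.arange(out_h, dtype=float))
    grid = np.stack([xs.ravel(), ys.ravel()], axis=1)
    coords = tps_transform_points(model, grid if tensor_mode else grid)
    if not _is_tensor(coords):
        # snap near-integer sample locations so identity warps are exact
        rounded = np.round(coords)
        coords = np.where(np.abs(coords - rounded) < 1e-9, rounded, coords)
        coords = Tensor(coords)
    sampled = ad.grid_sample(img_chw, coords)  # (C, P)
    c = sampled.shape[0]
    out = sampled.reshape(c, out_h, out_w)
    if tensor_mode:
        return out
    res = np.moveaxis(out.data, 0, 2)
    return res[:, :, 0] if squeeze else res


# --------------------------------------------------------------------------
# rigid / similarity alignment
# --------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """Similarity transform ``q = s * R @ p + t`` with det(R) = +1."""

    rotation: np.ndarray  # (2, 2)
    translation: np.ndarray  # (2,)
    scale: float = 1.0

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)

    @property
    def angle(self) -> float:
        """Rotation angle in radians."""
        return float(np.arctan2(self.rotation[1, 0], self.rotation[0, 0]))

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        return RigidTransform(
            rotation=rinv,
            translation=-rinv @ self.translation / self.scale,
            scale=1.0 / self.scale,
        )


def rigid_fit(source, target, with_scale: bool = False) -> RigidTransform:
    """Least-squares rigid (or similarity) alignment, Kabsch-Umeyama.

    Finds R, t (and s when ``with_scale``) minimizing
    ``sum_i || s R p_i + t - q_i ||^2`` with reflections excluded.
    """
    src = np.asarray(source, dtype=np.float64)
    tgt = np.asarray(target, dtype=np.float64)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("source and target must be matching (K, 2) arrays")
    if src.shape[0] < 2:
        raise ValueError("rigid_fit needs at least 2 points")
    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    sc, tc = src - mu_s, tgt - mu_t
    var_s = (sc**2).sum() / src.shape[0]
    if var_s < 1e-24:
        raise ValueError("all source points coincide; rotation is undefined")
    cov = tc.T @ sc / src.shape[0]
    u, dvals, vt = np.linalg.svd(cov)
    sgn = np.ones(2)
    if np.linalg.det(u @ vt) < 0:
        sgn[-1] = -1.0
    rot = u @ np.diag(sgn) @ vt
    scale = float((dvals * sgn).sum() / var_s) if with_scale else 1.0
    if with_scale and scale <= 0:
        raise ValueError("degenerate configuration: non-positive optimal scale")
    trans = mu_t - scale * rot @ mu_s
    return RigidTransform(rotation=rot, translation=trans, scale=scale)


def rigid_transform_points(transform: RigidTransform, points) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    return transform.scale * pts @ transform.rotation.T + transform.translation


def rigid_warp_image(transform: RigidTransform, image, out_shape=None):
    """Warp an image so content moves by ``transform`` (forward semantics).

    Output pixel q samples the input at ``transform^{-1}(q)``.  Accepts
    (H, W[, C]) numpy images or (C, H, W) Tensors (differentiable in the
    image only; the transform is a fixed parameter).
    """
    inv = transform.inverse()
    tensor_mode = _is_tensor(image)
    if tensor_mode:
        h, w = image.shape[1], image.shape[2]
    else:
        arr = np.asarray(image, dtype=np.float64)
        squeeze = arr.ndim == 2
        if squeeze:
            arr = arr[:, :, None]
        h, w = arr.shape[:2]
    out_h, out_w = (h, w) if out_shape is None else out_shape
    xs, ys = np.meshgrid(np.arange(out_w, dtype=float), np.arange(out_h, dtype=float))
    grid = np.stack([xs.ravel(), ys.ravel()], axis=1)
    coords = rigid_transform_points(inv, grid)
    rounded = np.round(coords)
    coords = np.where(np.abs(coords - rounded) < 1e-9, rounded, coords)
    if tensor_mode:
        sampled = ad.grid_sample(image, Tensor(coords))
        return sampled.reshape(image.shape[0], out_h, out_w)
    sampled = ad.grid_sample(Tensor(np.moveaxis(arr, 2, 0)), Tensor(coords))
    res = np.moveaxis(sampled.data.reshape(arr.shape[2], out_h, out_w), 0, 2)
    return res[:, :, 0] if squeeze else res


# --------------------------------------------------------------------------
# tissue area change
# --------------------------------------------------------------------------

def area_change(before, after, threshold: float = 0.1) -> float:
    """Relative foreground-area change dA in [0, 1].

    Foreground pixels have at least one channel >= threshold.  Defined
    as ``min(1, |A_after - A_before| / A_before)``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    b = np.asarray(before, dtype=np.float64)
    a = np.asarray(after, dtype=np.float64)
    if b.ndim == 2:
        b = b[:, :, None]
    if a.ndim == 2:
        a = a[:, :, None]
    if b.shape[:2] != a.shape[:2]:
        raise ValueError("before/after must share spatial shape")
    area_b = int((b >= threshold).any(axis=2).sum())
    area_a = int((a >= threshold).any(axis=2).sum())
    if area_b == 0:
        raise ValueError("before-image has no foreground; dA is undefined")
    return min(1.0, abs(area_a - area_b) / area_b)


# --------------------------------------------------------------------------
# YAML serialization
# --------------------------------------------------------------------------

def _to_plain(model) -> dict:
    if isinstance(model, TPSModel):
        cp = model.control_points
        cp = cp.data if _is_tensor(cp) else np.asarray(cp)
        aff = model.affine.data if _is_tensor(model.affine) else np.asarray(model.affine)
        wts = model.weights.data if _is_tensor(model.weights) else np.asarray(model.weights)
        return {
            "type": "tps",
            "control_points": cp.tolist(),
            "affine": np.asarray(aff).tolist(),
            "weights": np.asarray(wts).tolist(),
            "regularization": float(model.regularization),
            "bounds": [float(v) for v in model.bounds],
        }
    if isinstance(model, RigidTransform):
        return {
            "type": "rigid",
            "rotation": model.rotation.tolist(),
            "translation": model.translation.tolist(),
            "scale": float(model.scale),
        }
    raise TypeError(f"cannot serialize {type(model).__name__}")


def save_transform(path, model) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(model), fh, sort_keys=True)


def load_transform(path):
    with open(path) as fh:
        blob = yaml.safe_load(fh)
    if blob["type"] == "tps":
        return TPSModel(
            control_points=np.asarray(blob["control_points"], float),
            affine=np.asarray(blob["affine"], float),
            weights=np.asarray(blob["weights"], float),
            regularization=float(blob["regularization"]),
            bounds=tuple(blob["bounds"]),
        )
    if blob["type"] == "rigid":
        return RigidTransform(
            rotation=np.asarray(blob["rotation"], float),
            translation=np.asarray(blob["translation"], float),
            scale=float(blob["scale"]),
        )
    raise ValueError(f"unknown transform type {blob['type']!r}")
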