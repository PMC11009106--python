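"""MS-SSIM dissimilarities and the composite training losses.

All losses are of the form ``1 - MS-SSIM`` (a dissimilarity minimized
at perfect registration) and combine as

    pairwise:   L_total = L_base + 0.1 * L_consistency
    z-stack:    L = (1-dA) * D(Xj_tps, Xi_tps) + dA * D(Xj_tps, Xi_rigid)
    multimodal: L_total = L_base + 10 * L_intra + 0.1 * L_inter

where D is the MS-SSIM dissimilarity and L_inter is the RMSE between
first-layer detector latents.  MS-SSIM follows Wang et al.: Gaussian
window statistics (valid convolution), contrast+structure at every
scale, luminance only at the coarsest, combined as a weighted geometric
product with the standard five-scale weights (truncated and
renormalized when the image supports fewer scales).

Every operation accepts (H, W[, C]) numpy images (returning floats) or
(C, H, W) autodiff Tensors (returning scalar Tensors with gradients).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

__all__ = [
    "LossWeights",
    "ms_ssim",
    "dissim",
    "base_loss",
    "patch_consistency_loss",
    "global_consistency_loss",
    "pairwise_total_loss",
    "stack_loss",
    "inter_consistency_loss",
    "multimodal_total_loss",
]

# standard five-scale MS-SSIM weights (Wang et al.)
_MSSSIM_WEIGHTS = np.array([0.0448, 0.2856, 0.3001, 0.2363, 0.1333])
_C1 = 0.01**2
_C2 = 0.03**2


@dataclass
class LossWeights:
    """Scales and window sizes of the composite losses."""

    consistency_scale: float = 0.1
    intra_scale: float = 10.0
    inter_scale: float = 0.1
    msssim_window: int = 5
    patch_window: int = 3
    patch_size: int = 16

    def __post_init__(self):
        for name in ("consistency_scale", "intra_scale", "inter_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("msssim_window", "patch_window"):
            v = getattr(self, name)
            if v < 3 or v % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 3")


def _to_chw(image) -> Tensor:
    if isinstance(image, Tensor):
        if image.ndim != 3:
            raise ValueError("Tensor images must be (C, H, W)")
        return image
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError("images must be (H, W) or (H, W, C)")
    return Tensor(np.moveaxis(arr, 2, 0))


def _gaussian_kernel(window: int, sigma: float = 1.5) -> np.ndarray:
    half = (window - 1) / 2.0
    ax = np.arange(window) - half
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k2 = np.outer(g, g)
    return (k2 / k2.sum())[None, None]  # (1, 1, win, win)


def _filter(x: Tensor, kernel: np.ndarray) -> Tensor:
    """Valid Gaussian filtering of (C, H, W), channels independent."""
    c, h, w = x.shape
    return ad.conv2d(x.reshape(c, 1, h, w), Tensor(kernel), padding=0).reshape(
        c, h - kernel.shape[2] + 1, w - kernel.shape[3] + 1
    )


def _ssim_components(x: Tensor, y: Tensor, kernel: np.ndarray):
    """Mean luminance and contrast-structure terms of single-scale SSIM."""
    mu_x = _filter(x, kernel)
    mu_y = _filter(y, kernel)
    xx = _filter(x * x, kernel) - mu_x * mu_x
    yy = _filter(y * y, kernel) - mu_y * mu_y
    xy = _filter(x * y, kernel) - mu_x * mu_y
    lum = (2.0 * mu_x * mu_y + _C1) / (mu_x * mu_x + mu_y * mu_y + _C1)
    cs = (2.0 * xy + _C2) / (xx + yy + _C2)
    return lum, cs


def max_scales(shape, window: int) -> int:
    """Largest usable scale count (capped at 5) for a spatial shape."""
    m = min(shape)
    n = 0
    while n < 5 and m // (2**n) >= window:
        n += 1
    return n


def ms_ssim(x, y, window: int = 5, n_scales: int | None = None, weights=None):
    """Multiscale structural similarity of two equal-shape images.

    Returns a float for numpy inputs, a scalar Tensor for Tensor
    inputs.  Raises if the requested scale count does not fit the image
    (the spatial size must be at least ``window * 2**(n_scales-1)``).
    """
    xt, yt = _to_chw(x), _to_chw(y)
    if xt.shape != yt.shape:
        raise ValueError(f"shape mismatch: {xt.shape} vs {yt.shape}")
    feasible = max_scales(xt.shape[1:], window)
    if feasible < 1:
        raise ValueError(
            f"image {xt.shape[1:]} is smaller than the {window}x{window} window"
        )
    if n_scales is None:
        n_scales = feasible
    elif n_scales > feasible:
        raise ValueError(
            f"requested {n_scales} scales but image {xt.shape[1:]} supports "
            f"only {feasible} with window {window}; pass a smaller n_scales"
        )
    if weights is None:
        weights = _MSSSIM_WEIGHTS[:n_scales]
        weights = weights / weights.sum()
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (n_scales,):
        raise ValueError("need one weight per scale")

    kernel = _gaussian_kernel(window)
    log_terms = []
    for s in range(n_scales):
        lum, cs = _ssim_components(xt, yt, kernel)
        if s == n_scales - 1:
            val = (lum * cs).mean()
        else:
            val = cs.mean()
        log_terms.append(val.clamp_min(1e-6).log() * float(weights[s]))
        if s < n_scales - 1:
            # low-pass + dyadic downsampling; odd trailing row/col cropped
            c, h, w = xt.shape
            he, we = h - h % 2, w - w % 2
            xt = ad.avg_pool2d(xt[:, :he, :we].reshape(c, 1, he, we), 2).reshape(
                c, he // 2, we // 2
            )
            yt = ad.avg_pool2d(yt[:, :he, :we].reshape(c, 1, he, we), 2).reshape(
                c, he // 2, we // 2
            )
    total = log_terms[0]
    for t in log_terms[1:]:
        total = total + t
    out = total.exp()
    if isinstance(x, Tensor) or isinstance(y, Tensor):
        return out
    return out.item()


def dissim(x, y, window: int = 5, n_scales: int | None = None, weights=None):
    """MS-SSIM dissimilarity ``1 - MS-SSIM``, minimized at x = y."""
    return 1.0 - ms_ssim(x, y, window=window, n_scales=n_scales, weights=weights)


def base_loss(x_registered, x_target, weights: LossWeights | None = None):
    """Registration loss between a warped source and its target."""
    w = weights or LossWeights()
    return dissim(x_registered, x_target, window=w.msssim_window)


def global_consistency_loss(y_registered, x_target, weights: LossWeights | None = None):
    """Whole-image consistency dissimilarity (batch-effect-tolerant form)."""
    w = weights or LossWeights()
    return dissim(y_registered, x_target, window=w.msssim_window)


def _extract_patch(img: Tensor, cx: float, cy: float, size: int):
    c, h, w = img.shape
    half = size // 2
    x0 = int(round(cx)) - half
    y0 = int(round(cy)) - half
    x0, y0 = max(0, x0), max(0, y0)
    x1 = min(w, x0 + size)
    y1 = min(h, y0 + size)
    x0 = max(0, x1 - size)
    y0 = max(0, y1 - size)
    return img[:, y0:y1, x0:x1]


def patch_consistency_loss(
    y_registered, x_target, landmarks, weights: LossWeights | None = None
):
    """Mean patch dissimilarity around the landmarks (target frame).

    Patches (default 16 px) are clipped at image borders; patches that
    end up smaller than the patch window are skipped.  Raises when no
    usable patch remains.
    """
    w = weights or LossWeights()
    yt, xt = _to_chw(y_registered), _to_chw(x_target)
    if yt.shape != xt.shape:
        raise ValueError(f"shape mismatch: {yt.shape} vs {xt.shape}")
    pts = landmarks.data if isinstance(landmarks, Tensor) else np.asarray(landmarks)
    terms = []
    for cx, cy in pts:
        py = _extract_patch(yt, cx, cy, w.patch_size)
        px = _extract_patch(xt, cx, cy, w.patch_size)
        if min(py.shape[1:]) < w.patch_window:
            continue
        terms.append(dissim(py, px, window=w.patch_window))
    if not terms:
        raise ValueError("no usable landmark patches (all outside or too small)")
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    total = total * (1.0 / len(terms))
    if isinstance(y_registered, Tensor) or isinstance(x_target, Tensor):
        return total
    return total.item()


def pairwise_total_loss(base, consistency, weights: LossWeights | None = None):
    """``L_total = L_base + consistency_scale * L_consistency``."""
    w = weights or LossWeights()
    return base + w.consistency_scale * consistency


def stack_loss(x_j_tps, x_i_tps, x_i_rigid, dA, weights: LossWeights | None = None):
    """Area-change-gated z-stack loss.

    ``(1-dA) * D(Xj_tps, Xi_tps) + dA * D(Xj_tps, Xi_rigid)``: the more
    the TPS registration changes the tissue area, the more the rigid
    alignment dominates, forcing landmarks to act as anchor points.
    """
    if not 0.0 <= dA <= 1.0:
        raise ValueError("dA must lie in [0, 1]")
    w = weights or LossWeights()
    tps_term = dissim(x_j_tps, x_i_tps, window=w.msssim_window)
    rigid_term = dissim(x_j_tps, x_i_rigid, window=w.msssim_window)
    return (1.0 - dA) * tps_term + dA * rigid_term


def inter_consistency_loss(z_a, z_b):
    """RMSE between two latent activation tensors of equal shape."""
    at = z_a if isinstance(z_a, Tensor) else Tensor(np.asarray(z_a, float))
    bt = z_b if isinstance(z_b, Tensor) else Tensor(np.asarray(z_b, float))
    if at.shape != bt.shape:
        raise ValueError(f"latent shape mismatch: {at.shape} vs {bt.shape}")
    out = (((at - bt) ** 2).mean()).sqrt()
    if isinstance(z_a, Tensor) or isinstance(z_b, Tensor):
        return out
    return out.item()


def multimodal_total_loss(base, intra, inter, weights: LossWeights | None = None):
    """``L_total = L_base + intra_scale * L_intra + inter_scale * L_inter``."""
    w = weights or LossWeights()
    return base + w.intra_scale * intra + w.inter_scale * inter
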