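"""Unsupervised training regimes for the landmark detector.

Three regimes share one mechanism — detect landmarks on two views,
thin-plate-spline-register one view onto the other, and score the
registration with an MS-SSIM dissimilarity — and differ in how views
are paired:

* pairwise: two augmented variants of one section (base loss) plus a
  second section registered to the target (consistency loss, patch or
  whole-image variant).
* z-stack: every section is registered to a random reference both
  rigidly and by TPS; the loss mixes the two by the TPS area change dA,
  so landmarks behave as planar anchor points when TPS distorts area.
* multimodal: two detectors (one per modality); base and intra losses
  per modality plus an inter-modality RMSE between first-layer latents
  of the reference modality's detector.

Gradients flow through the spatial soft-argmax, the TPS linear solve
and the bilinear warp (a stop-gradient through the solve is available
via ``TrainConfig.stop_grad_tps``).  The rigid Kabsch-Umeyama fit and
the area change are computed outside the gradient tape: both are
either non-smooth (foreground counting) or add little signal compared
to the TPS path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Adam, Tensor
from .augment import AugmentConfig, background_mask, random_augment
from .detector import DetectorModel, dropout_indices, spatial_argmax
from .geometry import area_change, rigid_fit, rigid_warp_image, tps_fit, tps_warp_image
from .losses import (
    LossWeights,
    dissim,
    global_consistency_loss,
    inter_consistency_loss,
    multimodal_total_loss,
    pairwise_total_loss,
    patch_consistency_loss,
    stack_loss,
)

__all__ = [
    "TrainConfig",
    "lr_at_epoch",
    "has_converged",
    "train_pairwise",
    "train_stack",
    "train_multimodal",
]


@dataclass
class TrainConfig:
    """Optimization schedule and sampling parameters."""

    learning_rate: float = 1e-4
    lr_step_epochs: int = 10
    lr_gamma: float = 0.95
    batch_size: int = 48
    iterations_per_epoch: int = 300
    max_epochs: int = 80
    convergence_tol: float = 1e-4
    convergence_patience: int = 10
    dropout_p: float = 0.1
    min_keep: int = 4
    neighbor_radius: int = 3
    tps_lambda: float = 1e-6
    stop_grad_tps: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.convergence_patience < 1:
            raise ValueError("convergence_patience must be >= 1")
        for name in ("learning_rate", "lr_step_epochs", "lr_gamma", "batch_size",
                     "iterations_per_epoch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Stepped exponential schedule: lr * gamma**floor(epoch / step)."""
    return config.learning_rate * config.lr_gamma ** (epoch // config.lr_step_epochs)


def has_converged(loss_history, tol: float = 1e-4, patience: int = 10) -> bool:
    """True when the best-so-far loss improved < tol in each of the last
    ``patience`` epochs (the first epoch counts as no improvement)."""
    h = [float(v) for v in loss_history]
    if len(h) < patience:
        return False
    best = np.inf
    improvements = []
    for i, v in enumerate(h):
        improvements.append(0.0 if i == 0 else max(0.0, best - v))
        best = min(best, v)
    return all(imp < tol for imp in improvements[-patience:])


# --------------------------------------------------------------------------
# shared helpers
# --------------------------------------------------------------------------

def _to_chw_t(image: np.ndarray) -> Tensor:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return Tensor(np.moveaxis(arr, 2, 0))


def _batched_landmarks(detector: DetectorModel, images, temperature: float):
    """One network forward over all images; per-image soft landmarks."""
    batch = ad.stack([_to_chw_t(im) for im in images], axis=0)
    maps = detector.heatmaps(batch)
    pts = []
    for i in range(len(images)):
        pts.append(spatial_argmax(maps[i], mode="soft", temperature=temperature))
    return pts


def _register(
    src_image: np.ndarray,
    tgt_pts: Tensor,
    src_pts: Tensor,
    lam: float,
    size: int,
    stop_grad: bool,
):
    """TPS-warp ``src_image`` into the frame of the target landmarks."""
    if stop_grad:
        tgt_pts, src_pts = tgt_pts.detach(), src_pts.detach()
    model = tps_fit(tgt_pts, src_pts, lam=lam, bounds=(0.0, size - 1.0, 0.0, size - 1.0))
    return tps_warp_image(model, _to_chw_t(src_image))


def _suppressed_pair(reg: Tensor, tgt: np.ndarray, threshold: float = 0.1):
    """Union-background masking of a warped Tensor and its numpy target."""
    reg_np = np.moveaxis(reg.data, 0, 2)
    tgt = np.asarray(tgt, dtype=np.float64)
    if tgt.ndim == 2:
        tgt = tgt[:, :, None]
    union = background_mask(reg_np, threshold) | background_mask(tgt, threshold)
    mask = Tensor((~union).astype(np.float64)[None, :, :])
    tgt_m = tgt.copy()
    tgt_m[union] = 0.0
    return reg * mask, Tensor(np.moveaxis(tgt_m, 2, 0))


def _joint_dropout(pts_a: Tensor, pts_b: Tensor, cfg: TrainConfig, rng):
    idx = dropout_indices(pts_a.shape[0], cfg.dropout_p, min_keep=cfg.min_keep, rng=rng)
    return pts_a[idx], pts_b[idx], idx


def _finite_or_raise(value: float, context: str) -> None:
    if not np.isfinite(value):
        raise FloatingPointError(f"non-finite loss in {context}: {value}")


# --------------------------------------------------------------------------
# pairwise regime
# --------------------------------------------------------------------------

def train_pairwise(
    sections,
    detector: DetectorModel,
    train_config: TrainConfig | None = None,
    augment_config: AugmentConfig | None = None,
    loss_weights: LossWeights | None = None,
    consistency: str = "patch",
):
    """Self-supervised pairwise training on a list of (H, W, C) sections.

    ``consistency`` selects the patch variant (homogeneous benchmark
    mode) or the whole-image variant (tissue mode with batch effects).
    Returns ``(detector, history)``; ``history["total"]`` holds
    epoch-mean total losses.
    """
    if consistency not in ("patch", "global"):
        raise ValueError("consistency must be 'patch' or 'global'")
    if len(sections) < 1:
        raise ValueError("need at least one section")
    cfg = train_config or TrainConfig()
    aug = augment_config or AugmentConfig(target_size=np.asarray(sections[0]).shape[0])
    lw = loss_weights or LossWeights()
    rng = np.random.default_rng(cfg.seed)
    size = detector.config.input_size
    temp = detector.config.softmax_temperature
    opt = Adam(detector.parameters(), lr=cfg.learning_rate)
    history = {"total": [], "base": [], "consistency": [], "lr": []}

    for epoch in range(cfg.max_epochs):
        opt.lr = lr_at_epoch(cfg, epoch)
        epoch_tot, epoch_base, epoch_cons = [], [], []
        for _ in range(cfg.iterations_per_epoch):
            images, meta = [], []
            for _ in range(cfg.batch_size):
                si = int(rng.integers(len(sections)))
                x_tgt, _ = random_augment(sections[si], aug, rng)
                x_src, _ = random_augment(sections[si], aug, rng)
                yi = int(rng.integers(len(sections)))
                images.extend([x_tgt, x_src, sections[yi]])
                meta.append((x_tgt, x_src, sections[yi]))
            pts = _batched_landmarks(detector, images, temp)
            total = None
            for b, (x_tgt, x_src, y_img) in enumerate(meta):
                p_tgt, p_src, p_y = pts[3 * b], pts[3 * b + 1], pts[3 * b + 2]
                k_tgt, k_src, idx = _joint_dropout(p_tgt, p_src, cfg, rng)
                reg = _register(x_src, k_tgt, k_src, cfg.tps_lambda, size, cfg.stop_grad_tps)
                reg_m, tgt_m = _suppressed_pair(reg, x_tgt)
                l_base = dissim(reg_m, tgt_m, window=lw.msssim_window)
                k_tgt2, k_y, _ = _joint_dropout(p_tgt, p_y, cfg, rng)
                reg_y = _register(y_img, k_tgt2, k_y, cfg.tps_lambda, size, cfg.stop_grad_tps)
                regy_m, tgty_m = _suppressed_pair(reg_y, x_tgt)
                if consistency == "patch":
                    l_cons = patch_consistency_loss(regy_m, tgty_m, k_tgt2.data, lw)
                else:
                    l_cons = global_consistency_loss(regy_m, tgty_m, lw)
                l_tot = pairwise_total_loss(l_base, l_cons, lw)
                total = l_tot if total is None else total + l_tot
                epoch_base.append(l_base.item())
                epoch_cons.append(l_cons.item())
                epoch_tot.append(l_tot.item())
            total = total * (1.0 / cfg.batch_size)
            _finite_or_raise(total.item(), "pairwise batch")
            opt.zero_grad()
            total.backward()
            opt.step()
        history["total"].append(float(np.mean(epoch_tot)))
        history["base"].append(float(np.mean(epoch_base)))
        history["consistency"].append(float(np.mean(epoch_cons)))
        history["lr"].append(opt.lr)
        if has_converged(history["total"], cfg.convergence_tol, cfg.convergence_patience):
            break
    return detector, history


# --------------------------------------------------------------------------
# z-stack regime
# --------------------------------------------------------------------------

def train_stack(
    stack,
    detector: DetectorModel,
    train_config: TrainConfig | None = None,
    augment_config: AugmentConfig | None = None,
    loss_weights: LossWeights | None = None,
):
    """Anchor-point training on an ordered serial-section stack.

    Per section i: a random reference is drawn from the stack and a
    noisy neighbor X_j from within ``neighbor_radius`` sections (i
    itself allowed); X_i is registered to the reference both rigidly
    and by TPS, X_j by TPS, and the loss mixes the TPS and rigid terms
    by the area change dA of the TPS registration.  The whole stack is
    one batch.  Returns ``(detector, history)``; history includes the
    per-epoch median dA.
    """
    sections = list(stack)
    n = len(sections)
    if n < 2:
        raise ValueError("stack needs at least 2 sections")
    cfg = train_config or TrainConfig()
    aug = augment_config or AugmentConfig(
        target_size=np.asarray(sections[0]).shape[0], elastic_sigma_range=(5.5, 5.5)
    )
    lw = loss_weights or LossWeights()
    rng = np.random.default_rng(cfg.seed)
    size = detector.config.input_size
    temp = detector.config.softmax_temperature
    opt = Adam(detector.parameters(), lr=cfg.learning_rate)
    history = {"total": [], "median_dA": [], "lr": []}

    for epoch in range(cfg.max_epochs):
        opt.lr = lr_at_epoch(cfg, epoch)
        epoch_tot, epoch_da = [], []
        for _ in range(cfg.iterations_per_epoch):
            refs = [int(rng.integers(n)) for _ in range(n)]
            js, xjs = [], []
            for i in range(n):
                lo = max(0, i - cfg.neighbor_radius)
                hi = min(n - 1, i + cfg.neighbor_radius)
                j = int(rng.integers(lo, hi + 1))
                js.append(j)
                xj, _ = random_augment(sections[j], aug, rng)
                xjs.append(xj)
            pts = _batched_landmarks(detector, sections + xjs, temp)
            total = None
            for i in range(n):
                p_i, p_ref, p_j = pts[i], pts[refs[i]], pts[n + i]
                k_ref, k_i, idx = _joint_dropout(p_ref, p_i, cfg, rng)
                xi_tps = _register(sections[i], k_ref, k_i, cfg.tps_lambda, size, cfg.stop_grad_tps)
                # rigid fit outside the tape: landmarks detached
                rt = rigid_fit(k_i.data, k_ref.data)
                xi_rigid = rigid_warp_image(rt, _to_chw_t(sections[i]).detach())
                k_ref2 = p_ref[idx]
                k_j = p_j[idx]
                xj_tps = _register(xjs[i], k_ref2, k_j, cfg.tps_lambda, size, cfg.stop_grad_tps)
                da = area_change(sections[i], np.moveaxis(xi_tps.data, 0, 2))
                l_i = stack_loss(xj_tps, xi_tps, xi_rigid, da, lw)
                total = l_i if total is None else total + l_i
                epoch_tot.append(l_i.item())
                epoch_da.append(da)
            total = total * (1.0 / n)
            _finite_or_raise(total.item(), "stack batch")
            opt.zero_grad()
            total.backward()
            opt.step()
        history["total"].append(float(np.mean(epoch_tot)))
        history["median_dA"].append(float(np.median(epoch_da)))
        history["lr"].append(opt.lr)
        if has_converged(history["total"], cfg.convergence_tol, cfg.convergence_patience):
            break
    return detector, history


# --------------------------------------------------------------------------
# multimodal regime
# --------------------------------------------------------------------------

def train_multimodal(
    sections_a,
    sections_b,
    detector_a: DetectorModel,
    detector_b: DetectorModel,
    train_config: TrainConfig | None = None,
    augment_config: AugmentConfig | None = None,
    loss_weights: LossWeights | None = None,
):
    """Joint training of two modality-specific detectors.

    Per sample: a base loss per modality (augmented self-pair), an
    intra-modality consistency loss (whole-image), and an
    inter-modality loss: a section of B is registered into a section of
    A's frame via landmarks from the respective detectors, and the RMSE
    between first-layer latents of detector A on both images (the
    latent of A is computed before registration) ties the modalities
    together.  Returns ``((detector_a, detector_b), history)``.
    """
    if not sections_a or not sections_b:
        raise ValueError("both modality lists must be non-empty")
    cfg = train_config or TrainConfig()
    aug = augment_config or AugmentConfig(target_size=np.asarray(sections_a[0]).shape[0])
    lw = loss_weights or LossWeights()
    rng = np.random.default_rng(cfg.seed)
    size = detector_a.config.input_size
    temp = detector_a.config.softmax_temperature
    opt = Adam(detector_a.parameters() + detector_b.parameters(), lr=cfg.learning_rate)
    history = {"total": [], "base": [], "intra": [], "inter": [], "lr": []}

    def modality_losses(sections, detector, pts_pair, imgs_pair):
        (p_tgt, p_src, p_y), (x_tgt, x_src, y_img) = pts_pair, imgs_pair
        k_tgt, k_src, _ = _joint_dropout(p_tgt, p_src, cfg, rng)
        reg = _register(x_src, k_tgt, k_src, cfg.tps_lambda, size, cfg.stop_grad_tps)
        reg_m, tgt_m = _suppressed_pair(reg, x_tgt)
        l_base = dissim(reg_m, tgt_m, window=lw.msssim_window)
        k_tgt2, k_y, _ = _joint_dropout(p_tgt, p_y, cfg, rng)
        reg_y = _register(y_img, k_tgt2, k_y, cfg.tps_lambda, size, cfg.stop_grad_tps)
        regy_m, tgty_m = _suppressed_pair(reg_y, x_tgt)
        l_intra = global_consistency_loss(regy_m, tgty_m, lw)
        return l_base, l_intra

    for epoch in range(cfg.max_epochs):
        opt.lr = lr_at_epoch(cfg, epoch)
        e_tot, e_base, e_intra, e_inter = [], [], [], []
        for _ in range(cfg.iterations_per_epoch):
            total = None
            for _ in range(cfg.batch_size):
                sample_imgs, sample_pts = {}, {}
                for key, secs, det in (("a", sections_a, detector_a), ("b", sections_b, detector_b)):
                    si = int(rng.integers(len(secs)))
                    x_tgt, _ = random_augment(secs[si], aug, rng)
                    x_src, _ = random_augment(secs[si], aug, rng)
                    yi = int(rng.integers(len(secs)))
                    imgs = [x_tgt, x_src, secs[yi]]
                    sample_imgs[key] = imgs
                    sample_pts[key] = _batched_landmarks(det, imgs, temp)
                l_base_a, l_intra_a = modality_losses(sections_a, detector_a, sample_pts["a"], sample_imgs["a"])
                l_base_b, l_intra_b = modality_losses(sections_b, detector_b, sample_pts["b"], sample_imgs["b"])
                # inter-modality: register a B section into an A section's frame
                ai = int(rng.integers(len(sections_a)))
                bi = int(rng.integers(len(sections_b)))
                img_a, img_b = sections_a[ai], sections_b[bi]
                pa = _batched_landmarks(detector_a, [img_a], temp)[0]
                pb = _batched_landmarks(detector_b, [img_b], temp)[0]
                ka, kb, _ = _joint_dropout(pa, pb, cfg, rng)
                z_a = detector_a.stem_activation(ad.stack([_to_chw_t(img_a)], axis=0))
                reg_b = _register(img_b, ka, kb, cfg.tps_lambda, size, cfg.stop_grad_tps)
                z_b = detector_a.stem_activation(ad.stack([reg_b], axis=0))
                l_inter = inter_consistency_loss(z_a, z_b)
                l_base = (l_base_a + l_base_b) * 0.5
                l_intra = (l_intra_a + l_intra_b) * 0.5
                l_tot = multimodal_total_loss(l_base, l_intra, l_inter, lw)
                total = l_tot if total is None else total + l_tot
                e_base.append(l_base.item())
                e_intra.append(l_intra.item())
                e_inter.append(l_inter.item())
                e_tot.append(l_tot.item())
            total = total * (1.0 / cfg.batch_size)
            _finite_or_raise(total.item(), "multimodal batch")
            opt.zero_grad()
            total.backward()
            opt.step()
        history["total"].append(float(np.mean(e_tot)))
        history["base"].append(float(np.mean(e_base)))
        history["intra"].append(float(np.mean(e_intra)))
        history["inter"].append(float(np.mean(e_inter)))
        history["lr"].append(opt.lr)
        if has_converged(history["total"], cfg.convergence_tol, cfg.convergence_patience):
            break
    return (detector_a, detector_b), history
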