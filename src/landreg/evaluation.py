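"""Benchmark metrics and reference-frame registration utilities.

Landmark quality is scored without ground-truth detector labels:

* consistency error — distance between transform-then-detect and
  detect-then-transform under a known affine (equivariance).
* forward / backward error — held-out linear-regression error
  predicting manual annotations from detections (forward) or
  detections from annotations (backward), normalized by a length scale
  (default: the image diagonal).
* TRE — mean Euclidean distance of held-out corresponding target
  points after registering a consecutive section pair.
* ATRE — the TRE accumulated along a serial stack: every section's
  target points are propagated through the composed chain of fitted
  transforms into the reference frame and the per-section mean errors
  are summed.
* k-NN region accuracy — fraction of registered points whose majority
  label among the k nearest reference points matches their true label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .augment import apply_affine_to_points
from .geometry import rigid_fit, rigid_transform_points, tps_fit, tps_transform_points, tps_warp_image

__all__ = [
    "ErrorReport",
    "consistency_error",
    "forward_error",
    "backward_error",
    "tre",
    "atre",
    "knn_region_accuracy",
    "register_to_reference",
    "SectionRegistration",
]


@dataclass
class ErrorReport:
    """Container mirroring the JSON evaluation report."""

    consistency_per_landmark: list = field(default_factory=list)
    consistency_per_image: list = field(default_factory=list)
    forward_error: float | None = None
    backward_error: float | None = None
    tre_per_pair: list = field(default_factory=list)
    atre: float | None = None
    knn_accuracy: float | None = None

    def to_dict(self) -> dict:
        return {
            "consistency_per_landmark": [float(v) for v in self.consistency_per_landmark],
            "consistency_per_image": [float(v) for v in self.consistency_per_image],
            "forward_error": self.forward_error,
            "backward_error": self.backward_error,
            "tre_per_pair": [float(v) for v in self.tre_per_pair],
            "atre": self.atre,
            "knn_accuracy": self.knn_accuracy,
        }


def _detect_fn(detector):
    return detector.detect if hasattr(detector, "detect") else detector


def _warp_affine_image(image: np.ndarray, affine: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[:, :, None]
    h, w = arr.shape[:2]
    inv = np.linalg.inv(affine)
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    src = apply_affine_to_points(inv, np.stack([xs.ravel(), ys.ravel()], axis=1))
    out = np.stack(
        [
            map_coordinates(
                arr[:, :, c], [src[:, 1].reshape(h, w), src[:, 0].reshape(h, w)],
                order=1, mode="constant", cval=0.0,
            )
            for c in range(arr.shape[2])
        ],
        axis=2,
    )
    return out[:, :, 0] if squeeze else out


def consistency_error(detector, image, affine: np.ndarray) -> np.ndarray:
    """Per-landmark distance between affine(detect(x)) and detect(affine(x))."""
    detect = _detect_fn(detector)
    pts_then_affine = apply_affine_to_points(affine, detect(np.asarray(image)))
    affine_then_pts = detect(_warp_affine_image(image, affine))
    return np.linalg.norm(pts_then_affine - affine_then_pts, axis=1)


def _regression_error(
    x: np.ndarray, y: np.ndarray, normalizer: float, seed: int, train_fraction: float
) -> float:
    """Held-out OLS error: features x (N, 2K) -> targets y (N, 2M)."""
    n = x.shape[0]
    n_train = max(int(round(n * train_fraction)), 1)
    if n - n_train < 1:
        raise ValueError(f"need at least 2 images to split, got {n}")
    order = np.random.default_rng(seed).permutation(n)
    tr, te = order[:n_train], order[n_train:]
    design = np.hstack([np.ones((n_train, 1)), x[tr]])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            f"regression design is rank deficient ({rank}/{design.shape[1]}); "
            "falling back to ridge (1e-6) — consider more images",
            RuntimeWarning,
            stacklevel=3,
        )
        a = design.T @ design + 1e-6 * np.eye(design.shape[1])
        coef = np.linalg.solve(a, design.T @ y[tr])
    else:
        coef, *_ = np.linalg.lstsq(design, y[tr], rcond=None)
    pred = np.hstack([np.ones((len(te), 1)), x[te]]) @ coef
    diff = (pred - y[te]).reshape(len(te), -1, 2)
    return float(np.linalg.norm(diff, axis=2).mean() / normalizer)


def _stack_points(point_sets) -> np.ndarray:
    return np.stack([np.asarray(p, float).ravel() for p in point_sets])


def forward_error(
    detected, annotated, normalizer: float = 1.0, seed: int = 0, train_fraction: float = 0.5
) -> float:
    """Held-out error predicting annotations from detected landmarks.

    ``detected`` and ``annotated`` are per-image lists of (K, 2) and
    (M, 2) points.  A linear regression (with intercept) is fit on a
    seeded 50/50 split; the mean held-out Euclidean error over
    annotated points is divided by ``normalizer`` (pass e.g. the image
    diagonal or an inter-landmark distance).
    """
    return _regression_error(
        _stack_points(detected), _stack_points(annotated), normalizer, seed, train_fraction
    )


def backward_error(
    detected, annotated, normalizer: float = 1.0, seed: int = 0, train_fraction: float = 0.5
) -> float:
    """Held-out error predicting detected landmarks from annotations."""
    return _regression_error(
        _stack_points(annotated), _stack_points(detected), normalizer, seed, train_fraction
    )


def tre(predicted, actual) -> float:
    """Mean Euclidean distance between predicted and actual target points."""
    p = np.asarray(predicted, dtype=np.float64)
    a = np.asarray(actual, dtype=np.float64)
    if p.shape != a.shape:
        raise ValueError("predicted/actual shapes differ")
    return float(np.linalg.norm(p - a, axis=-1).mean())


def atre(pair_transforms, target_points) -> float:
    """Accumulated TRE along a serial stack.

    ``pair_transforms[i]`` maps section-i points into section i+1
    (callable on (K, 2) arrays); ``target_points[i]`` holds the
    ground-truth positions of the common anchors in section i.  Each
    section's anchors are propagated through the composed chain into
    the final section's frame and compared with the anchors annotated
    there; ATRE is the sum over sections of the mean per-section error
    (the reference section itself contributes zero).
    """
    pts = [np.asarray(p, float) for p in target_points]
    n = len(pts)
    if len(pair_transforms) != n - 1:
        raise ValueError("need exactly one transform per consecutive pair")
    total = 0.0
    for i in range(n):
        prop = pts[i].copy()
        for t in pair_transforms[i:]:
            prop = np.asarray(t(prop), float)
        total += float(np.linalg.norm(prop - pts[-1], axis=1).mean())
    return total


def knn_region_accuracy(
    reference_points, reference_labels, registered_points, true_labels, k: int = 5
) -> float:
    """Label-transfer accuracy of a k-NN classifier on registered points.

    Ties in the neighbor vote are broken toward the smallest label
    index.
    """
    ref = np.asarray(reference_points, dtype=np.float64)
    reg = np.asarray(registered_points, dtype=np.float64)
    ref_lab = np.asarray(reference_labels)
    true_lab = np.asarray(true_labels)
    if ref.shape[0] != ref_lab.shape[0] or reg.shape[0] != true_lab.shape[0]:
        raise ValueError("points and labels must align")
    classes, ref_idx = np.unique(ref_lab, return_inverse=True)
    tree = cKDTree(ref)
    _, nbrs = tree.query(reg, k=min(k, ref.shape[0]))
    nbrs = np.atleast_2d(nbrs.T).T  # (N, k)
    correct = 0
    for i in range(reg.shape[0]):
        votes = np.bincount(ref_idx[nbrs[i]], minlength=len(classes))
        if classes[int(np.argmax(votes))] == true_lab[i]:
            correct += 1
    return correct / reg.shape[0]


# --------------------------------------------------------------------------
# registration to a common reference frame
# --------------------------------------------------------------------------

@dataclass
class SectionRegistration:
    """One section registered into the reference frame."""

    image: np.ndarray  # warped section
    landmarks: np.ndarray  # detected landmarks in the section's own frame
    transform: object  # forward model: section points -> reference frame
    backward: object  # reference-frame points -> section points (image warp)

    def transfer_points(self, points) -> np.ndarray:
        from .geometry import TPSModel

        if isinstance(self.transform, TPSModel):
            return tps_transform_points(self.transform, points)
        return rigid_transform_points(self.transform, points)


def register_to_reference(
    sections,
    detector,
    reference_index: int = 0,
    method: str = "tps",
    lam: float = 1e-6,
):
    """Warp every section into the reference section's frame.

    Landmarks are detected on each section; per section a forward
    model (section -> reference, for point transfer) and a backward
    model (reference -> section, for hole-free image warping) are
    fitted with TPS or rigid alignment.  Returns a list of
    :class:`SectionRegistration`, one per section (the reference maps
    through an identity-equivalent fit).
    """
    if method not in ("tps", "rigid"):
        raise ValueError("method must be 'tps' or 'rigid'")
    detect = _detect_fn(detector)
    sections = list(sections)
    if not 0 <= reference_index < len(sections):
        raise IndexError("reference_index out of range")
    ref_pts = np.asarray(detect(sections[reference_index]), float)
    out = []
    for sec in sections:
        pts = np.asarray(detect(sec), float)
        if method == "tps":
            fwd = tps_fit(pts, ref_pts, lam=lam)
            bwd = tps_fit(ref_pts, pts, lam=lam)
            warped = tps_warp_image(bwd, sec)
        else:
            fwd = rigid_fit(pts, ref_pts)
            bwd = fwd.inverse()
            from .geometry import rigid_warp_image

            warped = rigid_warp_image(fwd, sec)
        out.append(
            SectionRegistration(image=warped, landmarks=pts, transform=fwd, backward=bwd)
        )
    return out
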