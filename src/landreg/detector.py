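"""Heatmap landmark detector: hourglass network, spatial argmax, drop-out.

The detector is an encoder-decoder ("hourglass") convolutional network
that maps an image to K single-channel heatmaps at input resolution,
each normalized by a spatial softmax to sum to one.  Landmarks are the
per-map argmax locations; training uses a differentiable soft argmax
(softmax-weighted expected coordinate) because the hard pixel argmax
has no useful gradient.

Two capacity presets are provided: ``reference`` mirrors the roughly
six-million-parameter scale of full training runs, while ``reduced``
(under 200k parameters, two pooling levels) keeps the entire pipeline
practical on a single CPU.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, asdict

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

__all__ = [
    "DetectorConfig",
    "DetectorModel",
    "build_detector",
    "spatial_argmax",
    "landmark_dropout",
    "dropout_indices",
    "first_layer_latent",
    "save_checkpoint",
    "load_checkpoint",
]

# channel layouts per capacity preset: [stem, level1, ..., levelD]
_PRESETS = {
    "reduced": [16, 32, 32],
    "reference": [96, 192, 384, 384],
}


@dataclass
class DetectorConfig:
    """Configuration of the landmark detector.

    n_landmarks must be at least 4: the TPS fit needs three
    non-collinear points and landmark drop-out requires head-room.
    input_size must be divisible by 2**depth (the pooling factor).
    """

    n_landmarks: int = 10
    input_channels: int = 3
    input_size: int = 128
    scale: str = "reduced"
    argmax_mode: str = "soft"
    softmax_temperature: float = 0.1

    def __post_init__(self):
        if self.n_landmarks < 4:
            raise ValueError("n_landmarks must be >= 4")
        if self.scale not in _PRESETS:
            raise ValueError(f"scale must be one of {sorted(_PRESETS)}")
        if self.softmax_temperature <= 0:
            raise ValueError("softmax_temperature must be positive")
        factor = 2 ** self.depth
        if self.input_size % factor:
            raise ValueError(
                f"input_size {self.input_size} must be a multiple of the "
                f"network downsampling factor {factor}"
            )

    @property
    def channels(self) -> list:
        return _PRESETS[self.scale]

    @property
    def depth(self) -> int:
        return len(_PRESETS[self.scale]) - 1


class DetectorModel:
    """Hourglass heatmap network with explicit parameter Tensors."""

    def __init__(self, config: DetectorConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        ch = config.channels
        self.params: dict[str, Tensor] = {}

        def conv_param(name, c_in, c_out, k=3):
            std = np.sqrt(2.0 / (c_in * k * k))
            self.params[f"{name}.w"] = Tensor(
                rng.normal(0.0, std, size=(c_out, c_in, k, k)), requires_grad=True
            )
            self.params[f"{name}.b"] = Tensor(np.zeros(c_out), requires_grad=True)

        conv_param("stem", config.input_channels, ch[0])
        for i in range(1, len(ch)):
            conv_param(f"enc{i}", ch[i - 1], ch[i])
        conv_param("bottleneck", ch[-1], ch[-1])
        for i in range(len(ch) - 1, 0, -1):
            conv_param(f"dec{i}", ch[i], ch[i - 1])
        conv_param("head", ch[0], config.n_landmarks, k=1)

    # -- introspection --------------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def parameters(self) -> list:
        return [self.params[k] for k in sorted(self.params)]

    def _conv(self, name, x, padding):
        return ad.conv2d(x, self.params[f"{name}.w"], self.params[f"{name}.b"], padding=padding)

    # -- forward passes -------------------------------------------------------
    def stem_activation(self, x: Tensor) -> Tensor:
        """Post-nonlinearity activation of the first convolutional block."""
        return self._conv("stem", x, padding=1).relu()

    def heatmaps(self, x) -> Tensor:
        """Forward pass: (N, C, H, W) -> (N, K, H, W) spatial-softmax maps."""
        x = ad.as_tensor(x)
        if x.ndim != 4:
            raise ValueError("expected a (N, C, H, W) batch")
        n, c, h, w = x.shape
        cfg = self.config
        if c != cfg.input_channels or h != cfg.input_size or w != cfg.input_size:
            raise ValueError(
                f"input {x.shape} does not match configured "
                f"({cfg.input_channels}, {cfg.input_size}, {cfg.input_size})"
            )
        ch = cfg.channels
        skips = [self.stem_activation(x)]
        y = skips[0]
        for i in range(1, len(ch)):
            y = self._conv(f"enc{i}", ad.avg_pool2d(y, 2), padding=1).relu()
            skips.append(y)
        y = self._conv("bottleneck", y, padding=1).relu()
        for i in range(len(ch) - 1, 0, -1):
            y = (self._conv(f"dec{i}", ad.upsample_nearest(y, 2), padding=1) + skips[i - 1]).relu()
        logits = self._conv("head", y, padding=0)  # (N, K, H, W)
        k = cfg.n_landmarks
        flat = logits.reshape(n, k, h * w)
        return ad.softmax(flat, axis=2).reshape(n, k, h, w)

    def detect(self, image: np.ndarray) -> np.ndarray:
        """Detect landmarks on one (H, W, C) image; returns (K, 2) xy pixels.

        Uses the configured argmax mode: the default soft mode reports
        sub-pixel expected coordinates of the temperature-sharpened
        heatmaps; hard mode reports the integer maxima.
        """
        arr = np.asarray(image, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        batch = Tensor(np.moveaxis(arr, 2, 0)[None])
        maps = self.heatmaps(batch)
        pts = spatial_argmax(
            maps.data[0],
            mode=self.config.argmax_mode,
            temperature=self.config.softmax_temperature,
        )
        return np.asarray(pts)


def build_detector(config: DetectorConfig, seed: int = 0) -> DetectorModel:
    """Build a detector with deterministic seeded initialization."""
    return DetectorModel(config, seed=seed)


def spatial_argmax(heatmaps, mode: str = "hard", temperature: float = 0.1):
    """Extract one (x, y) location per heatmap.

    hard mode returns the integer coordinates of each map's maximum
    (ties broken by the smallest row-major index); soft mode returns the
    expected coordinate under the temperature-sharpened distribution
    ``p ∝ h**(1/temperature)`` — for heatmaps produced by a spatial
    softmax this equals a softmax over the logits divided by the
    temperature, and it converges to the hard argmax as the temperature
    vanishes.  This is the differentiable surrogate used in training.
    ``heatmaps`` is (K, H, W), numpy or Tensor (Tensor only for soft
    mode).
    """
    if mode not in ("hard", "soft"):
        raise ValueError("mode must be 'hard' or 'soft'")
    is_t = isinstance(heatmaps, Tensor)
    data = heatmaps.data if is_t else np.asarray(heatmaps, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError("heatmaps must be (K, H, W)")
    k, h, w = data.shape
    sums = data.reshape(k, -1).sum(axis=1)
    if np.any(sums < 1e-12):
        bad = int(np.argmin(sums))
        raise ValueError(f"heatmap {bad} is all zero; argmax is undefined")
    if mode == "hard":
        flat_idx = data.reshape(k, -1).argmax(axis=1)
        ys, xs = np.unravel_index(flat_idx, (h, w))
        return np.stack([xs, ys], axis=1).astype(np.float64)
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    xs, ys = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    coords = np.stack([xs.ravel(), ys.ravel()], axis=1)  # (HW, 2)
    hm = heatmaps if is_t else Tensor(data)
    log_h = hm.reshape(k, h * w).clamp_min(1e-12).log()
    probs = ad.softmax(log_h * (1.0 / temperature), axis=1)
    out = probs @ Tensor(coords)
    return out if is_t else out.data


def dropout_indices(
    n_landmarks: int, p: float, min_keep: int = 4, rng=None
) -> np.ndarray:
    """Sample the kept-landmark index subset for landmark drop-out.

    Each landmark is dropped independently with probability ``p``; the
    draw is repeated until at least ``min_keep`` survive.  Applying the
    SAME subset to both point lists of a pair is the caller's contract.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError("drop probability must be in [0, 1)")
    if min_keep < 3:
        raise ValueError("min_keep must be >= 3 (TPS degenerates below 3)")
    if n_landmarks < min_keep:
        raise ValueError("cannot keep more landmarks than exist")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    while True:
        keep = rng.random(n_landmarks) >= p
        if keep.sum() >= min_keep:
            return np.flatnonzero(keep)


def landmark_dropout(landmarks, p: float, min_keep: int = 4, rng=None):
    """Randomly remove landmarks (kept subset resampled until >= min_keep)."""
    pts = landmarks if isinstance(landmarks, Tensor) else np.asarray(landmarks, float)
    idx = dropout_indices(pts.shape[0], p, min_keep=min_keep, rng=rng)
    return pts[idx]


def first_layer_latent(model: DetectorModel, image) -> Tensor:
    """Activations of the first conv block (post-ReLU, before pooling).

    ``image`` is (H, W, C) numpy or a (N, C, H, W) Tensor; the returned
    Latent has shape (N, F, H, W) and is gradient-capable for Tensor
    inputs.
    """
    if isinstance(image, Tensor):
        x = image
    else:
        arr = np.asarray(image, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        x = Tensor(np.moveaxis(arr, 2, 0)[None])
    cfg = model.config
    if x.shape[1] != cfg.input_channels or x.shape[2] != cfg.input_size:
        raise ValueError(
            f"input {x.shape} does not match configured "
            f"({cfg.input_channels}, {cfg.input_size}, {cfg.input_size})"
        )
    return model.stem_activation(x)


# --------------------------------------------------------------------------
# checkpoints: single .npz file carrying weights + config + seed
# --------------------------------------------------------------------------

def save_checkpoint(path, model: DetectorModel) -> None:
    """Write weights + config + seed as an .npz with reproducible bytes.

    The zip entries carry a fixed timestamp so identical models produce
    bit-identical files (np.savez would embed the wall clock).
    """
    import zipfile

    arrays = {f"param/{k}": v.data for k, v in model.params.items()}
    meta = json.dumps({"config": asdict(model.config), "seed": model.seed}, sort_keys=True)
    arrays["__meta__"] = np.frombuffer(meta.encode(), dtype=np.uint8)
    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        for name in sorted(arrays):
            buf = _io.BytesIO()
            np.lib.format.write_array(buf, np.asarray(arrays[name]))
            info = zipfile.ZipInfo(name + ".npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())


def load_checkpoint(path) -> DetectorModel:
    blob = np.load(path)
    meta = json.loads(bytes(blob["__meta__"]).decode())
    model = DetectorModel(DetectorConfig(**meta["config"]), seed=meta["seed"])
    for k in model.params:
        model.params[k].data[...] = blob[f"param/{k}"]
    return model
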