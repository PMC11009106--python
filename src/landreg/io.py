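"""File interchange: landmark CSVs, image directories, raster stacks."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_image",
    "write_image",
    "read_section_dir",
    "write_channel_tiff",
]


def read_landmarks_csv(path) -> dict:
    """Read landmarks as ``{section_id: (K, 2) array}``.

    The CSV has one header line and columns section_id, landmark_id
    (0-based; the ordering that identifies each landmark across
    sections), x, y in pixel coordinates.
    """
    df = pd.read_csv(path)
    missing = {"section_id", "landmark_id", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"landmark CSV lacks columns {sorted(missing)}")
    out = {}
    for sid, grp in df.groupby("section_id", sort=False):
        grp = grp.sort_values("landmark_id")
        ids = grp["landmark_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError(f"section {sid!r}: landmark_id must be 0..K-1 without gaps")
        out[sid] = grp[["x", "y"]].to_numpy(float)
    return out


def write_landmarks_csv(path, landmarks: dict) -> None:
    """Write ``{section_id: (K, 2)}`` landmark sets to CSV."""
    rows = []
    for sid, pts in landmarks.items():
        for li, (x, y) in enumerate(np.asarray(pts, float)):
            rows.append({"section_id": sid, "landmark_id": li, "x": x, "y": y})
    pd.DataFrame(rows, columns=["section_id", "landmark_id", "x", "y"]).to_csv(
        path, index=False
    )


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as float64 in [0, 1], (H, W[, C])."""
    arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return arr.astype(np.float64)


def write_image(path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit PNG/TIFF."""
    arr = np.clip(np.asarray(image, float), 0.0, 1.0)
    iio.imwrite(path, (arr * 255.0 + 0.5).astype(np.uint8))


def read_section_dir(path, suffixes=(".png", ".tif", ".tiff")) -> list:
    """Read an ordered section stack from a directory (sorted by name)."""
    files = sorted(p for p in Path(path).iterdir() if p.suffix.lower() in suffixes)
    if not files:
        raise FileNotFoundError(f"no images with suffixes {suffixes} in {path}")
    return [read_image(p) for p in files]


def write_channel_tiff(path, image: np.ndarray) -> None:
    """Write an (H, W, C) raster as a multi-page float32 TIFF (one page per channel)."""
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    tifffile.imwrite(path, np.moveaxis(arr, 2, 0))
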