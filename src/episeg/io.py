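"""Reading and writing of images, masks and result metadata."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .preprocessing import validate_rgb


def read_rgb(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB PNG/TIFF; alpha channels are rejected."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:
        raise ValueError(f"{path}: alpha channel not supported; flatten the image first")
    return validate_rgb(arr)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as a single-channel PNG with {0, 255} encoding."""
    m = np.asarray(mask, dtype=bool)
    iio.imwrite(path, (m.astype(np.uint8) * 255))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask image; any non-zero pixel is foreground."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=2)
    return arr > 0


def write_plane(path: str | Path, plane: np.ndarray) -> None:
    """Write a [0, 1] scalar plane as an 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(plane, dtype=np.float64), 0, 1)
    iio.imwrite(path, np.round(arr * 255).astype(np.uint8))


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
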