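"""Stain/lighting normalisation by per-channel cumulative-histogram matching.

Section thickness, staining batch and lamp colour all shift the RGB
histograms of H&E slides.  Each colour channel of the input is remapped by a
monotone grayscale transform chosen so that the cumulative histogram of the
transformed tissue pixels matches that of a reference image judged well
stained.  Only tissue (sample-mask) pixels take part — background pixels
neither influence the transform nor are modified by it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocessing import validate_rgb

N_LEVELS = 256


@dataclass
class ReferenceProfile:
    """Per-channel normalised cumulative histograms of a reference image.

    ``cdfs`` has shape (3, 256); each row is non-decreasing and ends at 1.
    """

    cdfs: np.ndarray
    source: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.cdfs = np.asarray(self.cdfs, dtype=np.float64)
        if self.cdfs.shape != (3, N_LEVELS):
            raise ValueError("cdfs must have shape (3, 256)")
        if np.any(np.diff(self.cdfs, axis=1) < -1e-12):
            raise ValueError("cumulative histograms must be non-decreasing")
        if not np.allclose(self.cdfs[:, -1], 1.0):
            raise ValueError("cumulative histograms must end at 1.0")

    def to_json(self, path: str | Path) -> None:
        payload = {"source": self.source, "cdfs": self.cdfs.tolist()}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceProfile":
        payload = json.loads(Path(path).read_text())
        return cls(cdfs=np.asarray(payload["cdfs"]), source=payload.get("source"))


def _channel_cdf(values: np.ndarray) -> np.ndarray:
    counts = np.bincount(values.ravel(), minlength=N_LEVELS).astype(np.float64)
    return np.cumsum(counts) / counts.sum()


def build_reference_profile(
    reference: np.ndarray, reference_sample_mask: np.ndarray, source: str | None = None
) -> ReferenceProfile:
    """Cumulative histograms of the reference image over its tissue pixels."""
    ref = validate_rgb(reference)
    mask = np.asarray(reference_sample_mask, dtype=bool)
    if mask.shape != ref.shape[:2]:
        raise ValueError("mask shape does not match reference image")
    if not mask.any():
        raise ValueError("reference sample mask is empty")
    cdfs = np.stack([_channel_cdf(ref[..., c][mask]) for c in range(3)])
    return ReferenceProfile(cdfs=cdfs, source=source)


def matching_transform(c_input: np.ndarray, c_ref: np.ndarray) -> np.ndarray:
    """Monotone level map minimising |c_ref(T(k)) - c_input(k)| per level.

    For each input level k the output level is the argmin over all 256
    candidates of the cumulative-histogram discrepancy, ties broken toward
    the lower output level.  Because both cumulative histograms are
    non-decreasing the resulting map is monotone non-decreasing.
    """
    c_input = np.asarray(c_input, dtype=np.float64)
    c_ref = np.asarray(c_ref, dtype=np.float64)
    diff = np.abs(c_ref[None, :] - c_input[:, None])  # (input level, output level)
    return np.argmin(diff, axis=1).astype(np.uint8)


def normalise_colour(
    image: np.ndarray, sample_mask: np.ndarray, profile: ReferenceProfile
) -> np.ndarray:
    """Remap each channel of the tissue pixels onto the reference histogram.

    Non-sample pixels pass through bit-identical.
    """
    arr = validate_rgb(image)
    mask = np.asarray(sample_mask, dtype=bool)
    if mask.shape != arr.shape[:2]:
        raise ValueError("mask shape does not match image")
    if not mask.any():
        raise ValueError("sample mask is empty")
    out = arr.copy()
    for c in range(3):
        channel = arr[..., c]
        c_in = _channel_cdf(channel[mask])
        t = matching_transform(c_in, profile.cdfs[c])
        out[..., c][mask] = t[channel[mask]]
    return out
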