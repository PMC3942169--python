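"""Otsu thresholding of the fused contrast plane over tissue pixels.

The fused plane is approximately bimodal — a bright epidermis component and
a darker dermis component — so the classical between-class-variance
criterion separates them.  The histogram is built strictly over sample
(tissue) pixels: background pixels were zeroed upstream and would otherwise
dominate the lower class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ThresholdResult:
    """Chosen threshold level (a bin boundary on [0, 1]), the between-class
    variance achieved there, and the histogram it was computed from."""

    level: float
    between_class_variance: float
    histogram: np.ndarray


def otsu_level(
    plane: np.ndarray, sample_mask: np.ndarray, bins: int = 256
) -> ThresholdResult:
    """Threshold maximising between-class variance of binned sample pixels.

    Intensities in [0, 1] are binned into ``bins`` equal bins; every bin
    boundary is a candidate cut and the one maximising the between-class
    variance (bin centres as class values) is returned, ties broken toward
    the lower level.
    """
    arr = np.asarray(plane, dtype=np.float64)
    mask = np.asarray(sample_mask, dtype=bool)
    if mask.shape != arr.shape:
        raise ValueError("mask shape does not match plane")
    vals = arr[mask]
    if vals.size == 0 or np.unique(vals).size < 2:
        raise ValueError("degenerate histogram: need at least two distinct sample values")

    idx = np.clip((vals * bins).astype(np.int64), 0, bins - 1)
    hist = np.bincount(idx, minlength=bins).astype(np.float64)

    p = hist / hist.sum()
    centres = (np.arange(bins) + 0.5) / bins
    omega = np.cumsum(p)                # class-0 weight for cut after bin t
    mu = np.cumsum(p * centres)         # class-0 unnormalised mean
    mu_total = mu[-1]

    w0 = omega[:-1]
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros(bins - 1)
    num = (mu_total * w0 - mu[:-1]) ** 2
    sigma_b[valid] = num[valid] / (w0[valid] * w1[valid])
    t = int(np.argmax(sigma_b))  # first maximum = lowest level on ties
    level = (t + 1) / bins
    return ThresholdResult(
        level=level,
        between_class_variance=float(sigma_b[t]),
        histogram=hist.astype(np.int64),
    )


def apply_level(
    plane: np.ndarray, sample_mask: np.ndarray, level: float
) -> np.ndarray:
    """Binary mask: 1 where plane > level and the pixel is tissue, else 0."""
    arr = np.asarray(plane, dtype=np.float64)
    mask = np.asarray(sample_mask, dtype=bool)
    if mask.shape != arr.shape:
        raise ValueError("mask shape does not match plane")
    if not (0.0 <= level <= 1.0):
        raise ValueError("level must lie in [0, 1]")
    return (arr > level) & mask
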