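"""Independent brute-force oracles used to validate the implementation.

Everything here is written from first principles (nested loops, exhaustive
search, textbook formulas) and deliberately shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def mode_of_nonzero_composite(image: np.ndarray) -> int:
    """Exhaustive 766-bin histogram argmax of nonzero K = R+G+B."""
    counts = np.zeros(766, dtype=np.int64)
    k = image.astype(np.int64).sum(axis=2)
    for v in k.ravel():
        if v > 0:
            counts[v] += 1
    return int(np.argmax(counts))


def mean_filter_interior(image: np.ndarray, size: int) -> np.ndarray:
    """Nested-loop window averages; defined on interior pixels only."""
    arr = np.asarray(image, dtype=np.float64)
    h, w = arr.shape[:2]
    r = size // 2
    out = np.full_like(arr, np.nan)
    for i in range(r, h - r):
        for j in range(r, w - r):
            out[i, j] = arr[i - r : i + r + 1, j - r : j + r + 1].mean(axis=(0, 1))
    return out


def shift_dilate(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Set-definition dilation: union of the mask shifted by every SE offset."""
    m = np.asarray(mask, dtype=bool)
    r = se.shape[0] // 2
    out = np.zeros_like(m)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if not se[dy + r, dx + r]:
                continue
            shifted = np.zeros_like(m)
            ys = slice(max(dy, 0), m.shape[0] + min(dy, 0))
            yd = slice(max(-dy, 0), m.shape[0] + min(-dy, 0))
            xs = slice(max(dx, 0), m.shape[1] + min(dx, 0))
            xd = slice(max(-dx, 0), m.shape[1] + min(-dx, 0))
            shifted[ys, xs] = m[yd, xd]
            out |= shifted
    return out


def shift_erode(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Set-definition erosion: intersection of shifts; out-of-frame = 0."""
    m = np.asarray(mask, dtype=bool)
    r = se.shape[0] // 2
    out = np.ones_like(m)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if not se[dy + r, dx + r]:
                continue
            shifted = np.zeros_like(m)  # beyond the frame counts as background
            ys = slice(max(-dy, 0), m.shape[0] + min(-dy, 0))
            yd = slice(max(dy, 0), m.shape[0] + min(dy, 0))
            xs = slice(max(-dx, 0), m.shape[1] + min(-dx, 0))
            xd = slice(max(dx, 0), m.shape[1] + min(dx, 0))
            shifted[ys, xs] = m[yd, xd]
            out &= shifted
    return out


def shift_close(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Infinite-plane closing restricted to the frame (pad, compose, crop)."""
    r = se.shape[0] // 2
    m = np.pad(np.asarray(mask, dtype=bool), r, constant_values=False)
    out = shift_erode(shift_dilate(m, se), se)
    return out[r : out.shape[0] - r, r : out.shape[1] - r] if r else out


def shift_open(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Infinite-plane opening restricted to the frame."""
    r = se.shape[0] // 2
    m = np.pad(np.asarray(mask, dtype=bool), r, constant_values=False)
    out = shift_dilate(shift_erode(m, se), se)
    return out[r : out.shape[0] - r, r : out.shape[1] - r] if r else out


def exhaustive_otsu(values: np.ndarray, bins: int = 256) -> tuple[int, float]:
    """Try all cuts of the binned histogram; maximise between-class variance.

    Returns (cut index t, variance); a cut after bin t means level (t+1)/bins.
    """
    idx = np.clip((np.asarray(values, dtype=np.float64) * bins).astype(int), 0, bins - 1)
    hist = np.bincount(idx, minlength=bins).astype(np.float64)
    total = hist.sum()
    centres = (np.arange(bins) + 0.5) / bins
    best_t, best_var = 0, -1.0
    for t in range(bins - 1):
        w0 = hist[: t + 1].sum() / total
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            var = 0.0
        else:
            mu0 = (hist[: t + 1] * centres[: t + 1]).sum() / (w0 * total)
            mu1 = (hist[t + 1 :] * centres[t + 1 :]).sum() / (w1 * total)
            var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_t, best_var = t, var
    return best_t, best_var


def cdf_match_transform(c_in: np.ndarray, c_ref: np.ndarray) -> np.ndarray:
    """Per-level exhaustive argmin over all 256 output levels."""
    t = np.zeros(256, dtype=int)
    for k in range(256):
        best_j, best = 0, np.inf
        for j in range(256):
            d = abs(c_ref[j] - c_in[k])
            if d < best:  # strict: ties stay at the lower level
                best_j, best = j, d
        t[k] = best_j
    return t


def srgb_to_lab(rgb: tuple[float, float, float]) -> tuple[float, float, float]:
    """Textbook sRGB (8-bit) -> XYZ (D65/2°) -> CIE L*a*b*."""

    def inv_gamma(u: float) -> float:
        u /= 255.0
        return u / 12.92 if u <= 0.04045 else ((u + 0.055) / 1.055) ** 2.4

    r, g, b = (inv_gamma(c) for c in rgb)
    x = 0.412456439089692 * r + 0.357576077643909 * g + 0.180437483266399 * b
    y = 0.212672851405623 * r + 0.715152155287818 * g + 0.0721749933075596 * b
    z = 0.0193338955823293 * r + 0.119192025881303 * g + 0.950304078536368 * b
    xn, yn, zn = 0.95047, 1.0, 1.08883

    def f(t: float) -> float:
        eps = (6 / 29) ** 3
        return t ** (1 / 3) if t > eps else t / (3 * (6 / 29) ** 2) + 4 / 29

    fx, fy, fz = f(x / xn), f(y / yn), f(z / zn)
    return 116 * fy - 16, 500 * (fx - fy), 200 * (fy - fz)


def channel_emd(a: np.ndarray, b: np.ndarray) -> float:
    """1-D earth-mover distance between two 8-bit sample sets via CDFs."""
    ca = np.cumsum(np.bincount(a.ravel(), minlength=256)) / a.size
    cb = np.cumsum(np.bincount(b.ravel(), minlength=256)) / b.size
    return float(np.abs(ca - cb).sum())
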