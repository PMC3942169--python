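"""Pixel-level evaluation of a segmentation against a manual ground truth.

The algorithm mask A_s and the manually marked truth A_t are compared over
the cropped frame (so an excess of background pixels cannot inflate the
scores): TP = |A_s ∩ A_t|, FP = |A_s \\ A_t|, FN = |A_t \\ A_s|,
TN = the rest.  Sensitivity = 100·TP/(TP+FN) measures how well epidermis
pixels are found, specificity = 100·TN/(TN+FP) how well non-epidermis
pixels are rejected, accuracy = 100·(TP+TN)/area combines the two.

Ground truth can also be ingested from mark-up images where an expert drew
the epidermis boundary in saturated green on the RGB image; the outline is
detected in the red/green channels and flood-filled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocessing import validate_rgb


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts and percentage metrics of one mask comparison."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    accuracy: float
    image_area: int

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "image_area": self.image_area,
        }

    def to_csv_line(self, header: bool = False) -> str:
        if header:
            return "tp,fp,fn,tn,sensitivity,specificity,accuracy,image_area"
        return (
            f"{self.tp},{self.fp},{self.fn},{self.tn},"
            f"{self.sensitivity},{self.specificity},{self.accuracy},{self.image_area}"
        )


def confusion_counts(a_s: np.ndarray, a_t: np.ndarray) -> EvalReport:
    """Confusion matrix and percentage metrics for algorithm vs truth masks."""
    s = np.asarray(a_s, dtype=bool)
    t = np.asarray(a_t, dtype=bool)
    if s.shape != t.shape:
        raise ValueError("mask shapes differ")
    tp = int(np.count_nonzero(s & t))
    fp = int(np.count_nonzero(s & ~t))
    fn = int(np.count_nonzero(~s & t))
    tn = int(np.count_nonzero(~s & ~t))
    area = s.size

    if tp + fn == 0:
        warnings.warn("no truth foreground pixels; sensitivity undefined")
        sens = math.nan
    else:
        sens = 100.0 * tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no truth background pixels; specificity undefined")
        spec = math.nan
    else:
        spec = 100.0 * tn / (tn + fp)
    acc = 100.0 * (tp + tn) / area
    return EvalReport(tp=tp, fp=fp, fn=fn, tn=tn, sensitivity=sens,
                      specificity=spec, accuracy=acc, image_area=area)


def truth_from_outline(
    marked: np.ndarray, red_max: int = 100, green_min: int = 150
) -> np.ndarray:
    """Binary truth mask from a green-outlined mark-up image.

    Outline pixels are detected where the red channel is low and the green
    channel high (a saturated green pen stroke on H&E material, which is
    itself red-dominated); enclosed interiors are flood-filled and the
    boundary stroke is included in the mask.  If no interior is enclosed
    (open contour) the boundary alone is returned with a warning.
    """
    arr = validate_rgb(marked)
    boundary = (arr[..., 0] < red_max) & (arr[..., 1] > green_min)
    if not boundary.any():
        raise ValueError("no outline pixels found")
    filled = ndimage.binary_fill_holes(boundary)
    if np.array_equal(filled, boundary):
        warnings.warn("outline encloses no interior (open contour?)")
    return filled


def summarise_reports(reports: list[EvalReport]) -> dict:
    """Mean, SEM, max, min of each percentage metric over a batch."""
    if not reports:
        raise ValueError("empty batch")
    out: dict = {"n": len(reports)}
    for metric in ("sensitivity", "specificity", "accuracy"):
        vals = np.array([getattr(r, metric) for r in reports], dtype=np.float64)
        sem = 0.0 if len(vals) < 2 else float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
        out[metric] = {
            "mean": float(np.nanmean(vals)),
            "sem": sem,
            "max": float(np.nanmax(vals)),
            "min": float(np.nanmin(vals)),
        }
    return out
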