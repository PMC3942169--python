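"""Morphological clean-up and shape classification of the coarse mask.

Closing then opening with a disk structuring element smooths the ragged
Otsu mask; small objects (stained debris, dermal cell clusters) are removed
and small holes (vacuoles, intraepidermal structures) filled.  Surviving
connected components are classified by area and extent: the epidermis is a
long thin undulating band, so its axis-aligned bounding box is mostly
empty (low extent), unlike the compact cell clusters of the dermis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .preprocessing import remove_small_components

FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def disk_element(radius: int) -> np.ndarray:
    """Exact Euclidean disk structuring element: 1 iff distance <= radius."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    y, x = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return (x * x + y * y) <= radius * radius


def dilate(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Binary dilation; out-of-frame neighbourhood treated as background."""
    return ndimage.binary_dilation(np.asarray(mask, dtype=bool), structure=se)


def erode(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Binary erosion; out-of-frame neighbourhood treated as background."""
    return ndimage.binary_erosion(
        np.asarray(mask, dtype=bool), structure=se, border_value=0
    )


def _padded(op_first, op_second, mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    # compose on a background-padded frame so the result matches the
    # set-theoretic composition on the infinite plane (a plain in-frame
    # composition would eat foreground at the frame border)
    r = se.shape[0] // 2
    m = np.pad(np.asarray(mask, dtype=bool), r, constant_values=False)
    out = op_second(op_first(m, se), se)
    return out[r : out.shape[0] - r, r : out.shape[1] - r] if r else out


def binary_close(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Closing (dilate then erode): bridges gaps, shrinks holes."""
    return _padded(dilate, erode, mask, se)


def binary_open(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Opening (erode then dilate): removes protrusions and thin bridges."""
    return _padded(erode, dilate, mask, se)


def fill_small_holes(mask: np.ndarray, max_hole_px: int) -> np.ndarray:
    """Fill 4-connected background holes strictly smaller than max_hole_px.

    A hole is a background component not connected to the frame border;
    larger holes (e.g. genuine dermis enclosed by epidermis in oblique
    sections) are preserved.
    """
    m = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(~m, structure=FOUR_CONNECTED)
    if n == 0:
        return m.copy()
    border = np.zeros(n + 1, dtype=bool)
    for edge in (labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]):
        border[np.unique(edge)] = True
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    fill = ~border & (sizes < max_hole_px)
    fill[0] = False
    return m | fill[labels]


def morph_refine(
    bw: np.ndarray,
    sample_mask: np.ndarray | None = None,
    se_radius: int = 8,
    min_object_px: int = 4000,
    max_hole_px: int = 7000,
    close_open: bool = True,
) -> np.ndarray:
    """Four-step refinement of the thresholded mask.

    close(disk) -> open(disk) -> remove 8-connected foreground objects
    smaller than ``min_object_px`` -> fill 4-connected holes smaller than
    ``max_hole_px``.  If ``sample_mask`` is given, any pixels outside the
    tissue that morphology may have switched on are reset to background.
    The close/open pair only simplifies object perimeters and can be
    disabled with ``close_open=False``.
    """
    m = np.asarray(bw, dtype=bool)
    if close_open:
        se = disk_element(se_radius)
        m = binary_close(m, se)
        m = binary_open(m, se)
    m = remove_small_components(m, min_object_px)
    m = fill_small_holes(m, max_hole_px)
    if sample_mask is not None:
        m = m & np.asarray(sample_mask, dtype=bool)
    return m


@dataclass
class RegionFeatures:
    """Shape summary and classification decision of one 8-connected component."""

    label: int
    area: int
    bbox_area: int
    extent: float
    bbox: tuple[int, int, int, int]  # (row_start, row_end, col_start, col_end)
    decision: str | None = None       # "retained" | "removed"
    reason: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.extent <= 1.0 + 1e-12):
            raise ValueError("extent must lie in (0, 1]")
        if self.area > self.bbox_area:
            raise ValueError("area cannot exceed bounding-box area")


def label_components(mask: np.ndarray) -> np.ndarray:
    """8-connected component labelling (deterministic label order)."""
    return measure.label(np.asarray(mask, dtype=bool), connectivity=2)


def measure_regions(mask: np.ndarray) -> list[RegionFeatures]:
    """Area, bounding-box area and extent of every 8-connected component."""
    labels = label_components(mask)
    out: list[RegionFeatures] = []
    for prop in measure.regionprops(labels):
        r0, c0, r1, c1 = prop.bbox
        bbox_area = (r1 - r0) * (c1 - c0)
        out.append(
            RegionFeatures(
                label=int(prop.label),
                area=int(prop.area),
                bbox_area=int(bbox_area),
                extent=float(prop.area / bbox_area),
                bbox=(r0, r1, c0, c1),
            )
        )
    return out


def classify_objects(
    regions: list[RegionFeatures],
    area_min: int = 20000,
    extent_max: float = 0.44,
    area_veto: int | None = 200000,
) -> list[RegionFeatures]:
    """Label each component epidermis (retained) or non-epidermis (removed).

    A component is retained iff its area is at least ``area_min`` and it is
    either elongated (extent <= ``extent_max``) or so large that the
    compactness rule is vetoed (area >= ``area_veto``).  ``area_veto=None``
    disables the veto clause.  Decisions are recorded in place with a
    machine-readable reason and the list is returned for chaining.
    """
    for r in regions:
        if r.area < area_min:
            r.decision, r.reason = "removed", "area_below_min"
        elif r.extent <= extent_max:
            r.decision, r.reason = "retained", "elongated_shape"
        elif area_veto is not None and r.area >= area_veto:
            r.decision, r.reason = "retained", "large_area_veto"
        else:
            r.decision, r.reason = "removed", "compact_shape"
    return regions


def mask_from_decisions(
    mask: np.ndarray,
    regions: list[RegionFeatures],
    extra_include: set[int] | None = None,
    exclude: set[int] | None = None,
) -> np.ndarray:
    """Rebuild a mask from classified regions with optional id overrides."""
    labels = label_components(mask)
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for r in regions:
        keep[r.label] = r.decision == "retained"
    if extra_include:
        for i in extra_include:
            keep[i] = True
    if exclude:
        for i in exclude:
            keep[i] = False
    keep[0] = False
    return keep[labels]


def apply_overrides(
    mask: np.ndarray,
    regions: list[RegionFeatures],
    include_ids: list[int] | None = None,
    exclude_ids: list[int] | None = None,
) -> np.ndarray:
    """Final mask = retained components - exclude_ids + include_ids.

    ``mask`` is the refined (pre-classification) mask whose labelling
    produced ``regions``.  Ids must refer to measured components; unknown
    ids raise with the list of valid ids.  This is the scriptable core of
    the approve/remove/add interaction step.
    """
    include = set(include_ids or [])
    exclude = set(exclude_ids or [])
    valid = {r.label for r in regions}
    unknown = (include | exclude) - valid
    if unknown:
        raise ValueError(
            f"unknown region id(s) {sorted(unknown)}; valid ids: {sorted(valid)}"
        )
    out = mask_from_decisions(mask, regions, extra_include=include, exclude=exclude)
    if not out.any():
        warnings.warn("override removed every region; final mask is empty")
    return out
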