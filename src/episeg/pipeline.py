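"""End-to-end segmentation pipeline and batch evaluation.

Stage order: background modelling -> tiling-border replacement -> content
cropping -> sample-mask extraction -> stain normalisation (optional, needs a
reference) -> contrast enhancement and fusion -> Otsu thresholding ->
morphological refinement -> object classification -> id-based overrides.
The whole pipeline is deterministic: identical input and configuration give
bit-identical masks.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import binarisation, contrast, evaluation, normalisation, preprocessing, refinement
from .io import read_rgb

logger = logging.getLogger("episeg")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline, defaulting to the optimised values."""

    # sample segmentation / cropping
    sample_smooth: int = 29
    bg_offset: float = 9.6
    sample_min_object: int = 25000
    # colour normalisation
    normalise: bool = True
    reference: str | None = None      # path to reference image or profile JSON
    # contrast model
    gray_p_low: float = 0.291
    bstar_p_low: float = 0.367
    p_high: float = 1.0
    enhance_smooth: int = 41
    # morphological refinement
    close_open: bool = True
    se_radius: int = 8
    refine_min_object: int = 4000
    refine_max_hole: int = 7000
    # object classification
    area_min: int = 20000
    extent_max: float = 0.44
    area_veto: int | None = 200000
    # user interaction
    interactive: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class SegmentationResult:
    """Everything one segmentation run produced.

    ``mask`` is in original-frame coordinates; ``mask_cropped``,
    ``sample_mask`` and the region table live in the cropped frame used for
    processing and evaluation.  ``crop_box`` maps between the two.
    """

    mask: np.ndarray
    mask_cropped: np.ndarray
    sample_mask: np.ndarray
    crop_box: tuple[int, int, int, int]
    otsu: binarisation.ThresholdResult
    regions: list[refinement.RegionFeatures]
    refined_mask: np.ndarray  # pre-classification, for overrides
    config: PipelineConfig
    timings: dict = field(default_factory=dict)
    overrides: dict = field(default_factory=dict)
    normalised: bool = False

    def metadata(self) -> dict:
        return {
            "crop_box": list(self.crop_box),
            "otsu_level": self.otsu.level,
            "otsu_between_class_variance": self.otsu.between_class_variance,
            "normalised": self.normalised,
            "regions": [
                {"label": r.label, "area": r.area, "bbox_area": r.bbox_area,
                 "extent": round(r.extent, 6), "decision": r.decision,
                 "reason": r.reason}
                for r in self.regions
            ],
            "overrides": self.overrides,
            "config": self.config.to_dict(),
            "timings": {k: round(v, 4) for k, v in self.timings.items()},
        }


def _resolve_profile(
    config: PipelineConfig,
    reference_image: np.ndarray | None,
    profile: normalisation.ReferenceProfile | None,
) -> normalisation.ReferenceProfile | None:
    if profile is not None:
        return profile
    ref = reference_image
    if ref is None and config.reference is not None:
        path = Path(config.reference)
        if path.suffix.lower() == ".json":
            return normalisation.ReferenceProfile.from_json(path)
        ref = read_rgb(path)
    if ref is None:
        return None
    model = preprocessing.compute_background_threshold(ref, offset=config.bg_offset)
    ref = preprocessing.replace_border_black(ref, model)
    ref, _ = preprocessing.crop_to_content(ref, model)
    ref_mask = preprocessing.make_sample_mask(
        ref, model, smooth_size=config.sample_smooth,
        min_object_px=config.sample_min_object,
    )
    return normalisation.build_reference_profile(ref, ref_mask)


def segment(
    image: np.ndarray | str | Path,
    config: PipelineConfig | None = None,
    reference_image: np.ndarray | None = None,
    profile: normalisation.ReferenceProfile | None = None,
    include_ids: list[int] | None = None,
    exclude_ids: list[int] | None = None,
    intermediates: dict | None = None,
) -> SegmentationResult:
    """Run the full epidermis segmentation on one image."""
    config = config or PipelineConfig()
    if isinstance(image, (str, Path)):
        image = read_rgb(image)
    else:
        image = preprocessing.validate_rgb(image)

    timings: dict[str, float] = {}

    def _stage(name: str):
        logger.info("stage %s", name)
        timings[name] = time.perf_counter()
        return timings[name]

    def _done(name: str) -> None:
        timings[name] = time.perf_counter() - timings[name]

    _stage("preprocessing")
    model = preprocessing.compute_background_threshold(image, offset=config.bg_offset)
    clean = preprocessing.replace_border_black(image, model)
    cropped, crop_box = preprocessing.crop_to_content(clean, model)
    sample_mask = preprocessing.make_sample_mask(
        cropped, model, smooth_size=config.sample_smooth,
        min_object_px=config.sample_min_object,
    )
    _done("preprocessing")

    normalised = False
    if config.normalise:
        _stage("normalisation")
        ref_profile = _resolve_profile(config, reference_image, profile)
        if ref_profile is None:
            raise ValueError(
                "normalisation enabled but no reference image or profile given "
                "(set normalise=False to skip)"
            )
        cropped = normalisation.normalise_colour(cropped, sample_mask, ref_profile)
        normalised = True
        _done("normalisation")

    _stage("contrast")
    fused = contrast.enhance(
        cropped, sample_mask,
        gray_p_low=config.gray_p_low, bstar_p_low=config.bstar_p_low,
        p_high=config.p_high, smooth_size=config.enhance_smooth,
        intermediates=intermediates,
    )
    _done("contrast")

    _stage("threshold")
    otsu = binarisation.otsu_level(fused, sample_mask)
    bw = binarisation.apply_level(fused, sample_mask, otsu.level)
    logger.info("otsu level %.4f (between-class variance %.6f)",
                otsu.level, otsu.between_class_variance)
    _done("threshold")

    _stage("refinement")
    refined = refinement.morph_refine(
        bw, sample_mask=sample_mask, se_radius=config.se_radius,
        min_object_px=config.refine_min_object,
        max_hole_px=config.refine_max_hole, close_open=config.close_open,
    )
    regions = refinement.classify_objects(
        refinement.measure_regions(refined),
        area_min=config.area_min, extent_max=config.extent_max,
        area_veto=config.area_veto,
    )
    mask_cropped = refinement.apply_overrides(refined, regions, include_ids, exclude_ids)
    _done("refinement")

    full = np.zeros(image.shape[:2], dtype=bool)
    r0, r1, c0, c1 = crop_box
    full[r0:r1, c0:c1] = mask_cropped

    return SegmentationResult(
        mask=full, mask_cropped=mask_cropped, sample_mask=sample_mask,
        crop_box=crop_box, otsu=otsu, regions=regions, refined_mask=refined,
        config=config, timings=timings,
        overrides={"include": sorted(include_ids or []),
                   "exclude": sorted(exclude_ids or [])},
        normalised=normalised,
    )


def run_batch(
    items: list[tuple[np.ndarray | str | Path, np.ndarray | None]],
    config: PipelineConfig | None = None,
    reference_image: np.ndarray | None = None,
    profile: normalisation.ReferenceProfile | None = None,
) -> dict:
    """Segment and (where truth is given) evaluate a batch of images.

    ``items`` is a list of (image, truth-or-None) pairs; truth masks are in
    original-frame coordinates and are cropped with each image's crop box
    before comparison, matching the cropped-frame metric convention.
    Returns per-image reports plus mean / SEM / max / min per metric.
    """
    if not items:
        raise ValueError("empty batch")
    reports: list[evaluation.EvalReport] = []
    per_image: list[dict] = []
    failures: list[dict] = []
    for i, (image, truth) in enumerate(items):
        try:
            result = segment(image, config=config,
                             reference_image=reference_image, profile=profile)
        except Exception as exc:  # noqa: BLE001 - batch collects failures
            logger.warning("item %d failed: %s", i, exc)
            failures.append({"item": i, "error": str(exc)})
            continue
        entry: dict = {"item": i, "otsu_level": result.otsu.level}
        if truth is not None:
            r0, r1, c0, c1 = result.crop_box
            truth_c = np.asarray(truth, dtype=bool)[r0:r1, c0:c1]
            report = evaluation.confusion_counts(result.mask_cropped, truth_c)
            reports.append(report)
            entry["report"] = report.to_dict()
        per_image.append(entry)
    summary: dict = {"per_image": per_image, "failures": failures}
    if reports:
        summary["metrics"] = evaluation.summarise_reports(reports)
    return summary
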