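"""Seeded synthetic H&E-like skin phantoms with exact ground truth.

A phantom emulates the features the segmentation exploits: a near-white
slide background, a thick pink fibrous dermis, a purple nucleus-rich
epidermis band running as a long undulating strip, and a thin pale flaky
stratum corneum on top.  Damage grades reproduce the histopathological
grading of the skin explant assay: grade I adds sparse white vacuoles to
the basal epidermis, grade II dense vacuolisation plus dark dyskeratotic
bodies, grade III a white sub-epidermal cleft along part of the junction,
and grade IV a complete separation of the epidermis from the dermis.  An
optional pure-black frame emulates the tiling/stitching border of slide
scanners.

Truth masks are derived analytically from the composed geometry: ``truth``
is the epidermis band excluding the stratum corneum and any vacuole/cleft
pixels (mirroring the manual mark-up convention), ``sample_truth`` is all
tissue.  Identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

GRADES = ("none", "I", "II", "III", "IV")

# Damage-feature intensity by grade: (vacuole count, dyskeratotic count).
_GRADE_FEATURES = {"none": (0, 0), "I": (35, 0), "II": (140, 60),
                   "III": (140, 60), "IV": (140, 60)}


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterisation of a synthetic skin section.

    Default colours are chosen to reproduce the H&E intensity/chroma
    ordering the segmentation relies on (epidermis darkest and bluest,
    dermis pink, background near-white), not to be photo-realistic.  The
    default 1200 x 1600 frame keeps the pipeline's absolute pixel-count
    thresholds (4000 / 7000 / 20000 / 25000) meaningful without rescaling.
    """

    height: int = 1200
    width: int = 1600
    grade: str = "none"
    seed: int = 0

    background_rgb: tuple[int, int, int] = (240, 238, 242)
    background_sigma: float = 3.0
    dermis_rgb: tuple[int, int, int] = (225, 170, 190)
    dermis_sigma: float = 8.0
    fibre_amplitude: float = 12.0
    epidermis_rgb: tuple[int, int, int] = (150, 110, 175)
    epidermis_sigma: float = 10.0
    nucleus_rgb: tuple[int, int, int] = (90, 60, 130)
    nucleus_density: float = 0.0015  # nuclei per epidermis px^2
    nucleus_radius: int = 4
    corneum_rgb: tuple[int, int, int] = (235, 200, 210)
    corneum_thickness: int = 24

    epidermis_thickness: int = 100
    #: peak undulation of the band centreline; large relative to the band
    #: thickness so the epidermis keeps the low bounding-box extent of a
    #: "long thin" object (below the 0.44 classification threshold).
    undulation_amplitude: float = 130.0
    dermis_depth: int = 400
    band_top_frac: float = 0.30  # mean vertical position of the junction band

    vacuole_rgb: tuple[int, int, int] = (246, 244, 247)
    vacuole_count: int | None = None  # None -> grade default
    vacuole_radius: int = 6
    dyskeratotic_rgb: tuple[int, int, int] = (70, 50, 95)
    dyskeratotic_count: int | None = None  # None -> grade default
    dyskeratotic_radius: int = 2
    cleft_height: int = 30
    cleft_fraction: float = 0.5
    separation_offset: int = 45

    stain_hue_shift: float = 0.0
    stain_gain: float = 1.0
    border_black_px: int = 16

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise ValueError(f"grade must be one of {GRADES}")
        for name in ("background_sigma", "dermis_sigma", "epidermis_sigma",
                     "fibre_amplitude", "undulation_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class PhantomOutput:
    """Rendered phantom plus its analytically derived truth masks."""

    image: np.ndarray        # H x W x 3 uint8
    truth: np.ndarray        # epidermis excluding corneum/vacuoles/clefts
    sample_truth: np.ndarray  # all tissue
    spec: PhantomSpec


def _undulation(width: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth pseudo-random centreline offset, |u| <= amplitude."""
    x = np.arange(width)
    phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
    u = 0.62 * np.sin(2 * np.pi * x / (0.9 * width) + phase1)
    u += 0.38 * np.sin(2 * np.pi * x / (0.37 * width) + phase2)
    return amplitude * u


def _paint_discs(
    img: np.ndarray,
    mask_out: np.ndarray | None,
    centres: np.ndarray,
    radius: int,
    rgb: tuple[int, int, int],
) -> None:
    """Paint filled discs of `radius` at integer (row, col) centres."""
    h, w = img.shape[:2]
    dy, dx = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    disc = (dx * dx + dy * dy) <= radius * radius
    colour = np.asarray(rgb, dtype=np.float64)
    for r, c in centres:
        r0, r1 = max(r - radius, 0), min(r + radius + 1, h)
        c0, c1 = max(c - radius, 0), min(c + radius + 1, w)
        sub = disc[r0 - (r - radius) : r1 - (r - radius),
                   c0 - (c - radius) : c1 - (c - radius)]
        img[r0:r1, c0:c1][sub] = colour
        if mask_out is not None:
            mask_out[r0:r1, c0:c1][sub] = True


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Render a phantom and its ground-truth masks from a spec."""
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)

    centre = _undulation(w, spec.undulation_amplitude, rng) + spec.band_top_frac * h
    epi_top = centre
    epi_bot = centre + spec.epidermis_thickness
    cor_top = epi_top - spec.corneum_thickness
    gap = spec.separation_offset if spec.grade == "IV" else 0
    derm_top = epi_bot + gap
    derm_bot = derm_top + spec.dermis_depth

    margin = spec.border_black_px
    if cor_top.min() < margin or derm_bot.max() > h - margin:
        raise ValueError("tissue bands exceed the image frame")

    rows = np.arange(h)[:, None]
    epi_band = (rows >= epi_top[None, :]) & (rows < epi_bot[None, :])
    cor_band = (rows >= cor_top[None, :]) & (rows < epi_top[None, :])
    derm_band = (rows >= derm_top[None, :]) & (rows < derm_bot[None, :])

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = spec.background_rgb
    if spec.background_sigma > 0:
        img += rng.normal(0.0, spec.background_sigma, size=img.shape)

    # dermis: pink with low-frequency fibrous brightness texture
    img[derm_band] = spec.dermis_rgb
    if spec.fibre_amplitude > 0:
        fibres = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=9)
        fibres *= spec.fibre_amplitude / max(fibres.std(), 1e-12)
        img[derm_band] += fibres[derm_band, None]
    if spec.dermis_sigma > 0:
        img[derm_band] += rng.normal(
            0.0, spec.dermis_sigma, size=(int(derm_band.sum()), 3)
        )

    # epidermis band
    img[epi_band] = spec.epidermis_rgb
    if spec.epidermis_sigma > 0:
        img[epi_band] += rng.normal(
            0.0, spec.epidermis_sigma, size=(int(epi_band.sum()), 3)
        )

    # stratum corneum: pale with flaky horizontal striping
    img[cor_band] = spec.corneum_rgb
    if spec.fibre_amplitude > 0:
        stripes = 0.6 * spec.fibre_amplitude * np.sin(2 * np.pi * rows / 7.0)
        img[cor_band] += np.broadcast_to(stripes, (h, w))[cor_band, None]
    if spec.background_sigma > 0:
        img[cor_band] += rng.normal(
            0.0, spec.background_sigma, size=(int(cor_band.sum()), 3)
        )

    # nuclei discs within the epidermis band
    n_nuclei = int(round(spec.nucleus_density * epi_band.sum()))
    if n_nuclei > 0:
        pad = spec.nucleus_radius + 3
        cx = rng.integers(pad, w - pad, size=n_nuclei)
        t = rng.uniform(0, 1, size=n_nuclei)
        cy = (epi_top[cx] + pad + t * (spec.epidermis_thickness - 2 * pad)).astype(int)
        _paint_discs(img, None, np.column_stack([cy, cx]), spec.nucleus_radius,
                     spec.nucleus_rgb)

    vac_count, dysk_count = _GRADE_FEATURES[spec.grade]
    if spec.vacuole_count is not None:
        vac_count = spec.vacuole_count
    if spec.dyskeratotic_count is not None:
        dysk_count = spec.dyskeratotic_count

    vacuole_mask = np.zeros((h, w), dtype=bool)
    if vac_count > 0:
        pad = spec.vacuole_radius + 3
        cx = rng.integers(pad, w - pad, size=vac_count)
        t = rng.uniform(0, 1, size=vac_count)
        # basal (lower) half of the band
        cy = (epi_bot[cx] - pad - t * (0.45 * spec.epidermis_thickness - pad)).astype(int)
        _paint_discs(img, vacuole_mask, np.column_stack([cy, cx]),
                     spec.vacuole_radius, spec.vacuole_rgb)

    if dysk_count > 0:
        pad = spec.dyskeratotic_radius + 3
        cx = rng.integers(pad, w - pad, size=dysk_count)
        t = rng.uniform(0, 1, size=dysk_count)
        cy = (epi_top[cx] + pad + t * (spec.epidermis_thickness - 2 * pad)).astype(int)
        _paint_discs(img, None, np.column_stack([cy, cx]),
                     spec.dyskeratotic_radius, spec.dyskeratotic_rgb)

    cleft_mask = np.zeros((h, w), dtype=bool)
    if spec.grade == "III" and spec.cleft_fraction > 0:
        length = int(spec.cleft_fraction * w)
        x0 = int(rng.integers(0, max(w - length, 1)))
        cols = slice(x0, x0 + length)
        half = spec.cleft_height / 2.0
        in_cleft = (rows >= (epi_bot[None, :] - half)) & (rows < (epi_bot[None, :] + half))
        in_cleft[:, : x0] = False
        in_cleft[:, x0 + length :] = False
        cleft_mask = in_cleft
        img[cleft_mask] = (248, 246, 249)

    truth = epi_band & ~vacuole_mask & ~cleft_mask
    sample_truth = cor_band | epi_band | derm_band

    if spec.border_black_px > 0:
        b = spec.border_black_px
        border = np.zeros((h, w), dtype=bool)
        border[:b, :] = border[-b:, :] = True
        border[:, :b] = border[:, -b:] = True
        img[border] = 0.0
        truth &= ~border
        sample_truth &= ~border

    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    out = PhantomOutput(image=image, truth=truth, sample_truth=sample_truth, spec=spec)
    if spec.stain_hue_shift != 0.0 or spec.stain_gain != 1.0:
        out = perturb_staining(out, hue_shift=spec.stain_hue_shift,
                               gain=spec.stain_gain, seed=spec.seed + 1)
    return out


def perturb_staining(
    output: PhantomOutput,
    hue_shift: float = 0.0,
    gain: float = 1.0,
    seed: int = 0,
    illum_amplitude: float = 0.03,
) -> PhantomOutput:
    """Global per-channel affine perturbation plus a mild illumination ramp.

    ``hue_shift`` tilts red up and blue down (or vice versa), ``gain``
    scales all channels, and a linear illumination gradient of relative
    amplitude ``illum_amplitude`` is applied in a seeded random direction.
    Truth masks are unchanged.  The identity perturbation (hue_shift 0,
    gain 1, illum_amplitude 0) returns the image unchanged.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    img = output.image.astype(np.float64)
    if hue_shift == 0.0 and gain == 1.0 and illum_amplitude == 0.0:
        return replace(output, image=output.image.copy())
    rng = np.random.default_rng(seed)
    gains = gain * np.array([1.0 + hue_shift, 1.0, 1.0 - hue_shift])
    h, w = img.shape[:2]
    theta = rng.uniform(0, 2 * np.pi)
    yy = (np.arange(h) / max(h - 1, 1) - 0.5)[:, None]
    xx = (np.arange(w) / max(w - 1, 1) - 0.5)[None, :]
    illum = 1.0 + 2.0 * illum_amplitude * (np.cos(theta) * xx + np.sin(theta) * yy)
    perturbed = img * gains[None, None, :] * illum[..., None]
    clipped_high = perturbed > 255.0
    new = np.clip(np.round(perturbed), 0, 255).astype(np.uint8)
    n_sample = int(output.sample_truth.sum())
    if n_sample > 0:
        frac = clipped_high[output.sample_truth].any(axis=-1).mean()
        if frac > 0.05:
            warnings.warn(
                f"staining perturbation clipped {100 * frac:.1f}% of sample pixels"
            )
    return replace(output, image=new)
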