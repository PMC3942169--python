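"""Shared fixtures: phantoms at study scale and a segmented phantom batch."""

from __future__ import annotations

import numpy as np
import pytest

from episeg.evaluation import confusion_counts
from episeg.phantoms import PhantomSpec, generate_phantom, perturb_staining
from episeg.pipeline import PipelineConfig, segment

#: Scaled-down phantom for unit tests that do not depend on the absolute
#: pixel-count thresholds of the full pipeline.
SMALL_SPEC = PhantomSpec(
    height=320, width=420, epidermis_thickness=40, undulation_amplitude=40.0,
    corneum_thickness=12, dermis_depth=100, nucleus_radius=3,
    vacuole_radius=4, cleft_height=14, separation_offset=20,
    border_black_px=6,
)


def small_spec(**overrides) -> PhantomSpec:
    from dataclasses import replace

    return replace(SMALL_SPEC, **overrides)


@pytest.fixture(scope="session")
def reference_phantom():
    """Unperturbed, well-stained phantom used as the normalisation target."""
    return generate_phantom(PhantomSpec(seed=100, grade="none"))


@pytest.fixture(scope="session")
def segmented_batch(reference_phantom):
    """Twenty perturbed phantoms (5 per damage grade) run end to end.

    Stain perturbations are drawn from a seeded generator: hue tilt within
    ±0.06, gain within [0.88, 1.02] — the staining/lighting variation band
    the normalisation step is meant to absorb.
    """
    entries = []
    config = PipelineConfig()
    i = 0
    for grade in ("I", "II", "III", "IV"):
        for k in range(5):
            spec = PhantomSpec(seed=200 + 17 * i, grade=grade)
            rng = np.random.default_rng(1000 + i)
            out = perturb_staining(
                generate_phantom(spec),
                hue_shift=float(rng.uniform(-0.06, 0.06)),
                gain=float(rng.uniform(0.88, 1.02)),
                seed=3000 + i,
            )
            result = segment(out.image, config=config,
                             reference_image=reference_phantom.image)
            r0, r1, c0, c1 = result.crop_box
            report = confusion_counts(result.mask_cropped, out.truth[r0:r1, c0:c1])
            entries.append({"grade": grade, "output": out, "result": result,
                            "report": report})
            i += 1
    return entries
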