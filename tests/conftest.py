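import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

import infarctsize as iz


@pytest.fixture(scope="session")
def quarter_phantom():
    """Default 512x512 phantom with a transmural 90-degree scar sector."""
    spec = iz.PhantomSpec(infarct_sector=(0.0, np.pi / 2), rng_seed=7)
    return iz.render_phantom(spec)


@pytest.fixture(scope="session")
def quarter_segmented(quarter_phantom):
    image, truth, seeds = quarter_phantom
    mask = iz.segment_section(image, seeds)
    centre, fallback = iz.lumen_centre(mask)
    trace = iz.cast_rays(mask, centre, used_fallback_centre=fallback)
    return mask, trace


@pytest.fixture(scope="session")
def small_phantom():
    """Cheap 256x256 phantom (120-degree transmural scar) for unit tests."""
    spec = iz.PhantomSpec(
        image_size=(256, 256),
        endo_radius=75.0,
        epi_radius=90.0,
        infarct_sector=(0.0, 2 * np.pi / 3),
        rng_seed=11,
    )
    return iz.render_phantom(spec)
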