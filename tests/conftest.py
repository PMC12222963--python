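import numpy as np
import pytest

from glomkit.core import MultiClassMask
from glomkit.synthetic import SyntheticSlideSpec, generate_slide


@pytest.fixture(scope="session")
def small_slide():
    """One 512x512 synthetic slide with touching pairs (seeded)."""
    spec = SyntheticSlideSpec(
        width=512,
        height=512,
        n_glomeruli=8,
        radius_range=(20.0, 36.0),
        overlap_fraction=0.3,
        seed=11,
    )
    return generate_slide(spec)


@pytest.fixture(scope="session")
def tiny_slide():
    """A 320x320 slide with isolated glomeruli only."""
    spec = SyntheticSlideSpec(
        width=320,
        height=320,
        n_glomeruli=6,
        radius_range=(14.0, 24.0),
        overlap_fraction=0.0,
        seed=7,
    )
    return generate_slide(spec)


def disk_mask(shape, center, radius, label=1, mpp=1.0) -> MultiClassMask:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    labels = np.zeros(shape, dtype=np.uint8)
    labels[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2] = label
    return MultiClassMask(labels, mpp)
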