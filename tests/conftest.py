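import numpy as np
import pytest

from spinemorph import (
    LabelMask,
    SpineLabelScheme,
    SpinePhantomSpec,
    generate_phantom,
)


@pytest.fixture(scope="session")
def scheme():
    return SpineLabelScheme.default()


@pytest.fixture(scope="session")
def straight_phantom():
    """Axis-aligned phantom at 1 mm: every height a whole number of pixels."""
    spec = SpinePhantomSpec(
        shape=(300, 256), spacing_mm=(1.0, 1.0), inter_level_angle_deg=0.0
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_phantom():
    """Small curved phantom for perturbation/agreement tests (fast)."""
    spec = SpinePhantomSpec(
        shape=(300, 256), spacing_mm=(1.0, 1.0), inter_level_angle_deg=4.0
    )
    return generate_phantom(spec)


def rectangle_mask(
    rows, cols, top, left, height_px, width_px, code=1, spacing=(1.0, 1.0), scheme=None
):
    """A single rectangular structure on an otherwise empty grid."""
    px = np.zeros((rows, cols), dtype=np.int64)
    px[top : top + height_px, left : left + width_px] = code
    return LabelMask(px, spacing, scheme or SpineLabelScheme.default())
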