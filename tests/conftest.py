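import numpy as np
import pytest

from lungdelta import masking, synthetic as syn
from lungdelta.volumes import BinaryMask, ScalarVolume

# Small geometry for fast unit tests; acceptance tests use the generator default.
SMALL_EXTENT = (32, 40, 40)
SMALL_SPACING = (2.0, 2.0, 2.0)


@pytest.fixture(scope="session")
def phantom():
    """Default-size thorax phantom shared by registration/statistics tests."""
    ct, lung, tumor, vessels = syn.generate_planning_ct(seed=1)
    return {"ct": ct, "lung": lung, "tumor": tumor, "vessels": vessels}


@pytest.fixture(scope="session")
def phantom_dose(phantom):
    ct = phantom["ct"]
    nz, ny, nx = ct.shape
    center_mm = (nz / 2 * 2.0, ny / 2 * 2.0, nx * 0.7 * 2.0)
    return syn.generate_dose_field(ct, center_mm, 74.0)


@pytest.fixture(scope="session")
def phantom_analysis(phantom):
    excl = masking.build_exclusion_mask(
        phantom["ct"], phantom["lung"], phantom["tumor"]
    )
    return masking.build_analysis_mask(phantom["lung"], excl, margin_mm=6.0)


@pytest.fixture
def cube_lung():
    """6x6x6 lung block with a 2x2x2 exclusion at its centre, 1 mm spacing.

    Placed inside a 12^3 grid so dilation has room; voxel counts are
    hand-countable (216 lung, 8 exclusion).
    """
    shape = (12, 12, 12)
    lung = np.zeros(shape, dtype=bool)
    lung[3:9, 3:9, 3:9] = True
    excl = np.zeros(shape, dtype=bool)
    excl[5:7, 5:7, 5:7] = True
    spacing = (1.0, 1.0, 1.0)
    return (
        BinaryMask(lung, spacing, label="lung"),
        BinaryMask(excl, spacing, label="exclusion"),
    )


def make_volume(values, spacing=(1.0, 1.0, 1.0), kind="ct", origin=(0.0, 0.0, 0.0)):
    return ScalarVolume(np.asarray(values, dtype=float), spacing, origin, kind=kind)
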