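import numpy as np
import pytest
from hypothesis import settings

import histostereo as hs

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sphere_region():
    """1 mm-radius sphere, ~4.19 mm³."""
    return hs.make_region("toy-sphere", {"ellipsoid": {"semi_axes_um": [1000.0] * 3}})


@pytest.fixture(scope="session")
def small_ellipsoid():
    """Small anisotropic ellipsoid (~2.1 mm³) for estimator-recovery runs."""
    return hs.make_region(
        "toy-ellipsoid", {"ellipsoid": {"semi_axes_um": [800.0, 700.0, 900.0]}}
    )


@pytest.fixture(scope="session")
def cn_region():
    """Synthetic IC central nucleus: ellipsoid with volume exactly 1362 mm³."""
    a, b = 7040.0, 4300.0
    c = 1362e9 * 3.0 / (4.0 * np.pi) / (a * b)
    return hs.make_region("IC-CN", {"ellipsoid": {"semi_axes_um": [a, b, c]}})


@pytest.fixture(scope="session")
def small_design():
    """Scaled-down fractionator design for toy regions (same fractions logic)."""
    return hs.SamplingDesign(
        section_period=5,
        cut_thickness_um=50.0,
        mounted_thickness_um=20.0,
        grid_um=(400.0, 400.0),
        frame_um=(100.0, 100.0),
        disector_height_um=18.0,
        guard_um=1.0,
    )
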