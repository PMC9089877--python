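import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import carbonpb as c

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_lib():
    """Four-energy library (ranges 60/90/120/150 mm), deterministic."""
    cfg = c.SyntheticBeamConfig(ranges_mm=(60.0, 90.0, 120.0, 150.0), seed=7)
    return c.synthesize_beam_library(cfg)


@pytest.fixture(scope="session")
def sobp_lib():
    """Library tiling 104-152 mm on the 3 mm lattice (SOBP studies)."""
    cfg = c.SyntheticBeamConfig(
        ranges_mm=tuple(np.arange(104.0, 155.0, 3.0)), seed=3)
    return c.synthesize_beam_library(cfg)


@pytest.fixture(scope="session")
def calib_lib():
    """Library covering the 101-200 mm reference-calibration window."""
    cfg = c.SyntheticBeamConfig(
        ranges_mm=tuple(np.arange(101.0, 201.0, 3.0)), seed=11)
    return c.synthesize_beam_library(cfg)


@pytest.fixture()
def water_ph():
    return c.water_box(lateral_mm=80.0, depth_mm=160.0, spacing=2.0)
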