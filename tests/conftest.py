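"""Shared fixtures: fit windows, phantoms and seeded RNG streams."""

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from rtflim import FitWindow

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")
from rtflim.synth import two_region_phantom


@pytest.fixture
def window128():
    """Standard study window: 128 bins of 0.1 ns (12.8 ns span)."""
    return FitWindow(0, 128, 0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


@pytest.fixture
def small_phantom():
    """Two-region phantom small enough for per-test simulation."""
    return two_region_phantom(
        rows=24, cols=24, bins=128, bin_width=0.1,
        photons_per_pixel=1e4, seed=7,
    )
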