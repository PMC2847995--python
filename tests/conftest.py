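import numpy as np
import pytest

from synaptrap.geometry import derive_spine_geometry


@pytest.fixture(scope="session")
def ref_geom():
    """Reference spine: 0.5 µm³, 9% PSD."""
    return derive_spine_geometry(0.5, 0.09)


@pytest.fixture(scope="session")
def small_geom():
    """Down-scaled spine used where full-size runs would be wasteful."""
    return derive_spine_geometry(0.02, 0.09)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
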