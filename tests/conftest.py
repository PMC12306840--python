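import numpy as np
import pytest

from cinedenoise.attention import AttentionGeometry
from cinedenoise.noise import synth_gfactor_map
from cinedenoise.phantom import PhantomSpec, generate_cine_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_series(rng):
    """Random real 5D series [1, 4, 2, 8, 8] for attention-level tests."""
    return rng.normal(size=(1, 4, 2, 8, 8))


@pytest.fixture(scope="session")
def desk_phantom():
    """A small 64×64, 8-phase phantom with masks (session-cached)."""
    spec = PhantomSpec(matrix=(64, 64), phases=8, endo_radii=(13.0, 10.5),
                       wall_thickness=5.5, seed=21)
    series, masks = generate_cine_phantom(spec)
    return spec, series, masks


@pytest.fixture(scope="session")
def desk_gmap():
    return synth_gfactor_map((64, 64), gmax=2.5, seed=33)


@pytest.fixture
def tiny_geom():
    return AttentionGeometry(window_px=4, patch_px=2, heads=2)
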