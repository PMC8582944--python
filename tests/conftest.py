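import numpy as np
import pytest
from hypothesis import settings

from casacarbon import GridSpec, SynthConfig, load_casa_params

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    return load_casa_params()


@pytest.fixture
def spec8():
    return GridSpec(8, 8, pixel_area=1.0e6)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_config():
    """Desk-scale scene config used throughout the suite (fast: 24x24)."""
    return SynthConfig(n_rows=24, n_cols=24, seed=11, layout_seed=3,
                       n_afforest_patches=1, afforest_patch_size=3,
                       n_urban_patches=1, urban_patch_size=3,
                       n_other_patches=1, other_patch_size=2)


def make_year(rng, spec, params=None, lu_code=3):
    """Random but physically plausible 12-month inputs on *spec*."""
    shape = (12,) + spec.shape
    season = -np.cos(2 * np.pi * np.arange(12) / 12.0)[:, None, None]
    ndvi = np.clip(0.45 + 0.15 * season + 0.05 * rng.standard_normal(shape), 0.08, 0.88)
    temp = 16.0 + 12.0 * season + rng.standard_normal(shape)
    precip = np.clip(100.0 * (1 + 0.8 * season) * (1 + 0.2 * rng.standard_normal(shape)), 0, None)
    rad = np.clip(390.0 * (1 + 0.5 * season) * (1 + 0.05 * rng.standard_normal(shape)), 0, None)
    return ndvi, precip, temp, rad
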