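import numpy as np
import pytest

import dichroma as dc


@pytest.fixture(scope="session")
def grid():
    return dc.DEFAULT_GRID


@pytest.fixture(scope="session")
def uvs_eye():
    return dc.build_average_eye("UVS")


@pytest.fixture(scope="session")
def vs_eye():
    return dc.build_average_eye("VS")


@pytest.fixture(scope="session")
def uvs_sensitivities(uvs_eye):
    return dc.build_eye_sensitivities(uvs_eye)


@pytest.fixture(scope="session")
def ideal(grid):
    return dc.builtin_illuminant("ideal", grid)


@pytest.fixture(scope="session")
def small_library():
    """Seeded 6-species, 5-patch dimorphic library, noise-free."""
    design = dc.SyntheticDesign(n_species=6, n_patches=5, seed=42, noise_sd=0.0)
    return dc.generate_library(design)


def gaussian_reflectance(grid, centre, amplitude=40.0, width=30.0, baseline=10.0):
    wl = grid.wavelengths
    vals = baseline + amplitude * np.exp(-0.5 * ((wl - centre) / width) ** 2)
    return dc.SpectralCurve(grid, np.clip(vals, 0, 100))
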