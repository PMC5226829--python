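"""Built-in illuminant irradiance spectra.

Seven illuminants are available: the *ideal* (wavelength-independent)
illuminant computed in code, the CIE standard daylight D65 packaged from the
standard 10-nm SPD table, and five habitat illuminants (forest shade,
woodland shade, woodland gaps, blue sky, cloudy sky). The habitat tables
shipped with the package are synthetic stand-ins with the qualitative
spectral character their names imply (see each table's provenance header);
replace the packaged CSVs with measured irradiances for quantitative work.

Because the receptor-noise model applies a von Kries correction, only the
*shape* of an illuminant matters: scaling any illuminant by a constant leaves
every JND unchanged (a tested invariance).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .spectra import DEFAULT_GRID, SpectralCurve, WavelengthGrid, _interp_onto

__all__ = ["Illuminant", "ILLUMINANT_NAMES", "builtin_illuminant"]

ILLUMINANT_NAMES = (
    "ideal",
    "forest_shade",
    "woodland_shade",
    "blue_sky",
    "D65",
    "woodland_gaps",
    "cloudy_sky",
)

_FILES = {
    "D65": "d65.csv",
    "forest_shade": "forest_shade_synthetic.csv",
    "woodland_shade": "woodland_shade_synthetic.csv",
    "woodland_gaps": "woodland_gaps_synthetic.csv",
    "blue_sky": "blue_sky_synthetic.csv",
    "cloudy_sky": "cloudy_sky_synthetic.csv",
}


@dataclass(frozen=True)
class Illuminant:
    name: str
    curve: SpectralCurve

    def __post_init__(self) -> None:
        if np.any(self.curve.values <= 0):
            raise ValueError(f"illuminant {self.name!r} must be strictly positive")


def builtin_illuminant(name: str, grid: WavelengthGrid = DEFAULT_GRID) -> Illuminant:
    """Return a named illuminant resampled to *grid*.

    ``ideal`` is constant (value 1) across the grid; the others are loaded
    from the packaged two-column tables (wavelength nm, relative irradiance).
    """
    if name == "ideal":
        return Illuminant(name, SpectralCurve(grid, np.ones(len(grid))))
    if name not in _FILES:
        raise ValueError(f"unknown illuminant {name!r}; choose from {ILLUMINANT_NAMES}")
    ref = resources.files("dichroma.data.illuminants") / _FILES[name]
    with ref.open("r") as fh:
        df = pd.read_csv(fh, comment="#")
    values = _interp_onto(df["wl"].to_numpy(float), df["irradiance"].to_numpy(float), grid)
    return Illuminant(name, SpectralCurve(grid, values))
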