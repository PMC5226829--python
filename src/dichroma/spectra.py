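"""Spectral curves, wavelength grids, and reflectance-library I/O.

All computation in this package happens on a single shared wavelength grid,
by default 300–700 nm at 1 nm (401 points) — the band over which avian single
cones and their filters are modelled. Curves are thin wrappers around a numpy
array plus the grid; integrals downstream are computed as grid sums times the
grid step.

Reflectance libraries are species × patch × sex collections of curves
(percent reflectance) plus a boolean "bare patch" mask marking patches that
carry no plumage and are excluded from scoring. Two CSV dialects are
supported:

* *wide*: a ``wl`` column plus one column per series, named
  ``<species><sep><patch><sep><sex>`` (separator configurable, parsed from
  the right so species names may contain the separator);
* *long*: columns ``wl, species, patch, sex, reflectance``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "SpectralCurve",
    "PatchSpectraSet",
    "DEFAULT_GRID",
    "SEXES",
    "resample",
    "read_reflectance_csv",
    "write_reflectance_csv",
    "read_bare_mask_csv",
]

SEXES = ("male", "female")


class SpectraError(ValueError):
    """Raised for malformed spectral inputs (labels, grids, CSV layout)."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nm."""

    start: float = 300.0
    stop: float = 700.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if not (self.start < self.stop):
            raise SpectraError(f"grid start {self.start} must be < stop {self.stop}")
        if self.step <= 0:
            raise SpectraError(f"grid step must be positive, got {self.step}")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)

    def __len__(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1


DEFAULT_GRID = WavelengthGrid(300.0, 700.0, 1.0)


@dataclass(frozen=True)
class SpectralCurve:
    """Non-negative spectral values on a wavelength grid.

    Units depend on role: percent reflectance, relative irradiance, or
    dimensionless transmission/sensitivity (≤ 1 after normalization).
    """

    grid: WavelengthGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or len(values) != len(self.grid):
            raise SpectraError(
                f"curve length {values.shape} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(values)):
            raise SpectraError("curve contains non-finite values")
        if np.any(values < 0):
            raise SpectraError("curve contains negative values; clean inputs first")
        object.__setattr__(self, "values", values)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def scaled(self, k: float) -> "SpectralCurve":
        return SpectralCurve(self.grid, self.values * k)


def resample(curve: SpectralCurve, grid: WavelengthGrid) -> SpectralCurve:
    """Linearly interpolate *curve* onto *grid*. Extrapolation is an error."""
    src = curve.grid
    if src == grid:
        return curve
    if grid.start < src.start or grid.stop > src.stop:
        raise SpectraError(
            f"target grid [{grid.start}, {grid.stop}] exceeds source "
            f"range [{src.start}, {src.stop}]; extrapolation is not allowed"
        )
    values = np.interp(grid.wavelengths, src.wavelengths, curve.values)
    return SpectralCurve(grid, values)


def _interp_onto(wl_src: np.ndarray, values: np.ndarray, grid: WavelengthGrid) -> np.ndarray:
    order = np.argsort(wl_src)
    wl_src, values = wl_src[order], values[order]
    if grid.start < wl_src[0] or grid.stop > wl_src[-1]:
        raise SpectraError(
            f"working grid [{grid.start}, {grid.stop}] exceeds the file's "
            f"wavelength range [{wl_src[0]}, {wl_src[-1]}]"
        )
    return np.interp(grid.wavelengths, wl_src, values)


@dataclass
class PatchSpectraSet:
    """Reflectance library: (species, patch, sex) → curve, plus bare mask.

    ``curves`` maps ``(species, patch, sex)`` to percent-reflectance curves;
    ``bare`` maps ``(species, patch)`` to True for non-feathered patches.
    """

    grid: WavelengthGrid
    species: list[str]
    patches: list[str]
    curves: dict[tuple[str, str, str], SpectralCurve]
    bare: dict[tuple[str, str], bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp in self.species:
            for patch in self.patches:
                present = [(sp, patch, sex) in self.curves for sex in SEXES]
                if any(present) and not all(present):
                    raise SpectraError(f"patch ({sp}, {patch}) present for only one sex")
        for sp, patch in self.bare:
            if sp not in self.species or patch not in self.patches:
                raise SpectraError(f"bare mask references unknown patch ({sp}, {patch})")

    def is_bare(self, species: str, patch: str) -> bool:
        return bool(self.bare.get((species, patch), False))

    def feathered_patches(self, species: str) -> list[str]:
        return [
            p
            for p in self.patches
            if not self.is_bare(species, p) and (species, p, "male") in self.curves
        ]

    def curve(self, species: str, patch: str, sex: str) -> SpectralCurve:
        try:
            return self.curves[(species, patch, sex)]
        except KeyError:
            raise SpectraError(f"no curve for ({species}, {patch}, {sex})") from None

    def set_bare_mask(self, bare: Mapping[tuple[str, str], bool]) -> None:
        for sp, patch in bare:
            if sp not in self.species or patch not in self.patches:
                raise SpectraError(f"bare mask references unknown patch ({sp}, {patch})")
        self.bare = dict(bare)

    @property
    def n_curves(self) -> int:
        return len(self.curves)


def _clean_reflectance(values: np.ndarray) -> np.ndarray:
    # Negative readings are spectrometer noise; quantum catches require R >= 0.
    return np.clip(values, 0.0, None)


def read_reflectance_csv(
    path: str | Path,
    dialect: str = "wide",
    grid: WavelengthGrid = DEFAULT_GRID,
    sep: str = "_",
) -> PatchSpectraSet:
    """Read a reflectance library CSV (percent reflectance vs nm).

    Parameters
    ----------
    dialect
        ``"wide"``: a ``wl`` column plus ``<species><sep><patch><sep><sex>``
        columns (sex and patch parsed from the right, so species names may
        contain *sep*). ``"long"``: columns wl/species/patch/sex/reflectance.
    grid
        Working grid; every series is linearly resampled onto it.
    """
    df = pd.read_csv(path, comment="#")
    if dialect == "wide":
        return _read_wide(df, grid, sep)
    if dialect == "long":
        return _read_long(df, grid)
    raise SpectraError(f"unknown dialect {dialect!r}; expected 'wide' or 'long'")


def _require_numeric(df: pd.DataFrame, cols: Iterable[str]) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        out[c] = pd.to_numeric(out[c], errors="raise")
    return out


def _read_wide(df: pd.DataFrame, grid: WavelengthGrid, sep: str) -> PatchSpectraSet:
    if "wl" not in df.columns:
        raise SpectraError("wide reflectance CSV must have a 'wl' wavelength column")
    df = _require_numeric(df, df.columns)
    wl = df["wl"].to_numpy(dtype=float)
    curves: dict[tuple[str, str, str], SpectralCurve] = {}
    species: list[str] = []
    patches: list[str] = []
    for col in df.columns:
        if col == "wl":
            continue
        try:
            sp, patch, sex = col.rsplit(sep, 2)
        except ValueError:
            raise SpectraError(
                f"cannot parse column {col!r} as <species>{sep}<patch>{sep}<sex>"
            ) from None
        sex = sex.lower()
        if sex not in SEXES:
            raise SpectraError(f"column {col!r}: sex {sex!r} not in {SEXES}")
        key = (sp, patch, sex)
        if key in curves:
            raise SpectraError(f"duplicate series for {key}")
        values = _clean_reflectance(_interp_onto(wl, df[col].to_numpy(dtype=float), grid))
        curves[key] = SpectralCurve(grid, values)
        if sp not in species:
            species.append(sp)
        if patch not in patches:
            patches.append(patch)
    return PatchSpectraSet(grid, species, patches, curves)


def _read_long(df: pd.DataFrame, grid: WavelengthGrid) -> PatchSpectraSet:
    required = {"wl", "species", "patch", "sex", "reflectance"}
    missing = required - set(df.columns)
    if missing:
        raise SpectraError(f"long reflectance CSV missing columns: {sorted(missing)}")
    df = _require_numeric(df, ["wl", "reflectance"])
    curves: dict[tuple[str, str, str], SpectralCurve] = {}
    species: list[str] = []
    patches: list[str] = []
    for (sp, patch, sex), sub in df.groupby(["species", "patch", "sex"], sort=False):
        sex = str(sex).lower()
        if sex not in SEXES:
            raise SpectraError(f"sex {sex!r} not in {SEXES}")
        key = (str(sp), str(patch), sex)
        if sub["wl"].duplicated().any():
            raise SpectraError(f"duplicate wavelengths for series {key}")
        values = _clean_reflectance(
            _interp_onto(sub["wl"].to_numpy(dtype=float), sub["reflectance"].to_numpy(dtype=float), grid)
        )
        curves[key] = SpectralCurve(grid, values)
        if key[0] not in species:
            species.append(key[0])
        if key[1] not in patches:
            patches.append(key[1])
    return PatchSpectraSet(grid, species, patches, curves)


def write_reflectance_csv(
    spectra: PatchSpectraSet, path: str | Path, dialect: str = "wide", sep: str = "_"
) -> None:
    """Write a library back to CSV in either dialect (round-trips exactly)."""
    wl = spectra.grid.wavelengths
    if dialect == "wide":
        data: dict[str, np.ndarray] = {"wl": wl}
        for sp in spectra.species:
            for patch in spectra.patches:
                for sex in SEXES:
                    key = (sp, patch, sex)
                    if key in spectra.curves:
                        data[f"{sp}{sep}{patch}{sep}{sex}"] = spectra.curves[key].values
        pd.DataFrame(data).to_csv(path, index=False)
    elif dialect == "long":
        rows = []
        for (sp, patch, sex), curve in spectra.curves.items():
            rows.append(
                pd.DataFrame(
                    {"wl": wl, "species": sp, "patch": patch, "sex": sex, "reflectance": curve.values}
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    else:
        raise SpectraError(f"unknown dialect {dialect!r}")


def read_bare_mask_csv(path: str | Path, spectra: PatchSpectraSet) -> dict[tuple[str, str], bool]:
    """Read a species × patch 0/1 matrix of bare (non-feathered) patches.

    Rows are species (first column), columns are patch labels. Labels must
    match the spectra library exactly; unknown labels are rejected.
    """
    df = pd.read_csv(path, comment="#", index_col=0)
    mask: dict[tuple[str, str], bool] = {}
    for sp in df.index:
        if sp not in spectra.species:
            raise SpectraError(f"bare mask references unknown species {sp!r}")
        for patch in df.columns:
            if patch not in spectra.patches:
                raise SpectraError(f"bare mask references unknown patch {patch!r}")
            mask[(str(sp), str(patch))] = bool(int(df.loc[sp, patch]))
    return mask
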