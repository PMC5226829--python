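"""Synthetic reflectance libraries with known ground truth.

Emulates the structure of a museum-specimen spectra library — per-species,
per-patch, per-sex mean percent-reflectance curves on 300–700 nm plus a
bare-patch mask — with controllable sexual colour differences, so every
pipeline stage can be exercised against a known truth record.

Each patch is a baseline level plus one or two Gaussian reflectance peaks
(optionally a sigmoid edge, the other common shape of real plumage
spectra). The sexual difference is a per-patch peak-centre shift (nm)
and/or amplitude change (%), scaled per species by a graded effect size so
that true effect magnitude and recovered dichromatism score can be
correlated. Measurement noise is spectrally smooth (correlated over a
configurable length, default 20 nm), mimicking spectrometer output rather
than white noise. A fixed seed makes the output bit-reproducible.

What this generator does *not* emulate: individual-level replicates (inputs
are sex means), specular artefacts, and the covariance structure of real
plumage patches within a species — so passing tests demonstrate pipeline
correctness, not field realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .spectra import DEFAULT_GRID, PatchSpectraSet, SpectralCurve, WavelengthGrid

__all__ = ["SyntheticDesign", "generate_library", "generate_uv_contrast_case"]


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of a synthetic spectra library.

    ``sex_shift_nm`` / ``sex_amplitude_pct`` are the *maximum* per-patch
    sexual differences; each species draws an effect scale in [0, 1]
    (graded evenly across species) that multiplies both.
    """

    n_species: int = 30
    n_patches: int = 15
    seed: int = 0
    baseline_range: tuple[float, float] = (5.0, 40.0)
    peak_amplitude_range: tuple[float, float] = (15.0, 55.0)
    peak_width_range: tuple[float, float] = (20.0, 60.0)
    peak_centre_range: tuple[float, float] = (330.0, 670.0)
    peaks_per_patch: tuple[int, int] = (1, 2)
    sex_shift_nm: float = 20.0
    sex_amplitude_pct: float = 20.0
    noise_sd: float = 0.0
    noise_corr_length_nm: float = 20.0
    bare_patch_prob: float = 0.0
    sigmoid_patch_prob: float = 0.2
    grid: WavelengthGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_patches < 1:
            raise ValueError("need at least one species and one patch")
        if self.noise_sd < 0 or not (0 <= self.bare_patch_prob < 1):
            raise ValueError("invalid noise or bare-patch settings")


def _gauss(wl: np.ndarray, centre: float, amp: float, width: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((wl - centre) / width) ** 2)


def _sigmoid(wl: np.ndarray, centre: float, amp: float, width: float) -> np.ndarray:
    return amp / (1.0 + np.exp(-(wl - centre) / width))


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, corr: float, step: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    raw = gaussian_filter1d(rng.normal(size=n), sigma=corr / step, mode="nearest")
    return sd * raw / raw.std()


def generate_library(design: SyntheticDesign) -> tuple[PatchSpectraSet, dict]:
    """Generate a seeded library plus its truth record.

    The truth record stores each species' effect scale and each patch's true
    centre shift and amplitude delta, and the bare mask — everything needed
    to check that computed dichromatism tracks the injected dimorphism.
    """
    # separate streams: noise draws must not perturb the structural draws,
    # so the same seed yields the same plumage geometry at any noise level
    rng, noise_rng = np.random.default_rng(design.seed).spawn(2)
    wl = design.grid.wavelengths
    species = [f"sp{i + 1:02d}" for i in range(design.n_species)]
    patches = [f"patch{j + 1:02d}" for j in range(design.n_patches)]
    # graded effect sizes: evenly spaced in [0, 1], shuffled
    scales = np.linspace(0.0, 1.0, design.n_species)
    rng.shuffle(scales)

    curves: dict[tuple[str, str, str], SpectralCurve] = {}
    bare: dict[tuple[str, str], bool] = {}
    truth: dict = {"design_seed": design.seed, "patch_labels": patches, "species": {}}
    for sp, scale in zip(species, scales):
        sp_truth: dict = {"effect_scale": float(scale), "patches": {}}
        for patch in patches:
            is_bare = bool(rng.random() < design.bare_patch_prob)
            bare[(sp, patch)] = is_bare
            baseline = rng.uniform(*design.baseline_range)
            n_peaks = int(rng.integers(design.peaks_per_patch[0], design.peaks_per_patch[1] + 1))
            shapes = []
            for _ in range(n_peaks):
                shapes.append(
                    (
                        "sigmoid" if rng.random() < design.sigmoid_patch_prob else "gauss",
                        rng.uniform(*design.peak_centre_range),
                        rng.uniform(*design.peak_amplitude_range),
                        rng.uniform(*design.peak_width_range),
                    )
                )
            shift = float(scale * design.sex_shift_nm * rng.choice([-1.0, 1.0]))
            amp_delta = float(scale * design.sex_amplitude_pct * rng.choice([-1.0, 1.0]))
            sp_truth["patches"][patch] = {
                "shift_nm": shift,
                "amplitude_delta_pct": amp_delta,
                "bare": is_bare,
            }
            for sex in ("male", "female"):
                d_c = shift if sex == "male" else 0.0
                d_a = 1.0 + (amp_delta / 100.0 if sex == "male" else 0.0)
                vals = np.full_like(wl, baseline, dtype=float)
                for kind, centre, amp, width in shapes:
                    f = _sigmoid if kind == "sigmoid" else _gauss
                    vals += f(wl, centre + d_c, amp * d_a, width)
                vals += _smooth_noise(
                    noise_rng, len(wl), design.noise_sd, design.noise_corr_length_nm, design.grid.step
                )
                curves[(sp, patch, sex)] = SpectralCurve(design.grid, np.clip(vals, 0.0, 100.0))
        truth["species"][sp] = sp_truth
    lib = PatchSpectraSet(design.grid, species, patches, curves, bare)
    return lib, truth


def generate_uv_contrast_case(
    design: SyntheticDesign | None = None,
    uv_centre: float = 355.0,
    uv_width: float = 14.0,
    amplitude: float = 40.0,
    amplitude_delta_pct: float = 60.0,
) -> PatchSpectraSet:
    """A single-species library whose sexual difference is confined to the UV.

    Both sexes share an identical long-wavelength reflectance profile; the
    male additionally differs only in the amplitude of a narrow peak centred
    below 400 nm. Such a patch should look more dichromatic to a UVS eye
    than to a VS eye, and less dichromatic through more UV-opaque ocular
    media — the discriminating test cases for eye-type claims.
    """
    design = design or SyntheticDesign(n_species=1, n_patches=1)
    grid = design.grid
    wl = grid.wavelengths
    if uv_centre + 3 * uv_width > 400.0:
        raise ValueError("UV peak must be confined below 400 nm")
    base = 15.0 + _gauss(wl, 560.0, 30.0, 50.0)
    female = base + _gauss(wl, uv_centre, amplitude, uv_width)
    male = base + _gauss(wl, uv_centre, amplitude * (1 + amplitude_delta_pct / 100.0), uv_width)
    curves = {
        ("uvbird", "uv_patch", "female"): SpectralCurve(grid, np.clip(female, 0, 100)),
        ("uvbird", "uv_patch", "male"): SpectralCurve(grid, np.clip(male, 0, 100)),
    }
    return PatchSpectraSet(grid, ["uvbird"], ["uv_patch"], curves)
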