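"""Single-parameter sweeps and exhaustive multi-parameter permutation.

The sensitivity analysis varies six classes of visual-model parameters:
light environment (7 illuminants), ocular-media T50 (4 values per eye
type), pigment peak sensitivities (11 sets: average, per-channel min/max,
all-min, all-max), oil-droplet cut-offs (9 sets: average, per-droplet
min/max, all-min, all-max), and relative cone densities (9 ratios). The
full Cartesian product is 7 × 4 × 11 × 9 × 9 = 24,948 parameterizations
per eye type.

``single_parameter_sweep`` recomputes species dichromatism tables while one
parameter class varies and summarizes every pairwise comparison;
``permute_all`` evaluates one species' mean score and above-threshold patch
count for every combination in a :class:`ParameterSpace`, caching the
optical stage (sensitivities, catches, von Kries signals) so that density
ratios — which only rescale channel noise — are applied afterwards.

Extreme parameter values that are not established physiology ship as
clearly marked placeholders; sweeps refuse to run on them unless
``allow_placeholders`` is set, so fabricated values can never silently
enter an analysis.
"""

from __future__ import annotations

import itertools
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .distance import NoiseModel, jnd_from_signals
from .illuminants import ILLUMINANT_NAMES, builtin_illuminant
from .receptors import (
    CHANNEL_NAMES,
    OcularMedia,
    OilDroplet,
    Photopigment,
    ReceptorChannel,
    VisualModelSpec,
    build_eye_sensitivities,
)
from .scoring import (
    JND_THRESHOLD,
    ComparisonStats,
    DichromatismTable,
    _fractional,
    compare_conditions,
    patch_jnd_matrix,
)
from .spectra import PatchSpectraSet

__all__ = [
    "SensitivitySet",
    "DropletSet",
    "DensityRatio",
    "ParameterSpace",
    "PlaceholderError",
    "build_parameter_space",
    "spec_for_combination",
    "single_parameter_sweep",
    "permute_all",
    "summarize_distributions",
]

_DROPLET_KINDS = ("C", "Y", "R")  # SWS2, MWS, LWS; SWS1 keeps its T droplet


class PlaceholderError(RuntimeError):
    """A sweep touched placeholder physiology without explicit permission."""


@dataclass(frozen=True)
class SensitivitySet:
    label: str
    lambda_max: tuple[float, float, float, float]
    placeholder: bool = False


@dataclass(frozen=True)
class DropletSet:
    """(λcut, Bmid) for the C, Y, R droplets (SWS2/MWS/LWS)."""

    label: str
    cut_bmid: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    placeholder: bool = False


@dataclass(frozen=True)
class DensityRatio:
    label: str
    densities: tuple[float, float, float, float]
    placeholder: bool = False


@dataclass(frozen=True)
class ParameterSpace:
    """Per-eye-type parameter sets whose Cartesian product is swept."""

    eye_type: str
    illuminants: tuple[str, ...]
    t50_values: tuple[float, ...]
    sensitivity_sets: tuple[SensitivitySet, ...]
    droplet_sets: tuple[DropletSet, ...]
    density_ratios: tuple[DensityRatio, ...]
    reference_weber: float = 0.05

    @property
    def size(self) -> int:
        return (
            len(self.illuminants)
            * len(self.t50_values)
            * len(self.sensitivity_sets)
            * len(self.droplet_sets)
            * len(self.density_ratios)
        )

    @property
    def has_placeholders(self) -> bool:
        return any(
            s.placeholder
            for s in (*self.sensitivity_sets, *self.droplet_sets, *self.density_ratios)
        )

    def combinations(self) -> Iterator[tuple]:
        return itertools.product(
            self.illuminants,
            self.t50_values,
            self.sensitivity_sets,
            self.droplet_sets,
            self.density_ratios,
        )


def spec_for_combination(
    eye_type: str,
    illuminant: str,
    t50: float,
    sens: SensitivitySet,
    droplets: DropletSet,
    densities: DensityRatio,
    reference_weber: float = 0.05,
) -> VisualModelSpec:
    """Assemble the full visual-model spec for one parameter combination."""
    channels = [ReceptorChannel("SWS1", Photopigment(sens.lambda_max[0]), OilDroplet("T"))]
    for name, kind, lmax, (cut, bmid) in zip(
        CHANNEL_NAMES[1:], _DROPLET_KINDS, sens.lambda_max[1:], droplets.cut_bmid
    ):
        channels.append(ReceptorChannel(name, Photopigment(lmax), OilDroplet(kind, cut, bmid)))
    return VisualModelSpec(
        eye_type=eye_type,
        channels=tuple(channels),  # type: ignore[arg-type]
        ocular=OcularMedia(t50),
        densities=densities.densities,
        reference_weber=reference_weber,
        illuminant=illuminant,
        label=f"{eye_type}|{illuminant}|T{t50:g}|{sens.label}|{droplets.label}|{densities.label}",
    )


def _load_space_config(eye_type: str) -> dict:
    ref = resources.files("dichroma.data.parameter_space") / f"{eye_type.lower()}.toml"
    with ref.open("rb") as fh:
        return tomllib.load(fh)


def build_parameter_space(eye_type: str, config: dict | None = None) -> ParameterSpace:
    """Build the swept parameter space for one eye type.

    *config* defaults to the packaged tables (average values are established
    physiology; extreme values may be placeholders and are flagged as such).
    Set cardinalities are enforced: 7 illuminants, 4 T50 values, 11
    sensitivity sets, 9 droplet sets, 9 density ratios.
    """
    cfg = config if config is not None else _load_space_config(eye_type)
    sens = tuple(
        SensitivitySet(e["label"], tuple(e["lambda_max"]), bool(e.get("placeholder", False)))
        for e in cfg["sensitivity_sets"]
    )
    drops = tuple(
        DropletSet(
            e["label"],
            tuple((pair[0], pair[1]) for pair in e["cut_bmid"]),  # type: ignore[arg-type]
            bool(e.get("placeholder", False)),
        )
        for e in cfg["droplet_sets"]
    )
    dens = tuple(
        DensityRatio(e["label"], tuple(e["densities"]), bool(e.get("placeholder", False)))
        for e in cfg["density_ratios"]
    )
    space = ParameterSpace(
        eye_type=eye_type,
        illuminants=tuple(cfg["illuminants"]),
        t50_values=tuple(cfg["t50_values"]),
        sensitivity_sets=sens,
        droplet_sets=drops,
        density_ratios=dens,
        reference_weber=float(cfg.get("reference_weber", 0.05)),
    )
    expected = cfg.get("expected_sizes")
    if expected is not None:
        actual = [
            len(space.illuminants),
            len(space.t50_values),
            len(space.sensitivity_sets),
            len(space.droplet_sets),
            len(space.density_ratios),
        ]
        if actual != list(expected):
            raise ValueError(f"parameter-space cardinalities {actual} != declared {expected}")
    return space


def _check_placeholders(space: ParameterSpace, allow: bool) -> None:
    if space.has_placeholders and not allow:
        bad = [
            s.label
            for s in (*space.sensitivity_sets, *space.droplet_sets, *space.density_ratios)
            if s.placeholder
        ]
        raise PlaceholderError(
            "parameter space contains placeholder physiology "
            f"({', '.join(bad)}); pass allow_placeholders=True to proceed"
        )


@dataclass(frozen=True)
class SweepResult:
    """All pairwise comparisons of a single-parameter sweep."""

    parameter: str
    labels: tuple[str, ...]
    vs_baseline: tuple[ComparisonStats, ...]
    pairwise: tuple[ComparisonStats, ...]
    tables: dict = field(repr=False, default_factory=dict)

    @property
    def most_divergent(self) -> ComparisonStats:
        return min(self.pairwise, key=lambda s: s.pearson_r)


def _apply_parameter(baseline: VisualModelSpec, parameter: str, value) -> VisualModelSpec:
    if parameter == "illuminant":
        return baseline.with_(illuminant=str(value), label=f"{baseline.eye_type}|illum={value}")
    if parameter == "ocular_t50":
        return baseline.with_(ocular=OcularMedia(float(value)), label=f"{baseline.eye_type}|T50={value:g}")
    if parameter == "sensitivity_set":
        channels = tuple(
            ReceptorChannel(ch.name, Photopigment(lmax), ch.droplet)
            for ch, lmax in zip(baseline.channels, value.lambda_max)
        )
        return baseline.with_(channels=channels, label=f"{baseline.eye_type}|sens={value.label}")
    if parameter == "droplet_set":
        channels = [baseline.channels[0]]
        for ch, kind, (cut, bmid) in zip(baseline.channels[1:], _DROPLET_KINDS, value.cut_bmid):
            channels.append(ReceptorChannel(ch.name, ch.pigment, OilDroplet(kind, cut, bmid)))
        return baseline.with_(channels=tuple(channels), label=f"{baseline.eye_type}|drop={value.label}")
    if parameter == "densities":
        dens = value.densities if isinstance(value, DensityRatio) else tuple(value)
        lab = value.label if isinstance(value, DensityRatio) else str(dens)
        return baseline.with_(densities=dens, label=f"{baseline.eye_type}|dens={lab}")
    raise ValueError(f"unknown sweep parameter {parameter!r}")


def single_parameter_sweep(
    spectra: PatchSpectraSet,
    baseline: VisualModelSpec,
    parameter: str,
    values: Sequence,
    allow_placeholders: bool = False,
) -> SweepResult:
    """Vary one parameter class; compare every value against the baseline
    and all pairs of values. The most divergent pair is the one with the
    lowest Pearson r of species mean scores."""
    for v in values:
        if getattr(v, "placeholder", False) and not allow_placeholders:
            raise PlaceholderError(
                f"value {getattr(v, 'label', v)!r} is placeholder physiology; "
                "pass allow_placeholders=True to proceed"
            )
    base_table = patch_jnd_matrix(spectra, baseline)
    tables: dict[str, DichromatismTable] = {}
    labels: list[str] = []
    for v in values:
        spec = _apply_parameter(baseline, parameter, v)
        labels.append(spec.label)
        tables[spec.label] = patch_jnd_matrix(spectra, spec)
    vs_baseline = tuple(compare_conditions(base_table, tables[lab]) for lab in labels)
    pairwise = tuple(
        compare_conditions(tables[la], tables[lb])
        for la, lb in itertools.combinations(labels, 2)
    ) or vs_baseline
    tables["baseline"] = base_table
    return SweepResult(parameter, tuple(labels), vs_baseline, pairwise, tables)


def permute_all(
    spectra: PatchSpectraSet,
    species: str,
    space: ParameterSpace,
    allow_placeholders: bool = False,
) -> pd.DataFrame:
    """Mean dichromatism score and above-threshold patch count for *species*
    under every combination in *space*.

    The optical stage (channel sensitivities → quantum catches → von Kries
    signals Δf per patch) is computed once per (sensitivity set, droplet
    set, T50, illuminant); density ratios only change channel noise and are
    applied to the cached signals.
    """
    _check_placeholders(space, allow_placeholders)
    patches = spectra.feathered_patches(species)
    if not patches:
        raise ValueError(f"species {species!r} has no feathered patches")
    grid = spectra.grid
    step = grid.step
    refl_m = np.stack([_fractional(spectra.curve(species, p, "male")).values for p in patches])
    refl_f = np.stack([_fractional(spectra.curve(species, p, "female")).values for p in patches])
    illum_curves = {name: builtin_illuminant(name, grid).curve.values for name in space.illuminants}
    weber_sets = [
        NoiseModel(d.densities, space.reference_weber).webers for d in space.density_ratios
    ]

    rows: list[tuple] = []
    for sens_set, drop_set, t50 in itertools.product(
        space.sensitivity_sets, space.droplet_sets, space.t50_values
    ):
        spec = spec_for_combination(
            space.eye_type, "ideal", t50, sens_set, drop_set, space.density_ratios[0],
            space.reference_weber,
        )
        S = np.stack([c.values for c in build_eye_sensitivities(spec, grid)])  # (4, n_wl)
        for illum in space.illuminants:
            eff = S * illum_curves[illum]  # (4, n_wl)
            norms = eff.sum(axis=1) * step
            qm = (refl_m @ eff.T) * step / norms  # (n_patch, 4) von Kries signals
            qf = (refl_f @ eff.T) * step / norms
            delta_f = np.log(qm / qf)
            for dens, webers in zip(space.density_ratios, weber_sets):
                jnds = np.array([jnd_from_signals(df, webers) for df in delta_f])
                floored = np.where(jnds >= JND_THRESHOLD, jnds, 0.0)
                rows.append(
                    (
                        illum,
                        t50,
                        sens_set.label,
                        drop_set.label,
                        dens.label,
                        floored.sum() / len(patches),
                        int((jnds > JND_THRESHOLD).sum()),
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "illuminant",
            "t50",
            "sensitivity_set",
            "droplet_set",
            "density_ratio",
            "mean_score",
            "n_patches_gt1",
        ],
    )
    df.attrs["species"] = species
    df.attrs["eye_type"] = space.eye_type
    return df


def summarize_distributions(result_uvs: pd.DataFrame, result_vs: pd.DataFrame) -> dict:
    """Combined-range summary of two eye types' permutation score sets.

    percent_difference = 100 · max/min of the pooled scores (NaN if min is
    0); overlap = length of the intersection of the two eye types' score
    ranges over the pooled range, floored at 0; mean_ratio = grand mean of
    UVS scores over grand mean of VS scores.
    """
    u = result_uvs["mean_score"].to_numpy()
    v = result_vs["mean_score"].to_numpy()
    lo, hi = min(u.min(), v.min()), max(u.max(), v.max())
    width = hi - lo
    inter = min(u.max(), v.max()) - max(u.min(), v.min())
    return {
        "min": float(lo),
        "max": float(hi),
        "percent_difference": float(100.0 * hi / lo) if lo > 0 else float("nan"),
        "overlap": float(max(inter, 0.0) / width) if width > 0 else 1.0,
        "mean_ratio_uvs_vs": float(u.mean() / v.mean()) if v.mean() > 0 else float("nan"),
        "n_uvs": int(len(u)),
        "n_vs": int(len(v)),
    }
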