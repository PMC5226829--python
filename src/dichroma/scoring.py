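"""Dichromatism scoring: per-patch male–female JNDs, species scores, ranks,
and the comparison statistics used to contrast two visual-model
parameterizations.

A species' dichromatism score is the mean of its male-vs-female patch
contrasts over *feathered* patches, with sub-threshold contrasts (< 1 JND,
i.e. indiscriminable) floored to 0 before averaging so that undetectable
differences do not inflate the score. Bare (non-feathered) patches are
excluded from both numerator and denominator.

Two parameterizations are compared by (1) the Pearson correlation of the
species mean scores and (2) rank statistics: how many species keep the same
rank, the mean/SD/maximum absolute rank change (rank 1 = most dichromatic;
ties get average ranks). Patch-level change summaries are reported for the
focal species most affected by mean score or by rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .distance import NoiseModel, jnd_distance, quantum_catches, von_kries
from .illuminants import builtin_illuminant
from .receptors import VisualModelSpec, build_eye_sensitivities
from .spectra import PatchSpectraSet, SpectralCurve

__all__ = [
    "DichromatismTable",
    "ComparisonStats",
    "PatchChangeStats",
    "REFLECTANCE_FLOOR",
    "patch_jnd_matrix",
    "floor_and_score",
    "rank_species",
    "compare_conditions",
    "patch_change_stats",
]

# Minimum fractional reflectance fed to the catch integral; avoids zero
# catches for channels whose sensitivity lies entirely in a spectral region
# where a patch reflects nothing (UV edge).
REFLECTANCE_FLOOR = 1e-4

JND_THRESHOLD = 1.0


@dataclass
class DichromatismTable:
    """Species × patch JND matrix under one model parameterization.

    ``raw`` holds un-floored JNDs (NaN for bare or missing patches);
    flooring (< 1 JND → 0) applies only when scores are formed.
    """

    raw: pd.DataFrame
    label: str = ""
    scored: bool = False

    @property
    def floored(self) -> pd.DataFrame:
        return self.raw.where(self.raw.isna() | (self.raw >= JND_THRESHOLD), 0.0)

    @property
    def n_feathered(self) -> pd.Series:
        return self.raw.notna().sum(axis=1)

    @property
    def scores(self) -> pd.Series:
        """Species mean dichromatism score: Σ floored / n_feathered."""
        return self.floored.sum(axis=1) / self.n_feathered

    @property
    def species(self) -> list[str]:
        return list(self.raw.index)


def _fractional(curve: SpectralCurve) -> SpectralCurve:
    # percent -> fractional, with the configured positivity floor
    return SpectralCurve(curve.grid, np.maximum(curve.values / 100.0, REFLECTANCE_FLOOR))


def patch_jnd_matrix(spectra: PatchSpectraSet, spec: VisualModelSpec) -> DichromatismTable:
    """Raw male-vs-female JND per feathered patch under *spec*.

    Builds the four channel sensitivities and the spec's illuminant once,
    then applies the catch → von Kries → receptor-noise pipeline per patch.
    """
    sens = build_eye_sensitivities(spec, spectra.grid)
    illum = builtin_illuminant(spec.illuminant, spectra.grid)
    webers = NoiseModel(spec.densities, spec.reference_weber).webers
    raw = pd.DataFrame(np.nan, index=spectra.species, columns=spectra.patches, dtype=float)
    for sp in spectra.species:
        for patch in spectra.feathered_patches(sp):
            qm = von_kries(
                quantum_catches(_fractional(spectra.curve(sp, patch, "male")), illum, sens),
                illum,
                sens,
            )
            qf = von_kries(
                quantum_catches(_fractional(spectra.curve(sp, patch, "female")), illum, sens),
                illum,
                sens,
            )
            raw.loc[sp, patch] = jnd_distance(qm, qf, webers).delta_s
    return DichromatismTable(raw=raw, label=spec.label or spec.eye_type)


def floor_and_score(table: DichromatismTable) -> DichromatismTable:
    """Mark the table as scored (flooring and species means are derived
    views; this records that the scoring rule has been applied)."""
    return DichromatismTable(raw=table.raw, label=table.label, scored=True)


def rank_species(scores: pd.Series) -> pd.Series:
    """Rank species by mean score, rank 1 = most dichromatic, ties averaged."""
    return pd.Series(stats.rankdata(-scores.to_numpy()), index=scores.index)


@dataclass(frozen=True)
class PatchChangeStats:
    """Patch-level change summary for one focal species between two models."""

    species: str
    n_below_threshold_a: int
    n_below_threshold_b: int
    n_changed_gt1: int
    max_change_jnd: float
    max_change_pct: float  # NaN when either side of the max-change patch < 1 JND
    pct_denominator: str = "smaller"


@dataclass(frozen=True)
class ComparisonStats:
    """Score- and rank-agreement statistics between two parameterizations."""

    label_a: str
    label_b: str
    pearson_r: float
    equal_rank: int
    mean_rank_change: float
    sd_rank_change: float
    max_rank_change: float
    focal_by_score: str
    focal_by_rank: str
    n_species: int


def compare_conditions(a: DichromatismTable, b: DichromatismTable) -> ComparisonStats:
    """Compare species scores/ranks under two parameterizations.

    Rank-change statistics are absolute changes averaged over all species.
    Focal species: largest |Δ mean score| and largest |Δ rank|.
    """
    if set(a.species) != set(b.species):
        raise ValueError("the two tables cover different species sets")
    sa = a.scores
    sb = b.scores.reindex(sa.index)
    if len(sa) >= 2 and sa.std() > 0 and sb.std() > 0:
        r = float(stats.pearsonr(sa, sb).statistic)
    else:
        r = float("nan")
    ra, rb = rank_species(sa), rank_species(sb)
    d = (ra - rb).abs()
    return ComparisonStats(
        label_a=a.label,
        label_b=b.label,
        pearson_r=r,
        equal_rank=int((d == 0).sum()),
        mean_rank_change=float(d.mean()),
        sd_rank_change=float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        max_rank_change=float(d.max()),
        focal_by_score=str((sa - sb).abs().idxmax()),
        focal_by_rank=str(d.idxmax()),
        n_species=len(sa),
    )


def patch_change_stats(
    a: DichromatismTable,
    b: DichromatismTable,
    species: str,
    pct_denominator: str = "smaller",
) -> PatchChangeStats:
    """Per-patch change summary for *species* between tables A and B.

    Counts use raw (un-floored) JNDs. The percentage change is reported for
    the patch with the largest |Δ JND|; it is NaN if either side of that
    patch is below 1 JND. The denominator convention is configurable
    ("smaller" | "larger" | "condition_a") and is recorded in the result.
    """
    if species not in a.species or species not in b.species:
        raise KeyError(f"unknown species {species!r}")
    ra = a.raw.loc[species].dropna()
    rb = b.raw.loc[species].reindex(ra.index)
    if rb.isna().any():
        raise ValueError("feathered patch sets differ between conditions")
    delta = (ra - rb).abs()
    patch = delta.idxmax()
    va, vb = float(ra[patch]), float(rb[patch])
    if min(va, vb) < JND_THRESHOLD:
        pct = float("nan")
    else:
        denom = {
            "smaller": min(va, vb),
            "larger": max(va, vb),
            "condition_a": va,
        }[pct_denominator]
        pct = 100.0 * float(delta[patch]) / denom
    return PatchChangeStats(
        species=species,
        n_below_threshold_a=int((ra < JND_THRESHOLD).sum()),
        n_below_threshold_b=int((rb < JND_THRESHOLD).sum()),
        n_changed_gt1=int((delta > JND_THRESHOLD).sum()),
        max_change_jnd=float(delta.max()),
        max_change_pct=pct,
        pct_denominator=pct_denominator,
    )
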