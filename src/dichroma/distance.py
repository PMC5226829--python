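"""Quantum catches, von Kries correction, and the receptor-noise distance.

The chromatic distance between two reflectance spectra A and B for a
tetrachromat follows Vorobyev & Osorio's receptor-noise-limited model:

* quantum catch per channel i: ``Q_i = Σ_λ R(λ) I(λ) S_i(λ) Δλ``
* von Kries-corrected catch:    ``q_i = Q_i / Σ_λ I(λ) S_i(λ) Δλ``
* receptor signal:              ``Δf_i = ln(q_i^A / q_i^B)``
* noise per channel:            ``e_i = ω_i`` (Weber fraction), with
  ``ω_i = ν / √η_i`` for relative cone density η_i, and the noise scale ν
  chosen so the most abundant channel has a fixed reference Weber fraction
  (0.05 by default; ties broken toward LWS).
* distance in just-noticeable differences (JND):

  ``ΔS² = [Σ_{i<j} (e_prod/(e_i e_j))² (Δf_i − Δf_j)²] / [Σ_i (e_prod/e_i)²]``

  where e_prod = Π e_k — the standard tetrachromatic formula, written here
  in its generic n-receptor form. ΔS = 1 is one JND; pairs below 1 JND are
  considered indiscriminable.

Catches are computed in relative units: the model is invariant to scaling
of the illuminant or of any channel's sensitivity (tested properties), so
no absolute calibration is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .illuminants import Illuminant
from .spectra import SpectralCurve

__all__ = [
    "NoiseModel",
    "ContrastResult",
    "ZeroCatchError",
    "quantum_catch",
    "quantum_catches",
    "von_kries",
    "weber_fractions",
    "jnd_distance",
    "jnd_from_signals",
]

# Most-abundant-channel ties break toward LWS (index 3), the classic
# reference receptor; higher index wins.
_LWS_INDEX = 3


class ZeroCatchError(ValueError):
    """A channel caught no light from a stimulus — the spectrum is invisible
    to that channel and a log-ratio signal is undefined.

    Callers may pre-floor reflectance at a small positive value (the scoring
    layer does, at 1e-4 fractional by default) instead of silently adding an
    epsilon here.
    """


@dataclass(frozen=True)
class NoiseModel:
    """Channel noise derived from relative cone densities.

    ``nu`` is the single-receptor noise standard deviation chosen so that
    ``weber[argmax(density)] == reference_weber``.
    """

    densities: tuple[float, float, float, float]
    reference_weber: float = 0.05

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.densities):
            raise ValueError("densities must be positive")
        if not (0.0 < self.reference_weber < 1.0):
            raise ValueError("reference Weber fraction must be in (0, 1)")

    @property
    def reference_index(self) -> int:
        eta = np.asarray(self.densities)
        best = eta.max()
        tied = np.flatnonzero(eta == best)
        return int(tied[-1])  # ties toward LWS (later channels)

    @property
    def nu(self) -> float:
        return self.reference_weber * float(np.sqrt(self.densities[self.reference_index]))

    @property
    def webers(self) -> np.ndarray:
        return self.nu / np.sqrt(np.asarray(self.densities, dtype=float))


def weber_fractions(noise: NoiseModel) -> np.ndarray:
    """Per-channel Weber fractions ω_i = ν/√η_i, most abundant pinned at ω_ref."""
    return noise.webers


@dataclass(frozen=True)
class ContrastResult:
    delta_f: np.ndarray
    delta_s: float


def quantum_catch(
    reflectance: SpectralCurve, illuminant: Illuminant, sensitivity: SpectralCurve
) -> float:
    """Absolute catch Q = Σ R·I·S·Δλ (reflectance in fractional units)."""
    for curve in (illuminant.curve, sensitivity):
        if curve.grid != reflectance.grid:
            raise ValueError("reflectance, illuminant and sensitivity must share a grid")
    if not np.any(sensitivity.values > 0):
        raise ValueError("sensitivity curve is identically zero")
    step = reflectance.grid.step
    return float(np.sum(reflectance.values * illuminant.curve.values * sensitivity.values) * step)


def quantum_catches(
    reflectance: SpectralCurve, illuminant: Illuminant, sensitivities: list[SpectralCurve]
) -> np.ndarray:
    return np.array([quantum_catch(reflectance, illuminant, s) for s in sensitivities])


def von_kries(
    catches: np.ndarray, illuminant: Illuminant, sensitivities: list[SpectralCurve]
) -> np.ndarray:
    """Normalize catches channel-wise by the catch of the adapting illuminant:
    q_i = Q_i / Σ I·S_i·Δλ. Removes any dependence on illuminant intensity."""
    step = sensitivities[0].grid.step
    norms = np.array(
        [float(np.sum(illuminant.curve.values * s.values) * step) for s in sensitivities]
    )
    if np.any(norms <= 0):
        raise ValueError("von Kries normalizer vanished for a channel")
    return np.asarray(catches, dtype=float) / norms


def jnd_from_signals(delta_f: np.ndarray, webers: np.ndarray) -> float:
    """Receptor-noise distance from per-channel signals Δf_i and noises ω_i.

    Generic n-receptor form: with w_i = 1/ω_i²,
    ΔS² = Σ_{i<j} w_i w_j (Δf_i − Δf_j)² / Σ_k w_k.
    """
    delta_f = np.asarray(delta_f, dtype=float)
    e = np.asarray(webers, dtype=float)
    w = 1.0 / e**2
    n = len(delta_f)
    num = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            num += w[i] * w[j] * (delta_f[i] - delta_f[j]) ** 2
    return float(np.sqrt(num / w.sum()))


def jnd_distance(qa: np.ndarray, qb: np.ndarray, webers: np.ndarray) -> ContrastResult:
    """Chromatic distance (JND) between von Kries-corrected catch vectors.

    Symmetric in (A, B); zero iff all Δf_i are equal (a pure intensity
    difference). Raises :class:`ZeroCatchError` on non-positive catches.
    """
    qa = np.asarray(qa, dtype=float)
    qb = np.asarray(qb, dtype=float)
    if np.any(qa <= 0) or np.any(qb <= 0):
        raise ZeroCatchError(
            "non-positive quantum catch: a stimulus is invisible to a channel"
        )
    delta_f = np.log(qa / qb)
    return ContrastResult(delta_f=delta_f, delta_s=jnd_from_signals(delta_f, webers))
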