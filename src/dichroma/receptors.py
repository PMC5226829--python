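"""Avian single-cone receptor model.

Builds the four single-cone spectral sensitivities (SWS1, SWS2, MWS, LWS)
of a parameterized tetrachromatic eye as the product of three curves:

1. **Visual pigment absorbance** from the wavelength of peak absorbance
   (λmax) using the near-universal A1 rhodopsin template of Govardovskii
   et al. (2000), α-band plus (optionally) β-band.
2. **Oil droplet transmission**: each cone carries a carotenoid oil droplet
   acting as a long-pass cut-off filter, modelled after Hart & Vorobyev
   (2005) as ``T(λ) = exp(−exp(−b·(λ − λo)))`` where the 1/e-transmission
   wavelength λo and decay rate b derive from the measured cut-off
   wavelength λcut and tangent gradient Bmid: ``b = 2.89·Bmid``,
   ``λo = λcut + 1.08/b``. T-type droplets (paired with SWS1) do not filter.
3. **Ocular media transmission** (cornea + lens): a long-pass filter
   summarized by the wavelength of 50% transmission (T50), modelled as a
   logistic ``T(λ) = 1/(1 + exp(−k·(λ − T50)))``.

Sensitivities are unit-peak normalized; the normalization is provably
irrelevant to JNDs after the von Kries correction (a tested invariance).

Two reference parameterizations are built in: the widely used "average"
UVS and VS avian visual systems, with the Pekin robin density ratio
1:2:2:4 and a reference Weber fraction of 0.05 for the most abundant cone.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

from .spectra import DEFAULT_GRID, SpectralCurve, WavelengthGrid

__all__ = [
    "Photopigment",
    "OilDroplet",
    "OcularMedia",
    "ReceptorChannel",
    "VisualModelSpec",
    "CHANNEL_NAMES",
    "pigment_absorbance",
    "droplet_transmission",
    "ocular_transmission",
    "channel_sensitivity",
    "build_eye_sensitivities",
    "build_average_eye",
    "load_visual_system",
]

CHANNEL_NAMES = ("SWS1", "SWS2", "MWS", "LWS")

# Govardovskii et al. (2000) A1 template constants.
PIGMENT_TEMPLATE = {
    "A": 69.7,
    "B": 28.0,
    "b": 0.922,
    "C": -14.9,
    "c": 1.104,
    "D": 0.674,
    # a = a0 + a1 * exp(-(lmax - a2)^2 / a3)
    "a0": 0.8795,
    "a1": 0.0459,
    "a2": 300.0,
    "a3": 11940.0,
    # beta band: amplitude, centre and width as linear functions of lmax
    "beta_A": 0.26,
    "beta_mu0": 189.0,
    "beta_mu1": 0.315,
    "beta_w0": -40.5,
    "beta_w1": 0.195,
}

# Oil droplet transmission constants (Hart & Vorobyev 2005); the
# Bmid-from-λmid entry is the exact tangent relation Bmid = 0.5/(λmid − λcut).
DROPLET_CONSTANTS = {
    "b_per_bmid": 2.89,
    "lambda_o_offset": 1.08,
    "half_absorbance": 0.5,
}

# Logistic slope of the ocular-media transmission curve (per nm);
# gives a 10–90% rise over ~42 nm, resembling published avian curves.
OCULAR_SLOPE = 0.105


class ReceptorError(ValueError):
    """Raised for invalid receptor parameterizations."""


@dataclass(frozen=True)
class Photopigment:
    """A1 visual pigment identified by its peak-absorbance wavelength (nm)."""

    lambda_max: float

    def __post_init__(self) -> None:
        if not (300.0 <= self.lambda_max <= 700.0):
            raise ReceptorError(f"lambda_max {self.lambda_max} outside 300–700 nm")


@dataclass(frozen=True)
class OilDroplet:
    """Cone oil droplet: T (non-filtering) or a C/Y/R cut-off filter.

    For filtering droplets ``lambda_cut`` plus exactly one of ``b_mid`` /
    ``lambda_mid`` must be given; ``lambda_o`` (1/e transmission point) and
    the decay rate ``b`` are derived.
    """

    kind: str
    lambda_cut: float | None = None
    b_mid: float | None = None
    lambda_mid: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("T", "C", "Y", "R"):
            raise ReceptorError(f"unknown droplet kind {self.kind!r}")
        if self.kind == "T":
            if self.lambda_cut is not None or self.b_mid is not None:
                raise ReceptorError("T-type droplets carry no filter parameters")
            return
        if self.lambda_cut is None:
            raise ReceptorError(f"{self.kind}-type droplet requires lambda_cut")
        if (self.b_mid is None) == (self.lambda_mid is None):
            raise ReceptorError(
                f"{self.kind}-type droplet requires exactly one of b_mid / lambda_mid"
            )
        if self.effective_b_mid() <= 0:
            raise ReceptorError("droplet gradient Bmid must be positive")

    def effective_b_mid(self) -> float:
        if self.b_mid is not None:
            return self.b_mid
        assert self.lambda_mid is not None and self.lambda_cut is not None
        denom = self.lambda_mid - self.lambda_cut
        if denom <= 0:
            raise ReceptorError("lambda_mid must exceed lambda_cut")
        return DROPLET_CONSTANTS["half_absorbance"] / denom

    @property
    def decay_rate(self) -> float:
        """Exponential decay rate b of the transmission model (per nm)."""
        return DROPLET_CONSTANTS["b_per_bmid"] * self.effective_b_mid()

    @property
    def lambda_o(self) -> float:
        """Wavelength (nm) at which droplet transmittance equals 1/e."""
        if self.kind == "T":
            raise ReceptorError("T-type droplets have no 1/e point")
        assert self.lambda_cut is not None
        return self.lambda_cut + DROPLET_CONSTANTS["lambda_o_offset"] / self.decay_rate


@dataclass(frozen=True)
class OcularMedia:
    """Cornea + lens long-pass filter, summarized by T50 (nm)."""

    t50: float

    def __post_init__(self) -> None:
        if not (300.0 <= self.t50 <= 450.0):
            raise ReceptorError(f"T50 {self.t50} outside the plausible 300–450 nm band")


@dataclass(frozen=True)
class ReceptorChannel:
    name: str
    pigment: Photopigment
    droplet: OilDroplet

    def __post_init__(self) -> None:
        if self.name not in CHANNEL_NAMES:
            raise ReceptorError(f"channel name {self.name!r} not in {CHANNEL_NAMES}")


@dataclass(frozen=True)
class VisualModelSpec:
    """One complete visual-model parameterization.

    ``densities`` are the relative cone abundances η (SWS1..LWS order);
    ``reference_weber`` is the Weber fraction pinned to the most abundant
    channel (ties broken toward LWS).
    """

    eye_type: str
    channels: tuple[ReceptorChannel, ReceptorChannel, ReceptorChannel, ReceptorChannel]
    ocular: OcularMedia
    densities: tuple[float, float, float, float]
    reference_weber: float = 0.05
    illuminant: str = "ideal"
    include_beta_band: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        if self.eye_type not in ("UVS", "VS"):
            raise ReceptorError(f"eye_type must be UVS or VS, got {self.eye_type!r}")
        if len(self.channels) != 4:
            raise ReceptorError("a tetrachromatic spec needs exactly 4 channels")
        if any(d <= 0 for d in self.densities):
            raise ReceptorError("densities must be positive")
        if not (0.0 < self.reference_weber < 1.0):
            raise ReceptorError("reference Weber fraction must be in (0, 1)")

    def with_(self, **changes) -> "VisualModelSpec":
        return replace(self, **changes)


def pigment_absorbance(
    pigment: Photopigment,
    grid: WavelengthGrid = DEFAULT_GRID,
    include_beta_band: bool = True,
) -> SpectralCurve:
    """Unit-peak pigment absorbance from λmax via the A1 template.

    The α-band is the Govardovskii et al. (2000) rational-exponential form in
    x = λmax/λ; the β-band is a Gaussian whose centre and width are linear in
    λmax. The sum is renormalized to unit peak.
    """
    t = PIGMENT_TEMPLATE
    lmax = pigment.lambda_max
    wl = grid.wavelengths
    x = lmax / wl
    a = t["a0"] + t["a1"] * np.exp(-((lmax - t["a2"]) ** 2) / t["a3"])
    alpha = 1.0 / (
        np.exp(t["A"] * (a - x))
        + np.exp(t["B"] * (t["b"] - x))
        + np.exp(t["C"] * (t["c"] - x))
        + t["D"]
    )
    total = alpha
    if include_beta_band:
        mu = t["beta_mu0"] + t["beta_mu1"] * lmax
        width = t["beta_w0"] + t["beta_w1"] * lmax
        beta = t["beta_A"] * np.exp(-(((wl - mu) / width) ** 2))
        total = alpha + beta
    return SpectralCurve(grid, total / total.max())


def droplet_transmission(droplet: OilDroplet, grid: WavelengthGrid = DEFAULT_GRID) -> SpectralCurve:
    """Oil-droplet transmission on *grid*: all-ones for T-type, else the
    Gompertz-type cut-off ``exp(−exp(−b(λ − λo)))`` (monotone, 1/e at λo)."""
    wl = grid.wavelengths
    if droplet.kind == "T":
        return SpectralCurve(grid, np.ones_like(wl))
    b = droplet.decay_rate
    return SpectralCurve(grid, np.exp(-np.exp(-b * (wl - droplet.lambda_o))))


def ocular_transmission(ocular: OcularMedia, grid: WavelengthGrid = DEFAULT_GRID) -> SpectralCurve:
    """Ocular-media transmission: logistic long-pass with T(T50) = 0.5."""
    wl = grid.wavelengths
    return SpectralCurve(grid, 1.0 / (1.0 + np.exp(-OCULAR_SLOPE * (wl - ocular.t50))))


def channel_sensitivity(
    channel: ReceptorChannel,
    ocular: OcularMedia | None,
    grid: WavelengthGrid = DEFAULT_GRID,
    include_beta_band: bool = True,
) -> SpectralCurve:
    """Unit-peak spectral sensitivity: pigment × droplet × ocular media.

    ``ocular=None`` means unit (non-filtering) ocular media; together with a
    T-type droplet the sensitivity then reduces to the pigment curve.
    """
    product = (
        pigment_absorbance(channel.pigment, grid, include_beta_band).values
        * droplet_transmission(channel.droplet, grid).values
        * (ocular_transmission(ocular, grid).values if ocular is not None else 1.0)
    )
    peak = product.max()
    if peak <= 0:
        raise ReceptorError(f"channel {channel.name} has zero sensitivity on the grid")
    return SpectralCurve(grid, product / peak)


def build_eye_sensitivities(
    spec: VisualModelSpec, grid: WavelengthGrid = DEFAULT_GRID
) -> list[SpectralCurve]:
    """The four channel sensitivities of *spec*, SWS1..LWS order."""
    return [
        channel_sensitivity(ch, spec.ocular, grid, spec.include_beta_band)
        for ch in spec.channels
    ]


# "Average" UVS / VS avian visual systems (Endler & Mielke parameter set):
# per-channel (λmax, droplet kind, λcut, Bmid) and ocular T50. The VS T50 of
# 348 nm is the value that reproduces the published sensitivity curves.
_AVERAGE_EYES = {
    "UVS": {
        "t50": 324.0,
        "channels": [
            ("SWS1", 367.0, "T", None, None),
            ("SWS2", 444.0, "C", 411.0, 0.0278),
            ("MWS", 501.0, "Y", 511.0, 0.023),
            ("LWS", 564.0, "R", 572.0, 0.022),
        ],
    },
    "VS": {
        "t50": 348.0,
        "channels": [
            ("SWS1", 412.0, "T", None, None),
            ("SWS2", 452.0, "C", 447.0, 0.0294),
            ("MWS", 505.0, "Y", 510.0, 0.028),
            ("LWS", 565.0, "R", 570.0, 0.020),
        ],
    },
}

# Pekin robin (Leiothrix lutea) relative cone densities, the classic
# receptor-noise default.
PEKIN_ROBIN_DENSITIES = (1.0, 2.0, 2.0, 4.0)


def build_average_eye(eye_type: str, illuminant: str = "ideal") -> VisualModelSpec:
    """The average UVS or VS avian eye: published λmax/λcut/Bmid/T50 values,
    1:2:2:4 densities, reference Weber fraction 0.05."""
    if eye_type not in _AVERAGE_EYES:
        raise ReceptorError(f"eye_type must be UVS or VS, got {eye_type!r}")
    cfg = _AVERAGE_EYES[eye_type]
    channels = tuple(
        ReceptorChannel(name, Photopigment(lmax), OilDroplet(kind, cut, bmid))
        for name, lmax, kind, cut, bmid in cfg["channels"]
    )
    return VisualModelSpec(
        eye_type=eye_type,
        channels=channels,  # type: ignore[arg-type]
        ocular=OcularMedia(cfg["t50"]),
        densities=PEKIN_ROBIN_DENSITIES,
        reference_weber=0.05,
        illuminant=illuminant,
        label=f"average_{eye_type}",
    )


def load_visual_system(
    name: str, illuminant: str = "ideal", allow_placeholders: bool = False
) -> VisualModelSpec:
    """Load a named visual-system parameter file shipped with the package.

    Files for fully characterized model species whose measured values are
    not bundled carry ``placeholder = true`` and are refused unless
    *allow_placeholders* is set, so stand-in physiology never enters an
    analysis silently.
    """
    ref = resources.files("dichroma.data.visual_systems") / f"{name}.toml"
    try:
        with ref.open("rb") as fh:
            cfg = tomllib.load(fh)
    except FileNotFoundError:
        raise ReceptorError(f"no visual-system file named {name!r}") from None
    if cfg.get("placeholder", False) and not allow_placeholders:
        raise ReceptorError(
            f"visual system {name!r} contains placeholder physiology; "
            "pass allow_placeholders=True to proceed"
        )
    channels = []
    for ch_name, lmax, dr in zip(CHANNEL_NAMES, cfg["lambda_max"], cfg["droplets"]):
        droplet = OilDroplet(dr["kind"], dr.get("lambda_cut"), dr.get("b_mid"))
        channels.append(ReceptorChannel(ch_name, Photopigment(float(lmax)), droplet))
    return VisualModelSpec(
        eye_type=cfg["eye_type"],
        channels=tuple(channels),
        ocular=OcularMedia(float(cfg["t50"])),
        densities=tuple(float(d) for d in cfg["densities"]),
        reference_weber=float(cfg.get("reference_weber", 0.05)),
        illuminant=illuminant,
        label=name,
    )
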