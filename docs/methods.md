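# Methods

## Spectral representation

All computation runs on one shared uniform wavelength grid, 300–700 nm at
1 nm (401 points) — the band over which avian single cones and their
pre-receptor filters are modelled. Curves off the grid are linearly
interpolated onto it; extrapolation is refused. Integrals are grid sums
× step, which is exactly reproducible and accurate to well below every
tolerance used here. Negative reflectance readings (instrument noise) are
clipped to 0 at read time; quantum catches require non-negative
reflectance. Reflectance is carried in percent in files and converted to
fractional units inside the catch integral, floored at 10⁻⁴ so that a
patch reflecting nothing inside a channel's band still yields a positive
catch (a zero catch makes the log-ratio signal undefined; the distance
layer raises a typed error rather than silently adding an epsilon, and the
scoring layer applies this documented floor instead).

## Receptor model

Channel sensitivity is the product of three curves, unit-peak normalized
(the normalization is provably irrelevant after the von Kries correction;
the invariance is tested):

1. **Pigment absorbance** — the Govardovskii et al. (2000) A1 template:
   α-band `1/(exp[A(a−x)] + exp[B(b−x)] + exp[C(c−x)] + D)` with
   x = λmax/λ, A = 69.7, B = 28, b = 0.922, C = −14.9, c = 1.104,
   D = 0.674, a = 0.8795 + 0.0459·exp(−(λmax−300)²/11940); β-band a
   Gaussian with amplitude 0.26, centre 189 + 0.315·λmax, width
   −40.5 + 0.195·λmax. The β-band is included by default and toggleable
   (`include_beta_band`), since pigment templates are published both ways.
2. **Oil-droplet transmission** — Hart & Vorobyev (2005):
   `T(λ) = exp(−exp(−b(λ−λo)))` with decay rate b = 2.89·Bmid and
   1/e-transmission point λo = λcut + 1.08/b, from the measured cut-off
   wavelength λcut and tangent gradient Bmid. When a source reports λmid
   instead of Bmid, the exact tangent geometry Bmid = 0.5/(λmid − λcut) is
   used; the constants live in one module-level table
   (`receptors.DROPLET_CONSTANTS`) so they can be corrected without code
   change. T-type droplets (paired with SWS1) are represented as an
   explicit non-filtering droplet (unit transmission on 300–700 nm), which
   keeps the four-channel pipeline uniform.
3. **Ocular-media transmission** — a logistic long-pass
   `T(λ) = 1/(1+exp(−k(λ−T50)))` anchored at the wavelength of 50%
   transmission, slope k = 0.105 nm⁻¹ (a 10–90% rise over ≈ 42 nm,
   resembling published avian cornea+lens curves). The logistic is this
   package's own choice of functional form; it satisfies every contract
   relied on downstream (T(T50) = 0.5 exactly, monotone non-decreasing,
   transmission everywhere weakly decreasing in T50) and the slope is a
   single exposed constant (`receptors.OCULAR_SLOPE`).

The built-in "average" UVS eye uses λmax (367, 444, 501, 564) nm, λcut
(—, 411, 511, 572) nm, Bmid (—, 0.0278, 0.023, 0.022), T50 324 nm; the
average VS eye λmax (412, 452, 505, 565), λcut (—, 447, 510, 570), Bmid
(—, 0.0294, 0.028, 0.020), T50 348 nm. The VS T50 of 348 nm (rather than
the 362 nm sometimes quoted) is the value that reproduces the published
average-eye sensitivity curves. Both default to the Pekin robin density
ratio 1:2:2:4 and reference Weber fraction 0.05.

## Noise and distance

Channel noise is density-derived: ω_i = ν/√η_i with ν chosen so the most
abundant channel has exactly the reference Weber fraction (0.05); density
ties break toward LWS, the classic reference receptor. The chromatic
distance is the receptor-noise-limited formula in generic-n form,
ΔS² = Σ_{i<j} w_i w_j (Δf_i−Δf_j)² / Σ_k w_k with w = 1/ω². This equals
the classic explicit tetrachromatic expression and, geometrically, the
noise-weighted distance of the signal vector Δf from the achromatic axis —
the test suite verifies it against an independent oracle that minimizes
Σ((Δf_i − c)/ω_i)² over the achromatic offset c numerically.

Consequences used as tests: ΔS is symmetric; zero for identical stimuli
and for any two flat (grey) spectra; exactly inverse-linear in a common
noise scale (6 JND → 3 at doubled Webers → 1.5 at quadrupled); invariant
to illuminant intensity and to rescaling any single channel's sensitivity.
Triangle-inequality behaviour is *not* asserted — the measure is a
threshold model and is not guaranteed metric far above threshold.

## Illuminants

Seven illuminants: ideal (wavelength-independent, computed), CIE standard
D65 (packaged from the standard 10-nm SPD table), and five habitat
illuminants (forest shade, woodland shade, woodland gaps, blue sky, cloudy
sky). The habitat tables shipped here are **synthetic stand-ins** carrying
only the qualitative spectral character their names imply (so named in
their filenames and provenance headers); replace them with measured
irradiances for quantitative habitat-specific work. Illuminant tables are
used in the units their sources declare, with no photon/energy conversion
applied — under the von Kries correction only spectral shape matters, and
the ideal illuminant is unit-convention-free. Because of von Kries, all
JNDs are invariant to illuminant scaling (tested to 10⁻¹⁰ relative).

## Scoring and comparison conventions

- Patch JNDs below 1 (indiscriminable) are floored to 0 *for scoring
  only*; raw JNDs are kept and used for change counts.
- Species score = Σ floored / number of feathered patches; bare patches
  are excluded from numerator and denominator.
- Ranks: 1 = most dichromatic; ties get average ranks. The direction is a
  disclosed convention — absolute rank-change statistics are direction-
  invariant.
- Rank-change statistics are absolute changes over **all** species (mean,
  sample SD, max).
- Patch "% change" needs a denominator the underlying convention of which
  is ambiguous; the default is the smaller of the two raw patch JNDs,
  selectable among {smaller, larger, condition_a}, and every report names
  the convention used. The % is reported as NA whenever either side of the
  max-change patch is below 1 JND.

## Parameter space and permutation

Per eye type: 7 illuminants × 4 ocular T50 values (UVS 314/324/334/344 nm;
VS 335/355/375/395 nm) × 11 pigment-sensitivity sets (average, each
channel at its min and max, all-min, all-max) × 9 droplet sets (average,
each filtering droplet at min/max, all-min, all-max) × 9 density ratios
= 24,948 combinations. The average values are established physiology; the
literature extremes are shipped as clearly flagged **placeholders**
(plausible ±12 nm λmax and ±15 nm λcut excursions, neutral density
ratios), and every sweep refuses placeholder entries unless
`allow_placeholders` is passed — fabricated physiology can never enter an
analysis silently. Edit `src/dichroma/data/parameter_space/*.toml` to
substitute measured extremes.

`permute_all` caches the optical stage: von Kries signals Δf per patch are
computed once per (sensitivity set, droplet set, T50, illuminant) — 2,772
optical configurations — and the 9 density ratios, which only rescale
channel noise, are applied to the cached signals. The full 24,948-row
sweep for one species runs in a few seconds; an invariant test confirms
that any cached combination equals its standalone recomputation.

Distribution summaries over a permutation: combined min/max; percent
difference = 100 · max/min (NA when min = 0); overlap = length of the
intersection of the two eye types' score ranges divided by the pooled
range, floored at 0; mean ratio = UVS grand mean / VS grand mean (a ratio
of grand means, since pairing combinations across eye types whose
parameter values differ is ill-defined). The percent-difference and
overlap definitions are this package's explicit choices for informally
described quantities.

## Synthetic data generator

Each patch is a baseline level plus 1–2 Gaussian reflectance peaks (20%
of shapes are sigmoid edges, the other common plumage-spectrum shape).
Sexual difference = per-patch peak-centre shift (≤ 20 nm) and/or amplitude
change (≤ 20%), multiplied by a per-species effect scale graded evenly
over [0, 1] — so true effect size and computed score can be
rank-correlated (the recovery test requires Spearman ρ > 0.9 at 30
species, zero noise). Measurement noise is spectrally smooth (Gaussian-
filtered white noise, correlation length 20 nm default) and drawn from a
separate random stream so the same seed yields identical plumage geometry
at any noise level. Reflectance is clipped to [0, 100]%. A dedicated
UV-contrast case confines the sexual difference below 400 nm, the
discriminating stimulus for UVS-vs-VS eye-type questions.

The generator emulates library *structure*, not galliform spectral
statistics: real patches have correlated colours within species,
melanin/structural-colour spectral shapes, and specimen-handling
artefacts. Passing tests therefore demonstrate pipeline correctness and
sensitivity-analysis behaviour, not field-accurate effect sizes.

## Problem sizes and defaults

The analysis drivers use a 30-species × 15-patch library (900 curves),
full 24,948-combination permutations for three exemplar species, and
1,000-vector oracle checks — sizes chosen so the complete pipeline runs in
well under a minute per driver on a single core while exercising every
code path at full parameter-space scale.

## Known limitations

- The habitat illuminants and parameter-space extremes are stand-ins (see
  above); quantitative habitat- or species-specific conclusions require
  measured tables.
- Achromatic (double-cone) contrast, rod/dim-light (quantum-noise) regimes,
  A2 chromophores and five-cone systems are out of scope.
- Supra-threshold JND differences are interpreted as distances, which is
  standard practice but behaviourally validated only sparsely.
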