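# dichroma

Receptor-noise tetrachromatic visual modelling and sensitivity analysis of
avian plumage dichromatism.

## The problem

How different do a male and a female bird look — *to a bird*? Avian colour
discrimination is commonly modelled with the receptor-noise-limited model:
each of the four single-cone classes (SWS1, SWS2, MWS, LWS) catches light
from a plumage patch, catches are normalized to the adapting illuminant
(von Kries correction), and the discriminability of two spectra is a
noise-weighted distance ΔS in units of just-noticeable differences (JND).
But the model needs a full visual-system parameterization — pigment peak
sensitivities, oil-droplet and ocular-media filtering, relative cone
densities, light environment — and these are measured for very few species.
This package quantifies how much the resulting *dichromatism scores* (the
species mean of male–female patch contrasts) depend on those assumptions,
by sweeping single parameters and exhaustively permuting all of them.

## The model

For channel *i* with spectral sensitivity *S<sub>i</sub>(λ)* (pigment
template × oil-droplet transmission × ocular-media transmission), stimulus
reflectance *R(λ)* and illuminant *I(λ)*:

- quantum catch  *Q<sub>i</sub> = Σ<sub>λ</sub> R·I·S<sub>i</sub>·Δλ*,
  von Kries-corrected *q<sub>i</sub> = Q<sub>i</sub> / Σ<sub>λ</sub> I·S<sub>i</sub>·Δλ*
- receptor signal  *Δf<sub>i</sub> = ln(q<sub>i</sub><sup>A</sup>/q<sub>i</sub><sup>B</sup>)*
- channel noise *e<sub>i</sub> = ω<sub>i</sub> = ν/√η<sub>i</sub>* from
  relative cone densities η, with the most abundant channel pinned at the
  reference Weber fraction (0.05)
- ΔS² = Σ<sub>i&lt;j</sub> w<sub>i</sub>w<sub>j</sub>(Δf<sub>i</sub>−Δf<sub>j</sub>)² / Σ<sub>k</sub>w<sub>k</sub>,
  with w<sub>i</sub> = 1/e<sub>i</sub>²  (the tetrachromatic
  receptor-noise distance in generic-*n* form)

Species score = mean of patch JNDs over feathered patches, with values
below 1 JND (indiscriminable) floored to 0. Two parameterizations are
compared by the Pearson r of species scores and by rank statistics
(equal-rank count, mean/SD/max absolute rank change), plus patch-level
change summaries for the most affected species.

## Worked example

```python
import dichroma as dc

# a seeded 30-species, 15-patch synthetic library with graded dimorphism
lib, truth = dc.generate_library(dc.SyntheticDesign(n_species=30, seed=20240101))

uvs = dc.patch_jnd_matrix(lib, dc.build_average_eye("UVS"))
vs  = dc.patch_jnd_matrix(lib, dc.build_average_eye("VS"))
cmp = dc.compare_conditions(uvs, vs)
print(f"r = {cmp.pearson_r:.4f}, equal rank {cmp.equal_rank}/{cmp.n_species}, "
      f"max |Δrank| {cmp.max_rank_change:.0f}")
```

prints (for this seed)

```
r = 0.9819, equal rank 8/30, max |Δrank| 4
```

i.e. assuming the wrong eye type leaves the score *distribution* almost
unchanged (r ≈ 0.98) while reordering most species' ranks — the
characteristic signature this analysis quantifies. The numbered drivers
under `analysis/` run the complete pipeline on this library:
`01_simulate_library.py` (generate + write CSVs), `02_score_dichromatism.py`
(scores, ranks, eye-type comparison), `03_single_parameter_sweeps.py`
(most-divergent pair per parameter class), `04_full_permutation.py`
(all 24,948 combinations per eye type for three exemplar species, with
range / percent-difference / overlap summaries). A `dichroma` CLI with
`simulate`, `score`, `sweep` and `permute` subcommands wraps the same
functions for shell use.

Real reflectance libraries are read with
`dc.read_reflectance_csv(path, dialect="wide"|"long")` plus
`dc.read_bare_mask_csv` for the bare-patch (non-feathered) mask; packaged
extreme parameter values that are not established physiology are flagged as
placeholders and refused unless explicitly allowed.

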