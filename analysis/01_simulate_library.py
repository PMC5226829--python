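"""Generate the seeded synthetic reflectance library used by the analysis.

Emulates a galliform-style museum library: 30 species × 15 plumage patches,
male and female mean curves on 300–700 nm, graded sexual colour differences
across species, a sprinkling of bare patches, and smooth measurement noise.
Writes the wide-dialect spectra CSV, bare-patch mask, and truth record to
results/library/.
"""

import json
from pathlib import Path

import pandas as pd

import dichroma as dc

OUT = Path(__file__).resolve().parents[1] / "results" / "library"
SEED = 20240101


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = dc.SyntheticDesign(
        n_species=30, n_patches=15, seed=SEED, noise_sd=0.5, bare_patch_prob=0.05
    )
    library, truth = dc.generate_library(design)
    dc.write_reflectance_csv(library, OUT / "spectra.csv", dialect="wide")
    mask = pd.DataFrame(
        [[int(library.is_bare(sp, p)) for p in library.patches] for sp in library.species],
        index=library.species, columns=library.patches,
    )
    mask.to_csv(OUT / "bare_mask.csv")
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    n_bare = int(mask.to_numpy().sum())
    print(f"library: {len(library.species)} species, {library.n_curves} curves, "
          f"{n_bare} bare patches -> {OUT}")


if __name__ == "__main__":
    main()
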