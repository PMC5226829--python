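"""Score sexual dichromatism under the average UVS and VS eyes.

For every species: per-patch male–female chromatic contrast (JND), flooring
of sub-threshold patches, mean score over feathered patches, and rank.
Writes per-eye-type patch matrices and the species score/rank table to
results/scores/, and reports the UVS-vs-VS eye comparison — the headline
"which eye type did you assume?" contrast.
"""

from pathlib import Path

import pandas as pd

import dichroma as dc

ROOT = Path(__file__).resolve().parents[1] / "results"


def load_library() -> dc.PatchSpectraSet:
    lib = dc.read_reflectance_csv(ROOT / "library" / "spectra.csv")
    lib.set_bare_mask(dc.read_bare_mask_csv(ROOT / "library" / "bare_mask.csv", lib))
    return lib


def main() -> None:
    out = ROOT / "scores"
    out.mkdir(parents=True, exist_ok=True)
    lib = load_library()
    tables = {}
    for eye in ("UVS", "VS"):
        spec = dc.build_average_eye(eye)
        table = dc.floor_and_score(dc.patch_jnd_matrix(lib, spec))
        tables[eye] = table
        table.raw.to_csv(out / f"patch_jnd_{eye}.csv")
    summary = pd.DataFrame(
        {
            "score_UVS": tables["UVS"].scores,
            "rank_UVS": dc.rank_species(tables["UVS"].scores),
            "score_VS": tables["VS"].scores,
            "rank_VS": dc.rank_species(tables["VS"].scores),
            "n_feathered": tables["UVS"].n_feathered,
        }
    )
    summary.to_csv(out / "species_scores.csv")
    cmp = dc.compare_conditions(tables["UVS"], tables["VS"])
    focal = dc.patch_change_stats(tables["UVS"], tables["VS"], cmp.focal_by_score)
    print(f"average UVS vs average VS over {cmp.n_species} species:")
    print(f"  Pearson r = {cmp.pearson_r:.4f}; equal rank {cmp.equal_rank}/{cmp.n_species}; "
          f"mean |Δrank| {cmp.mean_rank_change:.2f}; max |Δrank| {cmp.max_rank_change:.0f}")
    print(f"  focal species {focal.species}: max patch change {focal.max_change_jnd:.2f} JND "
          f"({'NA' if focal.max_change_pct != focal.max_change_pct else f'{focal.max_change_pct:.1f}%'},"
          f" denominator={focal.pct_denominator})")


if __name__ == "__main__":
    main()
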