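#!/usr/bin/env python
"""Expected cells and taxa in micrometre-scale neighborhoods.

For every biofilm section, combines its areal cell density, thickness and
taxon relative abundances into the expected number of cells and distinct taxa
in 10 um^2 and 1 mm^2 patches and in spheres of radius 5 and 20 um — the
scales relevant to cell-cell metabolic interactions.
"""

import argparse
from pathlib import Path

from biofilmgeo.core import read_count_table, read_physical
from biofilmgeo.neighborhoods import NeighborhoodQuery, neighborhood_richness_profile

QUERIES = [
    NeighborhoodQuery("area", area_um2=10.0),
    NeighborhoodQuery("area", area_um2=1e6),
    NeighborhoodQuery("volume", radius_um=5.0),
    NeighborhoodQuery("volume", radius_um=20.0),
]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    for preset in ("controlled", "uncontrolled"):
        table = read_count_table(args.datadir / preset / "counts.tsv")
        phys = read_physical(args.datadir / preset / "physical.tsv")
        prof = neighborhood_richness_profile(table, phys, QUERIES)
        prof.to_csv(args.outdir / f"neighborhoods_{preset}.tsv", sep="\t",
                    index=False, float_format="%.6g")
        for q in QUERIES:
            sub = prof[prof["query"] == q.label]
            print(f"{preset} {q.label}: {sub.expected_cells.min():.3g}-"
                  f"{sub.expected_cells.max():.3g} cells, "
                  f"{sub.expected_richness.min():.2f}-"
                  f"{sub.expected_richness.max():.2f} expected taxa")


if __name__ == "__main__":
    main()
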