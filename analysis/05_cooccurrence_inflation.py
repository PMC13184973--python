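#!/usr/bin/env python
"""Inflation of detected co-occurrences with sample area.

On a patchy, gradient-structured survey, counts significantly co-occurring
taxon pairs (exact hypergeometric upper tail, raw alpha) and ubiquitous taxa
for sampling strategies pooling 1-8 sections per sample, with the number of
samples equalized across conditions.
"""

import argparse
from pathlib import Path

import pandas as pd

from biofilmgeo.cooccurrence import equalized_sweep
from biofilmgeo.resampling import SamplingPlan, apply_plan
from biofilmgeo.synthetic import SyntheticConfig, generate_biofilm

GRADIENT_CONFIG = dict(
    n_taxa=200, n_sections=320, depth=1500,
    frac_monotonic=0.10, frac_peaked=0.50, peak_width_cm=4.0,
    gradient_strength=0.05, noise_overdispersion=0.5,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--iterations", type=int, default=20)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg = SyntheticConfig(seed=args.seed, **GRADIENT_CONFIG)
    table, meta, _ = generate_biofilm(cfg)
    sets = {}
    for strategy in ("contiguous", "discontiguous"):
        for k in (1, 2, 4, 8):
            plan = SamplingPlan(strategy=strategy, sections_per_sample=k,
                                merge_sides=True, rarefaction_depth=cfg.depth,
                                iterations=1, seed=args.seed)
            sets[f"{strategy}_k{k}"] = apply_plan(table, meta, plan)[0].table
    df = equalized_sweep(sets, n_select=20, iterations=args.iterations,
                         seed=args.seed, bh=False)
    df.to_csv(args.outdir / "cooccurrence_inflation.tsv", sep="\t",
              index=False, float_format="%.6g")
    med = df.groupby("condition")[["n_significant_pairs", "n_ubiquitous"]].median()
    print(med.to_string())
    print("\nPooling more sections per (contiguous) sample inflates both the "
          "significant-pair and ubiquitous-taxon counts.")


if __name__ == "__main__":
    main()
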