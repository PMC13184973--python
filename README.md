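# biofilmgeo

Centimetre-scale biogeography of biofilm microbial communities, and what it
does to sequencing-based surveys.

Biofilms sampled at cm resolution — e.g. a shower hose cut into 1.2 cm
sections, each side of the bisected pipe sequenced separately — show
spatially structured communities even in macroscopically homogeneous
environments: taxa whose relative abundance trends monotonically along the
pipe or peaks at specific locations, and community dissimilarity that grows
with distance. `biofilmgeo` provides a tested pipeline for the analyses this
kind of survey supports, with a synthetic spatially structured community
generator standing in for sequencing data:

- **Neighborhood diversity.** With areal cell density `D` (cells/cm²),
  thickness `t` (µm) and per-section relative abundances `p_i`, the expected
  number of distinct taxa among the `n` cells in a µm-scale neighborhood is
  the collector-curve (Heaps) expectation
  `E[R_m(n)] = m − Σ_i (1 − p_i)^n`, evaluated for planar patches
  (`n = D·A/10⁸`) and thickness-clipped spheres around a focal cell.
- **Sampling-strategy simulation.** Merge the two pipe sides, pool `k`
  sections per sample (contiguous along the pipe, or discontiguous at
  random), rarefy each pooled sample back to the original depth, and track
  how alpha diversity, Bray–Curtis dispersion, whole-environment richness
  and presence/absence co-occurrence counts (exact hypergeometric tail)
  respond.
- **Spatial statistics.** Per-taxon trend detection (Spearman + Wald–
  Wolfowitz runs test, exact small-sample tails, Benjamini–Hochberg across
  taxa) and segmented (two-piece linear) distance-decay breakpoint
  estimation with bootstrap standard errors.
- **Species–area scaling laws.** Randomised species–area (SAR) curves and
  nonlinear least-squares fits of the power law `R = c·Aᶻ` (PL) and the
  logarithmic power law `R = (b + c·log A)ᶻ` (LPL), compared by RMSE over
  repeated SAR estimates; `z` is the spatial turnover rate.

## Worked example

```sh
python analysis/01_simulate_surveys.py --seed 1
python analysis/06_scaling_laws.py --seed 1
python analysis/07_distance_decay_breakpoints.py --seed 1
```

prints, among other things:

```
controlled: 200 sections x depth 10000, 1905 taxa observed (pool 30000)
uncontrolled: 200 sections x depth 10000, 600 taxa observed (pool 600)
controlled: median RMSE PL 2.5 vs LPL 34.4; PL wins 100% of 100 SAR estimates
uncontrolled: median RMSE PL 16.1 vs LPL 15.6; PL wins 0% of 100 SAR estimates
uncontrolled: breakpoint 42.4 +/- 3.1 cm (slope 0.0044 -> 0.003)
fixture (truth 40 cm): recovered 40.0 +/- 0.5 cm
```

Read: in the homogeneous ("controlled") environment the taxon pool is far
from exhausted at the survey's depth, richness accumulates as a near-power
law, and the PL fits the SAR curves decisively better; in the heterogeneous
("uncontrolled") environment the community saturates its pool and the
log-saturating LPL wins. The distance-decay slope of the uncontrolled
environment changes tens of cm along the pipe, and a known 40 cm breakpoint
planted in a noisy fixture is recovered to sub-cm accuracy.

The other drivers (`02`–`05`) compute alpha/beta diversity and trend
classifications, µm-scale neighborhood richness (of order one cell and at
most a few taxa in 10 µm²), and the inflation of co-occurrence counts with
growing sample area. All tables land under `results/`.

A thin CLI mirrors the drivers for single steps, e.g.
`biofilmgeo simulate --preset controlled --seed 1 --outdir out/` and
`biofilmgeo fit-laws out/counts.tsv out/metadata.tsv`; `biofilmgeo run
config.yaml --outdir out/` executes the whole pipeline from a YAML config,
reproducibly to the byte for a fixed seed.

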