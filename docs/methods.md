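# Methods

## The setting

The package models a 1-D biofilm environment: a pipe of ~1.8 m cut into
1.2 cm sections, each bisected lengthwise into two sides (`side1`/`side2`),
every section sequenced to a fixed read depth and characterised physically
by an areal cell density (cells/cm²) and a biofilm thickness (µm). All
analyses consume a taxa × section integer count table plus per-section
metadata (axial position in cm, side, length, area; the default area of a
half section is `length × π·d/2` with inner diameter d = 0.8 cm). Sections
on opposite sides at the same axial position are at distance 0; missing
sections are simply absent and distances always use actual positions.

## Neighborhood diversity (collector-curve expectation)

For a neighborhood expected to contain `n` cells drawn from a section with
relative abundances `p`, the expected number of distinct taxa is

    E[R_m(n)] = m − Σ_i (1 − p_i)^n .

Choices that matter:

- `n` is real-valued (`(1−p)^n = exp(n·log1p(−p))`); the expectation
  interpolates smoothly between integer cell counts, so fractional expected
  cells (e.g. 0.7 cells in 10 µm²) need no rounding. `n = 0` returns 0.
- Planar patches: `n = D·A/10⁸` (1 cm² = 10⁸ µm²). Spherical neighborhoods
  around a focal cell: volumetric density `ρ = D/(10⁸·t)` is assumed uniform
  through the thickness, and the sphere of radius `r` is clipped by default
  to the slab via the symmetric intersection `V = 2π(r²a − a³/3)`,
  `a = min(r, t/2)`; unclipped (`a = r`, full sphere `4πr³/3`) is available
  for sensitivity analysis, since how a spherical neighborhood should meet
  the biofilm boundary is a modelling choice. The focal cell itself is not
  counted in `n` (a query flag can add it).
- Cells are assumed independently placed. Real biofilms contain clonal
  microcolonies, which makes these estimates a *theoretical upper bound* on
  local diversity, not a measurement.
- A Monte-Carlo oracle (`mc_neighborhood_richness`, multinomial draws)
  provides the independent check; the closed form also matches exact
  enumeration over all outcomes for tiny (m, n) in the tests.

## Synthetic surveys

`generate_biofilm` draws, per axial position, an expected composition =
base abundance × spatial modifier, then a Dirichlet-perturbed realised
composition, then multinomial reads at exactly `depth` per section:

- **Base SAD.** `lognormal` (σ = 1.5) or `zipf` (p ∝ rank^−a). Spatial
  roles — monotonic (`exp(±g·(x − L/2))`, direction 50/50) or peaked
  (Gaussian bump of width `peak_width_cm` at a random position, with a 0.05
  floor so peaked taxa remain rare rather than absent off-peak) — are
  assigned at random among the top `pattern_rank_limit` taxa by base
  abundance: in real surveys spatial patterns are not restricted to rare
  taxa (core members show them most), and patterns assigned to taxa below
  the detection limit would be unobservable by construction.
- **Noise.** Realised composition ~ Dirichlet with concentration
  `noise_overdispersion × n_taxa` centred on the expected composition;
  smaller values mean noisier sections. Because concentration is shared
  across taxa, rare taxa are intermittent (locally boosted or absent),
  which is the behaviour cm-scale replicates actually show.
- **Physical data.** Cell density and thickness are drawn log-uniformly
  within configured ranges (defaults 7×10⁶–3.9×10⁷ cells/cm², 10–100 µm),
  independent across sections — the density range spans about one cell per
  10 µm² at the low end.
- Everything is keyed to one seed through stable tokens
  (`_seeds.child_rng`), so identical configs reproduce identical tables.

### Environment presets

Two presets encode the contrast between a homogeneous and a heterogeneous
environment. Their nominal patterned fractions (20% and 26%) and observed
richness scales (a few hundred taxa) anchor the regimes the analysis is
meant to distinguish; gradient strengths, peak widths, pool sizes and noise
concentrations are free parameters chosen once for realism:

| preset | pool | SAD | depth | patterned | gradient | noise conc. |
|---|---|---|---|---|---|---|
| controlled | 30 000 | zipf a=2.0 | 10 000 | 12% + 8% of top 600 | 0.02/cm | 20 × n_taxa |
| uncontrolled | 600 | zipf a=1.1 | 10 000 | 16% + 10% | 0.05/cm | 2 × n_taxa |

The controlled preset is a large, rare-heavy pool far from exhaustion at
the survey's depth: taxon accumulation is then a near-power law (the Heaps
regime), only a few hundred taxa clear a denoiser-grade read floor, and
section-to-section noise is low. The uncontrolled preset is a modest, even
pool that the noisy survey effectively exhausts: richness accrues fast and
saturates, and sections are much noisier. These two shapes are what drive
the scaling-law selection result below.

A Zipf SAD was adopted for the presets after the lognormal alternative
proved structurally unable to produce a power-law-shaped SAR at any σ
(lognormal collector curves are concave in log-log space); lognormal
remains the default for ad-hoc configs.

## Diversity and partitioning

Alpha metrics per sample: observed richness, Shannon entropy (nats),
Gini–Simpson (1 − Σp²), Pielou evenness `H/ln(richness)` (defined as 0 at
richness 1, flagged). Beta diversity is Bray–Curtis,
`1 − 2Σmin(x,y)/(Σx+Σy)`. Rarefaction is a multivariate hypergeometric
draw (without replacement), seeded per (sample, iteration) from the master
seed. Distance decay tables contain all unordered section pairs with axial
distance, dissimilarity on (optionally subset and re-normalised) relative
abundances, and a same-side flag; subsetting re-normalises by default, raw
subset shares are available.

Core/satellite partitioning ranks taxa by the mean of their occupancy rank
and mean-relative-abundance rank (ties by taxon id), then walks down the
ranking: the contribution of the cumulative core set to community structure
is `1 − mean_s BC(core-only profile_s, full profile_s)` (computable in
closed form from cumulative sums), and the core ends at the last rank whose
addition still improves this contribution by ≥ 2% (threshold exposed).

## Trend detection

Per taxon, relative abundance ordered by axial position gets (i) a Spearman
test (mid-ranks; exact permutation tail for n ≤ 9, t-approximation above)
and (ii) a Wald–Wolfowitz runs test dichotomised around the median with
median ties dropped (exact runs distribution for n₁+n₂ ≤ 20, normal
approximation with continuity correction above; two-sided p = twice the
smaller tail, capped at 1). Benjamini–Hochberg runs across taxa separately
per test family; degenerate series (constant, or absent taxa) are not tests
and are excluded from the BH family rather than diluting it.
Classification precedence is monotonic > nonrandom > none.

Two facts about the detected fraction are worth knowing. First,
compositional closure means strongly trending abundant taxa induce *real*
compensatory trends in everyone else, so the detected fraction can exceed
the generated patterned fraction; the meaningful generator-consistency
check is recall on ground-truth roles (kept in
`metadata.attrs["spatial_roles"]`). Second, detection power is read-limited:
in the controlled preset most observed taxa sit near the detection floor,
so the detected fraction among denoiser-grade taxa (~2–17% across seeds)
runs below the preset's nominal 20%, with large seed-to-seed variance
driven by which dominant taxa carry patterns.

## Co-occurrence

Presence = count ≥ min_count (default 1). Each taxon pair is tested against
the central hypergeometric null (presences placed at random, marginals
fixed): one-sided upper tail `P(X' ≥ X)` for positive association
(two-sided available). Taxa present in every sample carry no information
under this null and are excluded but counted (their number is itself a
sampling-strategy readout); taxa absent everywhere are dropped. BH across
pairs is on by default; the *raw-α* count (BH off) is what the
sampling-distortion analyses report, since the affinity-style counting it
mirrors tests each pair on its own. Equal-sample-number comparisons
subsample samples, not sections.

## Sampling-strategy simulation

`apply_plan` = optional side merge → grouping (contiguous runs in axial
order, or a seeded random partition; a remainder smaller group is kept
rather than discarded) → count pooling → per-sample rarefaction to the
fixed depth. The whole-environment ("gamma") richness is that of the summed
rarefied samples: with per-sample depth fixed, fewer larger samples
sequence fewer total reads, which is exactly the regime in which pooling
erodes whole-environment richness. The distortion analyses use a patchy
survey (200 taxa, 320 sections, depth 1500, 50% peaked taxa of width 4 cm,
10% monotonic, noisy sections): pooling then raises per-sample alpha
diversity, lowers dispersion, lowers gamma richness, and — because pooling
both merges adjacent patches and averages away independent section noise —
inflates the significant-pair count.

## Scaling laws

SAR curves: `sar_exact` gives the closed-form expectation of richness over
all n-of-N sample subsets (`S − Σ_i C(N−o_i, n)/C(N, n)`), exact for equal
areas; `sar_random` averages random accumulation orderings and handles
unequal areas exactly. Areas are expressed as fractions of the total
environment area.

Fits are nonlinear least squares on (area, richness): PL initialised from
log-log regression; LPL (natural log) parametrised as
`c = exp(γ)`, `u_min = exp(β₀)` (bracket value at the smallest observed
area — positivity of `b + c·log A` holds on the observed range by
construction), with a 3-point multistart z ∈ {0.5, 1, 2}. The LPL exponent
is bounded to **z ∈ [0.05, 2.5]**: as z → ∞ with c/b → 0 the LPL family
degenerates into `b^z · A^(zc/b)`, i.e. an arbitrary power law, so without
the bound LPL asymptotically nests PL and an RMSE comparison between the
laws would be vacuous. The bound extends a little past the multistart grid;
fits that press against it (as LPL does on power-shaped curves) are exactly
the fits the comparison should count as losses for the log-saturating
family. RMSE is computed against the SAR curve points, and model comparison
repeats both fits over (by default 100) independently re-estimated SAR
curves, reporting each law's win fraction.

`area_for_richness_error` refits a law on growing curve prefixes and
reports the smallest observed area fraction whose fit extrapolates the
full-area richness within tolerance (default 10%).

## Breakpoint estimation

Two-segment continuous piecewise-linear least squares of dissimilarity on
distance: breakpoint by grid search over interior unique distances (3
excluded at each edge; at most 60 quantile-spaced candidates), refined by
bounded scalar minimisation between neighbouring grid points; the SE is the
standard deviation of the breakpoint over case-resampling bootstrap
replicates (reported as SE, explicitly). When the two-segment fit improves
on a single line by < 1% in SSE the `no_breakpoint` flag is set. One
breakpoint only.

## Problem sizes and reproducibility

The test suite runs the statistical checks at reduced problem sizes chosen
as the package's own defaults for routine verification: the model-selection
check uses presets scaled to a 10 000-taxon pool (controlled) and 400 taxa
(uncontrolled) over 100 sections at depth 1000 with 100 SAR estimates × 20
seeds; distortion checks use the patchy survey above over 20 seeds;
breakpoint recovery uses 500-point fixtures over 50 seeds with 60 bootstrap
replicates. Full-preset numbers are produced by `scripts/acceptance.py` and
the `analysis/` drivers. Every stochastic step derives its generator from
the master seed plus a stable token, pipeline TSVs are written with fixed
6-significant-digit formatting, and rerunning a config yields byte-identical
outputs.

## Known limitations

- Neighborhood richness ignores microcolony structure and EPS-rich dead
  space: upper bounds only. In the even-abundance uncontrolled preset the
  20 µm-radius estimates exceed what patchier real communities show.
- The generator has no phylogenetic signal, no chimeras/contamination, no
  extraction/PCR bias of physical pooling (pooling is additive on reads),
  and its side effect is off by default (magnitude unquantified).
- The co-occurrence test is an exact central-hypergeometric tail, a
  deliberate simplification of the affinity-MLE framework it stands in
  for; only the *count* of significant pairs is consumed downstream.
- The detected-trend fraction is power-limited in rare-heavy communities
  (see above); treat preset trend percentages as seed-variable.
- Breakpoint estimation fits one change point; environments with several
  turnover regimes need a different model.
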