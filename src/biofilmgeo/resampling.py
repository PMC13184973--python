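"""In-silico alternative sampling strategies.

Simulates how a survey would look had larger areas been sampled: merge the
two sides of each bisected section, pool ``k`` sections per sample either
contiguously along the pipe or as a random (discontiguous) partition, then
rarefy every pooled sample back to the original per-sample sequencing depth —
the fixed-depth regime of commercial sequencing.  Iterating the random parts
yields replicate simulated surveys from which alpha diversity, beta-diversity
dispersion, and whole-environment richness are summarised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import child_rng
from .core import SpatialCountTable, merge_counts
from .diversity import alpha_metrics, pairwise_bray_curtis, rarefy

__all__ = [
    "SamplingPlan",
    "SimulatedSampleSet",
    "merge_sides",
    "build_groups",
    "apply_plan",
    "strategy_sweep",
]

STRATEGIES = ("original", "contiguous", "discontiguous")


@dataclass(frozen=True)
class SamplingPlan:
    """A pooling + rarefaction scheme."""

    strategy: str = "contiguous"
    sections_per_sample: int = 1
    merge_sides: bool = True
    rarefaction_depth: int = 10_000
    iterations: int = 1
    seed: int = 0
    rarefy_samples: bool = True  # False studies pooling without depth control

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; one of {STRATEGIES}")
        if self.sections_per_sample < 1:
            raise ValueError("sections_per_sample must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class SimulatedSampleSet:
    """One replicate simulated survey: pooled (and rarefied) samples."""

    iteration: int
    table: SpatialCountTable
    meta: pd.DataFrame
    sample_area_fraction: np.ndarray  # per sample, fraction of total area
    plan: SamplingPlan = field(repr=False)


def merge_sides(
    table: SpatialCountTable, meta: pd.DataFrame
) -> tuple[SpatialCountTable, pd.DataFrame]:
    """Sum each bisected section with its counterpart at the same position.

    Already-merged input (all sides ``merged``) passes through unchanged.
    Sections lacking a counterpart raise with the orphan ids listed.
    """
    m = meta[meta["section_id"].isin(table.section_ids)].copy()
    if set(m["side"]) == {"merged"}:
        return table.copy(), m.reset_index(drop=True)
    groups: list[list[str]] = []
    rows: list[dict] = []
    orphans: list[str] = []
    for pos, grp in m.groupby("position_cm", sort=True):
        ids = list(grp["section_id"])
        if len(ids) != 2 or set(grp["side"]) != {"side1", "side2"}:
            orphans.extend(ids)
            continue
        ids.sort(key=lambda s: grp.set_index("section_id").at[s, "side"])
        groups.append(ids)
        rows.append(dict(
            section_id="+".join(ids),
            position_cm=pos,
            side="merged",
            length_cm=float(grp["length_cm"].iloc[0]),
            area_cm2=float(grp["area_cm2"].sum()),
            environment=grp["environment"].iloc[0] if "environment" in grp else "",
        ))
    if orphans:
        raise ValueError(f"unpaired sections (no side counterpart): {sorted(orphans)}")
    merged = merge_counts(table, groups)
    return merged, pd.DataFrame(rows)


def build_groups(
    meta: pd.DataFrame,
    strategy: str,
    k: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[list[str]]:
    """Partition sections into pooled samples of ``k`` sections.

    ``contiguous`` chunks consecutive runs in axial order; ``discontiguous``
    chunks a seeded uniformly random permutation.  When ``k`` does not divide
    the section count the trailing remainder forms a final smaller group.
    """
    ordered = meta.sort_values(["position_cm", "section_id"])["section_id"].tolist()
    n = len(ordered)
    if k > n:
        raise ValueError(f"k = {k} exceeds the {n} available sections")
    if strategy in ("original",) or k == 1:
        return [[s] for s in ordered]
    if strategy == "discontiguous":
        if rng is None:
            rng = np.random.default_rng(seed)
        ordered = [ordered[i] for i in rng.permutation(n)]
    elif strategy != "contiguous":
        raise ValueError(f"unknown strategy {strategy!r}")
    return [ordered[i:i + k] for i in range(0, n, k)]


def apply_plan(
    table: SpatialCountTable, meta: pd.DataFrame, plan: SamplingPlan
) -> list[SimulatedSampleSet]:
    """Execute a sampling plan: merge sides, pool, rarefy; one set per iteration."""
    if plan.merge_sides:
        table, meta = merge_sides(table, meta)
    total_area = float(meta["area_cm2"].sum())
    meta_idx = meta.set_index("section_id")
    out: list[SimulatedSampleSet] = []
    for it in range(plan.iterations):
        grp_rng = child_rng(plan.seed, "groups", plan.strategy, plan.sections_per_sample, it)
        groups = build_groups(meta, plan.strategy, plan.sections_per_sample, rng=grp_rng)
        pooled = merge_counts(table, groups)
        areas = np.array([meta_idx.loc[g, "area_cm2"].sum() for g in groups], dtype=float)
        positions = np.array([meta_idx.loc[g, "position_cm"].mean() for g in groups])
        counts = pooled.counts
        if plan.rarefy_samples:
            totals = counts.sum(axis=0)
            short = totals < plan.rarefaction_depth
            if short.any():
                sid = pooled.section_ids[int(np.argmax(short))]
                raise ValueError(
                    f"pooled sample {sid!r} has {totals[short][0]} reads "
                    f"< rarefaction depth {plan.rarefaction_depth}"
                )
            cols = [
                rarefy(counts[:, j], plan.rarefaction_depth,
                       rng=child_rng(plan.seed, "rarefy", pooled.section_ids[j], it))
                for j in range(pooled.n_sections)
            ]
            counts = np.column_stack(cols)
        sample_meta = pd.DataFrame(dict(
            section_id=pooled.section_ids,
            position_cm=positions,
            side="merged",
            length_cm=[meta_idx.loc[g, "length_cm"].sum() for g in groups],
            area_cm2=areas,
            environment=meta["environment"].iloc[0] if "environment" in meta else "",
        ))
        out.append(SimulatedSampleSet(
            iteration=it,
            table=SpatialCountTable(list(pooled.taxon_ids), list(pooled.section_ids), counts),
            meta=sample_meta,
            sample_area_fraction=areas / total_area,
            plan=plan,
        ))
    return out


def strategy_sweep(
    table: SpatialCountTable,
    meta: pd.DataFrame,
    k_values: list[int],
    strategies: list[str],
    depth: int,
    iterations: int,
    seed: int = 0,
    merge_sides_first: bool = True,
    rarefy_samples: bool = True,
) -> dict[str, pd.DataFrame]:
    """Alpha, beta, and whole-environment ("gamma") summaries over a sweep.

    Returns three tidy frames keyed by (strategy, k, iteration):

    ``alpha``  per-sample alpha metrics and the sample's area fraction;
    ``beta``   all pairwise Bray-Curtis dissimilarities among samples;
    ``gamma``  richness of the pooled environment-wide profile at the total
               depth implied by the fixed per-sample depth (fewer, larger
               samples sequence fewer total reads).
    """
    alpha_rows, beta_rows, gamma_rows = [], [], []
    for strategy in strategies:
        for k in k_values:
            plan = SamplingPlan(
                strategy=strategy, sections_per_sample=k, merge_sides=merge_sides_first,
                rarefaction_depth=depth, iterations=iterations, seed=seed,
                rarefy_samples=rarefy_samples,
            )
            for ss in apply_plan(table, meta, plan):
                key = dict(strategy=strategy, k=k, iteration=ss.iteration)
                counts = ss.table.counts
                for j, sid in enumerate(ss.table.section_ids):
                    rec = alpha_metrics(counts[:, j], sid)
                    alpha_rows.append({**key, **rec.__dict__,
                                       "area_fraction": ss.sample_area_fraction[j]})
                if ss.table.n_sections >= 2:
                    rel = counts / counts.sum(axis=0, keepdims=True)
                    dm = pairwise_bray_curtis(rel)
                    ids = ss.table.section_ids
                    idx = 0
                    for a in range(len(ids)):
                        for b in range(a + 1, len(ids)):
                            beta_rows.append({**key, "sample_a": ids[a],
                                              "sample_b": ids[b],
                                              "bray_curtis": float(dm[idx])})
                            idx += 1
                pooled = counts.sum(axis=1)
                gamma_rows.append({**key,
                                   "n_samples": ss.table.n_sections,
                                   "total_reads": int(pooled.sum()),
                                   "richness": int((pooled > 0).sum())})
    return dict(
        alpha=pd.DataFrame(alpha_rows),
        beta=pd.DataFrame(beta_rows),
        gamma=pd.DataFrame(gamma_rows),
    )
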