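"""Alpha diversity, Bray-Curtis beta diversity, rarefaction, distance decay,
and the abundance-occupancy core/satellite partition."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._seeds import child_rng
from .core import SpatialCountTable

__all__ = [
    "AlphaDiversityRecord",
    "PartitionResult",
    "rarefy",
    "alpha_metrics",
    "alpha_table",
    "bray_curtis",
    "pairwise_bray_curtis",
    "distance_decay",
    "core_satellite_partition",
]


@dataclass(frozen=True)
class AlphaDiversityRecord:
    """Alpha metrics of one sample.

    ``shannon`` is in nats; ``simpson`` is the Gini-Simpson index 1 - sum p^2;
    ``pielou`` is H / ln(richness), defined as 0 at richness 1 (flagged by
    ``pielou_degenerate``).
    """

    section_id: str
    richness: int
    shannon: float
    simpson: float
    pielou: float
    pielou_degenerate: bool = False


def rarefy(
    counts: Sequence[int],
    depth: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Subsample reads without replacement to ``depth`` (multivariate hypergeometric)."""
    counts = np.asarray(counts)
    if np.any(counts < 0) or counts.ndim != 1:
        raise ValueError("counts must be a non-negative 1-D vector")
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"insufficient reads: depth {depth} > total {total}")
    if depth == total:
        return counts.astype(np.int64, copy=True)
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts.astype(np.int64), depth).astype(np.int64)


def alpha_metrics(counts: Sequence[int], section_id: str = "") -> AlphaDiversityRecord:
    """Observed richness, Shannon (nats), Gini-Simpson, and Pielou evenness."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative count")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero sample")
    present = c[c > 0]
    p = present / total
    richness = len(present)
    shannon = float(-(p * np.log(p)).sum())
    simpson = float(1.0 - (p**2).sum())
    if richness == 1:
        return AlphaDiversityRecord(section_id, 1, 0.0, 0.0, 0.0, pielou_degenerate=True)
    return AlphaDiversityRecord(
        section_id, richness, shannon, simpson, shannon / np.log(richness)
    )


def alpha_table(table: SpatialCountTable) -> pd.DataFrame:
    """Alpha metrics for every section of a count table."""
    recs = [alpha_metrics(table.counts[:, j], table.section_ids[j])
            for j in range(table.n_sections)]
    return pd.DataFrame([r.__dict__ for r in recs])


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity 1 - 2 sum min(x, y) / (sum x + sum y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("negative entries")
    denom = x.sum() + y.sum()
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("all-zero vector")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def pairwise_bray_curtis(matrix: np.ndarray) -> np.ndarray:
    """Condensed pairwise Bray-Curtis over columns of a taxa x samples matrix."""
    from scipy.spatial.distance import pdist

    cols = np.asarray(matrix, dtype=float).T
    return pdist(cols, metric="braycurtis")


def distance_decay(
    table: SpatialCountTable,
    meta: pd.DataFrame,
    subset_taxa: Iterable[str] | None = None,
    renormalize: bool = True,
    subset_label: str = "total",
) -> pd.DataFrame:
    """Bray-Curtis dissimilarity of all section pairs vs axial distance.

    Dissimilarities are computed on relative abundances, optionally restricted
    to ``subset_taxa`` (re-normalised over the subset by default; with
    ``renormalize=False`` the subset counts keep their original share).
    Pairs in which a section has no reads on the subset are dropped with a
    warning.  Sections on different sides at the same axial position are at
    distance 0; the ``same_side`` flag carries the side split.
    """
    m = meta.set_index("section_id")
    sections = [s for s in table.section_ids if s in m.index]
    if len(sections) < 2:
        raise ValueError("need at least two sections with metadata")
    sub = table if subset_taxa is None else table.subset_taxa(subset_taxa)
    sub = sub.subset_sections(sections)
    full_totals = table.subset_sections(sections).column_totals().astype(float)
    counts = sub.counts.astype(float)
    denom = counts.sum(axis=0) if renormalize else full_totals
    ok = denom > 0
    if not ok.all():
        dropped = [s for s, good in zip(sections, ok) if not good]
        warnings.warn(f"sections with no subset reads dropped: {dropped}", stacklevel=2)
    keep = [i for i, good in enumerate(ok) if good]
    rel = counts[:, keep] / denom[keep]
    kept = [sections[i] for i in keep]
    pos = m.loc[kept, "position_cm"].to_numpy(dtype=float)
    side = m.loc[kept, "side"].to_numpy()

    rows = []
    for a in range(len(kept)):
        for b in range(a + 1, len(kept)):
            rows.append(dict(
                section_a=kept[a], section_b=kept[b],
                distance_cm=abs(pos[a] - pos[b]),
                dissimilarity=bray_curtis(rel[:, a], rel[:, b]),
                subset=subset_label,
                same_side=bool(side[a] == side[b]),
            ))
    return pd.DataFrame(rows)


@dataclass
class PartitionResult:
    """Core/satellite split from ranked abundance-occupancy."""

    core_taxa: list[str]
    satellite_taxa: list[str]
    rank_scores: pd.DataFrame  # taxon_id, occupancy, mean_abundance, rank, contribution
    elbow_index: int


def core_satellite_partition(
    table: SpatialCountTable, elbow_threshold: float = 0.02
) -> PartitionResult:
    """Partition taxa into core and satellite members.

    Taxa are ranked by the mean of their occupancy rank and mean relative
    abundance rank (descending, ties broken by taxon id).  Walking down the
    ranking, each added taxon's contribution to community structure is the
    increase in ``1 - mean_s BC(core-only profile_s, full profile_s)``; the
    core ends at the last rank whose addition still improves this similarity
    contribution by at least ``elbow_threshold`` (absolute).
    """
    if table.n_sections < 2:
        raise ValueError("occupancy undefined with a single section")
    counts = table.counts.astype(float)
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("empty section in table")
    rel = counts / totals
    occupancy = (counts > 0).mean(axis=1)
    mean_ab = rel.mean(axis=1)
    # descending ranks; average ranks on ties, then deterministic id tie-break
    score = (rankdata(-occupancy, method="average")
             + rankdata(-mean_ab, method="average")) / 2
    order = sorted(range(table.n_taxa), key=lambda i: (score[i], table.taxon_ids[i]))

    ranked = counts[order]  # taxa in rank order
    cum = np.cumsum(ranked, axis=0)  # cumulative core-profile counts per section
    # BC(core profile, full profile) has sum-min = core total, so the
    # similarity contribution after rank r is mean_s 2 cum_r / (cum_r + total)
    contrib = (2 * cum / (cum + totals)).mean(axis=1)
    gains = np.diff(np.concatenate([[0.0], contrib]))
    above = np.nonzero(gains >= elbow_threshold)[0]
    elbow = int(above[-1]) + 1 if len(above) else 1  # rank count; core never empty

    ordered_ids = [table.taxon_ids[i] for i in order]
    scores = pd.DataFrame(dict(
        taxon_id=ordered_ids,
        occupancy=occupancy[order],
        mean_abundance=mean_ab[order],
        rank=np.arange(1, table.n_taxa + 1),
        rank_score=score[order],
        contribution=contrib,
        gain=gains,
    ))
    return PartitionResult(
        core_taxa=ordered_ids[:elbow],
        satellite_taxa=ordered_ids[elbow:],
        rank_scores=scores,
        elbow_index=elbow,
    )
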