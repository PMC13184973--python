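"""Presence/absence co-occurrence testing.

For each taxon pair the number of samples in which both occur is compared to
the central hypergeometric null (random placement of each taxon's presences
across samples, marginals fixed).  The one-sided upper-tail p-value flags
positive association; Benjamini-Hochberg correction across all tested pairs
controls the FDR.  Taxa present in all samples carry no pairwise information
under this null and are excluded from testing but counted as ubiquitous —
their number is itself a sampling-strategy diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ._seeds import child_rng
from .core import SpatialCountTable

__all__ = [
    "CooccurrenceSummary",
    "presence_absence",
    "pair_pvalue",
    "count_significant",
    "equalized_sweep",
]


@dataclass
class CooccurrenceSummary:
    n_samples: int
    n_taxa_tested: int
    n_ubiquitous: int
    n_absent: int
    n_significant_pairs: int
    pair_records: pd.DataFrame


def presence_absence(table: SpatialCountTable, min_count: int = 1) -> pd.DataFrame:
    """Boolean taxa x samples detection matrix (count >= min_count)."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return pd.DataFrame(table.counts >= min_count,
                        index=pd.Index(table.taxon_ids, name="taxon_id"),
                        columns=table.section_ids)


def pair_pvalue(X: int, mA: int, mB: int, N: int, two_sided: bool = False) -> float:
    """Exact hypergeometric tail P(X' >= X) for co-occurrence count X.

    ``mA`` and ``mB`` are the taxa's presence counts among ``N`` samples.
    Symmetric in (mA, mB); ``two_sided`` doubles the smaller tail (capped at 1).
    """
    if not (0 <= mA <= N and 0 <= mB <= N):
        raise ValueError("marginals must lie in [0, N]")
    lo, hi = max(0, mA + mB - N), min(mA, mB)
    if not lo <= X <= hi:
        raise ValueError(f"infeasible co-occurrence count X={X} for ({mA}, {mB}, {N})")
    upper = float(hypergeom.sf(X - 1, N, mA, mB))
    if not two_sided:
        return min(upper, 1.0)
    lower = float(hypergeom.cdf(X, N, mA, mB))
    return min(1.0, 2.0 * min(upper, lower))


def count_significant(
    pa: pd.DataFrame,
    alpha_level: float = 0.05,
    bh: bool = True,
    two_sided: bool = False,
) -> CooccurrenceSummary:
    """Count significantly co-occurring taxon pairs in a presence matrix.

    Taxa present in every sample (ubiquitous) or in none are excluded from
    pair testing and tallied separately; remaining pairs get exact
    hypergeometric upper-tail p-values, BH-adjusted when ``bh`` is on.
    """
    mat = pa.to_numpy(dtype=bool)
    n_taxa, N = mat.shape
    if N < 2:
        raise ValueError("need at least two samples")
    marg = mat.sum(axis=1)
    ubiquitous = marg == N
    absent = marg == 0
    keep = ~(ubiquitous | absent)
    sub = mat[keep]
    ids = np.asarray(pa.index)[keep]
    m = marg[keep]
    n_kept = sub.shape[0]
    if n_kept >= 2:
        co = (sub.astype(np.int64) @ sub.astype(np.int64).T)
        iu, ju = np.triu_indices(n_kept, k=1)
        X = co[iu, ju]
        mA, mB = m[iu], m[ju]
        upper = hypergeom.sf(X - 1, N, mA, mB)
        if two_sided:
            lower = hypergeom.cdf(X, N, mA, mB)
            p = np.minimum(1.0, 2.0 * np.minimum(upper, lower))
        else:
            p = np.minimum(upper, 1.0)
        if bh:
            _, p_adj, _, _ = multipletests(p, method="fdr_bh")
        else:
            p_adj = p
        sig = p_adj <= alpha_level
        pairs = pd.DataFrame(dict(
            taxon_a=ids[iu], taxon_b=ids[ju], co_count=X,
            m_a=mA, m_b=mB, p=p, p_adjusted=p_adj, significant=sig,
        ))
        n_sig = int(sig.sum())
    else:
        pairs = pd.DataFrame(columns=["taxon_a", "taxon_b", "co_count",
                                      "m_a", "m_b", "p", "p_adjusted", "significant"])
        n_sig = 0
    return CooccurrenceSummary(
        n_samples=N,
        n_taxa_tested=n_kept,
        n_ubiquitous=int(ubiquitous.sum()),
        n_absent=int(absent.sum()),
        n_significant_pairs=n_sig,
        pair_records=pairs,
    )


def equalized_sweep(
    sample_sets: Mapping[str, Sequence[SpatialCountTable] | SpatialCountTable],
    n_select: int,
    iterations: int = 100,
    seed: int = 0,
    alpha_level: float = 0.05,
    bh: bool = True,
    min_count: int = 1,
) -> pd.DataFrame:
    """Equal-sample-number co-occurrence comparison across conditions.

    For each condition (one table, or a list of replicate tables cycled over
    iterations) and each of ``iterations`` draws, ``n_select`` samples are
    chosen at random and tested; the per-condition distribution of
    significant-pair and ubiquitous-taxon counts controls for the different
    numbers of samples the strategies produce.
    """
    rows = []
    for cond, tables in sample_sets.items():
        if isinstance(tables, SpatialCountTable):
            tables = [tables]
        if min(t.n_sections for t in tables) < n_select:
            raise ValueError(
                f"condition {cond!r}: fewer samples than n_select = {n_select}"
            )
        for it in range(iterations):
            t = tables[it % len(tables)]
            rng = child_rng(seed, "equalized", cond, it)
            chosen = sorted(rng.choice(t.n_sections, size=n_select, replace=False))
            sub = t.subset_sections([t.section_ids[j] for j in chosen])
            summary = count_significant(
                presence_absence(sub, min_count=min_count),
                alpha_level=alpha_level, bh=bh,
            )
            rows.append(dict(
                condition=cond, iteration=it, n_samples=n_select,
                n_taxa_tested=summary.n_taxa_tested,
                n_ubiquitous=summary.n_ubiquitous,
                n_significant_pairs=summary.n_significant_pairs,
            ))
    return pd.DataFrame(rows)
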