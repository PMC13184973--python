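"""Core containers and TSV I/O for spatially indexed community tables.

The central object is :class:`SpatialCountTable`, an integer taxa x section
read-count matrix with string labels on both axes.  Section-level spatial
context (1-D position along the environment, side of a bisected pipe, section
geometry) and physical measurements (areal cell density, biofilm thickness)
travel as plain ``pandas.DataFrame`` objects with fixed column schemas, read
and written as UTF-8 tab-separated text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SpatialCountTable",
    "PipelineConfig",
    "METADATA_COLUMNS",
    "PHYSICAL_COLUMNS",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_physical",
    "write_physical",
    "relative_abundances",
    "merge_counts",
    "half_pipe_area_cm2",
]

#: required columns of the section metadata frame
METADATA_COLUMNS = ("section_id", "position_cm", "side", "length_cm", "area_cm2")

#: required columns of the physical-measurement frame
PHYSICAL_COLUMNS = ("section_id", "cell_density_areal", "thickness_um")

VALID_SIDES = frozenset({"side1", "side2", "merged"})


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class SpatialCountTable:
    """Integer read counts of taxa (rows) across biofilm sections (columns)."""

    taxon_ids: list[str]
    section_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.section_ids = [str(s) for s in self.section_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise ValueError("non-integer count in matrix")
            counts = counts.astype(np.int64)
        else:
            counts = counts.astype(np.int64, copy=True)
        if counts.shape != (len(self.taxon_ids), len(self.section_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.section_ids)} sections"
            )
        if len(self.taxon_ids) < 1 or len(self.section_ids) < 1:
            raise ValueError("need at least one taxon and one section")
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at taxon {self.taxon_ids[i]!r}, "
                f"section {self.section_ids[j]!r}"
            )
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.section_ids, "section")
        self.counts = counts

    # -- basic accessors ----------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_sections(self) -> int:
        return len(self.section_ids)

    def section_index(self, section_id: str) -> int:
        try:
            return self.section_ids.index(section_id)
        except ValueError:
            raise KeyError(f"unknown section id: {section_id!r}") from None

    def column(self, section_id: str) -> np.ndarray:
        return self.counts[:, self.section_index(section_id)]

    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def copy(self) -> "SpatialCountTable":
        return SpatialCountTable(list(self.taxon_ids), list(self.section_ids), self.counts.copy())

    def subset_taxa(self, taxa: Iterable[str]) -> "SpatialCountTable":
        wanted = set(taxa)
        unknown = wanted - set(self.taxon_ids)
        if unknown:
            raise KeyError(f"unknown taxon ids: {sorted(unknown)}")
        idx = [i for i, t in enumerate(self.taxon_ids) if t in wanted]
        return SpatialCountTable([self.taxon_ids[i] for i in idx], list(self.section_ids), self.counts[idx])

    def subset_sections(self, sections: Sequence[str]) -> "SpatialCountTable":
        idx = [self.section_index(s) for s in sections]
        return SpatialCountTable(list(self.taxon_ids), list(sections), self.counts[:, idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.taxon_ids, name="taxon_id"),
                            columns=self.section_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SpatialCountTable":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpatialCountTable):
            return NotImplemented
        return (self.taxon_ids == other.taxon_ids
                and self.section_ids == other.section_ids
                and np.array_equal(self.counts, other.counts))


# -- TSV I/O ---------------------------------------------------------------


def read_count_table(path: str | Path) -> SpatialCountTable:
    """Read a taxa x section TSV (first column taxon ids, header section ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no section columns found")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = np.argwhere(~np.vectorize(lambda v: isinstance(v, (int, np.integer)))(arr))
        i, j = bad[0]
        raise ValueError(
            f"{path}: non-integer count at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if np.any(~np.isfinite(arr)) or np.any(arr != np.floor(arr)):
        i, j = np.argwhere(~np.isfinite(arr) | (arr != np.floor(arr)))[0]
        raise ValueError(
            f"{path}: non-integer count at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if np.any(arr < 0):
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"{path}: negative count at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return SpatialCountTable.from_dataframe(df)


def write_count_table(table: SpatialCountTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t")


def _read_frame(path: str | Path, required: Sequence[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: {what} file missing columns {missing}")
    df["section_id"] = df["section_id"].astype(str)
    if df["section_id"].duplicated().any():
        dup = df.loc[df["section_id"].duplicated(), "section_id"].iloc[0]
        raise ValueError(f"{path}: duplicate section id {dup!r}")
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read section metadata (position_cm, side, length_cm, area_cm2 [, environment])."""
    df = _read_frame(path, METADATA_COLUMNS, "metadata")
    validate_metadata(df)
    return df


def validate_metadata(meta: pd.DataFrame) -> None:
    if (meta["position_cm"] < 0).any():
        raise ValueError("position_cm must be >= 0")
    if (meta["length_cm"] <= 0).any():
        raise ValueError("length_cm must be > 0")
    if (meta["area_cm2"] <= 0).any():
        raise ValueError("area_cm2 must be > 0")
    bad = set(meta["side"].unique()) - VALID_SIDES
    if bad:
        raise ValueError(f"unknown side labels: {sorted(bad)}")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_physical(path: str | Path) -> pd.DataFrame:
    df = _read_frame(path, PHYSICAL_COLUMNS, "physical")
    if (df["cell_density_areal"] <= 0).any():
        raise ValueError("cell_density_areal must be > 0")
    if (df["thickness_um"] <= 0).any():
        raise ValueError("thickness_um must be > 0")
    return df


def write_physical(phys: pd.DataFrame, path: str | Path) -> None:
    phys.to_csv(path, sep="\t", index=False)


# -- shared numeric helpers ------------------------------------------------


def relative_abundances(table: SpatialCountTable, section_id: str) -> np.ndarray:
    """Per-taxon relative abundances p_i in one section (sums to 1)."""
    col = table.column(section_id).astype(float)
    total = col.sum()
    if total <= 0:
        raise ValueError(f"empty section: {section_id!r} has no reads")
    return col / total


def merge_counts(
    table: SpatialCountTable,
    groups: Sequence[Sequence[str]],
    names: Sequence[str] | None = None,
) -> SpatialCountTable:
    """Sum counts within disjoint groups of sections into pooled sections.

    Each group becomes one output section whose counts are the elementwise sum
    over its members; reads are conserved.  Sections not listed in any group
    are dropped.  Output sections are named after their members joined with
    ``'+'`` unless explicit ``names`` are given.
    """
    if not groups:
        raise ValueError("no groups given")
    seen: set[str] = set()
    known = set(table.section_ids)
    for g in groups:
        members = list(g)
        if not members:
            raise ValueError("empty group")
        for s in members:
            if s not in known:
                raise KeyError(f"unknown section id in group: {s!r}")
            if s in seen:
                raise ValueError(f"overlapping groups: section {s!r} appears twice")
            seen.add(s)
    if names is None:
        names = ["+".join(g) for g in groups]
    cols = [table.counts[:, [table.section_index(s) for s in g]].sum(axis=1) for g in groups]
    return SpatialCountTable(list(table.taxon_ids), list(names), np.column_stack(cols))


def half_pipe_area_cm2(length_cm: float, inner_diameter_cm: float = 0.8) -> float:
    """Inner surface area of one half of a length-wise bisected pipe section."""
    if length_cm <= 0 or inner_diameter_cm <= 0:
        raise ValueError("length and diameter must be positive")
    return length_cm * math.pi * inner_diameter_cm / 2


# -- run configuration -----------------------------------------------------


@dataclass
class PipelineConfig:
    """Shared knobs for a full analysis run."""

    seed: int = 0
    rarefaction_depth: int = 10_000
    alpha_level: float = 0.05
    bh_enabled: bool = True
    iterations: int = 100
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rarefaction_depth < 0:
            raise ValueError("rarefaction_depth must be >= 0")
        if not 0 < self.alpha_level < 1:
            raise ValueError("alpha_level must be in (0, 1)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {k: raw.pop(k) for k in
                  ("seed", "rarefaction_depth", "alpha_level", "bh_enabled", "iterations")
                  if k in raw}
        return cls(extra=raw, **fields)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "seed": self.seed,
            "rarefaction_depth": self.rarefaction_depth,
            "alpha_level": self.alpha_level,
            "bh_enabled": self.bh_enabled,
            "iterations": self.iterations,
            **self.extra,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
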