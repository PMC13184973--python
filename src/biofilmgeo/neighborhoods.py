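"""Expected cells and taxonomic richness in micrometre-scale neighborhoods.

A biofilm section with areal cell density ``D`` (cells/cm^2) and thickness
``t`` (um) holds, in expectation, ``D x A / 1e8`` cells in a planar patch of
``A`` um^2, and ``rho x V`` cells in a spherical neighborhood of radius ``r``
um around a focal cell, where ``rho = D / (1e8 t)`` is the volumetric density
under the assumption that cells are distributed uniformly through the
thickness, and ``V`` is the sphere volume, optionally clipped to the biofilm
slab.

Given the section's relative abundances ``p_i`` and an expected neighborhood
cell count ``n``, the expected number of distinct taxa among ``n`` random
cells follows the closed-form collector ("Heaps") expectation

    E[R_m(n)] = m - sum_i (1 - p_i)^n

which is evaluated at real-valued ``n`` (the expectation interpolates
smoothly between integer cell counts).  Because real biofilms contain
microcolonies of clonal cells, these estimates are a theoretical upper bound
on local diversity, not a measurement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from ._seeds import child_rng
from .core import SpatialCountTable, relative_abundances

__all__ = [
    "NeighborhoodQuery",
    "cells_in_area",
    "cells_in_volume",
    "heaps_expected_richness",
    "mc_neighborhood_richness",
    "neighborhood_richness_profile",
]

UM2_PER_CM2 = 1e8


@dataclass(frozen=True)
class NeighborhoodQuery:
    """A planar (``area_um2``) or spherical (``radius_um``) neighborhood."""

    kind: str  # {"area", "volume"}
    area_um2: float | None = None
    radius_um: float | None = None
    clip_to_thickness: bool = True
    include_focal: bool = False

    def __post_init__(self) -> None:
        if self.kind == "area":
            if not (self.area_um2 and self.area_um2 > 0) or self.radius_um is not None:
                raise ValueError("area query needs a positive area_um2 and no radius")
        elif self.kind == "volume":
            if not (self.radius_um and self.radius_um > 0) or self.area_um2 is not None:
                raise ValueError("volume query needs a positive radius_um and no area")
        else:
            raise ValueError(f"unknown query kind {self.kind!r}")

    @property
    def label(self) -> str:
        if self.kind == "area":
            return f"area_{self.area_um2:g}um2"
        return f"radius_{self.radius_um:g}um"


def cells_in_area(density_cells_cm2: float, area_um2: float) -> float:
    """Expected cells in a planar patch: density x area (1 cm^2 = 1e8 um^2)."""
    if density_cells_cm2 <= 0 or area_um2 <= 0:
        raise ValueError("density and area must be positive")
    return density_cells_cm2 * area_um2 / UM2_PER_CM2


def sphere_slab_volume(radius_um: float, thickness_um: float, clip: bool = True) -> float:
    """Volume of a sphere of radius r centred mid-slab, optionally clipped.

    With half-height ``a = min(r, t/2)`` (or ``a = r`` unclipped) the
    intersection volume is ``2 pi (r^2 a - a^3 / 3)``; for ``a = r`` this is
    the full sphere ``4 pi r^3 / 3``.
    """
    if radius_um <= 0 or thickness_um <= 0:
        raise ValueError("radius and thickness must be positive")
    a = min(radius_um, thickness_um / 2) if clip else radius_um
    return 2 * np.pi * (radius_um**2 * a - a**3 / 3)


def cells_in_volume(
    density_cells_cm2: float,
    thickness_um: float,
    radius_um: float,
    clip: bool = True,
) -> float:
    """Expected cells in a spherical neighborhood inside the biofilm slab."""
    if density_cells_cm2 <= 0:
        raise ValueError("density must be positive")
    rho = density_cells_cm2 / (UM2_PER_CM2 * thickness_um)  # cells / um^3
    return rho * sphere_slab_volume(radius_um, thickness_um, clip=clip)


def heaps_expected_richness(p: Sequence[float], n: float) -> float:
    """Closed-form expected number of distinct taxa among n random cells.

    ``p`` must be non-negative and sum to 1 (tolerance 1e-8); ``n >= 0`` may
    be fractional.  Zero-abundance entries contribute nothing, so the result
    lies in ``[0, m]`` with ``m = len(p)`` and approaches the number of
    positive-abundance taxa as ``n`` grows.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative abundance")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"abundances sum to {p.sum():.6g}, expected 1")
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return 0.0
    with np.errstate(divide="ignore"):
        log_miss = np.log1p(-np.minimum(p, 1.0))  # log(1 - p_i); -inf at p = 1
    # per-taxon detection probability 1 - (1-p)^n, numerically via expm1
    terms = -np.expm1(n * log_miss)
    terms[p >= 1.0] = 1.0
    return float(terms.sum())


def mc_neighborhood_richness(
    p: Sequence[float],
    n: int,
    reps: int = 100_000,
    seed: int = 0,
    chunk: int = 50_000,
) -> tuple[float, float]:
    """Monte-Carlo oracle: mean and sd of distinct taxa over multinomial draws."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative abundance")
    if n < 1 or reps < 1:
        raise ValueError("n and reps must be >= 1")
    rng = child_rng(seed, "mc_neighborhood", n, reps)
    total = 0.0
    total_sq = 0.0
    done = 0
    while done < reps:
        size = min(chunk, reps - done)
        draws = rng.multinomial(n, p / p.sum(), size=size)
        distinct = (draws > 0).sum(axis=1).astype(float)
        total += distinct.sum()
        total_sq += (distinct**2).sum()
        done += size
    mean = total / reps
    var = max(total_sq / reps - mean**2, 0.0)
    return mean, float(np.sqrt(var))


def neighborhood_richness_profile(
    table: SpatialCountTable,
    physical: pd.DataFrame,
    queries: Sequence[NeighborhoodQuery],
) -> pd.DataFrame:
    """Expected cells and richness per (section, query).

    Sections without a physical-measurement row are skipped with a warning.
    Columns: section_id, query, expected_cells, expected_richness,
    section_richness.
    """
    phys = physical.set_index("section_id")
    rows: list[dict] = []
    for sid in table.section_ids:
        if sid not in phys.index:
            warnings.warn(f"no physical data for section {sid!r}; skipped", stacklevel=2)
            continue
        density = float(phys.at[sid, "cell_density_areal"])
        thickness = float(phys.at[sid, "thickness_um"])
        p = relative_abundances(table, sid)
        m_present = int((p > 0).sum())
        for q in queries:
            if q.kind == "area":
                n = cells_in_area(density, q.area_um2)
            else:
                n = cells_in_volume(density, thickness, q.radius_um, clip=q.clip_to_thickness)
            if q.include_focal:
                n += 1.0
            rows.append(dict(
                section_id=sid,
                query=q.label,
                expected_cells=n,
                expected_richness=heaps_expected_richness(p, n),
                section_richness=m_present,
            ))
    return pd.DataFrame(rows)
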