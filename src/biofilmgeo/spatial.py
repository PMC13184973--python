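"""Per-taxon spatial trend tests and distance-decay breakpoint estimation.

Monotonic trends of relative abundance along the pipe are detected by
Spearman correlation (exact permutation tail for tiny series, t-approximation
otherwise); non-random but non-monotonic patterns by the Wald-Wolfowitz runs
test around the series median (exact runs distribution for short series,
normal approximation with continuity correction otherwise).  P-values are
Benjamini-Hochberg adjusted across taxa within each test family.

Changes in the spatial turnover of beta diversity are located by a
two-segment continuous piecewise-linear ("segmented") least-squares fit of
dissimilarity on distance, with the breakpoint found by grid search plus
golden-section refinement and its uncertainty by case-resampling bootstrap.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from ._seeds import child_rng
from .core import SpatialCountTable

__all__ = [
    "TrendTest",
    "RunsTest",
    "BreakpointFit",
    "spearman_trend",
    "runs_test",
    "runs_distribution",
    "classify_trends",
    "breakpoint_fit",
]

#: largest n for which the Spearman permutation null is fully enumerated
SPEARMAN_EXACT_N = 9
#: largest n1 + n2 for which the exact runs distribution is used
RUNS_EXACT_N = 20


class TrendTest(NamedTuple):
    rho: float
    p: float
    degenerate: bool = False


class RunsTest(NamedTuple):
    n_runs: int
    n_above: int
    n_below: int
    p: float


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_trend(values: Sequence[float], positions: Sequence[float]) -> TrendTest:
    """Spearman rank correlation of a series against 1-D position.

    Mid-ranks handle ties.  Up to ``SPEARMAN_EXACT_N`` observations the
    two-sided p-value is the exact permutation tail (all n! orderings
    enumerated); beyond that the usual t-approximation with n - 2 degrees of
    freedom is used.  A constant series is degenerate: rho = 0, p = 1, flag
    set.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(positions, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("values and positions must be equal-length 1-D vectors")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TrendTest(0.0, 1.0, degenerate=True)
    rx, ry = _rank(x), _rank(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= SPEARMAN_EXACT_N:
        p = _spearman_exact_p(rx, ry, rho)
    else:
        t = rho * math.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    return TrendTest(rho, min(max(p, np.finfo(float).tiny), 1.0))


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation tail P(|rho| >= |rho_obs|) by full enumeration."""
    n = len(rx)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    target = abs(rho_obs) * denom - 1e-9
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        s = abs(float(rx_c[list(perm)] @ ry_c))
        count += s >= target
        total += 1
    return count / total


def runs_distribution(n1: int, n2: int) -> np.ndarray:
    """Exact pmf of the number of runs R = 2..n1+n2 in a random arrangement.

    Index r of the returned vector holds P(R = r) (entries 0 and 1 are 0).
    """
    n = n1 + n2
    total = math.comb(n, n1)
    pmf = np.zeros(n + 1)
    for r in range(2, n + 1):
        if r % 2 == 0:
            k = r // 2
            ways = 2 * math.comb(n1 - 1, k - 1) * math.comb(n2 - 1, k - 1)
        else:
            k = (r - 1) // 2
            ways = (math.comb(n1 - 1, k) * math.comb(n2 - 1, k - 1)
                    + math.comb(n1 - 1, k - 1) * math.comb(n2 - 1, k))
        pmf[r] = ways / total
    return pmf


def runs_test(series: Sequence[float]) -> RunsTest:
    """Wald-Wolfowitz runs test for non-randomness of a 1-D series.

    The series is dichotomized around its median (values equal to the median
    dropped).  Two-sided p: twice the smaller exact tail of the runs
    distribution when n1 + n2 <= ``RUNS_EXACT_N``, else a normal
    approximation with continuity correction.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 6:
        raise ValueError("need a 1-D series of at least 6 observations")
    med = np.median(x)
    signs = np.sign(x - med)
    signs = signs[signs != 0]
    if len(signs) < 2 or np.ptp(signs) == 0:
        raise ValueError("degenerate series: constant around its median")
    n1 = int((signs > 0).sum())
    n2 = int((signs < 0).sum())
    runs = int(1 + (np.diff(signs) != 0).sum())
    n = n1 + n2
    if n <= RUNS_EXACT_N:
        pmf = runs_distribution(n1, n2)
        lower = pmf[: runs + 1].sum()
        upper = pmf[runs:].sum()
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        mu = 1 + 2 * n1 * n2 / n
        var = 2 * n1 * n2 * (2 * n1 * n2 - n) / (n**2 * (n - 1))
        sd = math.sqrt(var)
        z = (abs(runs - mu) - 0.5) / sd
        p = float(min(1.0, 2 * stats.norm.sf(max(z, 0.0))))
    return RunsTest(runs, n1, n2, max(p, np.finfo(float).tiny))


def classify_trends(
    table: SpatialCountTable,
    meta: pd.DataFrame,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Classify every taxon's spatial pattern as monotonic, nonrandom, or none.

    Relative abundances are ordered by axial position (ties by side, then id);
    each taxon gets a Spearman trend test and a runs test on the same series.
    BH adjustment is applied across taxa separately per test family, and a
    taxon is ``monotonic`` when the adjusted Spearman p <= alpha, else
    ``nonrandom`` when the adjusted runs p <= alpha, else ``none``.
    """
    m = meta.set_index("section_id").loc[table.section_ids].reset_index()
    order = m.sort_values(["position_cm", "side", "section_id"])["section_id"].tolist()
    if len(order) < 6:
        raise ValueError("need at least 6 sections")
    sub = table.subset_sections(order)
    pos = meta.set_index("section_id").loc[order, "position_cm"].to_numpy(dtype=float)
    rel = sub.counts / sub.counts.sum(axis=0, keepdims=True)

    rows = []
    for i, taxon in enumerate(sub.taxon_ids):
        series = rel[i]
        sp = spearman_trend(series, pos)
        if sp.degenerate:
            runs_p, degenerate = 1.0, True
        else:
            try:
                runs_p = runs_test(series).p
                degenerate = False
            except ValueError:
                runs_p, degenerate = 1.0, True
        rows.append(dict(taxon_id=taxon, spearman_rho=sp.rho, spearman_p=sp.p,
                         runs_p=runs_p, degenerate=degenerate or sp.degenerate))
    df = pd.DataFrame(rows)
    # degenerate taxa (constant/absent series) are not tests; keeping their
    # p = 1 placeholders out of the BH family avoids diluting the correction
    ok = ~df["degenerate"].to_numpy()
    for raw, adj in (("spearman_p", "rho_p_adj"), ("runs_p", "runs_p_adj")):
        df[adj] = 1.0
        if ok.any():
            _, padj, _, _ = multipletests(df.loc[ok, raw], method="fdr_bh")
            df.loc[ok, adj] = padj
    cls = np.where(df["degenerate"], "none",
                   np.where(df["rho_p_adj"] <= alpha_level, "monotonic",
                            np.where(df["runs_p_adj"] <= alpha_level, "nonrandom", "none")))
    df["classification"] = cls
    return df


@dataclass
class BreakpointFit:
    """Two-segment continuous piecewise-linear fit of dissimilarity vs distance."""

    breakpoint_cm: float
    breakpoint_se_cm: float
    slope_left: float
    slope_right: float
    intercept: float
    sse: float
    sse_single_line: float
    no_breakpoint: bool  # two-segment fit improves SSE by < 1% over one line
    n_boot: int


def _segmented_sse(d: np.ndarray, y: np.ndarray, psi: float) -> tuple[float, np.ndarray]:
    X = np.column_stack([np.ones_like(d), d, np.maximum(d - psi, 0.0)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


def _best_breakpoint(
    d: np.ndarray, y: np.ndarray, max_candidates: int = 60, min_edge: int = 3
) -> tuple[float, float, np.ndarray]:
    uniq = np.unique(d)
    inner = uniq[min_edge:-min_edge] if len(uniq) > 2 * min_edge else uniq[1:-1]
    if len(inner) == 0:
        raise ValueError("too few distinct distances for a breakpoint search")
    if len(inner) > max_candidates:
        qs = np.linspace(0, 1, max_candidates)
        inner = np.unique(np.quantile(inner, qs))
    sses = np.array([_segmented_sse(d, y, psi)[0] for psi in inner])
    i = int(np.argmin(sses))
    lo = inner[max(i - 1, 0)]
    hi = inner[min(i + 1, len(inner) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda psi: _segmented_sse(d, y, psi)[0],
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-4 * (d.max() - d.min())},
        )
        psi = float(res.x)
        if _segmented_sse(d, y, psi)[0] > sses[i]:
            psi = float(inner[i])
    else:
        psi = float(inner[i])
    sse, beta = _segmented_sse(d, y, psi)
    return psi, sse, beta


def breakpoint_fit(
    distance: Sequence[float],
    dissimilarity: Sequence[float],
    n_boot: int = 199,
    seed: int = 0,
    max_candidates: int = 60,
) -> BreakpointFit:
    """Locate the distance at which the dissimilarity-distance slope changes.

    Least-squares two-segment fit, breakpoint by grid search over (at most
    ``max_candidates``) interior distance values refined by bounded
    minimisation; ``breakpoint_se_cm`` is the standard deviation of the
    breakpoint over ``n_boot`` case-resampling bootstrap replicates.  When
    the two-segment fit beats a single line by less than 1% in SSE the
    ``no_breakpoint`` flag is set.
    """
    d = np.asarray(distance, dtype=float)
    y = np.asarray(dissimilarity, dtype=float)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError("distance and dissimilarity must be equal-length vectors")
    if len(d) < 10:
        raise ValueError("need at least 10 points")
    if np.ptp(d) == 0:
        raise ValueError("distances must span a positive range")

    psi, sse, beta = _best_breakpoint(d, y, max_candidates=max_candidates)
    X1 = np.column_stack([np.ones_like(d), d])
    b1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid1 = y - X1 @ b1
    sse1 = float(resid1 @ resid1)
    no_bp = sse1 <= 0 or (sse1 - sse) / sse1 < 0.01

    boots = []
    rng = child_rng(seed, "breakpoint_boot")
    for _ in range(n_boot):
        idx = rng.integers(0, len(d), size=len(d))
        db, yb = d[idx], y[idx]
        if np.ptp(db) == 0 or len(np.unique(db)) < 4:
            continue
        try:
            psi_b, _, _ = _best_breakpoint(db, yb, max_candidates=max_candidates)
        except (ValueError, np.linalg.LinAlgError):  # pragma: no cover
            continue
        boots.append(psi_b)
    se = float(np.std(boots, ddof=1)) if len(boots) > 1 else float("nan")
    return BreakpointFit(
        breakpoint_cm=psi,
        breakpoint_se_cm=se,
        slope_left=float(beta[1]),
        slope_right=float(beta[1] + beta[2]),
        intercept=float(beta[0]),
        sse=sse,
        sse_single_line=sse1,
        no_breakpoint=bool(no_bp),
        n_boot=len(boots),
    )
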