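"""Nonparametric group statistics for pooled per-nucleus measurements.

Group contrasts use the two-sided Mann-Whitney U test (exact by
enumeration for small tie-free samples, normal approximation with tie and
continuity corrections otherwise) with Bonferroni correction across a
comparison family.  Distribution summaries follow the Tukey box-plot
convention (whiskers at the most extreme data within 1.5 IQR of the box).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "GroupComparison",
    "BoxSummary",
    "mann_whitney_u",
    "bonferroni",
    "box_summary",
    "sem_curves",
]


@dataclass
class GroupComparison:
    group_x: str
    group_y: str
    n_x: int
    n_y: int
    U: float
    p: float
    p_adj: float | None = None
    method: str = "exact"


@dataclass
class BoxSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x: number of (x_i, y_j) pairs with x_i > y_j, ties count 1/2."""
    ranks = rankdata(np.concatenate([x, y]))
    r_x = ranks[: len(x)].sum()
    return float(r_x - len(x) * (len(x) + 1) / 2)


def _exact_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumerating all assignments of ranks to x.

    Valid with ties (midranks are enumerated like any other values).
    Two-sided p = P(|U - mu| >= |U_obs - mu|) under the null.
    """
    n_x, n_y = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    mu = n_x * n_y / 2.0
    dev = abs(u_obs - mu) - 1e-12
    total = comb(n_x + n_y, n_x)
    hits = 0
    base = n_x * (n_x + 1) / 2
    for idx in combinations(range(n_x + n_y), n_x):
        u = ranks[list(idx)].sum() - base
        if abs(u - mu) >= dev:
            hits += 1
    return hits / total


def _asymptotic_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Normal approximation with tie-corrected variance and continuity
    correction."""
    n_x, n_y = len(x), len(y)
    n = n_x + n_y
    mu = n_x * n_y / 2.0
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (abs(u_obs - mu) - 0.5) / sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * (1.0 - 0.5 * (1.0 + erf(z / sqrt(2.0))))))


def mann_whitney_u(
    x,
    y,
    mode: str = "auto",
    group_x: str = "x",
    group_y: str = "y",
) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    ``mode='auto'`` uses exact enumeration when ``n_x + n_y <= 16`` and the
    pooled sample has no ties, else the tie-corrected normal approximation
    with continuity correction.  ``U`` is reported for the x sample
    (``U_xy + U_yx = n_x * n_y``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("exact", "asymptotic", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    u = _u_statistic(x, y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if mode == "auto":
        mode = "exact" if (x.size + y.size <= 16 and not has_ties) else "asymptotic"
    p = _exact_p(x, y, u) if mode == "exact" else _asymptotic_p(x, y, u)
    return GroupComparison(
        group_x=group_x,
        group_y=group_y,
        n_x=int(x.size),
        n_y=int(y.size),
        U=u,
        p=min(1.0, p),
        method=mode,
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: each p -> min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)


def box_summary(values) -> BoxSummary:
    """Tukey box-plot summary of a sample.

    Quartiles use the linear-interpolation rule; whiskers sit at the most
    extreme observations within 1.5 IQR of the box; everything beyond is
    an outlier.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    whisker_low = float(inside.min()) if inside.size else float(q1)
    whisker_high = float(inside.max()) if inside.size else float(q3)
    outliers = np.sort(v[(v < lo_fence) | (v > hi_fence)])
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        outliers=outliers,
    )


def sem_curves(curves) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and SEM (sample SD / sqrt(n)) across replicate curves."""
    arrs = [np.asarray(c, dtype=float) for c in curves]
    if len(arrs) < 2:
        raise ValueError("need at least 2 curves")
    length = len(arrs[0])
    if any(len(a) != length for a in arrs):
        raise ValueError("curves must have equal length")
    mat = np.stack(arrs)
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / sqrt(mat.shape[0])
    return mean, sem
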