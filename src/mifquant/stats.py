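"""Pharmacodynamic statistics: percent change from vehicle, unpaired
Mann-Whitney comparisons, and Spearman rank concordance.

Conventions (each oracle-checkable and recorded on the result object):

* Mann-Whitney U is the rank-sum statistic with ties sharing mid-ranks.
  When the pooled sample is tie-free and n_a + n_b <= ``exact_cutoff``
  (default 16) the two-sided p is exact: the smaller tail probability of U
  over all C(N, n_a) equally likely rank assignments, doubled and capped at
  1.  Otherwise a tie-corrected normal approximation with a 0.5 continuity
  correction is used.  Identical groups give z = 0, hence p = 1.
* Spearman's rho is the product-moment correlation of mid-ranks; its p uses
  the large-sample t approximation with n - 2 degrees of freedom (exact at
  |rho| = 1, where p = 0).  Constant input leaves rho undefined (NaN).
* Percent change from vehicle is 100 * (sample - vehicle_mean) / vehicle_mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import norm, rankdata, t as t_dist


class StatsError(ValueError):
    pass


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    method: str  # "exact" or "normal_approx"

    def __post_init__(self) -> None:
        if not 0 <= self.u_statistic <= self.n_a * self.n_b:
            raise StatsError("U outside [0, n_a * n_b]")
        if not 0 < self.p_value <= 1:
            raise StatsError("p-value outside (0, 1]")


@dataclass
class Concordance:
    rho: float  # NaN when undefined (constant input)
    p_value: float
    n: int
    method: str = "t_approx"
    note: str = ""


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float


def percent_change_from_vehicle(sample_value: float, vehicle_mean: float) -> float:
    """100 * (sample - vehicle mean) / vehicle mean."""
    if vehicle_mean == 0:
        raise StatsError("undefined baseline: vehicle mean is 0")
    return 100.0 * (sample_value - vehicle_mean) / vehicle_mean


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
    exact_cutoff: int = 16,
) -> GroupComparison:
    """Unpaired two-sided Mann-Whitney test of two numeric samples."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise StatsError("empty group")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # mid-ranks for ties
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)
    has_ties = len(np.unique(pooled)) < len(pooled)

    if not has_ties and n_a + n_b <= exact_cutoff:
        p = _exact_two_sided_p(u_a, n_a, n_b)
        method = "exact"
    else:
        p = _normal_approx_two_sided_p(u_a, n_a, n_b, pooled)
        method = "normal_approx"
    return GroupComparison(label_a, label_b, n_a, n_b, u_a, p, method)


def _exact_two_sided_p(u_obs: float, n_a: int, n_b: int) -> float:
    """Tail-doubled exact p by enumerating every rank assignment."""
    n = n_a + n_b
    offset = n_a * (n_a + 1) // 2
    total = comb(n, n_a)
    le = ge = 0
    for c in combinations(range(1, n + 1), n_a):
        u = sum(c) - offset
        if u <= u_obs:
            le += 1
        if u >= u_obs:
            ge += 1
    one_sided = min(le, ge) / total
    return min(1.0, 2.0 * one_sided)


def _normal_approx_two_sided_p(
    u_obs: float, n_a: int, n_b: int, pooled: np.ndarray
) -> float:
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    diff = u_obs - mu
    # 0.5 continuity correction toward the mean
    z = (diff - 0.5 * np.sign(diff)) / sqrt(var) if diff != 0 else 0.0
    return min(1.0, 2.0 * float(norm.sf(abs(z))))


def spearman(x: Sequence[float], y: Sequence[float]) -> Concordance:
    """Spearman rank-order correlation with mid-rank ties."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise StatsError("length mismatch")
    n = len(x)
    if n < 3:
        raise StatsError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return Concordance(float("nan"), float("nan"), n, note="constant input: rho undefined")
    rx, ry = rankdata(x), rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0 - 1e-15:
        p = 0.0
    else:
        t = rho * sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * float(t_dist.sf(abs(t), n - 2))
    return Concordance(rho, min(p, 1.0), n)


def summarize_groups(
    values: Mapping[str, Sequence[Optional[float]]],
    reference: Optional[str] = None,
    contrasts: Optional[Sequence[tuple[str, str]]] = None,
) -> tuple[list[GroupSummary], list[GroupComparison]]:
    """Per-group mean/SD/n plus pairwise Mann-Whitney comparisons.

    ``values`` maps group label to that group's metric values; missing
    values (None/NaN) are excluded and ``n`` reflects the exclusions.
    Contrasts default to each non-reference group vs ``reference`` (the
    vehicle group) when given, else all pairs in label order.  SD is the
    sample (ddof=1) standard deviation, 0 for singleton groups.
    """
    clean: dict[str, np.ndarray] = {}
    for g, vals in values.items():
        arr = np.asarray([v for v in vals if v is not None], float)
        arr = arr[~np.isnan(arr)]
        if arr.size == 0:
            raise StatsError(f"group {g!r} empty after excluding missing values")
        clean[g] = arr

    summaries = [
        GroupSummary(g, int(v.size), float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0)
        for g, v in clean.items()
    ]

    if contrasts is None:
        labels = list(clean)
        if reference is not None:
            if reference not in clean:
                raise StatsError(f"unknown reference group {reference!r}")
            contrasts = [(reference, g) for g in labels if g != reference]
        else:
            contrasts = list(combinations(labels, 2))
    comparisons = []
    for ga, gb in contrasts:
        if ga not in clean or gb not in clean:
            raise StatsError(f"unknown group in contrast ({ga!r}, {gb!r})")
        comparisons.append(mann_whitney(clean[ga], clean[gb], ga, gb))
    return summaries, comparisons


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment (optional; unadjusted tests are the default)."""
    m = len(p_values)
    order = np.argsort(p_values)
    adjusted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p_values[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()
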