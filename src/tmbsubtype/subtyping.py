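"""Tumor-mutation-burden subtyping.

Per-sample TMB is the count of somatic mutations (all classes by default;
a nonsynonymous-only mode is provided).  The 1-D TMB distribution is
partitioned by an exact dynamic program minimizing within-cluster sum of
squares; the number of clusters is chosen by a Gaussian-mixture BIC.
Subtype labels are thresholded: TMB strictly above the threshold (cohort
mean by default) is TMB-H, otherwise TMB-L.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .io_cohort import CohortTable, SYNONYMOUS_CLASSES


class CountingMode(str, Enum):
    ALL_SOMATIC = "all_somatic"
    NONSYNONYMOUS_ONLY = "nonsynonymous_only"


class ThresholdRule(str, Enum):
    MEAN = "mean"
    MEDIAN = "median"
    KMEANS_BOUNDARY = "kmeans_boundary"


class Subtype(str, Enum):
    TMB_H = "TMB-H"
    TMB_L = "TMB-L"


@dataclass(frozen=True)
class TmbProfile:
    sample_ids: tuple[str, ...]
    tmb: tuple[int, ...]
    counting_mode: CountingMode

    def as_array(self) -> np.ndarray:
        return np.asarray(self.tmb, dtype=float)


@dataclass(frozen=True)
class ClusterResult:
    k: int
    assignments: tuple[int, ...]  # cluster index per input value, centers ascending
    boundaries: tuple[float, ...]  # k-1 cut values (midpoints between clusters)
    centers: tuple[float, ...]
    wcss_by_k: dict[int, float]
    bic_by_k: dict[int, float]
    k_selected: int


@dataclass(frozen=True)
class SubtypeAssignment:
    threshold: float
    rule: ThresholdRule
    sample_ids: tuple[str, ...]
    labels: tuple[Subtype, ...]


def compute_tmb(
    cohort: CohortTable,
    counting_mode: CountingMode = CountingMode.ALL_SOMATIC,
) -> TmbProfile:
    """Count somatic mutations per sample; zero-mutation samples get 0."""
    counts = {s: 0 for s in cohort.sample_ids}
    for m in cohort.mutations:
        if (
            counting_mode is CountingMode.NONSYNONYMOUS_ONLY
            and m.variant_class in SYNONYMOUS_CLASSES
        ):
            continue
        counts[m.sample_id] += 1
    return TmbProfile(
        sample_ids=tuple(cohort.sample_ids),
        tmb=tuple(counts[s] for s in cohort.sample_ids),
        counting_mode=counting_mode,
    )


# ---------------------------------------------------------------------------
# Exact 1-D k-means by dynamic programming


def _interval_cost(prefix: np.ndarray, prefix_sq: np.ndarray, i: int, j: int) -> float:
    """WCSS of sorted values[i..j] inclusive, O(1) via prefix sums."""
    n = j - i + 1
    s = prefix[j + 1] - prefix[i]
    sq = prefix_sq[j + 1] - prefix_sq[i]
    return max(sq - s * s / n, 0.0)


def ckmeans_1d(values: Sequence[float], k: int) -> tuple[np.ndarray, float]:
    """Optimal k-partition of 1-D data minimizing within-cluster SS.

    Returns ``(assignments, wcss)`` where assignments index clusters ordered
    by increasing center and refer to the input order.  The partition is
    globally optimal: a dynamic program over the sorted order, O(k n^2) with
    O(1) interval costs.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("values must be a non-empty 1-D array")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    n = x.size
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")

    order = np.argsort(x, kind="stable")
    xs = x[order]
    prefix = np.concatenate([[0.0], np.cumsum(xs)])
    prefix_sq = np.concatenate([[0.0], np.cumsum(xs * xs)])

    # cost[m][j] = optimal WCSS of xs[0..j] split into m+1 clusters
    cost = np.full((k, n), np.inf)
    back = np.zeros((k, n), dtype=int)
    for j in range(n):
        cost[0, j] = _interval_cost(prefix, prefix_sq, 0, j)
    for m in range(1, k):
        for j in range(m, n):
            best, best_i = np.inf, m
            for i in range(m, j + 1):  # cluster m covers xs[i..j]
                c = cost[m - 1, i - 1] + _interval_cost(prefix, prefix_sq, i, j)
                if c < best:
                    best, best_i = c, i
            cost[m, j] = best
            back[m, j] = best_i

    # recover cut points on the sorted order
    starts = [0] * k
    j = n - 1
    for m in range(k - 1, 0, -1):
        starts[m] = back[m, j]
        j = starts[m] - 1
    labels_sorted = np.zeros(n, dtype=int)
    for m in range(k):
        end = starts[m + 1] if m + 1 < k else n
        labels_sorted[starts[m]:end] = m
    assignments = np.empty(n, dtype=int)
    assignments[order] = labels_sorted
    return assignments, float(cost[k - 1, n - 1])


def _cluster_stats(x: np.ndarray, assignments: np.ndarray, k: int):
    sizes = np.array([(assignments == m).sum() for m in range(k)])
    centers = np.array([x[assignments == m].mean() for m in range(k)])
    return sizes, centers


def _bic_gaussian(x: np.ndarray, assignments: np.ndarray, k: int) -> float:
    """Gaussian-mixture BIC for a hard 1-D partition (higher is better).

    Each cluster contributes a Gaussian with mixing weight n_m/n; the
    per-cluster variance is floored at ``(1e-3 * sd(x))^2`` (absolute floor
    1e-9) so zero-variance clusters stay finite without letting singleton
    clusters dominate the likelihood.  Parameters: k-1 weights + k means +
    k variances = 3k - 1.
    """
    n = x.size
    floor = max(1e-9, (1e-3 * float(np.std(x))) ** 2)
    loglik = 0.0
    for m in range(k):
        xm = x[assignments == m]
        nm = xm.size
        var = max(float(np.var(xm)), floor)
        loglik += nm * (
            np.log(nm / n) - 0.5 * np.log(2 * np.pi * var)
        ) - 0.5 * np.sum((xm - xm.mean()) ** 2) / var
    return 2.0 * loglik - (3 * k - 1) * np.log(n)


def select_k_bic(
    values: Sequence[float], k_min: int = 1, k_max: int = 9
) -> ClusterResult:
    """Fit ckmeans_1d for each k in [k_min, k_max] and pick k by BIC.

    k_max is clamped to n.  Ties in BIC go to the smallest k.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("values must be non-empty")
    k_max = min(k_max, x.size)
    k_min = max(1, min(k_min, k_max))

    wcss_by_k: dict[int, float] = {}
    bic_by_k: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in range(k_min, k_max + 1):
        assignments, wcss = ckmeans_1d(x, k)
        wcss_by_k[k] = wcss
        bic_by_k[k] = _bic_gaussian(x, assignments, k)
        fits[k] = assignments

    k_selected = max(sorted(bic_by_k), key=lambda k: (bic_by_k[k], -k))
    assignments = fits[k_selected]
    _, centers = _cluster_stats(x, assignments, k_selected)
    boundaries = tuple(
        (x[assignments == m].max() + x[assignments == m + 1].min()) / 2.0
        for m in range(k_selected - 1)
    )
    return ClusterResult(
        k=k_selected,
        assignments=tuple(int(a) for a in assignments),
        boundaries=boundaries,
        centers=tuple(float(c) for c in centers),
        wcss_by_k=wcss_by_k,
        bic_by_k=bic_by_k,
        k_selected=k_selected,
    )


def assign_subtypes(
    profile: TmbProfile, rule: ThresholdRule = ThresholdRule.MEAN
) -> SubtypeAssignment:
    """Label each sample TMB-H iff its TMB strictly exceeds the threshold.

    The threshold is the cohort mean (default), the median, or the boundary
    of the optimal k=2 partition.
    """
    x = np.asarray(profile.tmb, dtype=float)
    if x.size == 0:
        raise ValueError("profile has no samples")
    if rule is ThresholdRule.MEAN:
        threshold = float(np.mean(x))
    elif rule is ThresholdRule.MEDIAN:
        threshold = float(np.median(x))
    elif rule is ThresholdRule.KMEANS_BOUNDARY:
        if x.size < 2 or np.ptp(x) == 0:
            threshold = float(np.max(x))  # no split possible: everything TMB-L
        else:
            assignments, _ = ckmeans_1d(x, 2)
            threshold = float(
                (x[assignments == 0].max() + x[assignments == 1].min()) / 2.0
            )
    else:  # pragma: no cover
        raise ValueError(f"unknown rule {rule}")
    labels = tuple(Subtype.TMB_H if t > threshold else Subtype.TMB_L for t in x)
    return SubtypeAssignment(
        threshold=threshold,
        rule=rule,
        sample_ids=profile.sample_ids,
        labels=labels,
    )
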