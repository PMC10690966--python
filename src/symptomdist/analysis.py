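"""Within- and between-subgroup distance analysis and the permutation test.

A subgroup is *coherent* when its within-group standardized distances are
low, and two subgroups are *differentiated* when their between-group
distances are high.  Within-group vectors contain one ratio per unordered
pair (n(n-1)/2 dyads); between-group vectors one ratio per cross pair
(n_a * n_b dyads).  Group separation is tested by permutation: the observed
statistic is the median between-group ratio, and each replicate reshuffles
the specifier / non-specifier labels (preserving group sizes) and recomputes
it; the p-value is the plain proportion of replicates at least as extreme as
the observed value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .distances import DistanceSpec, cross_ratios, pairwise_ratios
from .schema import Cohort
from .specifiers import SubgroupPartition

__all__ = [
    "DistanceVector",
    "DistanceSummary",
    "PermutationResult",
    "within_group_distances",
    "between_group_distances",
    "summarize_distances",
    "count_profile_categories",
    "permutation_test",
]

# float guard for comparing medians that are exact multiples of 1/(2 k v)
_TIE_EPS = 1e-12


@dataclass
class DistanceVector:
    """All standardized dyad ratios for one group pair."""

    group_pair: tuple[str, str]
    values: np.ndarray
    spec: DistanceSpec

    @property
    def n_dyads(self) -> int:
        return self.values.size


@dataclass
class DistanceSummary:
    """Boxplot-ready five-number core: median and quartiles (linear
    interpolation convention)."""

    group_pair: tuple[str, str]
    median: float
    q1: float
    q3: float
    n_dyads: int


@dataclass
class PermutationResult:
    observed: float
    permuted: np.ndarray
    p_value: float
    n_permutations: int
    seed: int
    which: str = ""
    group_sizes: tuple[int, int] = (0, 0)


def _member_indices(cohort: Cohort, members: Sequence[str]) -> np.ndarray:
    return np.array([cohort.index_of(m) for m in members], dtype=np.intp)


def within_group_distances(
    cohort: Cohort,
    members: Sequence[str],
    spec: DistanceSpec,
    label: str = "within",
) -> DistanceVector:
    """One standardized ratio per unordered pair of group members."""
    idx = _member_indices(cohort, members)
    if idx.size < 2:
        raise ValueError(f"group {label!r} has {idx.size} member(s); no dyads to compare")
    if cohort.missing[idx].any():
        raise ValueError("distances are undefined with missing values; listwise-delete first")
    values = pairwise_ratios(cohort.values[idx], spec)
    return DistanceVector(group_pair=(label, "within"), values=values, spec=spec)


def between_group_distances(
    cohort: Cohort,
    group_a: Sequence[str],
    group_b: Sequence[str],
    spec: DistanceSpec,
    labels: tuple[str, str] = ("A", "B"),
) -> DistanceVector:
    """One standardized ratio per cross pair of two disjoint groups."""
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap; a between-group comparison needs a partition")
    ia, ib = _member_indices(cohort, group_a), _member_indices(cohort, group_b)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("both groups must be non-empty")
    if cohort.missing[ia].any() or cohort.missing[ib].any():
        raise ValueError("distances are undefined with missing values; listwise-delete first")
    values = cross_ratios(cohort.values[ia], cohort.values[ib], spec).ravel()
    return DistanceVector(group_pair=labels, values=values, spec=spec)


def summarize_distances(dv: DistanceVector) -> DistanceSummary:
    """Median and quartiles of a dyad-distance vector."""
    if dv.n_dyads == 0:
        raise ValueError("cannot summarize an empty distance vector")
    q1, med, q3 = np.percentile(dv.values, [25, 50, 75])
    return DistanceSummary(
        group_pair=dv.group_pair,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        n_dyads=dv.n_dyads,
    )


def count_profile_categories(cohort: Cohort) -> int:
    """Number of distinct symptom vectors — the legacy all-or-nothing
    heterogeneity count that distance ratios refine."""
    if cohort.has_missing:
        raise ValueError("profile categories are undefined with missing values")
    if cohort.n == 0:
        return 0
    return np.unique(cohort.values, axis=0).shape[0]


def _ratio_matrix(cohort: Cohort, idx: np.ndarray, spec: DistanceSpec) -> np.ndarray:
    """Full square ratio matrix for the pooled group (float32 above 2,000
    respondents to bound memory)."""
    vals = cohort.values[idx]
    mat = cross_ratios(vals, vals, spec)
    if idx.size > 2000:
        mat = mat.astype(np.float32)
    return mat


def permutation_test(
    cohort: Cohort,
    partition: SubgroupPartition,
    which: str,
    spec: DistanceSpec,
    n_permutations: int = 100,
    seed: int = 0,
    statistic_mode: str = "full_median",
    plus_one: bool = False,
) -> PermutationResult:
    """Label-shuffling test of between-group separation.

    ``observed`` is the median between-group ratio under the true labels.
    Each replicate shuffles the specifier/non-specifier labels within the
    pooled group (sizes preserved) and recomputes the statistic; ties count
    as "as extreme".  ``statistic_mode='single_dyad'`` replaces the replicate
    statistic with the ratio of one random cross dyad per shuffle — the
    literal narrow reading of label-shuffle-then-one-dyad resampling — and is
    provided for comparison only.  ``plus_one`` applies the (1 + c)/(1 + B)
    smoothed estimator instead of the plain proportion c/B.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    group_a, group_b = partition.split(which)
    if not group_a or not group_b:
        raise ValueError(f"degenerate {which!r} split: sizes {len(group_a)}/{len(group_b)}")
    if cohort.has_missing:
        raise ValueError("distances are undefined with missing values; listwise-delete first")

    ia, ib = _member_indices(cohort, group_a), _member_indices(cohort, group_b)
    pooled = np.concatenate([ia, ib])
    n_a = ia.size
    mat = _ratio_matrix(cohort, pooled, spec)

    def between_median(order: np.ndarray) -> float:
        a, b = order[:n_a], order[n_a:]
        return float(np.median(mat[np.ix_(a, b)]))

    identity = np.arange(pooled.size)
    observed = between_median(identity)

    rng = np.random.default_rng(seed)
    permuted = np.empty(n_permutations, dtype=np.float64)
    for r in range(n_permutations):
        order = rng.permutation(pooled.size)
        if statistic_mode == "full_median":
            permuted[r] = between_median(order)
        elif statistic_mode == "single_dyad":
            i = order[rng.integers(n_a)]
            j = order[n_a + rng.integers(pooled.size - n_a)]
            permuted[r] = float(mat[i, j])
        else:
            raise ValueError(f"unknown statistic_mode {statistic_mode!r}")

    c = int(np.count_nonzero(permuted >= observed - _TIE_EPS))
    p = (1 + c) / (1 + n_permutations) if plus_one else c / n_permutations
    return PermutationResult(
        observed=observed,
        permuted=permuted,
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        which=which,
        group_sizes=(n_a, ib.size),
    )
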