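"""Dyadic distances between symptom profiles and their standardized ratios.

Three metrics are supported.  The Hamming distance D_H counts the binary
items on which two profiles disagree; the Manhattan distance D_M sums the
absolute item-wise severity differences (and equals D_H on binary data); the
Euclidean distance is provided for comparison only.  Distances are made
comparable across instruments by standardizing to [0, 1]:

    R_H = D_H / k          (k = number of items in the analysis schema)
    R_M = D_M / (k * v)    (v = maximum possible item severity)

so a ratio of 1 means the two profiles disagree maximally on every item.
Hamming and Manhattan values are computed in integer arithmetic and are
exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .schema import SchemaMismatchError, SymptomProfile, SymptomSchema

__all__ = [
    "DistanceSpec",
    "hamming_distance",
    "manhattan_distance",
    "euclidean_distance",
    "standardized_ratio",
    "pairwise_ratios",
    "cross_ratios",
]

METRICS = ("hamming", "manhattan", "euclidean")


@dataclass(frozen=True)
class DistanceSpec:
    """Metric plus the normalizing constants of the standardized ratio."""

    metric: str
    k: int
    v: int = 1

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.v < 1:
            raise ValueError("v must be >= 1")
        if self.metric == "hamming" and self.v != 1:
            raise ValueError("hamming distance is defined on binary schemas (v = 1)")

    @classmethod
    def from_schema(cls, schema: SymptomSchema, metric: str) -> "DistanceSpec":
        v = schema.max_severity
        if metric == "hamming" and not schema.is_binary:
            raise SchemaMismatchError("hamming distance needs a binary schema")
        return cls(metric=metric, k=schema.k, v=v)

    @property
    def max_distance(self) -> float:
        if self.metric == "euclidean":
            return float(self.v * np.sqrt(self.k))
        return float(self.k * self.v)


def _pair_arrays(x, y) -> tuple[np.ndarray, np.ndarray]:
    """Validate a dyad (profiles or raw vectors) and return value arrays."""
    if isinstance(x, SymptomProfile) or isinstance(y, SymptomProfile):
        if not (isinstance(x, SymptomProfile) and isinstance(y, SymptomProfile)):
            raise TypeError("compare two profiles or two arrays, not a mix")
        if x.schema.item_ids != y.schema.item_ids:
            raise SchemaMismatchError("profiles are on different schemas")
        if x.has_missing or y.has_missing:
            raise ValueError("distances are undefined on profiles with missing values")
        return x.values, y.values
    xa, ya = np.asarray(x, dtype=np.int64), np.asarray(y, dtype=np.int64)
    if xa.shape != ya.shape:
        raise SchemaMismatchError(f"length mismatch: {xa.shape} vs {ya.shape}")
    return xa, ya


def hamming_distance(x, y) -> int:
    """Number of binary items on which two profiles disagree (D_H)."""
    xa, ya = _pair_arrays(x, y)
    if not (np.isin(xa, (0, 1)).all() and np.isin(ya, (0, 1)).all()):
        raise ValueError("hamming distance needs binary (0/1) profiles")
    return int(np.abs(xa - ya).sum())


def manhattan_distance(x, y) -> int:
    """Sum of absolute item-wise severity differences (D_M)."""
    xa, ya = _pair_arrays(x, y)
    return int(np.abs(xa - ya).sum())


def euclidean_distance(x, y) -> float:
    """sqrt of summed squared item differences; comparison metric only."""
    xa, ya = _pair_arrays(x, y)
    return float(np.sqrt(((xa - ya) ** 2).sum()))


def standardized_ratio(d: Union[int, float], spec: DistanceSpec) -> float:
    """Distance scaled to [0, 1] by the maximal attainable distance."""
    if d < 0:
        raise ValueError("distance cannot be negative")
    if d > spec.max_distance + 1e-9:
        raise ValueError(
            f"distance {d} exceeds the maximum {spec.max_distance} for "
            f"{spec.metric} with k={spec.k}, v={spec.v}; schema/metric mix-up?"
        )
    return float(d) / spec.max_distance


def _check_matrix(values: np.ndarray, spec: DistanceSpec) -> np.ndarray:
    a = np.asarray(values, dtype=np.int64)
    if a.ndim != 2 or a.shape[1] != spec.k:
        raise SchemaMismatchError(f"expected (n, {spec.k}) value matrix, got {a.shape}")
    if spec.metric == "hamming" and not np.isin(a, (0, 1)).all():
        raise ValueError("hamming distance needs binary (0/1) values")
    if a.min(initial=0) < 0 or a.max(initial=0) > spec.v:
        raise ValueError(f"values outside [0, {spec.v}] for v={spec.v}")
    return a


def pairwise_ratios(values: np.ndarray, spec: DistanceSpec) -> np.ndarray:
    """Standardized ratios for all unordered pairs of rows (condensed form,
    scipy ``pdist`` ordering)."""
    a = _check_matrix(values, spec)
    scipy_metric = "euclidean" if spec.metric == "euclidean" else "cityblock"
    return pdist(a, metric=scipy_metric) / spec.max_distance


def cross_ratios(
    values_a: np.ndarray,
    values_b: np.ndarray,
    spec: DistanceSpec,
    block_size: int = 4096,
) -> np.ndarray:
    """Standardized ratios for every cross pair, as an (n_a, n_b) matrix.

    Rows of ``values_a`` are processed in blocks so very large group pairs
    never materialize intermediate buffers beyond one block.
    """
    a = _check_matrix(values_a, spec)
    b = _check_matrix(values_b, spec)
    scipy_metric = "euclidean" if spec.metric == "euclidean" else "cityblock"
    out = np.empty((a.shape[0], b.shape[0]), dtype=np.float64)
    for start in range(0, a.shape[0], block_size):
        stop = min(start + block_size, a.shape[0])
        out[start:stop] = cdist(a[start:stop], b, metric=scipy_metric)
    out /= spec.max_distance
    return out
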