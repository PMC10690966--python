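"""Symptom instrument schemas, respondent profiles and cohort containers.

A schema describes the items of a symptom inventory (binary present/absent
items, as in lay-administered diagnostic interviews, or ordinal 0..v severity
items, as in self-report questionnaires), together with each item's mapping
to one of the nine DSM major-depressive-episode criteria and, optionally, to
a specifier feature (melancholic or atypical).  A cohort holds one value
vector per respondent, aligned to schema order, with an explicit missingness
mask so that cleaning steps such as listwise deletion stay auditable.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
import yaml

__all__ = [
    "SymptomItem",
    "SymptomSchema",
    "SymptomProfile",
    "Cohort",
    "SchemaMismatchError",
    "load_schema",
    "bundled_schema",
    "bundled_config_path",
]

BINARY = "binary"
ORDINAL = "ordinal"
_SCALES = (BINARY, ORDINAL)
_SPECIFIER_FEATURES = ("melancholic", "atypical")


class SchemaMismatchError(ValueError):
    """Raised when data, rule or operation references items a schema lacks."""


@dataclass(frozen=True)
class SymptomItem:
    """One inventory item.

    ``max_value`` is the top of the item's response scale: 1 for binary
    items, v for ordinal severity items.  ``dsm_criterion`` (1-9) says which
    MDE criterion an endorsed item can satisfy; several items may map to the
    same criterion (e.g. insomnia and hypersomnia both satisfy the sleep
    criterion).  ``specifier_feature`` tags items that also belong to the
    melancholic or atypical specifier definitions.
    """

    item_id: str
    label: str = ""
    scale: str = BINARY
    min_value: int = 0
    max_value: int = 1
    dsm_criterion: Optional[int] = None
    specifier_feature: Optional[str] = None

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r} for item {self.item_id!r}")
        if self.max_value < self.min_value:
            raise ValueError(f"item {self.item_id!r}: max_value < min_value")
        if self.scale == BINARY and (self.min_value, self.max_value) != (0, 1):
            raise ValueError(f"binary item {self.item_id!r} must have range [0, 1]")
        if self.dsm_criterion is not None and not 1 <= self.dsm_criterion <= 9:
            raise ValueError(f"item {self.item_id!r}: dsm_criterion must be in 1..9")
        if self.specifier_feature is not None and self.specifier_feature not in _SPECIFIER_FEATURES:
            raise ValueError(
                f"item {self.item_id!r}: unknown specifier_feature {self.specifier_feature!r}"
            )


@dataclass(frozen=True)
class SymptomSchema:
    """An ordered item universe; ``k`` (the symptom-space size) is its length."""

    name: str
    items: tuple[SymptomItem, ...]

    def __post_init__(self) -> None:
        if len(self.items) == 0:
            raise ValueError("schema needs at least one item")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item_ids in schema {self.name!r}: {dupes}")

    @property
    def k(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def index(self, item_id: str) -> int:
        for i, it in enumerate(self.items):
            if it.item_id == item_id:
                return i
        raise SchemaMismatchError(f"schema {self.name!r} has no item {item_id!r}")

    def __contains__(self, item_id: str) -> bool:
        return any(it.item_id == item_id for it in self.items)

    def item(self, item_id: str) -> SymptomItem:
        return self.items[self.index(item_id)]

    @property
    def is_binary(self) -> bool:
        return all(it.scale == BINARY for it in self.items)

    @property
    def max_severity(self) -> int:
        """Uniform maximum item score v; raises on mixed-scale schemas."""
        maxima = {it.max_value for it in self.items}
        if len(maxima) != 1:
            raise SchemaMismatchError(
                f"schema {self.name!r} mixes item scales {sorted(maxima)}; "
                "severity-normalised ratios need a single maximum"
            )
        return maxima.pop()

    @property
    def min_values(self) -> np.ndarray:
        return np.array([it.min_value for it in self.items], dtype=np.int64)

    @property
    def max_values(self) -> np.ndarray:
        return np.array([it.max_value for it in self.items], dtype=np.int64)

    def subschema(self, item_ids: Sequence[str], name: Optional[str] = None) -> "SymptomSchema":
        items = tuple(self.item(i) for i in item_ids)
        return SymptomSchema(name or f"{self.name}_subset", items)

    def criterion_map(self) -> dict[int, list[str]]:
        """Items grouped by the DSM criterion (1-9) they can satisfy."""
        out: dict[int, list[str]] = {}
        for it in self.items:
            if it.dsm_criterion is not None:
                out.setdefault(it.dsm_criterion, []).append(it.item_id)
        return out

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "items": [
                {
                    "item_id": it.item_id,
                    "label": it.label,
                    "scale": it.scale,
                    "min_value": it.min_value,
                    "max_value": it.max_value,
                    "dsm_criterion": it.dsm_criterion,
                    "specifier_feature": it.specifier_feature,
                }
                for it in self.items
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SymptomSchema":
        items = tuple(
            SymptomItem(
                item_id=raw["item_id"],
                label=raw.get("label", ""),
                scale=raw.get("scale", BINARY),
                min_value=int(raw.get("min_value", 0)),
                max_value=int(raw.get("max_value", 1)),
                dsm_criterion=raw.get("dsm_criterion"),
                specifier_feature=raw.get("specifier_feature"),
            )
            for raw in d["items"]
        )
        return cls(name=d["name"], items=items)


@dataclass
class SymptomProfile:
    """One respondent's item-value vector, aligned to a schema."""

    respondent_id: str
    values: np.ndarray
    schema: SymptomSchema
    missing_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.shape != (self.schema.k,):
            raise SchemaMismatchError(
                f"profile {self.respondent_id!r}: {self.values.size} values "
                f"for a {self.schema.k}-item schema"
            )
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.schema.k, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        ok = self.missing_mask | (
            (self.values >= self.schema.min_values) & (self.values <= self.schema.max_values)
        )
        if not ok.all():
            bad = self.schema.item_ids[int(np.argmin(ok))]
            raise ValueError(f"profile {self.respondent_id!r}: value out of range at {bad!r}")

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def value(self, item_id: str) -> int:
        return int(self.values[self.schema.index(item_id)])


class Cohort:
    """Respondent profiles sharing one schema, stored as an n x k matrix."""

    def __init__(
        self,
        schema: SymptomSchema,
        values: np.ndarray,
        respondent_ids: Sequence[str],
        missing: Optional[np.ndarray] = None,
    ) -> None:
        self.schema = schema
        self.values = np.asarray(values, dtype=np.int64)
        if self.values.ndim != 2 or self.values.shape[1] != schema.k:
            raise SchemaMismatchError(
                f"cohort values must be (n, {schema.k}), got {self.values.shape}"
            )
        self.respondent_ids = [str(r) for r in respondent_ids]
        if len(self.respondent_ids) != self.values.shape[0]:
            raise ValueError("respondent_ids length does not match value rows")
        if len(set(self.respondent_ids)) != len(self.respondent_ids):
            raise ValueError("respondent_ids must be unique")
        if missing is None:
            missing = np.zeros_like(self.values, dtype=bool)
        self.missing = np.asarray(missing, dtype=bool)
        if self.missing.shape != self.values.shape:
            raise ValueError("missing mask shape does not match values")
        obs = ~self.missing
        lo, hi = schema.min_values, schema.max_values
        if not ((self.values >= lo) | self.missing).all() or not (
            (self.values <= hi) | self.missing
        ).all():
            raise ValueError("observed values outside item scale bounds")
        del obs

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __len__(self) -> int:
        return self.n

    @property
    def has_missing(self) -> bool:
        return bool(self.missing.any())

    def profile(self, i: int) -> SymptomProfile:
        return SymptomProfile(
            respondent_id=self.respondent_ids[i],
            values=self.values[i],
            schema=self.schema,
            missing_mask=self.missing[i],
        )

    def __iter__(self) -> Iterator[SymptomProfile]:
        return (self.profile(i) for i in range(self.n))

    def index_of(self, respondent_id: str) -> int:
        try:
            return self.respondent_ids.index(respondent_id)
        except ValueError:
            raise KeyError(f"no respondent {respondent_id!r} in cohort") from None

    def subset(self, row_idx: Iterable[int]) -> "Cohort":
        idx = np.asarray(list(row_idx), dtype=np.intp)
        return Cohort(
            self.schema,
            self.values[idx],
            [self.respondent_ids[i] for i in idx],
            self.missing[idx],
        )

    def with_schema(self, schema: SymptomSchema, values: np.ndarray, missing=None) -> "Cohort":
        return Cohort(schema, values, self.respondent_ids, missing)


def load_schema(path: Union[str, Path]) -> SymptomSchema:
    """Read a schema from a YAML config file."""
    with open(path) as fh:
        return SymptomSchema.from_dict(yaml.safe_load(fh))


def save_schema(schema: SymptomSchema, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(schema.to_dict(), fh, sort_keys=False)


def bundled_config_path(name: str) -> Path:
    """Path of a config file shipped with the package (``data/<name>.yaml``)."""
    res = importlib.resources.files("symptomdist").joinpath("data", f"{name}.yaml")
    p = Path(str(res))
    if not p.exists():
        raise FileNotFoundError(f"no bundled config {name!r}")
    return p


def bundled_schema(name: str) -> SymptomSchema:
    """Load a schema shipped with the package, e.g. ``audadis_raw`` or ``ids_core``."""
    return load_schema(bundled_config_path(name))
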