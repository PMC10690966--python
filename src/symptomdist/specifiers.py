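"""Melancholic / atypical specifier classification with the DSM hierarchy.

A specifier rule is an m-of-n feature count plus optional required features.
Each *feature* is an OR-set of item ids: a feature with several items
(e.g. psychomotor retardation or agitation) counts once no matter how many
of its items are endorsed.  The DSM hierarchical rule is applied by
:func:`apply_hierarchy`: melancholia is evaluated first, and only
non-melancholic respondents are then assessed for atypical features, so the
resulting labels (melancholic / atypical / neither) partition the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .schema import (
    Cohort,
    SchemaMismatchError,
    SymptomProfile,
    SymptomSchema,
    bundled_config_path,
)

__all__ = [
    "SpecifierRule",
    "SubgroupPartition",
    "load_rules",
    "bundled_rules",
    "classify_melancholic_nesarc",
    "classify_atypical_nesarc",
    "apply_hierarchy",
]

LABELS = ("melancholic", "atypical", "neither")


@dataclass(frozen=True)
class SpecifierRule:
    """m-of-n feature rule: present iff all required features are present and
    at least ``min_features`` of ``feature_items`` are present."""

    name: str
    feature_items: tuple[tuple[str, ...], ...] = ()
    min_features: int = 0
    required_features: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        if self.min_features > len(self.feature_items):
            raise ValueError(
                f"rule {self.name!r}: min_features {self.min_features} exceeds "
                f"the {len(self.feature_items)} features defined"
            )
        if self.min_features == 0 and not self.required_features:
            raise ValueError(f"rule {self.name!r} can never discriminate: no conditions")

    def validate_against(self, schema: SymptomSchema) -> None:
        for feature in self.feature_items + self.required_features:
            for item_id in feature:
                if item_id not in schema:
                    raise SchemaMismatchError(
                        f"rule {self.name!r} references item {item_id!r}, "
                        f"absent from schema {schema.name!r}"
                    )

    def _feature_present(self, profile: SymptomProfile, feature: Sequence[str]) -> bool:
        idx = [profile.schema.index(i) for i in feature]
        if profile.missing_mask[idx].any():
            raise ValueError(
                f"rule {self.name!r}: missing value among items {list(feature)} "
                f"for respondent {profile.respondent_id!r}"
            )
        return bool((profile.values[idx] == 1).any())

    def is_met(self, profile: SymptomProfile) -> bool:
        if not profile.schema.is_binary:
            raise SchemaMismatchError(
                f"rule {self.name!r} needs a binary (or dichotomized) profile"
            )
        self.validate_against(profile.schema)
        for feature in self.required_features:
            if not self._feature_present(profile, feature):
                return False
        n_present = sum(self._feature_present(profile, f) for f in self.feature_items)
        return n_present >= self.min_features

    def met_vector(self, cohort: Cohort) -> np.ndarray:
        """Vectorized :meth:`is_met` over a cohort."""
        if not cohort.schema.is_binary:
            raise SchemaMismatchError(f"rule {self.name!r} needs a binary cohort")
        self.validate_against(cohort.schema)

        def feat(feature: Sequence[str]) -> np.ndarray:
            idx = [cohort.schema.index(i) for i in feature]
            if cohort.missing[:, idx].any():
                raise ValueError(
                    f"rule {self.name!r}: missing values among items {list(feature)}"
                )
            return (cohort.values[:, idx] == 1).any(axis=1)

        ok = np.ones(cohort.n, dtype=bool)
        for feature in self.required_features:
            ok &= feat(feature)
        if self.feature_items:
            count = np.zeros(cohort.n, dtype=np.int64)
            for feature in self.feature_items:
                count += feat(feature)
            ok &= count >= self.min_features
        return ok


def _rule_from_dict(name: str, d: dict) -> SpecifierRule:
    return SpecifierRule(
        name=name,
        feature_items=tuple(tuple(f) for f in d.get("feature_items", [])),
        min_features=int(d.get("min_features", 0)),
        required_features=tuple(tuple(f) for f in d.get("required_features", [])),
    )


def load_rules(path: Union[str, Path]) -> dict[str, SpecifierRule]:
    """Load a ``rules:`` config file mapping rule names to definitions."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {name: _rule_from_dict(name, d) for name, d in raw["rules"].items()}


def bundled_rules(name: str) -> dict[str, SpecifierRule]:
    """Bundled rule sets: ``rules_nesarc`` or ``rules_dsm5_ids``."""
    return load_rules(bundled_config_path(name))


def classify_melancholic_nesarc(
    profile: SymptomProfile, rule: Optional[SpecifierRule] = None
) -> bool:
    """Proxy melancholic classification on a binary interview profile
    (at least three of five features)."""
    rule = rule or bundled_rules("rules_nesarc")["melancholic"]
    return rule.is_met(profile)


def classify_atypical_nesarc(
    profile: SymptomProfile, rule: Optional[SpecifierRule] = None
) -> bool:
    """Proxy atypical classification: hypersomnia and hyperphagia both present."""
    rule = rule or bundled_rules("rules_nesarc")["atypical"]
    return rule.is_met(profile)


@dataclass
class SubgroupPartition:
    """Mutually exclusive, exhaustive specifier labels per respondent."""

    respondent_ids: list[str]
    labels: np.ndarray  # array of strings from LABELS

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.respondent_ids) != self.labels.size:
            raise ValueError("labels and respondent_ids length mismatch")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}; expected {LABELS}")

    @property
    def n(self) -> int:
        return self.labels.size

    def ids(self, label: str) -> list[str]:
        return [r for r, l in zip(self.respondent_ids, self.labels) if l == label]

    @property
    def counts(self) -> dict[str, int]:
        return {lab: int((self.labels == lab).sum()) for lab in LABELS}

    def split(self, which: str) -> tuple[list[str], list[str]]:
        """Specifier vs non-specifier id sets for one analysis.

        ``melancholic`` splits the whole cohort; ``atypical`` splits only the
        non-melancholic respondents (hierarchy), so atypical + non-atypical
        counts sum to the non-melancholic count.
        """
        if which == "melancholic":
            spec = self.ids("melancholic")
            non = self.ids("atypical") + self.ids("neither")
        elif which == "atypical":
            spec = self.ids("atypical")
            non = self.ids("neither")
        else:
            raise ValueError(f"unknown specifier {which!r}")
        return spec, non


def apply_hierarchy(
    cohort: Cohort,
    mel_rule: Optional[SpecifierRule] = None,
    aty_rule: Optional[SpecifierRule] = None,
) -> SubgroupPartition:
    """Label every respondent melancholic, atypical or neither.

    Melancholia is evaluated first; respondents meeting the melancholic rule
    cannot also be labeled atypical, however their atypical features read.
    """
    rules = None
    if mel_rule is None or aty_rule is None:
        rules = bundled_rules("rules_nesarc")
    mel_rule = mel_rule or rules["melancholic"]
    aty_rule = aty_rule or rules["atypical"]
    labels = np.array(["neither"] * cohort.n, dtype=object)
    if cohort.n:
        mel = mel_rule.met_vector(cohort)
        aty = aty_rule.met_vector(cohort) & ~mel
        labels[mel] = "melancholic"
        labels[aty] = "atypical"
    return SubgroupPartition(list(cohort.respondent_ids), labels)
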