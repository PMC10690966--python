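"""Cohort cleaning: listwise deletion, item aggregation, dichotomization
and the five-of-nine MDE screen.

The aggregation steps mirror how overlapping interview questions are
collapsed before heterogeneity analysis so that near-duplicate items do not
inflate apparent dissimilarity: the four appetite/weight questions become
two direction-specific items, the three suicidal-thought gradations become a
single suicidal-thoughts item (keeping the attempt separate), and subjective
restlessness — which does not count toward psychomotor agitation — is
dropped.  Applied to the 21-item raw interview schema this yields the
16-item analysis schema.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Union

import numpy as np

from .schema import (
    BINARY,
    Cohort,
    SchemaMismatchError,
    SymptomItem,
    SymptomProfile,
    SymptomSchema,
)

__all__ = [
    "listwise_delete",
    "aggregate_appetite_weight",
    "aggregate_suicidality",
    "drop_restlessness",
    "nesarc_cleaning_chain",
    "dichotomize",
    "dichotomize_cohort",
    "screen_mde",
    "screen_cohort_mde",
]


def listwise_delete(cohort: Cohort) -> Cohort:
    """Keep only respondents with zero missing items (input unchanged)."""
    keep = np.flatnonzero(~cohort.missing.any(axis=1))
    if keep.size == 0:
        warnings.warn("listwise deletion removed every respondent", stacklevel=2)
    return cohort.subset(keep)


def _or_combine(cohort: Cohort, source_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """OR binary source columns: present if any present, missing only if no
    constituent is present and at least one is missing."""
    idx = [cohort.schema.index(i) for i in source_ids]
    vals = cohort.values[:, idx]
    miss = cohort.missing[:, idx]
    present = ((vals == 1) & ~miss).any(axis=1)
    missing = ~present & miss.any(axis=1)
    return present.astype(np.int64), missing


def _replace_items(
    cohort: Cohort,
    replacements: dict[str, tuple[SymptomItem, Sequence[str]]],
    schema_name: str,
) -> Cohort:
    """Rebuild the schema, replacing the anchor item of each group by a
    combined item and dropping the other constituents in place."""
    consumed = {sid for _, sources in replacements.values() for sid in sources}
    for sid in consumed:
        if sid not in cohort.schema:
            raise SchemaMismatchError(f"aggregation needs item {sid!r}, absent from schema")
    new_items: list[SymptomItem] = []
    new_cols: list[np.ndarray] = []
    new_miss: list[np.ndarray] = []
    for item in cohort.schema.items:
        if item.item_id in replacements:
            combined, sources = replacements[item.item_id]
            vals, miss = _or_combine(cohort, sources)
            new_items.append(combined)
            new_cols.append(vals)
            new_miss.append(miss)
        elif item.item_id in consumed:
            continue
        else:
            j = cohort.schema.index(item.item_id)
            new_items.append(item)
            new_cols.append(cohort.values[:, j])
            new_miss.append(cohort.missing[:, j])
    schema = SymptomSchema(schema_name, tuple(new_items))
    return Cohort(
        schema,
        np.column_stack(new_cols),
        cohort.respondent_ids,
        np.column_stack(new_miss),
    )


def aggregate_appetite_weight(cohort: Cohort) -> Cohort:
    """Collapse the four appetite/weight questions into two items.

    ``appetite_weight_decrease`` is present iff reduced appetite or reduced
    weight (or both) is present; likewise for the increase item.  k drops
    by 2.
    """
    dec = SymptomItem(
        "appetite_weight_decrease",
        "Decreased appetite or weight",
        BINARY,
        dsm_criterion=3,
        specifier_feature="melancholic",
    )
    inc = SymptomItem(
        "appetite_weight_increase",
        "Increased appetite or weight",
        BINARY,
        dsm_criterion=3,
        specifier_feature="atypical",
    )
    return _replace_items(
        cohort,
        {
            "reduced_appetite": (dec, ["reduced_appetite", "reduced_weight"]),
            "increased_appetite": (inc, ["increased_appetite", "increased_weight"]),
        },
        cohort.schema.name + "+appwt",
    )


def aggregate_suicidality(cohort: Cohort) -> Cohort:
    """Collapse death ideation, desire to die and suicidal ideation into one
    suicidal-thoughts item; the attempt item stays separate.  k drops by 2."""
    thoughts = SymptomItem(
        "suicidal_thoughts",
        "Thoughts of death or suicide",
        BINARY,
        dsm_criterion=9,
    )
    return _replace_items(
        cohort,
        {
            "death_ideation": (
                thoughts,
                ["death_ideation", "desire_to_die", "suicidal_ideation"],
            )
        },
        cohort.schema.name + "+suic",
    )


def drop_restlessness(cohort: Cohort, item_id: str = "restlessness") -> Cohort:
    """Remove the subjective-restlessness item (no-op with a warning if absent)."""
    if item_id not in cohort.schema:
        warnings.warn(f"schema has no item {item_id!r}; nothing dropped", stacklevel=2)
        return cohort
    keep = [i for i in cohort.schema.item_ids if i != item_id]
    idx = [cohort.schema.index(i) for i in keep]
    schema = SymptomSchema(
        cohort.schema.name + "-restl",
        tuple(cohort.schema.items[j] for j in idx),
    )
    return Cohort(schema, cohort.values[:, idx], cohort.respondent_ids, cohort.missing[:, idx])


def nesarc_cleaning_chain(cohort: Cohort, schema_name: str = "audadis_mde_16") -> Cohort:
    """Full raw-interview cleaning chain (aggregate, drop restlessness).

    On the bundled 21-item raw schema this yields the 16-item analysis
    schema.  Listwise deletion is not part of the chain; call it explicitly
    before or after.
    """
    out = drop_restlessness(aggregate_suicidality(aggregate_appetite_weight(cohort)))
    schema = SymptomSchema(schema_name, out.schema.items)
    return Cohort(schema, out.values, out.respondent_ids, out.missing)


def _binary_twin(schema: SymptomSchema) -> SymptomSchema:
    items = tuple(
        SymptomItem(
            it.item_id,
            it.label,
            BINARY,
            dsm_criterion=it.dsm_criterion,
            specifier_feature=it.specifier_feature,
        )
        for it in schema.items
    )
    return SymptomSchema(schema.name + "_bin", items)


def dichotomize(profile: SymptomProfile, threshold: int) -> SymptomProfile:
    """Binary twin of an ordinal profile: item present iff value >= threshold.

    ``threshold`` must lie in [1, max_value]; threshold 1 is plain
    any-endorsement binarization.
    """
    v = profile.schema.max_severity
    if not 1 <= threshold <= v:
        raise ValueError(f"threshold {threshold} outside [1, {v}]")
    return SymptomProfile(
        profile.respondent_id,
        (profile.values >= threshold).astype(np.int64),
        _binary_twin(profile.schema),
        profile.missing_mask,
    )


def dichotomize_cohort(cohort: Cohort, threshold: int) -> Cohort:
    """Vectorized :func:`dichotomize` over a whole cohort."""
    v = cohort.schema.max_severity
    if not 1 <= threshold <= v:
        raise ValueError(f"threshold {threshold} outside [1, {v}]")
    return Cohort(
        _binary_twin(cohort.schema),
        (cohort.values >= threshold).astype(np.int64),
        cohort.respondent_ids,
        cohort.missing,
    )


def _criterion_matrix(schema: SymptomSchema) -> np.ndarray:
    """(9, k) boolean map from DSM criterion to schema items."""
    cmap = schema.criterion_map()
    if not cmap:
        raise SchemaMismatchError(f"schema {schema.name!r} maps no items to DSM criteria")
    for c in (1, 2):
        if c not in cmap:
            raise SchemaMismatchError(
                f"schema {schema.name!r} maps no item to core criterion {c} "
                "(sad mood / anhedonia); MDE screening needs both"
            )
    m = np.zeros((9, schema.k), dtype=bool)
    for crit, ids in cmap.items():
        for i in ids:
            m[crit - 1, schema.index(i)] = True
    return m


def screen_mde(profile: SymptomProfile) -> bool:
    """Five-of-nine MDE symptom screen on a binary profile.

    A criterion is met if any item mapped to it is present (insomnia OR
    hypersomnia meets the sleep criterion); the screen passes iff at least
    five criteria are met and at least one of them is sad mood or anhedonia.
    """
    if not profile.schema.is_binary:
        raise SchemaMismatchError("MDE screen needs a binary (or dichotomized) profile")
    m = _criterion_matrix(profile.schema)
    met = (m & (profile.values == 1)).any(axis=1)
    return bool(met.sum() >= 5 and (met[0] or met[1]))


def screen_cohort_mde(cohort: Cohort, keep: bool = True) -> Union[Cohort, np.ndarray]:
    """Apply :func:`screen_mde` to every respondent.

    With ``keep=True`` returns the screened-in sub-cohort; otherwise returns
    the boolean pass vector.
    """
    if not cohort.schema.is_binary:
        raise SchemaMismatchError("MDE screen needs a binary (or dichotomized) cohort")
    m = _criterion_matrix(cohort.schema)
    met = (cohort.values[:, None, :] == 1) & m[None, :, :]
    crit_met = met.any(axis=2)
    passed = (crit_met.sum(axis=1) >= 5) & (crit_met[:, 0] | crit_met[:, 1])
    if keep:
        return cohort.subset(np.flatnonzero(passed))
    return passed
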