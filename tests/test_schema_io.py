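"""Schema containers, cohort file I/O dialects and cleaning operations."""

import numpy as np
import pytest

from symptomdist import (
    Cohort,
    SchemaMismatchError,
    SymptomItem,
    SymptomProfile,
    SymptomSchema,
    aggregate_appetite_weight,
    aggregate_suicidality,
    dichotomize,
    dichotomize_cohort,
    drop_restlessness,
    listwise_delete,
    nesarc_cleaning_chain,
    read_cohort,
    screen_mde,
    write_cohort,
)
from symptomdist.io import CohortParseError
from symptomdist.schema import load_schema, save_schema

from conftest import make_binary_cohort, raw_profile_row


# ---------------------------------------------------------------- containers

def test_schema_rejects_duplicate_item_ids():
    items = (SymptomItem("a"), SymptomItem("a"))
    with pytest.raises(ValueError, match="duplicate"):
        SymptomSchema("dup", items)


def test_profile_value_bounds_enforced(mde16_schema):
    values = np.zeros(mde16_schema.k, dtype=int)
    values[0] = 2  # binary item
    with pytest.raises(ValueError, match="out of range"):
        SymptomProfile("p1", values, mde16_schema)


def test_cohort_requires_unique_ids(mde16_schema):
    values = np.zeros((2, mde16_schema.k), dtype=int)
    with pytest.raises(ValueError, match="unique"):
        Cohort(mde16_schema, values, ["r1", "r1"])


def test_schema_yaml_roundtrip(tmp_path, mde16_schema):
    path = tmp_path / "schema.yaml"
    save_schema(mde16_schema, path)
    again = load_schema(path)
    assert again == mde16_schema


# ----------------------------------------------------------------- file I/O

def _write_table(path, header, rows, sep=","):
    path.write_text("\n".join([sep.join(header)] + [sep.join(r) for r in rows]) + "\n")


def test_audadis_dialect_recode(tmp_path, raw_schema):
    header = ["respondent_id"] + raw_schema.item_ids
    row_present = ["p1"] + ["1"] * raw_schema.k
    row_absent = ["p2"] + ["2"] * raw_schema.k
    row_unknown = ["p3"] + ["9"] + ["2"] * (raw_schema.k - 1)
    path = tmp_path / "c.csv"
    _write_table(path, header, [row_present, row_absent, row_unknown])
    cohort = read_cohort(path, raw_schema, dialect="audadis_one_two")
    assert cohort.n == 3
    assert cohort.values[0].tolist() == [1] * raw_schema.k
    assert cohort.values[1].tolist() == [0] * raw_schema.k
    assert cohort.missing[2, 0] and not cohort.missing[2, 1:].any()


def test_missing_column_names_the_column(tmp_path, raw_schema):
    header = ["respondent_id"] + raw_schema.item_ids[:-1]
    _write_table(tmp_path / "c.csv", header, [["p1"] + ["1"] * (raw_schema.k - 1)])
    with pytest.raises(SchemaMismatchError, match="suicide_attempt"):
        read_cohort(tmp_path / "c.csv", raw_schema, dialect="audadis_one_two")


def test_zero_one_parse_error_is_located(tmp_path, mde16_schema):
    header = ["respondent_id"] + mde16_schema.item_ids
    good = ["p1"] + ["0"] * mde16_schema.k
    bad = ["p2"] + ["x"] + ["0"] * (mde16_schema.k - 1)
    _write_table(tmp_path / "c.csv", header, [good, bad])
    with pytest.raises(CohortParseError, match="row 1.*'sad_mood'"):
        read_cohort(tmp_path / "c.csv", mde16_schema)


def test_roundtrip_bit_exact(tmp_path, mde16_schema, rng):
    values = (rng.random((20, mde16_schema.k)) < 0.4).astype(np.int64)
    missing = rng.random((20, mde16_schema.k)) < 0.1
    cohort = Cohort(mde16_schema, values, [f"p{i}" for i in range(20)], missing)
    for sep in (",", "\t"):
        path = tmp_path / f"c{len(sep)}.csv"
        write_cohort(cohort, path, sep=sep)
        again = read_cohort(path, mde16_schema)
        assert np.array_equal(again.missing, cohort.missing)
        obs = ~cohort.missing
        assert np.array_equal(again.values[obs], cohort.values[obs])
        assert again.respondent_ids == cohort.respondent_ids


# ------------------------------------------------------------------ cleaning

def test_listwise_delete_counts(mde16_schema, rng):
    values = np.zeros((10, mde16_schema.k), dtype=int)
    missing = np.zeros_like(values, dtype=bool)
    missing[3, 5] = missing[7, 0] = True
    cohort = Cohort(mde16_schema, values, [f"p{i}" for i in range(10)], missing)
    kept = listwise_delete(cohort)
    assert kept.n == 8
    assert not kept.has_missing
    assert cohort.n == 10  # input unchanged
    assert listwise_delete(kept).respondent_ids == kept.respondent_ids


def test_listwise_delete_all_removed_warns(mde16_schema):
    cohort = Cohort(
        mde16_schema,
        np.zeros((2, mde16_schema.k), dtype=int),
        ["a", "b"],
        np.ones((2, mde16_schema.k), dtype=bool),
    )
    with pytest.warns(UserWarning, match="every respondent"):
        assert listwise_delete(cohort).n == 0


def test_listwise_retention_matches_missingness_rate(mde16_schema):
    # cohort flow of a large epidemiological sample: 6,448 candidate cases,
    # 5,749 complete ones => per-row completeness 89.16%; simulate that
    # missingness process and check the Monte-Carlo retention
    n, target = 6448, 5749 / 6448
    g = np.random.default_rng(42)
    row_incomplete = g.random(n) >= target
    missing = np.zeros((n, mde16_schema.k), dtype=bool)
    missing[row_incomplete, 0] = True
    cohort = Cohort(mde16_schema, np.zeros((n, 16), dtype=int),
                    [str(i) for i in range(n)], missing)
    retained = listwise_delete(cohort).n / n
    se = np.sqrt(target * (1 - target) / n)
    assert abs(retained - target) < 3 * se


def _raw_cohort(raw_schema, present_sets):
    values = np.vstack([raw_profile_row(raw_schema, s) for s in present_sets])
    return Cohort(raw_schema, values, [f"p{i}" for i in range(len(present_sets))])


def test_appetite_weight_aggregation(raw_schema):
    cohort = _raw_cohort(raw_schema, [
        {"reduced_appetite"},                         # decrease via one item
        set(),                                        # nothing
        {"increased_appetite", "increased_weight"},   # OR does not double count
    ])
    agg = aggregate_appetite_weight(cohort)
    assert agg.schema.k == raw_schema.k - 2
    dec = agg.schema.index("appetite_weight_decrease")
    inc = agg.schema.index("appetite_weight_increase")
    assert agg.values[0, dec] == 1 and agg.values[0, inc] == 0
    assert agg.values[1, dec] == 0 and agg.values[1, inc] == 0
    assert agg.values[2, inc] == 1 and agg.values[2, dec] == 0


def test_suicidality_aggregation(raw_schema):
    cohort = _raw_cohort(raw_schema, [
        {"desire_to_die"},
        {"suicide_attempt"},
        {"death_ideation", "desire_to_die", "suicidal_ideation", "suicide_attempt"},
    ])
    agg = aggregate_suicidality(cohort)
    assert agg.schema.k == raw_schema.k - 2
    th = agg.schema.index("suicidal_thoughts")
    at = agg.schema.index("suicide_attempt")
    assert agg.values[0, th] == 1 and agg.values[0, at] == 0
    assert agg.values[1, th] == 0 and agg.values[1, at] == 1
    assert agg.values[2, th] == 1 and agg.values[2, at] == 1


def test_drop_restlessness_is_projection(raw_schema, rng):
    values = (rng.random((5, raw_schema.k)) < 0.5).astype(np.int64)
    cohort = Cohort(raw_schema, values, [f"p{i}" for i in range(5)])
    out = drop_restlessness(cohort)
    assert out.schema.k == raw_schema.k - 1
    keep = [i for i in raw_schema.item_ids if i != "restlessness"]
    for item in keep:
        a = out.values[:, out.schema.index(item)]
        b = cohort.values[:, raw_schema.index(item)]
        assert np.array_equal(a, b)
    with pytest.warns(UserWarning, match="nothing dropped"):
        twice = drop_restlessness(out)
    assert twice.schema.item_ids == out.schema.item_ids


def test_cleaning_chain_yields_16_item_schema(raw_schema, mde16_schema, rng):
    values = (rng.random((30, raw_schema.k)) < 0.5).astype(np.int64)
    cohort = Cohort(raw_schema, values, [f"p{i}" for i in range(30)])
    cleaned = nesarc_cleaning_chain(cohort)
    assert cleaned.schema.item_ids == mde16_schema.item_ids
    assert cleaned.schema.k == 16
    # aggregations commute
    other = aggregate_appetite_weight(aggregate_suicidality(cohort))
    assert np.array_equal(drop_restlessness(other).values, cleaned.values)


def test_aggregation_missing_item_errors(mde16_schema):
    cohort = Cohort(mde16_schema, np.zeros((1, 16), dtype=int), ["p0"])
    with pytest.raises(SchemaMismatchError):
        aggregate_appetite_weight(cohort)


def test_aggregation_missingness_propagation(raw_schema):
    # a present constituent decides the combined item even if another is
    # missing; all-absent with a missing constituent stays missing
    values = np.zeros((2, raw_schema.k), dtype=int)
    missing = np.zeros_like(values, dtype=bool)
    ra, rw = raw_schema.index("reduced_appetite"), raw_schema.index("reduced_weight")
    values[0, ra] = 1
    missing[0, rw] = True
    missing[1, ra] = True
    cohort = Cohort(raw_schema, values, ["p0", "p1"], missing)
    agg = aggregate_appetite_weight(cohort)
    dec = agg.schema.index("appetite_weight_decrease")
    assert agg.values[0, dec] == 1 and not agg.missing[0, dec]
    assert agg.missing[1, dec]


# ------------------------------------------------------------- dichotomizing

def test_dichotomize_thresholds():
    from symptomdist import synthetic_ordinal_schema

    schema = synthetic_ordinal_schema(4, 3)
    prof = SymptomProfile("p", np.array([3, 0, 2, 1]), schema)
    d2 = dichotomize(prof, 2)
    assert d2.values.tolist() == [1, 0, 1, 0]
    assert d2.schema.is_binary
    d1 = dichotomize(prof, 1)
    assert d1.values.tolist() == [1, 0, 1, 1]  # any endorsement
    with pytest.raises(ValueError):
        dichotomize(prof, 0)
    with pytest.raises(ValueError):
        dichotomize(prof, 4)


def test_dichotomize_cohort_matches_per_profile(rng):
    from symptomdist import synthetic_ordinal_schema

    schema = synthetic_ordinal_schema(6, 3)
    values = rng.integers(0, 4, size=(10, 6))
    cohort = Cohort(schema, values, [f"p{i}" for i in range(10)])
    dc = dichotomize_cohort(cohort, 2)
    for i in range(10):
        assert np.array_equal(dc.values[i], dichotomize(cohort.profile(i), 2).values)


# ---------------------------------------------------------------- MDE screen

def _mde_profile(schema, present):
    return SymptomProfile("p", raw_profile_row(schema, present), schema)


def test_screen_mde_rules(mde16_schema):
    five_with_core = {"sad_mood", "fatigue", "guilt", "hypersomnia", "suicidal_thoughts"}
    assert screen_mde(_mde_profile(mde16_schema, five_with_core))
    five_without_core = {"fatigue", "guilt", "hypersomnia", "suicidal_thoughts",
                         "diminished_concentration"}
    assert not screen_mde(_mde_profile(mde16_schema, five_without_core))
    four_with_core = {"sad_mood", "fatigue", "guilt", "hypersomnia"}
    assert not screen_mde(_mde_profile(mde16_schema, four_with_core))
    # items OR within a criterion: insomnia and hypersomnia both count once
    both_sleep = {"sad_mood", "fatigue", "guilt", "hypersomnia", "insomnia_sleep_onset"}
    assert not screen_mde(_mde_profile(mde16_schema, both_sleep))


def test_screen_mde_monotone(mde16_schema, rng):
    # adding a present symptom never flips the screen from true to false
    for _ in range(200):
        values = (rng.random(16) < 0.5).astype(np.int64)
        prof = SymptomProfile("p", values, mde16_schema)
        if screen_mde(prof):
            j = rng.integers(16)
            more = values.copy()
            more[j] = 1
            assert screen_mde(SymptomProfile("p", more, mde16_schema))


def test_screen_mde_requires_criterion_map():
    schema = SymptomSchema("bare", (SymptomItem("a"), SymptomItem("b")))
    prof = SymptomProfile("p", np.array([1, 1]), schema)
    with pytest.raises(SchemaMismatchError, match="criteri"):
        screen_mde(prof)
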