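import numpy as np
import pytest

from symptomdist import (
    Cohort,
    SymptomItem,
    SymptomSchema,
    bundled_schema,
    synthetic_binary_schema,
)


@pytest.fixture(scope="session")
def raw_schema() -> SymptomSchema:
    return bundled_schema("audadis_raw")


@pytest.fixture(scope="session")
def mde16_schema() -> SymptomSchema:
    return bundled_schema("audadis_mde_16")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def make_binary_cohort(
    n: int, k: int = 16, p: float = 0.5, seed: int = 0, schema: SymptomSchema | None = None
) -> Cohort:
    """Small i.i.d. Bernoulli cohort for unit tests."""
    schema = schema or synthetic_binary_schema(k)
    g = np.random.default_rng(seed)
    values = (g.random((n, schema.k)) < p).astype(np.int64)
    return Cohort(schema, values, [f"r{i}" for i in range(n)])


def raw_profile_row(schema: SymptomSchema, present: set[str]) -> np.ndarray:
    """0/1 row for *schema* with the named items present."""
    return np.array([1 if i in present else 0 for i in schema.item_ids], dtype=np.int64)
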