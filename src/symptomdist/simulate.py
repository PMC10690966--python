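"""Synthetic cohort generation.

The generator produces cohorts with the statistical structure the
heterogeneity analysis assumes, so the full pipeline is exercisable without
access-controlled survey or trial data:

* ``marginal_bernoulli`` — independent per-item endorsement at configurable
  marginal rates; the bundled default rates reproduce the symptom marginals
  of a large epidemiological MDE sample (items are independent, which real
  symptom data are not — an optional equicorrelated Gaussian-copula knob adds
  pairwise dependence as an extension).
* ``panel_a`` — the idealized best case for subgrouping: two internally
  constant groups that disagree on every item (within ratios exactly 0,
  between ratios exactly 1).
* ``panel_b`` — complete heterogeneity: labels assigned independently of
  i.i.d. random profiles, so within- and between-group ratios coincide.
* ``panel_c`` — a mixed case: the specifier group is perfectly coherent
  (constant profile, within ratios 0) while non-specifier profiles are
  i.i.d. Bernoulli(0.75), putting the between-group median at 0.75.
* ``ordinal`` — i.i.d. categorical severity items on {0..v}.

Same seed and config always give a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import yaml
from scipy.stats import norm

from .clean import screen_cohort_mde
from .schema import (
    BINARY,
    ORDINAL,
    Cohort,
    SymptomItem,
    SymptomSchema,
    bundled_config_path,
    bundled_schema,
)
from .specifiers import SubgroupPartition

__all__ = [
    "ScenarioConfig",
    "generate_marginal_cohort",
    "generate_scenario_cohort",
    "generate_ordinal_cohort",
    "nesarc_endorsement_rates",
    "nesarc_like_cohort",
    "synthetic_binary_schema",
    "synthetic_ordinal_schema",
]

SCENARIOS = ("marginal_bernoulli", "panel_a", "panel_b", "panel_c", "ordinal")

# Bernoulli rate of non-specifier items in the mixed scenario; puts the
# between-group median at 0.75 against the constant all-absent specifier
# profile while leaving the non-specifier group visibly heterogeneous.
PANEL_C_OUTGROUP_RATE = 0.75


@dataclass
class ScenarioConfig:
    scenario: str
    n: int
    k: int = 16
    v: int = 1
    endorsement_probs: Optional[Sequence[float]] = None
    ordinal_pmf: Optional[Sequence[float]] = None
    # specifier subgroups are minorities in field data (roughly 10-45% of
    # cases), so planted scenarios default to a 1:3 specifier split
    specifier_fraction: float = 0.25
    correlation: float = 0.0
    require_mde: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 <= self.correlation < 1:
            raise ValueError("correlation must be in [0, 1)")
        if not 0 < self.specifier_fraction < 1:
            raise ValueError("specifier_fraction must be in (0, 1)")


def synthetic_binary_schema(k: int, name: str = "synthetic_binary") -> SymptomSchema:
    """Generic k-item binary schema (no DSM mapping) for simulations."""
    return SymptomSchema(
        name, tuple(SymptomItem(f"s{i + 1:02d}", f"synthetic item {i + 1}") for i in range(k))
    )


def synthetic_ordinal_schema(k: int, v: int, name: str = "synthetic_ordinal") -> SymptomSchema:
    return SymptomSchema(
        name,
        tuple(
            SymptomItem(f"s{i + 1:02d}", f"synthetic item {i + 1}", ORDINAL, 0, v)
            for i in range(k)
        ),
    )


def _resolve_probs(config: ScenarioConfig, schema: SymptomSchema) -> np.ndarray:
    probs = config.endorsement_probs
    if probs is None:
        probs = np.full(schema.k, 0.5)
    elif isinstance(probs, dict):
        probs = np.array([probs[i] for i in schema.item_ids], dtype=float)
    else:
        probs = np.asarray(probs, dtype=float)
    if probs.shape != (schema.k,):
        raise ValueError(f"need {schema.k} endorsement probabilities, got {probs.shape}")
    if (probs < 0).any() or (probs > 1).any():
        raise ValueError("endorsement probabilities must lie in [0, 1]")
    return probs


def _draw_binary(
    rng: np.random.Generator, n: int, probs: np.ndarray, correlation: float
) -> np.ndarray:
    if correlation == 0.0:
        return (rng.random((n, probs.size)) < probs).astype(np.int64)
    # equicorrelated Gaussian copula: z = sqrt(rho) * shared + sqrt(1-rho) * own
    shared = rng.standard_normal((n, 1))
    own = rng.standard_normal((n, probs.size))
    z = np.sqrt(correlation) * shared + np.sqrt(1.0 - correlation) * own
    return (z < norm.ppf(probs)).astype(np.int64)


def generate_marginal_cohort(
    config: ScenarioConfig, schema: Optional[SymptomSchema] = None
) -> Cohort:
    """Independent (or copula-correlated) Bernoulli endorsement per item.

    With ``require_mde=True`` only profiles passing the five-of-nine screen
    are retained (rejection sampling); an acceptance rate below 1e-4 raises,
    naming the offending probabilities.
    """
    if config.scenario != "marginal_bernoulli":
        raise ValueError("config.scenario must be 'marginal_bernoulli'")
    schema = schema or synthetic_binary_schema(config.k)
    probs = _resolve_probs(config, schema)
    rng = np.random.default_rng(config.seed)

    if not config.require_mde:
        values = _draw_binary(rng, config.n, probs, config.correlation)
        ids = [f"r{i + 1:05d}" for i in range(config.n)]
        return Cohort(schema, values, ids)

    kept: list[np.ndarray] = []
    accepted = drawn = 0
    batch = max(4 * config.n, 1000)
    while accepted < config.n:
        values = _draw_binary(rng, batch, probs, config.correlation)
        passed = screen_cohort_mde(Cohort(schema, values, [str(i) for i in range(batch)]),
                                   keep=False)
        drawn += batch
        sel = values[passed]
        accepted += sel.shape[0]
        kept.append(sel)
        if drawn >= max(100_000, 20 * config.n) and accepted / drawn < 1e-4:
            raise ValueError(
                "MDE rejection sampling is infeasible (acceptance rate "
                f"{accepted / drawn:.2e}) for endorsement probabilities {probs.tolist()}"
            )
    values = np.concatenate(kept)[: config.n]
    ids = [f"r{i + 1:05d}" for i in range(config.n)]
    return Cohort(schema, values, ids)


def _scenario_partition(n_spec: int, n_non: int) -> SubgroupPartition:
    # the planted specifier group is labeled 'melancholic' as a placeholder
    # so the partition plugs straight into split()/permutation_test
    ids = [f"r{i + 1:05d}" for i in range(n_spec + n_non)]
    labels = np.array(["melancholic"] * n_spec + ["neither"] * n_non, dtype=object)
    return SubgroupPartition(ids, labels)


def generate_scenario_cohort(config: ScenarioConfig) -> tuple[Cohort, SubgroupPartition]:
    """Planted-subgroup scenarios for coherence/differentiation geometry."""
    if config.scenario not in ("panel_a", "panel_b", "panel_c"):
        raise ValueError("config.scenario must be panel_a, panel_b or panel_c")
    rng = np.random.default_rng(config.seed)
    schema = synthetic_binary_schema(config.k, name=config.scenario)
    n_spec = int(round(config.n * config.specifier_fraction))
    n_non = config.n - n_spec
    if n_spec == 0 or n_non == 0:
        raise ValueError(
            f"specifier_fraction {config.specifier_fraction} leaves an empty group at n={config.n}"
        )

    if config.scenario == "panel_a":
        values = np.vstack(
            [
                np.zeros((n_spec, config.k), dtype=np.int64),
                np.ones((n_non, config.k), dtype=np.int64),
            ]
        )
    elif config.scenario == "panel_b":
        values = (rng.random((config.n, config.k)) < 0.5).astype(np.int64)
    else:  # panel_c
        values = np.vstack(
            [
                np.zeros((n_spec, config.k), dtype=np.int64),
                (rng.random((n_non, config.k)) < PANEL_C_OUTGROUP_RATE).astype(np.int64),
            ]
        )

    partition = _scenario_partition(n_spec, n_non)
    cohort = Cohort(schema, values, partition.respondent_ids)
    return cohort, partition


def generate_ordinal_cohort(
    config: ScenarioConfig, schema: Optional[SymptomSchema] = None
) -> Cohort:
    """I.i.d. categorical severity items on {0..v} (uniform by default)."""
    if config.scenario != "ordinal":
        raise ValueError("config.scenario must be 'ordinal'")
    if config.v < 1:
        raise ValueError("v must be >= 1 for ordinal cohorts")
    schema = schema or synthetic_ordinal_schema(config.k, config.v)
    pmf = config.ordinal_pmf
    if pmf is None:
        pmf = np.full(config.v + 1, 1.0 / (config.v + 1))
    pmf = np.asarray(pmf, dtype=float)
    if pmf.shape != (config.v + 1,):
        raise ValueError(f"ordinal_pmf must have {config.v + 1} entries")
    if (pmf < 0).any() or abs(pmf.sum() - 1.0) > 1e-8:
        raise ValueError(f"ordinal_pmf must be a probability vector; got sum {pmf.sum()}")
    rng = np.random.default_rng(config.seed)
    values = rng.choice(config.v + 1, size=(config.n, config.k), p=pmf)
    ids = [f"r{i + 1:05d}" for i in range(config.n)]
    return Cohort(schema, values.astype(np.int64), ids)


def nesarc_endorsement_rates() -> tuple[SymptomSchema, np.ndarray]:
    """Bundled 16-item analysis schema plus its default endorsement rates."""
    schema = bundled_schema("audadis_mde_16")
    with open(bundled_config_path("nesarc_endorsement")) as fh:
        raw = yaml.safe_load(fh)
    probs = np.array([raw["endorsement"][i] for i in schema.item_ids], dtype=float)
    return schema, probs


def nesarc_like_cohort(
    n: int,
    seed: int = 0,
    require_mde: bool = True,
    correlation: float = 0.0,
) -> Cohort:
    """Convenience generator: 16 binary items at the bundled endorsement
    rates, screened for MDE by default."""
    schema, probs = nesarc_endorsement_rates()
    config = ScenarioConfig(
        scenario="marginal_bernoulli",
        n=n,
        k=schema.k,
        endorsement_probs=probs,
        correlation=correlation,
        require_mde=require_mde,
        seed=seed,
    )
    return generate_marginal_cohort(config, schema=schema)
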