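"""End-to-end orchestration: read, clean, screen, partition, measure, test.

``run_pipeline`` reproduces the standard analysis layout on any cohort:
within-group distance ratios for the whole sample and for each specifier /
non-specifier subgroup, between-group ratios for the melancholic and (within
non-melancholic) atypical splits, boxplot-ready summaries, and a label-
shuffling permutation test per split.  Every output is accompanied by a run
log (config, seed, package versions) sufficient to reproduce it; stage
errors propagate with the stage name and partial outputs are removed.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    DistanceSummary,
    DistanceVector,
    PermutationResult,
    between_group_distances,
    count_profile_categories,
    permutation_test,
    summarize_distances,
    within_group_distances,
)
from .clean import dichotomize_cohort, listwise_delete, nesarc_cleaning_chain, screen_cohort_mde
from .distances import DistanceSpec
from .io import read_cohort, write_cohort
from .schema import Cohort, SymptomSchema, load_schema
from .specifiers import SpecifierRule, SubgroupPartition, apply_hierarchy, load_rules

__all__ = ["PipelineError", "AnalysisReport", "analyze_cohort", "run_pipeline",
           "run_variant_symptom_sets"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisReport:
    """In-memory result bundle of one analysis pass."""

    metric: str
    k: int
    v: int
    n: int
    profile_categories: int
    counts: dict[str, int]
    summaries: list[DistanceSummary]
    permutations: dict[str, PermutationResult]
    distance_vectors: dict[str, DistanceVector] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": s.group_pair[0],
                "comparison": s.group_pair[1],
                "median": s.median,
                "q1": s.q1,
                "q3": s.q3,
                "n_dyads": s.n_dyads,
            }
            for s in self.summaries
        ]
        return pd.DataFrame(rows)


def _maybe_within(
    cohort: Cohort, members: list[str], spec: DistanceSpec, label: str
) -> Optional[DistanceVector]:
    if len(members) < 2:
        return None
    return within_group_distances(cohort, members, spec, label=label)


def analyze_cohort(
    cohort: Cohort,
    partition: SubgroupPartition,
    metric: str = "hamming",
    n_permutations: int = 100,
    seed: int = 0,
    keep_vectors: bool = False,
) -> AnalysisReport:
    """Distance summaries and permutation tests for both specifier splits.

    Splits whose specifier or non-specifier side is empty (or has fewer than
    two members for a within-group comparison) are skipped rather than
    failing the whole run.
    """
    spec = DistanceSpec.from_schema(cohort.schema, metric)
    vectors: dict[str, DistanceVector] = {}
    summaries: list[DistanceSummary] = []
    permutations: dict[str, PermutationResult] = {}

    whole = _maybe_within(cohort, cohort.respondent_ids, spec, "all")
    if whole is not None:
        vectors["all_within"] = whole

    for which in ("melancholic", "atypical"):
        group, non_group = partition.split(which)
        w_spec = _maybe_within(cohort, group, spec, which)
        w_non = _maybe_within(cohort, non_group, spec, f"non_{which}")
        if w_spec is not None:
            vectors[f"{which}_within"] = w_spec
        if w_non is not None:
            vectors[f"non_{which}_within"] = w_non
        if group and non_group:
            vectors[f"{which}_between"] = between_group_distances(
                cohort, group, non_group, spec, labels=(which, f"non_{which}")
            )
            permutations[which] = permutation_test(
                cohort, partition, which, spec, n_permutations=n_permutations, seed=seed
            )

    summaries = [summarize_distances(dv) for dv in vectors.values()]
    report = AnalysisReport(
        metric=metric,
        k=spec.k,
        v=spec.v,
        n=cohort.n,
        profile_categories=(
            count_profile_categories(cohort) if cohort.schema.is_binary else -1
        ),
        counts=partition.counts,
        summaries=summaries,
        permutations=permutations,
        distance_vectors=vectors if keep_vectors else {},
    )
    return report


def _write_outputs(
    report: AnalysisReport,
    out_dir: Path,
    run_log: dict,
    prefix: str = "",
) -> list[Path]:
    from .plotting import boxplot_summaries  # deferred: pulls in matplotlib

    written: list[Path] = []
    summary_path = out_dir / f"{prefix}summary.csv"
    report.summary_frame().to_csv(summary_path, index=False)
    written.append(summary_path)

    perm_path = out_dir / f"{prefix}permutation.json"
    perm_payload = {
        which: {
            "observed": res.observed,
            "p_value": res.p_value,
            "n_permutations": res.n_permutations,
            "seed": res.seed,
            "group_sizes": list(res.group_sizes),
        }
        for which, res in report.permutations.items()
    }
    perm_path.write_text(json.dumps(perm_payload, indent=2))
    written.append(perm_path)

    fig_path = out_dir / f"{prefix}boxplot.svg"
    boxplot_summaries(report.summaries, fig_path, title=f"{report.metric} ratios (k={report.k})")
    written.append(fig_path)

    log_path = out_dir / f"{prefix}run_log.json"
    log_path.write_text(json.dumps(run_log, indent=2))
    written.append(log_path)
    return written


def run_pipeline(
    cohort: Union[str, Path, Cohort],
    schema: Union[str, Path, SymptomSchema, None] = None,
    rules: Union[str, Path, dict[str, SpecifierRule], None] = None,
    metric: str = "hamming",
    n_permutations: int = 100,
    seed: int = 0,
    out_dir: Union[str, Path, None] = None,
    dialect: str = "zero_one",
    apply_cleaning_chain: bool = False,
    apply_listwise: bool = True,
    apply_mde_screen: bool = False,
    dichotomize_threshold: Optional[int] = None,
) -> AnalysisReport:
    """Full analysis on a cohort file or in-memory cohort.

    Stages: read -> clean (optional interview aggregation chain, listwise
    deletion) -> optional dichotomization and MDE screen -> specifier
    partition -> within/between distances -> summaries -> permutation tests
    -> outputs under ``out_dir`` (if given): summary table, boxplot (vector
    graphics plus the underlying table), permutation report and run log.
    """
    stage = "configure"
    created_dir = False
    out_path: Optional[Path] = None
    try:
        if out_dir is not None:
            out_path = Path(out_dir)
            created_dir = not out_path.exists()
            out_path.mkdir(parents=True, exist_ok=True)

        stage = "read"
        if isinstance(cohort, Cohort):
            data = cohort
        else:
            if schema is None:
                raise ValueError("reading a cohort file requires a schema")
            sch = schema if isinstance(schema, SymptomSchema) else load_schema(schema)
            data = read_cohort(cohort, sch, dialect=dialect)

        stage = "clean"
        if apply_cleaning_chain:
            data = nesarc_cleaning_chain(data)
        if apply_listwise:
            data = listwise_delete(data)

        analysis_data = data
        stage = "screen"
        binary_view = data
        if dichotomize_threshold is not None:
            binary_view = dichotomize_cohort(data, dichotomize_threshold)
        if apply_mde_screen:
            passed = screen_cohort_mde(binary_view, keep=False)
            keep = np.flatnonzero(passed)
            analysis_data = data.subset(keep)
            binary_view = binary_view.subset(keep)

        stage = "partition"
        if rules is None:
            partition = apply_hierarchy(binary_view)
        else:
            ruleset = rules if isinstance(rules, dict) else load_rules(rules)
            partition = apply_hierarchy(
                binary_view, ruleset["melancholic"], ruleset["atypical"]
            )

        stage = "analyze"
        report = analyze_cohort(
            analysis_data,
            partition,
            metric=metric,
            n_permutations=n_permutations,
            seed=seed,
        )

        stage = "write"
        if out_path is not None:
            run_log = {
                "package": "symptomdist",
                "version": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "metric": metric,
                "k": report.k,
                "v": report.v,
                "n": report.n,
                "n_permutations": n_permutations,
                "seed": seed,
                "dialect": dialect,
                "apply_cleaning_chain": apply_cleaning_chain,
                "apply_listwise": apply_listwise,
                "apply_mde_screen": apply_mde_screen,
                "dichotomize_threshold": dichotomize_threshold,
                "counts": report.counts,
            }
            _write_outputs(report, out_path, run_log)
        return report
    except Exception as exc:
        if out_path is not None and created_dir and out_path.exists():
            shutil.rmtree(out_path, ignore_errors=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc


def run_variant_symptom_sets(
    cohort: Cohort,
    schema_full: SymptomSchema,
    schema_core: SymptomSchema,
    partition: SubgroupPartition,
    metric: str = "manhattan",
    n_permutations: int = 100,
    seed: int = 0,
) -> dict[str, AnalysisReport]:
    """Run the analysis under two nested symptom sets.

    The same respondents are analyzed once with all symptoms (including
    specifier features) and once with only the core criterion symptoms; the
    two reports are keyed by schema name and carry their own k, so the ratio
    denominators differ between the runs.
    """
    core_ids = set(schema_core.item_ids)
    full_ids = set(schema_full.item_ids)
    if not core_ids < full_ids:
        raise ValueError("core schema must be a strict subset of the full schema")
    if cohort.schema.item_ids != schema_full.item_ids:
        raise ValueError("cohort must be aligned to the full schema")

    reports: dict[str, AnalysisReport] = {}
    for sch in (schema_full, schema_core):
        idx = [cohort.schema.index(i) for i in sch.item_ids]
        sub = Cohort(sch, cohort.values[:, idx], cohort.respondent_ids, cohort.missing[:, idx])
        reports[sch.name] = analyze_cohort(
            sub, partition, metric=metric, n_permutations=n_permutations, seed=seed
        )
    return reports
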