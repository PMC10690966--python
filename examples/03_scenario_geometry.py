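"""Three reference scenarios for reading within/between distance ratios.

Each planted scenario illustrates one geometry of subgroup structure:

* panel_a  — two internally identical, maximally separated groups:
             within-group ratios are exactly 0 and between-group ratios
             exactly 1 (perfect coherence and differentiation).
* panel_b  — labels carry no information: within- and between-group ratio
             distributions coincide (complete heterogeneity everywhere).
* panel_c  — a perfectly coherent specifier group against a heterogeneous
             remainder: within-specifier 0, between-group median high.
"""

from symptomdist import (
    DistanceSpec,
    ScenarioConfig,
    between_group_distances,
    generate_scenario_cohort,
    summarize_distances,
    within_group_distances,
)

spec = DistanceSpec("hamming", k=16)

for scenario in ("panel_a", "panel_b", "panel_c"):
    cohort, partition = generate_scenario_cohort(
        ScenarioConfig(scenario=scenario, n=400, k=16, seed=11))
    group_a, group_b = partition.split("melancholic")
    w_a = summarize_distances(within_group_distances(cohort, group_a, spec))
    w_b = summarize_distances(within_group_distances(cohort, group_b, spec))
    btw = summarize_distances(between_group_distances(cohort, group_a, group_b, spec))
    print(f"{scenario}:  within-specifier median={w_a.median:.3f}  "
          f"within-other median={w_b.median:.3f}  between median={btw.median:.3f}")
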