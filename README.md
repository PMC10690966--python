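# symptomdist

Quantify symptom heterogeneity in depression by measuring distances between
individual symptom profiles.

## The scientific problem

A major depressive episode (MDE) can be diagnosed from many different symptom
combinations, and clinical specifiers ("melancholic features", "atypical
features") are meant to carve out more homogeneous subgroups. Whether they
actually do is an empirical question: if a specifier picks out a coherent
syndrome, respondents *within* the specifier subgroup should have more similar
symptom profiles than respondents in *different* subgroups.

This package operationalizes "similar" with distances between profiles:

* **Hamming distance** on binary (present/absent) profiles:
  `D_H(x, y) = Σ |x_i − y_i|`, standardized as `R_H = D_H / k` for `k` items.
* **Manhattan distance** on ordinal severity profiles (0..v per item),
  standardized as `R_M = D_M / (k·v)`.
* **Euclidean distance** for comparison (emphasizes large per-item gaps).

Both ratios live in [0, 1]: 0 means identical profiles, 1 maximal disagreement
on every item. Heterogeneity of a subgroup is summarized by the median (and
quartiles) of all within-group dyad ratios; differentiation between subgroups
by the median of all between-group dyad ratios, with significance assessed by
a label-shuffling permutation test.

The package provides:

* schemas for symptom inventories (a 16-item binary MDE analysis set derived
  from a 21-item epidemiological interview, plus 22- and 17-item ordinal
  rating-scale inventories), with YAML round-tripping;
* data cleaning for the interview coding (1 = present / 2 = absent),
  aggregation of appetite/weight and suicidality items, listwise deletion,
  dichotomization, and the 5-of-9 MDE screen with the mood/anhedonia gate;
* hierarchical specifier classification (melancholic features evaluated
  first; atypical features only among non-melancholic respondents);
* vectorized all-pairs within/between distance computation, quartile
  summaries, profile-category counting, and the permutation test;
* a synthetic-cohort generator with endorsement-calibrated marginals, an
  optional equicorrelated dependence knob, an MDE rejection-sampling filter,
  and three planted reference scenarios;
* a pipeline with reproducible output bundles (tables, figures, run log) and
  a `symptomdist` command-line interface.

## Worked example

```python
import numpy as np
from symptomdist import (DistanceSpec, hamming_distance, manhattan_distance,
                         euclidean_distance, standardized_ratio)

alice = np.array([1, 1, 0, 0, 1, 0, 0, 1, 0, 1, 1, 0, 1, 0, 0, 0])
bob   = np.array([1, 0, 1, 0, 1, 1, 0, 1, 0, 0, 1, 0, 1, 0, 1, 0])
d = hamming_distance(alice, bob)            # 5
spec = DistanceSpec("hamming", k=16)
standardized_ratio(d, spec)                 # 0.3125

x = np.array([3, 3, 0, 2, 1, 0])
y = np.array([0, 0, 0, 2, 1, 0])
manhattan_distance(x, y)                    # 6
euclidean_distance(x, y)                    # 4.2426...
```

Running `python examples/02_synthetic_cohort_pipeline.py` generates an
endorsement-calibrated synthetic cohort of 500 screened respondents,
classifies them (this run: 387 melancholic, 27 atypical, 86 neither), and
prints the distance summaries — the whole-sample within median is 0.3750
with quartiles [0.3125, 0.4375], the melancholic within median is 0.3750, and
the melancholic / non-melancholic between median is also 0.3750 with
permutation p = 1.000: under item-independent simulation the specifier does
not carve out a more coherent subgroup, mirroring the negative finding this
kind of analysis is designed to detect.

The planted scenarios (`python examples/03_scenario_geometry.py`) pin the
interpretation scale:

```
panel_a:  within-specifier median=0.000  within-other median=0.000  between median=1.000
panel_b:  within-specifier median=0.500  within-other median=0.500  between median=0.500
panel_c:  within-specifier median=0.000  within-other median=0.375  between median=0.750
```

## Command line

```bash
symptomdist simulate --scenario nesarc_like --n 500 --seed 42 --out cohort.csv
symptomdist pipeline --cohort cohort.csv \
    --schema src/symptomdist/data/audadis_mde_16.yaml \
    --rules  src/symptomdist/data/rules_nesarc.yaml \
    --permutations 200 --seed 7 --out results/
```

The output bundle contains `summary.csv`, `permutation.json`, `boxplot.svg`
and `run_log.json`; reruns with the same seed are byte-identical.

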