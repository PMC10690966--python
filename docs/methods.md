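# Methods

## Model

Respondent `i` is a symptom profile `x_i ∈ {0, …, v}^k` over a fixed schema of
`k` items (`v = 1` for binary present/absent inventories, `v = 3` for the
0–3 ordinal rating scales). Disagreement between two profiles is

* Hamming (binary): `D_H(x, y) = Σ_j |x_j − y_j|`,
* Manhattan (ordinal): `D_M(x, y) = Σ_j |x_j − y_j|`,
* Euclidean (comparison only): `D_E(x, y) = sqrt(Σ_j (x_j − y_j)²)`.

Each distance is standardized by its maximum attainable value (`k` for
Hamming, `k·v` for Manhattan, `v·sqrt(k)` for Euclidean), giving a ratio in
[0, 1]. On binary data Hamming and Manhattan coincide and
`D_E = sqrt(D_H)`.

For a subgroup `A`, heterogeneity is the distribution of ratios over all
`n_A(n_A−1)/2` within-group dyads; differentiation between `A` and `B` is the
distribution over all `n_A·n_B` between-group dyads. These partition the
pooled dyads exactly: `within_A + within_B + between_AB = n(n−1)/2`.
Distributions are summarized by median and quartiles (NumPy linear
interpolation, i.e. `numpy.percentile` with the default `linear` method).

## Screening and cleaning

The epidemiological interview records 21 binary items coded 1 = present,
2 = absent (`audadis_one_two` dialect; any other code becomes missing). The
cleaning chain aggregates the four appetite/weight items into
decrease/increase indicators and the three suicidal-ideation items into a
single indicator (logical OR; the result is missing only if no aggregated
item is present and at least one is missing), keeps the suicide-attempt item,
and drops the restlessness item, yielding the 16-item analysis schema.
Listwise deletion removes respondents with any remaining missing item.

The MDE screen requires at least 5 of the 9 diagnostic criteria (an item
mapped to a criterion counts the criterion as met) and criterion 1 (sad mood)
or 2 (anhedonia) to be present.

## Specifier rules

Rules are m-of-n feature counts, where each feature is an OR-set of items
(e.g. psychomotor retardation OR agitation counts once). The epidemiological
proxy rules are: melancholic = at least 3 of {anhedonia, psychomotor
retardation/agitation, guilt, early-morning awakening, appetite/weight
decrease}; atypical = hypersomnia AND appetite/weight increase. Rules are
applied hierarchically: melancholic is evaluated first and excludes atypical,
so atypical + non-atypical always equals non-melancholic.

The ordinal-inventory rule set (`rules_dsm5_ids`) is a reconstruction from
the published criterion wording, applied to severity profiles dichotomized at
severity ≥ 2. The atypical mood-reactivity gate has no dedicated item in the
bundled inventories and is omitted; this is a documented limitation, not a
claim of diagnostic fidelity.

## Permutation test

The observed statistic is the median standardized between-group ratio. Group
labels are shuffled `B` times preserving group sizes; the p-value is the
plain proportion of shuffled statistics ≥ the observed one (ties within
1e-12 count toward the numerator), with an optional plus-one smoothed
estimator `(1+c)/(1+B)`. The full pooled ratio matrix is cached once
(float32 above n = 2000), so each shuffle is a submatrix median; this is
numerically identical to recomputation because the metrics depend only on the
profile pair.

**Discreteness and calibration.** The median of integer-valued dyad distances
lies on a coarse lattice, so permuted statistics frequently tie exactly with
the observed one and the plain-proportion p is conservative — a validity
property (the type-I error never exceeds the nominal level), not a defect.
The effect *grows* with group size, because the empirical median concentrates
on a lattice atom shared by all shuffles. Near-nominal behaviour requires a
statistic that is effectively continuous across shuffles. The calibration
study in the test suite therefore uses the Euclidean median on ordinal
cohorts with (a) an even number of between-group dyads, so the median
averages two order statistics, (b) unequal group sizes (4 vs 6), so
complementary labelings do not duplicate permuted statistics, and (c) many
items (k = 120, v = 3), so pooled dyad values are almost all distinct. Under
that design the empirical rate of p ≤ 0.05 over 500 exchangeable null
cohorts falls within the binomial 95% band around 0.05; a companion test
documents that the integer-metric median never exceeds the band (level
control) while typically falling below it.

With a perfectly separated planted cohort the observed median is the maximum
(1.0), but a label shuffle can re-attain it by concentrating enough planted
profiles in one group; the probability is hypergeometric and is negligible
only when the specifier group is a small minority. The minimum-p checks use
a 10-of-200 specifier group, where the per-shuffle tie probability is of
order 1e-7.

## Synthetic cohorts

`generate_marginal_cohort` draws items independently as Bernoulli(p_item);
defaults use published per-item endorsement rates for respondents with a
lifetime MDE (e.g. sad mood 0.9497, anhedonia 0.8760, suicide attempt
0.1105). Optional features:

* **Dependence:** an equicorrelated Gaussian copula (`correlation` in [0, 1))
  adds positive inter-item association while preserving the marginals.
* **Screening:** rejection sampling retains only profiles passing the MDE
  screen, erroring if the acceptance rate falls below 1e-4.

Independence is a deliberate simplification: it preserves marginal rates and
the dyad-distance scale but understates profile clustering, so hierarchical
subgroup shares in synthetic cohorts do not match field-reported shares
(melancholic comes out larger). Conclusions about specifier coherence should
not be read off the independent-item generator; it exists to exercise the
analysis machinery at realistic marginals. Under independence the expected
standardized Hamming ratio between two profiles with common endorsement rate
p is exactly `2p(1−p)`, which the tests verify by Monte Carlo.

Planted scenarios fix the geometry rather than the marginals:

* `panel_a`: specifier group all-zeros, remainder all-ones → within ratios
  exactly 0, between ratios exactly 1.
* `panel_b`: iid Bernoulli(0.5) items with uninformative labels → within and
  between distributions coincide (median ≈ 0.5 at k = 16).
* `panel_c`: specifier group constant (all-zeros), remainder iid
  Bernoulli(0.75) → within-specifier exactly 0, between median 0.75 (each
  between dyad ratio is the remainder profile's endorsement fraction), and
  the remainder's within median 2·0.75·0.25 = 0.375. A mixed case with
  `within-specifier < within-other < between` cannot be produced with a
  *higher* within-other value: for iid items the expected within ratio
  `2p(1−p)` is at most 0.5, with equality only at p = 0.5, where the between
  median against an all-zero group would also be 0.5.

The default specifier fraction is 0.25, reflecting that specifier subgroups
are typically minorities of a case sample. Generator defaults were fixed
before the acceptance checks were run and are study conditions, not tuning
knobs.

## Numerical conventions

* Quartiles: NumPy linear-interpolation percentiles.
* Tie tolerance in the permutation test: 1e-12 (distances are ratios of
  small integers or square roots of integers; 1e-12 is far below the lattice
  spacing at any supported k).
* All-pairs distances delegate to `scipy.spatial.distance.pdist`/`cdist`
  (`cityblock`, `euclidean`); between-group blocks are computed in chunks of
  4096 rows to bound memory.
* Every stochastic routine takes an explicit integer seed and uses
  `numpy.random.default_rng`; identical seeds give byte-identical outputs,
  including the pipeline's CSV/JSON bundles.
* Dichotomization threshold defaults to severity ≥ 2 on 0–3 scales (the
  conventional "moderate or worse" cut).

## Design decisions

* Distance primitives accept either raw arrays or schema-validated profiles;
  validation (schema identity, missing values, binary-only for Hamming)
  happens at the boundary so the numerical kernels stay vectorized.
* The pipeline is a thin orchestration over library calls; failures carry the
  stage name (`configure/read/clean/screen/partition/analyze/write`) and
  partial output directories are removed.
* The command-line interface wraps the same library functions for shell-based
  workflows; everything it produces is reachable from Python.
* Bundled inventories beyond the 16-item interview schema are reconstructions
  for demonstration and testing; fixture-scale data are generated, not
  shipped.
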