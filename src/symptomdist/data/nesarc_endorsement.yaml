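# Marginal endorsement probabilities for the 16 analysis symptoms among
# respondents meeting lifetime MDE criteria in a NESARC-like population
# (proportions of cases endorsing each symptom).  Used as the default
# per-item Bernoulli rates of the synthetic-cohort generator so that
# simulated cohorts have realistic symptom marginals; items are generated
# independently, which real data are not.
schema: audadis_mde_16
endorsement:
  sad_mood: 0.9497
  anhedonia: 0.8760
  appetite_weight_decrease: 0.6008
  appetite_weight_increase: 0.3642
  insomnia_sleep_onset: 0.6942
  early_morning_awakening: 0.5490
  hypersomnia: 0.4683
  psychomotor_retardation: 0.4076
  psychomotor_agitation: 0.3750
  fatigue: 0.8471
  worthlessness: 0.6255
  guilt: 0.5813
  diminished_concentration: 0.8471
  indecisiveness: 0.7577
  suicidal_thoughts: 0.5951
  suicide_attempt: 0.1105
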