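# 16-item binary analysis schema for the AUDADIS-IV-style inventory, i.e.
# audadis_raw after combining appetite/weight and suicidal-thought items and
# removing subjective restlessness.  This is the symptom space (k = 16) for
# Hamming distance ratios on a NESARC-like cohort.
name: audadis_mde_16
items:
  - {item_id: sad_mood, label: Depressed or sad mood, scale: binary, dsm_criterion: 1}
  - {item_id: anhedonia, label: Loss of interest or pleasure, scale: binary, dsm_criterion: 2, specifier_feature: melancholic}
  - {item_id: appetite_weight_decrease, label: Decreased appetite or weight, scale: binary, dsm_criterion: 3, specifier_feature: melancholic}
  - {item_id: appetite_weight_increase, label: Increased appetite or weight, scale: binary, dsm_criterion: 3, specifier_feature: atypical}
  - {item_id: insomnia_sleep_onset, label: Trouble falling asleep, scale: binary, dsm_criterion: 4}
  - {item_id: early_morning_awakening, label: Waking too early, scale: binary, dsm_criterion: 4, specifier_feature: melancholic}
  - {item_id: hypersomnia, label: Sleeping too much, scale: binary, dsm_criterion: 4, specifier_feature: atypical}
  - {item_id: psychomotor_retardation, label: Moving or talking slowly, scale: binary, dsm_criterion: 5, specifier_feature: melancholic}
  - {item_id: psychomotor_agitation, label: Fidgeting or pacing, scale: binary, dsm_criterion: 5, specifier_feature: melancholic}
  - {item_id: fatigue, label: Fatigue or loss of energy, scale: binary, dsm_criterion: 6}
  - {item_id: worthlessness, label: Feelings of worthlessness, scale: binary, dsm_criterion: 7}
  - {item_id: guilt, label: Excessive or inappropriate guilt, scale: binary, dsm_criterion: 7, specifier_feature: melancholic}
  - {item_id: diminished_concentration, label: Trouble concentrating, scale: binary, dsm_criterion: 8}
  - {item_id: indecisiveness, label: Trouble making decisions, scale: binary, dsm_criterion: 8}
  - {item_id: suicidal_thoughts, label: Thoughts of death or suicide, scale: binary, dsm_criterion: 9}
  - {item_id: suicide_attempt, label: Attempted suicide, scale: binary, dsm_criterion: 9}
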