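# Synthetic reconstruction of an IDS-SR-style ordinal (0-3) depression
# inventory covering the core MDE criteria plus the melancholic and atypical
# specifier features.  Item selection and criterion mapping follow the
# instrument's published structure but are a reconstruction, not the exact
# parsing used in any particular trial; edit to match your own data.
name: ids_full
items:
  - {item_id: sad_mood, label: Feeling sad, scale: ordinal, max_value: 3, dsm_criterion: 1}
  - {item_id: anhedonia, label: Capacity for pleasure or enjoyment, scale: ordinal, max_value: 3, dsm_criterion: 2, specifier_feature: melancholic}
  - {item_id: appetite_decrease, label: Decreased appetite, scale: ordinal, max_value: 3, dsm_criterion: 3, specifier_feature: melancholic}
  - {item_id: appetite_increase, label: Increased appetite, scale: ordinal, max_value: 3, dsm_criterion: 3, specifier_feature: atypical}
  - {item_id: weight_decrease, label: Weight loss, scale: ordinal, max_value: 3, dsm_criterion: 3, specifier_feature: melancholic}
  - {item_id: weight_increase, label: Weight gain, scale: ordinal, max_value: 3, dsm_criterion: 3, specifier_feature: atypical}
  - {item_id: sleep_onset_insomnia, label: Falling asleep, scale: ordinal, max_value: 3, dsm_criterion: 4}
  - {item_id: mid_nocturnal_insomnia, label: Sleep during the night, scale: ordinal, max_value: 3, dsm_criterion: 4}
  - {item_id: early_morning_insomnia, label: Waking up too early, scale: ordinal, max_value: 3, dsm_criterion: 4, specifier_feature: melancholic}
  - {item_id: hypersomnia, label: Sleeping too much, scale: ordinal, max_value: 3, dsm_criterion: 4, specifier_feature: atypical}
  - {item_id: psychomotor_slowing, label: Feeling slowed down, scale: ordinal, max_value: 3, dsm_criterion: 5, specifier_feature: melancholic}
  - {item_id: psychomotor_agitation, label: Feeling restless, scale: ordinal, max_value: 3, dsm_criterion: 5, specifier_feature: melancholic}
  - {item_id: energy_fatigue, label: Energy level, scale: ordinal, max_value: 3, dsm_criterion: 6}
  - {item_id: view_of_self, label: View of myself, scale: ordinal, max_value: 3, dsm_criterion: 7}
  - {item_id: self_criticism_blame, label: Self-criticism and blame, scale: ordinal, max_value: 3, dsm_criterion: 7, specifier_feature: melancholic}
  - {item_id: concentration_decisions, label: Concentration and decision making, scale: ordinal, max_value: 3, dsm_criterion: 8}
  - {item_id: suicidal_ideation, label: Thoughts of death or suicide, scale: ordinal, max_value: 3, dsm_criterion: 9}
  - {item_id: mood_nonreactivity, label: Mood fails to brighten to desired events, scale: ordinal, max_value: 3, specifier_feature: melancholic}
  - {item_id: distinct_quality_of_mood, label: Mood distinctly different from grief, scale: ordinal, max_value: 3, specifier_feature: melancholic}
  - {item_id: diurnal_variation_morning_worse, label: Mood worse in the morning, scale: ordinal, max_value: 3, specifier_feature: melancholic}
  - {item_id: leaden_paralysis, label: Leaden paralysis / physical energy, scale: ordinal, max_value: 3, specifier_feature: atypical}
  - {item_id: interpersonal_sensitivity, label: Interpersonal rejection sensitivity, scale: ordinal, max_value: 3, specifier_feature: atypical}
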