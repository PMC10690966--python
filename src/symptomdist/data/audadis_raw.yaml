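# Raw AUDADIS-IV-style lifetime MDE symptom inventory: binary present/absent
# items in disaggregated form (appetite and weight queried separately, three
# suicidal-thought gradations plus attempt, restlessness alongside the two
# psychomotor items).  The cleaning chain reduces these 21 items to the
# 16-item analysis schema (audadis_mde_16).
name: audadis_raw
items:
  - {item_id: sad_mood, label: Depressed or sad mood, scale: binary, dsm_criterion: 1}
  - {item_id: anhedonia, label: Loss of interest or pleasure, scale: binary, dsm_criterion: 2, specifier_feature: melancholic}
  - {item_id: reduced_appetite, label: Decreased appetite, scale: binary, dsm_criterion: 3}
  - {item_id: reduced_weight, label: Weight loss, scale: binary, dsm_criterion: 3}
  - {item_id: increased_appetite, label: Increased appetite, scale: binary, dsm_criterion: 3}
  - {item_id: increased_weight, label: Weight gain, scale: binary, dsm_criterion: 3}
  - {item_id: insomnia_sleep_onset, label: Trouble falling asleep, scale: binary, dsm_criterion: 4}
  - {item_id: early_morning_awakening, label: Waking too early, scale: binary, dsm_criterion: 4, specifier_feature: melancholic}
  - {item_id: hypersomnia, label: Sleeping too much, scale: binary, dsm_criterion: 4, specifier_feature: atypical}
  - {item_id: psychomotor_retardation, label: Moving or talking slowly, scale: binary, dsm_criterion: 5, specifier_feature: melancholic}
  - {item_id: psychomotor_agitation, label: Fidgeting or pacing, scale: binary, dsm_criterion: 5, specifier_feature: melancholic}
  - {item_id: restlessness, label: Feelings of restlessness, scale: binary}
  - {item_id: fatigue, label: Fatigue or loss of energy, scale: binary, dsm_criterion: 6}
  - {item_id: worthlessness, label: Feelings of worthlessness, scale: binary, dsm_criterion: 7}
  - {item_id: guilt, label: Excessive or inappropriate guilt, scale: binary, dsm_criterion: 7, specifier_feature: melancholic}
  - {item_id: diminished_concentration, label: Trouble concentrating, scale: binary, dsm_criterion: 8}
  - {item_id: indecisiveness, label: Trouble making decisions, scale: binary, dsm_criterion: 8}
  - {item_id: death_ideation, label: Thoughts of death, scale: binary, dsm_criterion: 9}
  - {item_id: desire_to_die, label: Wanting to die, scale: binary, dsm_criterion: 9}
  - {item_id: suicidal_ideation, label: Thoughts of killing oneself, scale: binary, dsm_criterion: 9}
  - {item_id: suicide_attempt, label: Attempted suicide, scale: binary, dsm_criterion: 9}
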