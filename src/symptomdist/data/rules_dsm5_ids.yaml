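# Reconstructed DSM-5 melancholic/atypical feature rules over the ids_full
# item set, applied to profiles dichotomized at a configurable severity
# threshold.  Melancholic: gate of anhedonia or mood non-reactivity, plus at
# least three B-criterion features.  Atypical: at least two B-criterion
# features; the DSM-5 mood-reactivity gate is an ABSENCE requirement that
# this presence-based rule engine cannot express, so it is omitted here —
# a known limitation of this reconstruction.
rules:
  melancholic:
    feature_items:
      - [distinct_quality_of_mood]
      - [diurnal_variation_morning_worse]
      - [early_morning_insomnia]
      - [psychomotor_slowing, psychomotor_agitation]
      - [appetite_decrease, weight_decrease]
      - [self_criticism_blame]
    min_features: 3
    required_features:
      - [anhedonia, mood_nonreactivity]
  atypical:
    feature_items:
      - [appetite_increase, weight_increase]
      - [hypersomnia]
      - [leaden_paralysis]
      - [interpersonal_sensitivity]
    min_features: 2
    required_features: []
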