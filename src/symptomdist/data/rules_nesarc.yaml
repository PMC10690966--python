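# Proxy specifier definitions for a binary AUDADIS-IV-style inventory
# (audadis_mde_16), used when the inventory does not query the full DSM
# specifier feature sets.  Melancholic: at least three of five features,
# where a feature with several items (psychomotor retardation/agitation)
# counts once however many of its items are endorsed.  Atypical: hypersomnia
# and hyperphagia both present.  The melancholic-before-atypical hierarchy is
# applied by the classifier, not encoded here.
rules:
  melancholic:
    feature_items:
      - [anhedonia]
      - [psychomotor_retardation, psychomotor_agitation]
      - [guilt]
      - [early_morning_awakening]
      - [appetite_weight_decrease]
    min_features: 3
    required_features: []
  atypical:
    feature_items: []
    min_features: 0
    required_features:
      - [hypersomnia]
      - [appetite_weight_increase]
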