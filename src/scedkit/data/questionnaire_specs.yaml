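# Secondary-outcome questionnaire scoring specifications.
# Only total scores are modelled; item text is out of scope.
hapys:               # Health Anxiety by Proxy Scale
  n_items: 26
  item_min: 0
  item_max: 4
  aggregation: sum   # total 0-104
hapys_impact:        # HAPYS impact section
  n_items: 6
  item_min: 0
  item_max: 3
  aggregation: sum   # total 0-18
acrs_protect:        # Adult Responses to Children's Symptoms, protect subscale
  n_items: 13
  item_min: 0
  item_max: 4
  aggregation: mean  # average 0-4
acrs_monitor:        # Adult Responses to Children's Symptoms, monitor subscale
  n_items: 4
  item_min: 0
  item_max: 4
  aggregation: mean  # average 0-4
pcs_p:               # Pain Catastrophizing Scale, parent version
  n_items: 13
  item_min: 0
  item_max: 4
  aggregation: sum   # total 0-52
wi6r:                # Whiteley Index 6, revised
  n_items: 6
  item_min: 0
  item_max: 4
  aggregation: sum   # total 0-24
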