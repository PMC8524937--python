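[
  {"scenario_id": "#1", "prep_offset_weeks": 0, "length_weeks": 8, "prep_reduction": 0.30, "treat_reduction": 0.30},
  {"scenario_id": "#2", "prep_offset_weeks": 0, "length_weeks": 8, "prep_reduction": 0.50, "treat_reduction": 0.30},
  {"scenario_id": "#3", "prep_offset_weeks": 4, "length_weeks": 8, "prep_reduction": 0.30, "treat_reduction": 0.30},
  {"scenario_id": "#4", "prep_offset_weeks": 2, "length_weeks": 8, "prep_reduction": 0.30, "treat_reduction": 0.30},
  {"scenario_id": "#5", "prep_offset_weeks": 1, "length_weeks": 8, "prep_reduction": 0.30, "treat_reduction": 0.30},
  {"scenario_id": "#6", "prep_offset_weeks": 0, "length_weeks": 6, "prep_reduction": 0.50, "treat_reduction": 0.50},
  {"scenario_id": "#7", "prep_offset_weeks": 1, "length_weeks": 6, "prep_reduction": 0.50, "treat_reduction": 0.50},
  {"scenario_id": "#8", "prep_offset_weeks": 1, "length_weeks": 4, "prep_reduction": 0.70, "treat_reduction": 0.70},
  {"scenario_id": "#9", "prep_offset_weeks": 4, "length_weeks": 4, "prep_reduction": 0.70, "treat_reduction": 0.70}
]
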