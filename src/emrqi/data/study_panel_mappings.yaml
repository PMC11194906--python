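# SYNTHETIC calibration of the expert-panel coefficient mappings.
# The published study reports panel-level Cs = 0.88 and Ca = 0.90 but not the
# score tables behind them; this familiarity mapping is calibrated so that a
# panel of 7 "very familiar" and 9 "relatively familiar" experts reproduces
# Cs = 0.88 exactly.  The judgment table is the conventional Delphi table.
familiarity_scores:
  very_familiar: 0.97
  relatively_familiar: 0.81
judgment_table:
  practical_experience: {high: 0.5, medium: 0.4, low: 0.3}
  theoretical_analysis: {high: 0.3, medium: 0.2, low: 0.1}
  peer_knowledge: {high: 0.1, medium: 0.1, low: 0.1}
  intuition: {high: 0.1, medium: 0.1, low: 0.1}
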