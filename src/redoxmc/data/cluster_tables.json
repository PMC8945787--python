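{
  "table1_bold": {
    "FX": [2.46, 2.44, 2.44, 2.35],
    "FA": [2.46, 2.48, 2.52, 2.34],
    "FB": [2.44, 2.49, 2.50, 2.35]
  },
  "table1_avg": {"FX": 2.42, "FA": 2.45, "FB": 2.45},
  "table3_terms": {
    "FX": {"dG_bkbn": 15.10, "ddG_rxn": 79.99, "dG_resd": -104.32, "dEm": 12.81},
    "FA": {"dG_bkbn": 17.03, "ddG_rxn": 75.70, "dG_resd": -96.66, "dEm": 4.35},
    "FB": {"dG_bkbn": 16.61, "ddG_rxn": 76.27, "dG_resd": -91.77, "dEm": 4.14}
  },
  "em_values": {
    "em_sol_mV": -170.0,
    "calculated_mV": {"FX": -715.0, "FA": -355.0, "FB": -346.0}
  }
}
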