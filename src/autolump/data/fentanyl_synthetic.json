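{
  "name": "fentanyl-17-state-topology",
  "provenance": "synthetic_placeholder",
  "note": "17-state fentanyl PBPK topology (arterial, venous, lung, perfused tissues, liver/spleen/gut with deep sub-compartments, portal drainage, hepatic elimination). Numeric Q/V/Kp/clearance/exchange values are SYNTHETIC placeholders: plausible adult-human physiology and lipophilic-opioid partitioning, NOT the published fentanyl parameter set. Units: minutes, litres, micrograms.",
  "output_state": "arterial",
  "dose": {"state": "arterial", "amount": 750.0},
  "arterial_volume": 1.7,
  "venous_volume": 3.9,
  "cardiac_output": 5.617,
  "lung": {"name": "lung", "V": 0.53, "Kp": 3.5},
  "physiology": [
    {"name": "brain", "Q": 0.76, "V": 1.45, "Kp": 4.0},
    {"name": "heart", "Q": 0.24, "V": 0.33, "Kp": 3.5},
    {"name": "kidney", "Q": 1.24, "V": 0.31, "Kp": 4.5},
    {"name": "muscle", "Q": 0.86, "V": 29.0, "Kp": 3.0},
    {"name": "skin", "Q": 0.32, "V": 3.4, "Kp": 4.0},
    {"name": "adipose", "Q": 0.28, "V": 13.5, "Kp": 35.0},
    {"name": "carcass", "Q": 0.45, "V": 9.3, "Kp": 4.0},
    {"name": "liver", "Q": 0.39, "V": 1.8, "Kp": 4.5, "clearance": 0.95,
     "sub_compartments": [
       {"name": "L_cpt_1", "V": 0.9, "k_in": 0.05, "k_out": 0.02}
     ]},
    {"name": "spleen", "Q": 0.077, "V": 0.19, "Kp": 4.0, "drains_to": "liver",
     "sub_compartments": [
       {"name": "S_cpt_1", "V": 0.1, "k_in": 0.08, "k_out": 0.03}
     ]},
    {"name": "gut", "Q": 1.0, "V": 1.1, "Kp": 5.0, "drains_to": "liver",
     "sub_compartments": [
       {"name": "G_cpt_1", "V": 0.55, "k_in": 0.06, "k_out": 0.025},
       {"name": "G_cpt_2", "V": 0.55, "k_in": 0.03, "k_out": 0.01}
     ]}
  ]
}
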