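{
 "agents": [
  {"agent_id": "DFO",    "true_dm": 16.902, "true_m": 1.5, "denticity_class": "hexadentate"},
  {"agent_id": "SIH",    "true_dm": 14.004, "true_m": 1.5, "denticity_class": "tridentate"},
  {"agent_id": "NHAPI",  "true_dm": 19.137, "true_m": 1.5, "denticity_class": "tridentate"},
  {"agent_id": "Dp44mT", "true_dm": 0.004,  "true_m": 2.0, "denticity_class": "tridentate"},
  {"agent_id": "TMX",    "true_dm": 14.5,   "true_m": 2.0}
 ],
 "pairs": [
  {"agent_a": "NHAPI",  "agent_b": "TMX", "ci_star": 0.5},
  {"agent_a": "Dp44mT", "agent_b": "TMX", "ci_star": 0.7},
  {"agent_a": "DFO",    "agent_b": "TMX", "ci_star": 1.5}
 ],
 "plate": {"n_experiments": 4, "replicates_per_dose": 3, "noise_sd": 0.05,
           "control_wells": 8, "multipliers": [0.125, 0.25, 0.5, 1, 2, 4]}
}
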