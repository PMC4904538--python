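[
  {"fiber_type": "commercial_chrysotile", "scenario": "lifetime", "relative_potency": 1},
  {"fiber_type": "amosite", "scenario": "lifetime", "relative_potency": 100},
  {"fiber_type": "crocidolite", "scenario": "lifetime", "relative_potency": 500},
  {"fiber_type": "commercial_chrysotile", "scenario": "occupational", "relative_potency": 1},
  {"fiber_type": "amosite", "scenario": "occupational", "relative_potency": 35},
  {"fiber_type": "crocidolite", "scenario": "occupational", "relative_potency": 200},
  {"fiber_type": "commercial_chrysotile", "scenario": "example", "relative_potency": 1},
  {"fiber_type": "generic_amphibole", "scenario": "example", "relative_potency": 50}
]
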