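[
 {"ligandId": "407", "targetSpecies": "Human", "affinityParameter": "pKi",
  "affinity": 8.0, "action": "Antagonist", "targetGeneSymbol": "GENC",
  "targetUniprot": "P10003"},
 {"ligandId": "407", "targetSpecies": "Mouse", "affinityParameter": "pKi",
  "affinity": 8.5, "action": "Antagonist", "targetGeneSymbol": "GENC",
  "targetUniprot": "P10003"}
]
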