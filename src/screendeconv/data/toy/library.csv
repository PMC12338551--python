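SMILES,Sample ID,Gene Symbol
CCO,T001,
CC(=O)Oc1ccccc1C(=O)O,T002,
CN1C=NC2=C1C(=O)N(C(=O)N2C)C,T003,
CCN.Cl,T004,
c1ccccc1O,T005,
xyz(,T006,
CCCCO,T007,
CCC(=O)O,T008,GENA
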