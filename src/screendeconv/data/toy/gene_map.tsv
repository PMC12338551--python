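symbol	uniprot
GENA	P10001
GENB	P10002
GENC	P10003
GEND	P10004
GENE	P10005
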