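SET001	toy mechanism one	GENA	GENB	GENC
SET002	toy mechanism two	GEND	GENE
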