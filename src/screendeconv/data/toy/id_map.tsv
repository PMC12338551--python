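inchikey	source	source_id
LFQSCWFLJHTTHZ-UHFFFAOYSA-N	drugbank	DB00001
BSYNRYMUTXBXSQ-UHFFFAOYSA-N	chembl	CHEMBL25
RYYVLZVUVIJVGH-UHFFFAOYSA-N	iuphar	407
QUSNBJAOOMFDIB-UHFFFAOYSA-N	pubchem	6341
ISWSIDIOOBJBQZ-UHFFFAOYSA-N	pharmgkb	PA10040
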