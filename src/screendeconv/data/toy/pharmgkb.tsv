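Entity1_id	Entity1_name	Entity1_type	Entity2_id	Entity2_name	Entity2_type	Evidence	Association	PK	PD
PA10040	phenol	Chemical	PGK5	GENE	Gene	ClinicalAnnotation	associated	yes
PA10040	phenol	Chemical	PGK9	NOT_IN_MAP	Gene	ClinicalAnnotation	associated	yes
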