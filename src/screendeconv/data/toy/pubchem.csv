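cid,target_accession,target_taxonomy,activity_type,activity_value,activity_unit
6341,P10004,Homo sapiens,IC50,500,nM
6341,P10004,Homo sapiens,IC50,50,uM
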