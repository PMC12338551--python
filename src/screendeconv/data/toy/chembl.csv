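molecule_chembl_id,target_accession,target_organism,target_type,assay_type,standard_type,pchembl_value,action_type
CHEMBL25,P10002,Homo sapiens,SINGLE PROTEIN,B,IC50,6.2,INHIBITOR
CHEMBL25,P10003,Homo sapiens,SINGLE PROTEIN,B,IC50,4.9,
CHEMBL25,P10002,Homo sapiens,PROTEIN COMPLEX,B,IC50,7.0,
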