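{
  "_comment": "Hand-counted stage expectations for the toy bundle. Evidence surviving the filters: T001-P10001 (drugbank, known-action yes), T002-P10002 (chembl pChEMBL 6.2), T003-P10003 (iuphar pKi 8 Human), T004-P10004 (pubchem IC50 500 nM), T005-P10005 (pharmgkb GENE), T008-P10001 (user GENA). Filtered: drugbank unknown-action, chembl pChEMBL 4.9 and PROTEIN COMPLEX, iuphar Mouse, pubchem 50 uM, pharmgkb NOT_IN_MAP.",
  "standardize": {"compounds_in": 8, "parse_ok": 7, "parse_failed": 1},
  "hits": {"hit_ids": 3},
  "map": {"compounds_with_source_ids": 5, "malformed_mapping_rows": 0},
  "annotate": {
    "evidence_records": 6,
    "per_source": {"drugbank": 1, "pharmgkb": 1, "iuphar": 1,
                   "pubchem": 1, "chembl": 1, "user": 1}
  },
  "collate": {"pairs": 6, "unique_targets": 5,
              "resolved_compounds": 6, "unresolved_compounds": 2},
  "enrich": {"hit_pairs": 3, "hit_targets": 3, "targets_tested": 3,
             "enriched_fdr": 0, "enriched_p": 0},
  "classify": {"enriched_targets_used": 0, "classified_hits": 0, "calls": 0},
  "expected_p_values": {"P10001": 0.8, "P10002": 0.5, "P10003": 0.5},
  "expected_q_values": {"P10001": 0.8, "P10002": 0.75, "P10003": 0.75}
}
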