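# Offline dump dialects

Each adapter reads a minimal faithful subset of its source's public
schema. Real exports can be reshaped to these dialects with a few
column renames. All tabular files are UTF-8; TSV where the source
distributes TSV, CSV otherwise.

## Identifier map (`id_map.tsv`, UniChem-style)

TSV columns: `inchikey`, `source`, `source_id`. One row per
key/source/id triple; `source` ∈ {drugbank, pharmgkb, iuphar, pubchem,
chembl}. Keys may be full-structure or salt-stripped parent keys;
lookup tries the full key first, then the parent.

## Gene map (`gene_map.tsv`, Pharos-style)

TSV columns: `symbol`, `uniprot`. Resolves gene symbols (PharmGKB rows,
user annotations) to UniProt accessions.

## DrugBank-style XML

```xml
<drugbank>
  <drug>
    <drugbank-id>DB00001</drugbank-id>
    <targets>
      <target>
        <known-action>yes|no|unknown</known-action>
        <organism>Humans</organism>
        <polypeptide>
          <gene-name>HRH1</gene-name>
          <external-identifiers>
            <external-identifier>
              <resource>UniProtKB</resource>
              <identifier>P35367</identifier>
            </external-identifier>
          </external-identifiers>
        </polypeptide>
      </target>
    </targets>
  </drug>
</drugbank>
```

## PharmGKB-style relationships TSV

Columns: `Entity1_id`, `Entity1_name`, `Entity1_type`, `Entity2_id`,
`Entity2_name`, `Entity2_type`, `Evidence`, `Association`, `PK`, `PD`.
Rows where one entity is a Chemical (PA id) and the other a Gene
(symbol in the name column) are used; either orientation works.

## IUPHAR-style interactions JSON

A JSON array of objects with fields `ligandId`, `targetSpecies`,
`affinityParameter` (pKi, pIC50, ...), `affinity` (−log10 molar),
`action` (curator mechanism string, may be empty), `targetGeneSymbol`,
`targetUniprot`. The accession is carried in the file so parsing needs
no live symbol-resolution service.

## PubChem-style bioactivity CSV

Columns: `cid`, `target_accession`, `target_taxonomy` (name or taxid),
`activity_type` (IC50, EC50, Ki, ...), `activity_value`,
`activity_unit` (pM/nM/uM/mM/M).

## ChEMBL-style activity CSV

Columns: `molecule_chembl_id`, `target_accession`, `target_organism`,
`target_type`, `assay_type` (B/F or binding/functional),
`standard_type`, `pchembl_value`, `action_type`.

## Gene sets (GMT)

Standard GMT: `term_id <TAB> description <TAB> member1 <TAB> member2 ...`,
one set per line, members as gene symbols.

## Hit list

Plain text, one library `Sample ID` per line.
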