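"""Per-source annotation-dump parsers producing harmonized evidence records.

Five public resources contribute compound-target evidence: DrugBank and
PharmGKB are curated association databases (no activity values), while
IUPHAR/BPS Guide to Pharmacology, PubChem and ChEMBL carry quantitative
bioactivity. Each parser reads an offline dump in a minimal faithful
dialect of the source's public schema (documented in
``docs/fixture_dialects.md``), applies that source's filters — human
targets only, bioactivity at 10 uM or better, ChEMBL pChEMBL >= 5 on
single-protein binding/functional assays — and emits
:class:`CompoundTargetRecord` rows keyed by library ``sample_id``.

Compound resolution goes through a UniChem-style identifier-mapping
table (InChIKey -> per-source compound id). A library compound matches a
source id through its full (salt-containing) InChIKey first, falling
back to the salt-stripped parent key, so salt-form registrations on
either side still connect.
"""

from __future__ import annotations

import json
import logging
import re
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from lxml import etree

from .chem import INCHIKEY_RE, CompoundRecord

logger = logging.getLogger(__name__)

SOURCES = ("drugbank", "pharmgkb", "iuphar", "pubchem", "chembl", "user")
CURATED_SOURCES = frozenset({"drugbank", "pharmgkb", "user"})
BIOACTIVITY_SOURCES = frozenset({"iuphar", "pubchem", "chembl"})

#: inclusive potency cutoff for bioactivity-based annotations, mol/L (10 uM)
ACTIVITY_CUTOFF_MOLAR = 1.0e-5
#: inclusive pChEMBL floor; pChEMBL 5 is the 10 uM cutoff on the -log10 scale
PCHEMBL_MIN = 5.0

_HUMAN_TOKENS = {"human", "humans", "homo sapiens", "9606"}

#: concentration-typed potency parameters a molar cutoff is defined for
_CONC_TYPE_RE = re.compile(r"^(IC|EC|AC|XC)\d+$|^(KI|KD|KB|KM|KA|POTENCY)$", re.I)

_UNIT_TO_MOLAR = {
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "μm": 1e-6,
    "nm": 1e-9, "pm": 1e-12,
}


@dataclass
class CompoundTargetRecord:
    """One harmonized compound-target evidence row from a single source."""

    sample_id: str
    source: str
    uniprot_acc: str
    gene_symbol: Optional[str] = None
    activity_type: Optional[str] = None
    activity_value_molar: Optional[float] = None
    pchembl: Optional[float] = None
    action_field: Optional[str] = None
    assay_class: Optional[str] = None
    organism: str = "human"

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")

    def key(self) -> tuple[str, str]:
        return (self.sample_id, self.uniprot_acc)


class SourceIdMap:
    """Library-restricted view of an InChIKey -> per-source compound-id table.

    ``entries`` maps InChIKeys to ``{(source, source_id), ...}``. Per
    compound and per source, the full-structure key is consulted first
    and the parent key only if the full key has no id for that source.
    """

    def __init__(self, entries: dict[str, set[tuple[str, str]]],
                 records: Iterable[CompoundRecord]):
        self.entries = entries
        # (source, source_id) -> [sample_id, ...] restricted to the library
        self._reverse: dict[tuple[str, str], list[str]] = defaultdict(list)
        self._per_sample: dict[str, set[tuple[str, str]]] = {}
        for rec in records:
            if not rec.parse_ok:
                continue
            hits: set[tuple[str, str]] = set()
            for source in SOURCES:
                found = self._ids_for_key(rec.inchikey_full, source)
                if not found and rec.inchikey_parent != rec.inchikey_full:
                    found = self._ids_for_key(rec.inchikey_parent, source)
                hits.update(found)
            self._per_sample[rec.sample_id] = hits
            for pair in hits:
                self._reverse[pair].append(rec.sample_id)

    def _ids_for_key(self, key: Optional[str], source: str) -> set[tuple[str, str]]:
        if key is None:
            return set()
        return {(s, i) for (s, i) in self.entries.get(key, set()) if s == source}

    def sample_ids_for(self, source: str, source_id: str) -> list[str]:
        return self._reverse.get((source, source_id), [])

    def mappings_for(self, sample_id: str) -> set[tuple[str, str]]:
        return self._per_sample.get(sample_id, set())

    def resolved_sample_ids(self) -> set[str]:
        return {sid for sid, hits in self._per_sample.items() if hits}


def map_identifiers(records: list[CompoundRecord], mapping_table: str | Path,
                    stats: Optional[dict] = None) -> SourceIdMap:
    """Load a UniChem-style mapping table restricted to the given library.

    The table is tab-delimited with columns ``inchikey``, ``source``,
    ``source_id``. Malformed rows (bad key, unknown source, missing id)
    are skipped with a warning and counted in ``stats['malformed_mapping_rows']``.
    """
    entries: dict[str, set[tuple[str, str]]] = defaultdict(set)
    malformed = 0
    df = pd.read_csv(mapping_table, sep="\t", dtype=str, keep_default_na=False)
    for col in ("inchikey", "source", "source_id"):
        if col not in df.columns:
            raise ValueError(f"mapping table missing column {col!r}")
    for row in df.itertuples(index=False):
        key, source, source_id = row.inchikey.strip(), row.source.strip(), row.source_id.strip()
        if not INCHIKEY_RE.match(key) or source not in SOURCES or not source_id:
            logger.warning("skipping malformed mapping row: %s", (key, source, source_id))
            malformed += 1
            continue
        entries[key].add((source, source_id))
    if stats is not None:
        stats["malformed_mapping_rows"] = stats.get("malformed_mapping_rows", 0) + malformed
    return SourceIdMap(dict(entries), records)


def load_gene_map(path: str | Path) -> dict[str, str]:
    """Gene symbol -> UniProt accession table (Pharos-style TSV)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("symbol", "uniprot"):
        if col not in df.columns:
            raise ValueError(f"gene map missing column {col!r}")
    return {r.symbol.strip(): r.uniprot.strip() for r in df.itertuples(index=False)
            if r.symbol.strip() and r.uniprot.strip()}


def _is_human(token: str) -> bool:
    return token.strip().lower() in _HUMAN_TOKENS


def _bump(stats: Optional[dict], key: str, n: int = 1) -> None:
    if stats is not None:
        stats[key] = stats.get(key, 0) + n


def parse_drugbank(xml_path: str | Path, id_map: SourceIdMap,
                   stats: Optional[dict] = None) -> list[CompoundTargetRecord]:
    """Curated drug-target associations from a DrugBank-style XML dump.

    Targets whose ``known-action`` attribute is ``unknown`` (no evidence the
    pharmacological action runs through that target) and non-human targets
    are filtered out; the UniProt accession is read from the target
    polypeptide's external identifiers.
    """
    tree = etree.parse(str(xml_path))
    records: list[CompoundTargetRecord] = []
    for drug in tree.getroot().iter("drug"):
        db_id_el = drug.find("drugbank-id")
        if db_id_el is None or not db_id_el.text:
            continue
        sample_ids = id_map.sample_ids_for("drugbank", db_id_el.text.strip())
        if not sample_ids:
            continue
        for target in drug.iter("target"):
            known_action = (target.findtext("known-action") or "").strip().lower()
            if known_action == "unknown":
                continue
            organism = target.findtext("organism") or ""
            if not _is_human(organism):
                continue
            acc = None
            gene = None
            poly = target.find("polypeptide")
            if poly is not None:
                gene = (poly.findtext("gene-name") or "").strip() or None
                for ext in poly.iter("external-identifier"):
                    resource = (ext.findtext("resource") or "").lower()
                    if "uniprot" in resource:
                        acc = (ext.findtext("identifier") or "").strip()
                        break
            if not acc:
                logger.warning("drugbank target without UniProt id under drug %s",
                               db_id_el.text)
                _bump(stats, "drugbank_targets_without_uniprot")
                continue
            for sid in sample_ids:
                records.append(CompoundTargetRecord(
                    sample_id=sid, source="drugbank", uniprot_acc=acc,
                    gene_symbol=gene))
    return records


def parse_pharmgkb(tsv_path: str | Path, id_map: SourceIdMap,
                   gene_map: str | Path | dict[str, str],
                   stats: Optional[dict] = None) -> list[CompoundTargetRecord]:
    """Chemical-gene relationships from a PharmGKB-style relationships TSV.

    Rows linking a mapped chemical to a gene yield one record each; gene
    symbols resolve to UniProt accessions through the Pharos-style gene
    map and unresolvable symbols are dropped (counted).
    """
    symbols = gene_map if isinstance(gene_map, dict) else load_gene_map(gene_map)
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    records: list[CompoundTargetRecord] = []
    for row in df.itertuples(index=False):
        ents = [(row.Entity1_id, row.Entity1_name, row.Entity1_type),
                (row.Entity2_id, row.Entity2_name, row.Entity2_type)]
        chem = next((e for e in ents if e[2].strip().lower() == "chemical"), None)
        gene = next((e for e in ents if e[2].strip().lower() == "gene"), None)
        if chem is None or gene is None:
            continue
        sample_ids = id_map.sample_ids_for("pharmgkb", chem[0].strip())
        if not sample_ids:
            continue
        symbol = gene[1].strip()
        acc = symbols.get(symbol)
        if acc is None:
            _bump(stats, "pharmgkb_unresolved_symbols")
            continue
        for sid in sample_ids:
            records.append(CompoundTargetRecord(
                sample_id=sid, source="pharmgkb", uniprot_acc=acc,
                gene_symbol=symbol))
    return records


def parse_iuphar(json_path: str | Path, id_map: SourceIdMap,
                 stats: Optional[dict] = None,
                 activity_cutoff_molar: float = ACTIVITY_CUTOFF_MOLAR,
                 ) -> list[CompoundTargetRecord]:
    """Ligand-target interactions from an IUPHAR-style interactions JSON.

    Affinities arrive on the -log10 molar scale (pKi, pIC50, ...) and are
    converted to mol/L via 10**(-p); records above the 10 uM cutoff or
    against non-human targets are removed. The curators' ``action`` string
    (Agonist, Antagonist, ...) is carried into ``action_field`` for the
    downstream mechanism classifier.
    """
    with open(json_path) as fh:
        interactions = json.load(fh)
    records: list[CompoundTargetRecord] = []
    for row in interactions:
        sample_ids = id_map.sample_ids_for("iuphar", str(row.get("ligandId", "")).strip())
        if not sample_ids:
            continue
        if not _is_human(str(row.get("targetSpecies", ""))):
            continue
        try:
            p_affinity = float(row["affinity"])
        except (KeyError, TypeError, ValueError):
            _bump(stats, "iuphar_unparseable_affinity")
            continue
        molar = 10.0 ** (-p_affinity)
        if molar > activity_cutoff_molar:
            continue
        acc = str(row.get("targetUniprot", "")).strip()
        if not acc:
            _bump(stats, "iuphar_missing_uniprot")
            continue
        param = str(row.get("affinityParameter", "")).strip() or None
        action = str(row.get("action", "")).strip() or None
        for sid in sample_ids:
            records.append(CompoundTargetRecord(
                sample_id=sid, source="iuphar", uniprot_acc=acc,
                gene_symbol=str(row.get("targetGeneSymbol", "")).strip() or None,
                activity_type=param, activity_value_molar=molar,
                action_field=action))
    return records


def parse_pubchem(table_path: str | Path, id_map: SourceIdMap,
                  stats: Optional[dict] = None,
                  activity_cutoff_molar: float = ACTIVITY_CUTOFF_MOLAR,
                  ) -> list[CompoundTargetRecord]:
    """Bioactivity rows from a PubChem-style bioactivity table (CSV).

    Only concentration-typed potency parameters (IC50/EC50/AC50/XC50/Ki/
    Kd/... ) are kept, since a molar cutoff is undefined for qualitative
    outcomes; values are normalized from nM/uM/mM to mol/L and rows above
    10 uM or against non-human taxa are removed. Unknown unit tokens drop
    the row (counted).
    """
    df = pd.read_csv(table_path, dtype=str, keep_default_na=False)
    records: list[CompoundTargetRecord] = []
    for row in df.itertuples(index=False):
        sample_ids = id_map.sample_ids_for("pubchem", row.cid.strip())
        if not sample_ids:
            continue
        if not _is_human(row.target_taxonomy):
            continue
        act_type = row.activity_type.strip()
        if not _CONC_TYPE_RE.match(act_type):
            _bump(stats, "pubchem_nonconcentration_rows")
            continue
        unit = row.activity_unit.strip().lower()
        factor = _UNIT_TO_MOLAR.get(unit)
        if factor is None:
            logger.warning("pubchem row with unconvertible unit %r dropped", unit)
            _bump(stats, "pubchem_unknown_units")
            continue
        try:
            molar = float(row.activity_value) * factor
        except ValueError:
            _bump(stats, "pubchem_unparseable_values")
            continue
        if molar > activity_cutoff_molar:
            continue
        acc = row.target_accession.strip()
        if not acc:
            continue
        for sid in sample_ids:
            records.append(CompoundTargetRecord(
                sample_id=sid, source="pubchem", uniprot_acc=acc,
                activity_type=act_type, activity_value_molar=molar))
    return records


def parse_chembl(extract_path: str | Path, id_map: SourceIdMap,
                 stats: Optional[dict] = None,
                 pchembl_min: float = PCHEMBL_MIN) -> list[CompoundTargetRecord]:
    """Activity rows from a ChEMBL-style extract (CSV).

    Keeps human, single-protein targets from binding or functional assays
    with pChEMBL >= 5 (pChEMBL = -log10 molar IC50/XC50/EC50/AC50/Ki/Kd/
    Potency, so 5 is the 10 uM cutoff). Rows without a pChEMBL value are
    not potency measurements and are dropped. ``action_type`` is carried
    into ``action_field``.
    """
    df = pd.read_csv(extract_path, dtype=str, keep_default_na=False)
    records: list[CompoundTargetRecord] = []
    assay_map = {"b": "binding", "binding": "binding",
                 "f": "functional", "functional": "functional"}
    for row in df.itertuples(index=False):
        sample_ids = id_map.sample_ids_for("chembl", row.molecule_chembl_id.strip())
        if not sample_ids:
            continue
        if not _is_human(row.target_organism):
            continue
        if row.target_type.strip().upper() != "SINGLE PROTEIN":
            continue
        assay_class = assay_map.get(row.assay_type.strip().lower())
        if assay_class is None:
            continue
        try:
            pchembl = float(row.pchembl_value)
        except ValueError:
            _bump(stats, "chembl_missing_pchembl")
            continue
        if pchembl < pchembl_min:
            continue
        acc = row.target_accession.strip()
        if not acc:
            continue
        for sid in sample_ids:
            records.append(CompoundTargetRecord(
                sample_id=sid, source="chembl", uniprot_acc=acc,
                activity_type=row.standard_type.strip() or None,
                activity_value_molar=10.0 ** (-pchembl), pchembl=pchembl,
                action_field=row.action_type.strip() or None,
                assay_class=assay_class))
    return records


def attach_user_annotations(records: list[CompoundRecord],
                            gene_map: str | Path | dict[str, str],
                            stats: Optional[dict] = None) -> list[CompoundTargetRecord]:
    """Turn user-supplied gene symbols on library rows into evidence records.

    A blank Gene Symbol column contributes nothing (and is not an error);
    symbols missing from the gene map are dropped with a count.
    """
    symbols = gene_map if isinstance(gene_map, dict) else load_gene_map(gene_map)
    out: list[CompoundTargetRecord] = []
    for rec in records:
        if not rec.user_gene_symbol:
            continue
        acc = symbols.get(rec.user_gene_symbol)
        if acc is None:
            _bump(stats, "user_unresolved_symbols")
            continue
        out.append(CompoundTargetRecord(
            sample_id=rec.sample_id, source="user", uniprot_acc=acc,
            gene_symbol=rec.user_gene_symbol))
    return out


def parse_all_sources(paths: dict[str, str | Path], id_map: SourceIdMap,
                      library: list[CompoundRecord],
                      gene_map: dict[str, str],
                      stats: Optional[dict] = None,
                      activity_cutoff_molar: float = ACTIVITY_CUTOFF_MOLAR,
                      pchembl_min: float = PCHEMBL_MIN) -> list[CompoundTargetRecord]:
    """Run every adapter whose input path is present; concatenate records."""
    records: list[CompoundTargetRecord] = []
    if "drugbank" in paths:
        records += parse_drugbank(paths["drugbank"], id_map, stats)
    if "pharmgkb" in paths:
        records += parse_pharmgkb(paths["pharmgkb"], id_map, gene_map, stats)
    if "iuphar" in paths:
        records += parse_iuphar(paths["iuphar"], id_map, stats, activity_cutoff_molar)
    if "pubchem" in paths:
        records += parse_pubchem(paths["pubchem"], id_map, stats, activity_cutoff_molar)
    if "chembl" in paths:
        records += parse_chembl(paths["chembl"], id_map, stats, pchembl_min)
    records += attach_user_annotations(library, gene_map, stats)
    return records


_RECORD_COLUMNS = ["sample_id", "source", "uniprot_acc", "gene_symbol",
                   "activity_type", "activity_value_molar", "pchembl",
                   "action_field", "assay_class", "organism"]


def records_to_frame(records: list[CompoundTargetRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [[getattr(r, c) for c in _RECORD_COLUMNS] for r in records],
        columns=_RECORD_COLUMNS,
    )


def write_source_metadata(records: list[CompoundTargetRecord],
                          out_dir: str | Path) -> None:
    """Per-source evidence CSVs, one file per annotation resource."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = records_to_frame(records)
    for source in SOURCES:
        sub = frame[frame["source"] == source]
        if len(sub):
            sub.to_csv(out_dir / f"annotations_{source}.csv", index=False)
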