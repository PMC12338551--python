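"""Compound standardization and salt-aware identifier generation.

Screening libraries arrive as SMILES strings of varying quality: salt
forms, protonation-state variants and outright unparseable entries are
common. Cross-database identifier mapping works on InChIKeys, so every
library entry is normalized once here and carries two keys afterwards —
one for the structure as supplied (salt included) and one for the
salt-stripped parent — which lets downstream identifier lookup match
whichever form the annotation source registered.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: 14-char skeleton block, 10-char proton/stereo block, 1-char version flag.
INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

LIBRARY_SMILES_COL = "SMILES"
LIBRARY_ID_COL = "Sample ID"
LIBRARY_GENE_COL = "Gene Symbol"


class SchemaError(ValueError):
    """Input table does not carry the required column headers."""


@dataclass
class CompoundRecord:
    """One screening-library entry with standardized structure and identifiers.

    ``inchikey_full`` hashes the normalized structure including any salt
    fragments; ``inchikey_parent`` hashes the salt-stripped parent and
    equals ``inchikey_full`` for single-fragment structures. Both are
    ``None`` when the SMILES did not parse (``parse_ok`` False) — such
    entries are retained, never dropped, so library counts are conserved.
    """

    sample_id: str
    smiles_raw: str
    smiles_canonical: Optional[str] = None
    inchikey_full: Optional[str] = None
    inchikey_parent: Optional[str] = None
    user_gene_symbol: Optional[str] = None
    parse_ok: bool = False

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        for key in (self.inchikey_full, self.inchikey_parent):
            if key is not None and not INCHIKEY_RE.match(key):
                raise ValueError(f"malformed InChIKey: {key!r}")


def load_library(table_path: str | Path, require_gene_column: bool = False) -> list[CompoundRecord]:
    """Read a screening-library table into un-standardized records.

    Accepts CSV, TSV or Excel. Column headers must match exactly:
    ``SMILES``, ``Sample ID`` and (optionally) ``Gene Symbol``. Rows with
    a blank SMILES or blank Sample ID are kept with ``parse_ok=False``
    (blank Sample IDs get a positional placeholder so the row count is
    conserved).
    """
    table_path = Path(table_path)
    if not table_path.exists():
        raise IOError(f"library table not found: {table_path}")
    suffix = table_path.suffix.lower()
    if suffix in {".xlsx", ".xls"}:
        df = pd.read_excel(table_path, dtype=str)
    else:
        sep = "\t" if suffix in {".tsv", ".tab", ".txt"} else ","
        df = pd.read_csv(table_path, sep=sep, dtype=str, keep_default_na=False)
    df = df.fillna("")

    required = [LIBRARY_SMILES_COL, LIBRARY_ID_COL]
    if require_gene_column:
        required.append(LIBRARY_GENE_COL)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {table_path.name}")

    has_gene = LIBRARY_GENE_COL in df.columns
    i_smiles = df.columns.get_loc(LIBRARY_SMILES_COL)
    i_id = df.columns.get_loc(LIBRARY_ID_COL)
    i_gene = df.columns.get_loc(LIBRARY_GENE_COL) if has_gene else None
    records: list[CompoundRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        smiles = str(row[i_smiles]).strip()
        sample_id = str(row[i_id]).strip()
        gene = str(row[i_gene]).strip() if has_gene else ""
        rec = CompoundRecord(
            sample_id=sample_id or f"__row_{i}__",
            smiles_raw=smiles,
            user_gene_symbol=gene or None,
            parse_ok=False,
        )
        if not sample_id or not smiles:
            rec.parse_ok = False  # flagged, not dropped
        records.append(rec)
    return records


def standardize_structure(smiles_raw: str) -> tuple[Optional[str], bool]:
    """Normalize a SMILES string to a canonical form.

    Applies the RDKit cleanup transformations (explicit-hydrogen removal,
    functional-group normalization, metal disconnection, reionization)
    and returns the canonical SMILES of the result. The output is a fixed
    point: re-standardizing it returns the identical string. Unparseable
    input yields ``(None, False)``; no exception escapes.
    """
    if not smiles_raw or not smiles_raw.strip():
        return None, False
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        return None, False
    try:
        mol = rdMolStandardize.Cleanup(mol)
        canonical = Chem.MolToSmiles(mol)
    except Exception:  # noqa: BLE001 - RDKit raises various internal types
        return None, False
    if not canonical:
        return None, False
    return canonical, True


class EmptyParentError(ValueError):
    """Salt stripping removed every fragment (no organic parent remains)."""


def strip_salt_parent(smiles_canonical: str) -> str:
    """Return the canonical SMILES of the salt-stripped parent structure.

    The parent is the largest organic fragment: most heavy atoms among
    fragments containing at least one carbon, ties broken by canonical-
    SMILES lexicographic order. Simple protonation states are neutralized
    after fragment selection. Single-fragment carbon-bearing inputs come
    back unchanged (up to neutralization). A structure with no
    carbon-bearing fragment (e.g. table salt) raises
    :class:`EmptyParentError`.
    """
    mol = Chem.MolFromSmiles(smiles_canonical)
    if mol is None:
        raise ValueError(f"not a valid canonical SMILES: {smiles_canonical!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    organic = [f for f in frags
               if any(a.GetSymbol() == "C" for a in f.GetAtoms())]
    if not organic:
        raise EmptyParentError(f"no organic parent fragment in {smiles_canonical!r}")
    parent = max(organic,
                 key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))
    # neutralize after fragment selection; counter-ion charges are gone with
    # their fragments so recombining charge on the parent is safe
    uncharger = rdMolStandardize.Uncharger()
    neutral = uncharger.uncharge(parent)
    pre, post = Chem.MolToSmiles(parent), Chem.MolToSmiles(neutral)
    if pre != post:
        logger.debug("charge neutralization: %s -> %s", pre, post)
    return post


def make_inchikeys(smiles_canonical: str, parent_smiles: Optional[str]) -> tuple[str, str]:
    """InChIKeys for the full (salt-containing) structure and its parent.

    For single-fragment structures both keys are identical. Raises
    ``ValueError`` if InChI generation fails; callers flag the record and
    exclude it from identifier mapping.
    """
    full = _inchikey(smiles_canonical)
    parent = _inchikey(parent_smiles) if parent_smiles else full
    return full, parent


def _inchikey(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot regenerate molecule from {smiles!r}")
    key = Chem.MolToInchiKey(mol)
    if not key or not INCHIKEY_RE.match(key):
        raise ValueError(f"InChI generation failed for {smiles!r}")
    return key


def standardize_record(rec: CompoundRecord) -> CompoundRecord:
    """Fill the standardized fields of one record in place and return it."""
    canonical, ok = standardize_structure(rec.smiles_raw)
    if not ok:
        rec.smiles_canonical = None
        rec.inchikey_full = None
        rec.inchikey_parent = None
        rec.parse_ok = False
        return rec
    rec.smiles_canonical = canonical
    try:
        try:
            parent = strip_salt_parent(canonical)
        except EmptyParentError:
            parent = None  # keep the full-structure key only
        full_key = _inchikey(canonical)
        parent_key = _inchikey(parent) if parent is not None else full_key
    except ValueError:
        rec.smiles_canonical = None
        rec.inchikey_full = None
        rec.inchikey_parent = None
        rec.parse_ok = False
        return rec
    rec.inchikey_full = full_key
    rec.inchikey_parent = parent_key
    rec.parse_ok = True
    return rec


def standardize_library(records: list[CompoundRecord]) -> list[CompoundRecord]:
    """Standardize every record; count is conserved, failures stay flagged."""
    return [standardize_record(r) for r in records]


_CSV_COLUMNS = ["sample_id", "smiles_raw", "smiles_canonical",
                "inchikey_full", "inchikey_parent", "user_gene_symbol", "parse_ok"]


def write_standardized_csv(records: list[CompoundRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for r in records:
            writer.writerow([
                r.sample_id, r.smiles_raw, r.smiles_canonical or "",
                r.inchikey_full or "", r.inchikey_parent or "",
                r.user_gene_symbol or "", str(r.parse_ok),
            ])


def read_standardized_csv(path: str | Path) -> list[CompoundRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(CompoundRecord(
                sample_id=row["sample_id"],
                smiles_raw=row["smiles_raw"],
                smiles_canonical=row["smiles_canonical"] or None,
                inchikey_full=row["inchikey_full"] or None,
                inchikey_parent=row["inchikey_parent"] or None,
                user_gene_symbol=row["user_gene_symbol"] or None,
                parse_ok=row["parse_ok"] == "True",
            ))
    return records
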