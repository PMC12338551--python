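"""Synthetic screening campaigns with planted ground truth.

Every input the pipeline consumes — library table, hit list, the five
annotation-source dumps, identifier map, gene map, gene sets — can be
generated here from a single seed, together with a manifest that records
each emitted evidence row and whether it should survive that source's
filters. The generator emulates the structure of real inputs (salt
forms, invalid SMILES, unmappable compounds, sub- and supra-threshold
activities, non-human decoy targets) while staying fully offline:
structures are composed from a curated alphabet of valid fragments, so
standardization exercises real chemistry without any downloads.

Association model: each (compound, target) pair is present independently
with probability ``baseline_rate``; for hit compounds the probability on
each planted target is multiplied by its fold factor (capped at 1).
Hits are a uniform random subset of the library. All randomness derives
from the one spec seed through fixed per-purpose streams, so bundles are
reproducible file by file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from lxml import etree

from . import chem
from .collate import CompoundTargetPair

# attachable scaffold suffixes; prefixed with an alkyl chain to make each
# (chain length, scaffold) structure unique
_SCAFFOLDS = [
    "c1ccccc1", "c1ccncc1", "c1ccc2ccccc2c1", "C(=O)O", "C(N)=O", "C#N",
    "C(F)(F)F", "N1CCOCC1", "N1CCNCC1", "C1CCCCC1", "c1ccc(O)cc1",
    "c1ccc(N)cc1", "c1ccc(Cl)cc1", "OCC(O)CO", "N(C)C", "S(=O)(=O)N",
    "c1cccnc1N", "C(=O)NC", "c1ccsc1", "c1cc[nH]c1", "C(=O)c1ccccc1",
    "Oc1ccncc1", "NC(=O)c1ccccc1", "n1ccnc1", "C1CCNCC1",
]
# carbon-free counter-ions only: an organic counter-ion larger than the
# parent would legitimately win largest-organic-fragment selection and
# alias distinct compounds onto one parent InChIKey
_SALTS = ["Cl", "Br", "OS(=O)(=O)O", "OP(=O)(O)O"]

_IUPHAR_PARAMS = ["pKi", "pIC50", "pEC50", "pKd"]
_PUBCHEM_TYPES = ["IC50", "EC50", "Ki", "Kd", "AC50"]
_CHEMBL_TYPES = ["IC50", "EC50", "Ki", "Kd", "Potency", "AC50"]
_ACTIONS = ["Antagonist", "Agonist", "Inhibitor", ""]
_CHEMBL_ACTIONS = ["INHIBITOR", "ANTAGONIST", "AGONIST", ""]

_STREAMS = {"structure": 1, "hits": 2, "assoc": 3, "source": 4,
            "activity": 5, "decoy": 6, "user": 7, "mapping": 8,
            "genesets": 9, "null": 10}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


def target_accession(j: int) -> str:
    return f"P{j:05d}"


def target_symbol(j: int) -> str:
    return f"TG{j}"


def sample_name(i: int) -> str:
    return f"CMPD{i:05d}"


@dataclass(frozen=True)
class SyntheticScreenSpec:
    """Parameters of a generated screening campaign.

    Defaults describe a mid-size bioactive-collection screen: a few
    thousand entries, a ~2% chance that any given compound carries an
    annotation for any given target, 5% of the library called as hits,
    and one mechanistic driver whose association rate among hits is
    five-fold the baseline.
    """

    n_compounds: int = 2000
    n_targets: int = 100
    baseline_rate: float = 0.02
    hit_fraction: float = 0.05
    planted_targets: tuple = ((0, 5.0),)
    source_mix: tuple = (("drugbank", 0.10), ("pharmgkb", 0.10),
                         ("iuphar", 0.20), ("pubchem", 0.30), ("chembl", 0.30))
    salt_fraction: float = 0.10
    invalid_fraction: float = 0.02
    unmapped_fraction: float = 0.05
    multi_source_prob: float = 0.20
    decoy_fraction: float = 0.15
    action_prob: float = 0.5
    gene_symbol_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_rate", "hit_fraction", "salt_fraction",
                     "invalid_fraction", "unmapped_fraction",
                     "multi_source_prob", "decoy_fraction", "action_prob",
                     "gene_symbol_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be positive")
        if self.hit_fraction * self.n_compounds < 1:
            raise ValueError("hit_fraction * n_compounds must be at least 1")
        for j, fold in self.planted_targets:
            if not 0 <= j < self.n_targets:
                raise ValueError(f"planted target index {j} out of range")
            if fold < 1:
                raise ValueError(f"planted fold must be >= 1, got {fold}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class ScreenBundle:
    """Paths of a generated bundle plus its ground-truth bookkeeping."""

    spec: SyntheticScreenSpec
    out_dir: Path
    paths: dict
    hit_ids: list
    surviving_pairs: set        # {(sample_id, uniprot_acc)} expected post-collation
    planted_accessions: list
    manifest: pd.DataFrame


def smiles_for_compound(i: int) -> str:
    chain = "C" * (1 + i // len(_SCAFFOLDS))
    return chain + _SCAFFOLDS[i % len(_SCAFFOLDS)]


def sample_associations(spec: SyntheticScreenSpec) -> tuple[list, set, list]:
    """Fast in-memory draw of the association model.

    Returns ``(associations, hit_ids, planted_accessions)`` where
    associations are (sample_id, uniprot_acc) tuples over all compounds,
    ignoring chemistry/mapping dropout (every compound is observable).
    """
    rng_h = _rng(spec.seed, "hits")
    rng_a = _rng(spec.seed, "assoc")
    n, t = spec.n_compounds, spec.n_targets
    n_hits = int(round(spec.hit_fraction * n))
    hit_idx = set(rng_h.choice(n, size=n_hits, replace=False).tolist())
    prob = np.full((n, t), spec.baseline_rate)
    for j, fold in spec.planted_targets:
        col = np.full(n, spec.baseline_rate)
        col[list(hit_idx)] = min(1.0, spec.baseline_rate * fold)
        prob[:, j] = col
    draws = rng_a.random((n, t)) < prob
    assoc = [(sample_name(i), target_accession(j)) for i, j in zip(*np.nonzero(draws))]
    hit_ids = {sample_name(i) for i in hit_idx}
    planted = [target_accession(j) for j, _ in spec.planted_targets]
    return assoc, hit_ids, planted


def associations_to_pairs(associations: list) -> list[CompoundTargetPair]:
    """Wrap bare (sample_id, accession) tuples as deduplicated pairs."""
    seen = {}
    for sid, acc in associations:
        if (sid, acc) not in seen:
            seen[(sid, acc)] = CompoundTargetPair(sample_id=sid, uniprot_acc=acc)
    return [seen[k] for k in sorted(seen)]


def generate_screen(spec: SyntheticScreenSpec, out_dir: str | Path) -> ScreenBundle:
    """Materialize a full fixture bundle for one synthetic campaign.

    Writes the library table, hit list, five source dumps, identifier and
    gene maps, a GMT file with one gene set per planted mechanism (plus
    decoy sets), and a manifest marking for every emitted evidence row
    whether it survives its source's filters. Running the real pipeline
    on the bundle must reproduce exactly the manifest's surviving pair
    set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng_s = _rng(spec.seed, "structure")
    rng_src = _rng(spec.seed, "source")
    rng_act = _rng(spec.seed, "activity")
    rng_dec = _rng(spec.seed, "decoy")
    rng_usr = _rng(spec.seed, "user")
    rng_map = _rng(spec.seed, "mapping")
    rng_gs = _rng(spec.seed, "genesets")

    n, t = spec.n_compounds, spec.n_targets
    associations, hit_ids, planted = sample_associations(spec)

    # --- compound roster: structures, salts, invalids, mapping dropout ---
    is_invalid = rng_s.random(n) < spec.invalid_fraction
    is_salt = rng_s.random(n) < spec.salt_fraction
    salt_pick = rng_s.integers(0, len(_SALTS), size=n)
    is_unmapped = rng_map.random(n) < spec.unmapped_fraction
    user_gene = rng_usr.random(n) < spec.gene_symbol_fraction
    user_target = rng_usr.integers(0, t, size=n)
    # a couple of deliberately unresolvable symbols to exercise the drop path
    user_bad = rng_usr.random(n) < 0.1

    smiles_raw, keys_full, keys_parent = [], [], []
    for i in range(n):
        if is_invalid[i]:
            smiles_raw.append(f"not_a_smiles_{i}(")
            keys_full.append(None)
            keys_parent.append(None)
            continue
        s = smiles_for_compound(i)
        if is_salt[i]:
            s = s + "." + _SALTS[salt_pick[i]]
        smiles_raw.append(s)
        canonical, ok = chem.standardize_structure(s)
        assert ok, s
        try:
            parent = chem.strip_salt_parent(canonical)
        except chem.EmptyParentError:
            parent = None
        full_key, parent_key = chem.make_inchikeys(canonical, parent)
        keys_full.append(full_key)
        keys_parent.append(parent_key)

    mapped = [keys_full[i] is not None and not is_unmapped[i] for i in range(n)]

    # --- library + hits ---
    gene_col = []
    for i in range(n):
        if user_gene[i]:
            gene_col.append("NOT_A_GENE" if user_bad[i] else target_symbol(user_target[i]))
        else:
            gene_col.append("")
    library = pd.DataFrame({
        "SMILES": smiles_raw,
        "Sample ID": [sample_name(i) for i in range(n)],
        "Gene Symbol": gene_col,
    })
    library.to_csv(out_dir / "library.csv", index=False)
    hits_sorted = sorted(hit_ids)
    (out_dir / "hits.txt").write_text("\n".join(hits_sorted) + "\n")

    # --- identifier map: parent key always; full key for even salt forms ---
    source_ids = {
        "drugbank": lambda i: f"DB{i:05d}",
        "pharmgkb": lambda i: f"PA{10000 + i}",
        "iuphar": lambda i: str(1000 + i),
        "pubchem": lambda i: str(100000 + i),
        "chembl": lambda i: f"CHEMBL{100000 + i}",
    }
    map_rows = []
    for i in range(n):
        if not mapped[i]:
            continue
        key = keys_parent[i]
        for source, make_id in source_ids.items():
            map_rows.append((key, source, make_id(i)))
        if is_salt[i] and i % 2 == 0 and keys_full[i] != keys_parent[i]:
            for source, make_id in source_ids.items():
                map_rows.append((keys_full[i], source, make_id(i)))
    pd.DataFrame(map_rows, columns=["inchikey", "source", "source_id"]).to_csv(
        out_dir / "id_map.tsv", sep="\t", index=False)

    # --- gene map (all target symbols resolvable) ---
    pd.DataFrame(
        [(target_symbol(j), target_accession(j)) for j in range(t)],
        columns=["symbol", "uniprot"],
    ).to_csv(out_dir / "gene_map.tsv", sep="\t", index=False)

    # --- evidence rows per association + decoys + boundary records ---
    sources = [s for s, _ in spec.source_mix]
    weights = np.array([w for _, w in spec.source_mix], dtype=float)
    weights = weights / weights.sum()

    manifest_rows = []  # sample_id, acc, source, survives, reason, detail
    drugbank_targets: dict[int, list] = {}
    pharmgkb_rows, iuphar_rows, pubchem_rows, chembl_rows = [], [], [], []

    def emit(i: int, j: int, source: str, survives: bool, reason: str,
             mode: Optional[str] = None) -> None:
        sid, acc, sym = sample_name(i), target_accession(j), target_symbol(j)
        detail = mode or ""
        if source == "drugbank":
            known_action = "unknown" if mode == "unknown_action" else "yes"
            organism = "Rat" if mode == "nonhuman" else "Humans"
            drugbank_targets.setdefault(i, []).append((known_action, organism, sym, acc))
        elif source == "pharmgkb":
            symbol = "NOT_A_GENE" if mode == "bad_symbol" else sym
            pharmgkb_rows.append((source_ids["pharmgkb"](i), sample_name(i), "Chemical",
                                  f"PGK{j}", symbol, "Gene", "yes", "associated", "", ""))
        elif source == "iuphar":
            species = "Mouse" if mode == "nonhuman" else "Human"
            if mode == "weak":
                affinity = round(float(rng_dec.uniform(3.0, 4.9)), 2)
            else:
                affinity = round(float(rng_act.uniform(5.0, 9.0)), 2)
            iuphar_rows.append({
                "ligandId": source_ids["iuphar"](i),
                "targetSpecies": species,
                "affinityParameter": str(rng_act.choice(_IUPHAR_PARAMS)),
                "affinity": affinity,
                "action": str(rng_act.choice(_ACTIONS)) if rng_act.random() < spec.action_prob else "",
                "targetGeneSymbol": sym,
                "targetUniprot": acc,
            })
        elif source == "pubchem":
            taxon = "Rattus norvegicus" if mode == "nonhuman" else "Homo sapiens"
            act_type = str(rng_act.choice(_PUBCHEM_TYPES))
            unit = "nM"
            if mode == "weak":
                value = round(float(rng_dec.uniform(11.0, 500.0)), 3)
                unit = "uM"
            elif mode == "boundary":
                act_type, value, unit = "IC50", 10.0, "uM"
            elif mode == "bad_unit":
                value, unit = 5.0, "ugmL"
            elif mode == "qualitative":
                act_type, value, unit = "Active", 1.0, "nM"
            else:
                value = round(float(10.0 ** rng_act.uniform(0.0, 4.0)), 3)
            pubchem_rows.append((source_ids["pubchem"](i), acc, taxon,
                                 act_type, value, unit))
        elif source == "chembl":
            organism = "Rattus norvegicus" if mode == "nonhuman" else "Homo sapiens"
            target_type = "PROTEIN COMPLEX" if mode == "complex" else "SINGLE PROTEIN"
            assay = "A" if mode == "bad_assay" else str(rng_act.choice(["B", "F"]))
            if mode == "weak":
                pchembl = round(float(rng_dec.uniform(3.0, 4.9)), 2)
            elif mode == "boundary":
                pchembl = 5.0
            elif mode == "no_pchembl":
                pchembl = ""
            else:
                pchembl = round(float(rng_act.uniform(5.0, 9.0)), 2)
            action = (str(rng_act.choice(_CHEMBL_ACTIONS))
                      if rng_act.random() < spec.action_prob else "")
            chembl_rows.append((source_ids["chembl"](i), acc, organism, target_type,
                                assay, str(rng_act.choice(_CHEMBL_TYPES)),
                                pchembl, action))
        manifest_rows.append((sid, acc, source, survives, reason, detail))

    decoy_modes = [
        ("drugbank", "unknown_action"), ("drugbank", "nonhuman"),
        ("pharmgkb", "bad_symbol"),
        ("iuphar", "nonhuman"), ("iuphar", "weak"),
        ("pubchem", "nonhuman"), ("pubchem", "weak"),
        ("pubchem", "bad_unit"), ("pubchem", "qualitative"),
        ("chembl", "nonhuman"), ("chembl", "weak"),
        ("chembl", "complex"), ("chembl", "bad_assay"), ("chembl", "no_pchembl"),
    ]

    index_of = {sample_name(i): i for i in range(n)}
    for sid, acc in associations:
        i, j = index_of[sid], int(acc[1:])
        if is_invalid[i]:
            manifest_rows.append((sid, acc, "", False, "invalid_structure", ""))
            continue
        if not mapped[i]:
            # dump rows are still emitted under the compound's (unregistered)
            # source ids; the pipeline must ignore them
            src = str(rng_src.choice(sources, p=weights))
            emit(i, j, src, False, "compound_unmapped")
            continue
        src = str(rng_src.choice(sources, p=weights))
        emit(i, j, src, True, "ok")
        if rng_src.random() < spec.multi_source_prob:
            other = str(rng_src.choice([s for s in sources if s != src]))
            emit(i, j, other, True, "ok")
        if rng_dec.random() < spec.decoy_fraction:
            d_src, d_mode = decoy_modes[int(rng_dec.integers(0, len(decoy_modes)))]
            emit(i, j, d_src, False, "filtered", d_mode)

    # boundary records: inclusive 10 uM and pChEMBL = 5 must both survive
    first_mapped = next((i for i in range(n) if mapped[i]), None)
    if first_mapped is not None:
        jb = (spec.planted_targets[0][0] + 1) % t if spec.planted_targets else 0
        emit(first_mapped, jb, "pubchem", True, "boundary_10uM", "boundary")
        emit(first_mapped, (jb + 1) % t, "chembl", True, "boundary_pchembl5", "boundary")

    # user annotations from the Gene Symbol column
    for i in range(n):
        if not user_gene[i]:
            continue
        sid = sample_name(i)
        if user_bad[i]:
            manifest_rows.append((sid, "", "user", False, "unresolvable_symbol", ""))
        else:
            manifest_rows.append((sid, target_accession(user_target[i]),
                                  "user", True, "ok", ""))

    # --- write the five dumps ---
    root = etree.Element("drugbank")
    for i in sorted(drugbank_targets):
        drug = etree.SubElement(root, "drug")
        etree.SubElement(drug, "drugbank-id").text = source_ids["drugbank"](i)
        targets_el = etree.SubElement(drug, "targets")
        for known_action, organism, sym, acc in drugbank_targets[i]:
            tg = etree.SubElement(targets_el, "target")
            etree.SubElement(tg, "known-action").text = known_action
            etree.SubElement(tg, "organism").text = organism
            poly = etree.SubElement(tg, "polypeptide")
            etree.SubElement(poly, "gene-name").text = sym
            ext_ids = etree.SubElement(poly, "external-identifiers")
            ext = etree.SubElement(ext_ids, "external-identifier")
            etree.SubElement(ext, "resource").text = "UniProtKB"
            etree.SubElement(ext, "identifier").text = acc
    (out_dir / "drugbank.xml").write_bytes(
        etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8"))

    pd.DataFrame(pharmgkb_rows, columns=[
        "Entity1_id", "Entity1_name", "Entity1_type", "Entity2_id",
        "Entity2_name", "Entity2_type", "Evidence", "Association", "PK", "PD",
    ]).to_csv(out_dir / "pharmgkb.tsv", sep="\t", index=False)

    with open(out_dir / "iuphar.json", "w") as fh:
        json.dump(iuphar_rows, fh, indent=1, sort_keys=True)

    pd.DataFrame(pubchem_rows, columns=[
        "cid", "target_accession", "target_taxonomy", "activity_type",
        "activity_value", "activity_unit",
    ]).to_csv(out_dir / "pubchem.csv", index=False)

    pd.DataFrame(chembl_rows, columns=[
        "molecule_chembl_id", "target_accession", "target_organism",
        "target_type", "assay_type", "standard_type", "pchembl_value",
        "action_type",
    ]).to_csv(out_dir / "chembl.csv", index=False)

    # --- gene sets: one per planted mechanism + decoy sets ---
    gmt_lines = []
    for k, (j, _fold) in enumerate(spec.planted_targets):
        others = rng_gs.choice([x for x in range(t) if x != j],
                               size=min(9, t - 1), replace=False)
        members = [target_symbol(j)] + [target_symbol(int(x)) for x in others]
        gmt_lines.append("\t".join([f"PW{k:04d}", f"planted mechanism {k}", *members]))
    for k in range(3):
        members = rng_gs.choice(t, size=min(10, t), replace=False)
        gmt_lines.append("\t".join(
            [f"PWDECOY{k}", f"decoy set {k}",
             *[target_symbol(int(x)) for x in members]]))
    (out_dir / "gene_sets.gmt").write_text("\n".join(gmt_lines) + "\n")

    manifest = pd.DataFrame(manifest_rows, columns=[
        "sample_id", "uniprot_acc", "source", "survives", "reason", "detail"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)

    surviving_pairs = {(r.sample_id, r.uniprot_acc)
                       for r in manifest.itertuples(index=False) if r.survives}
    summary = {
        "n_compounds": n,
        "n_targets": t,
        "n_hits": len(hits_sorted),
        "planted_accessions": [target_accession(j) for j, _ in spec.planted_targets],
        "n_evidence_rows": len(manifest),
        "n_surviving_pairs": len(surviving_pairs),
        "n_invalid_structures": int(is_invalid.sum()),
        "seed": spec.seed,
    }
    with open(out_dir / "manifest_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    paths = {name: out_dir / fname for name, fname in [
        ("library", "library.csv"), ("hits", "hits.txt"),
        ("drugbank", "drugbank.xml"), ("pharmgkb", "pharmgkb.tsv"),
        ("iuphar", "iuphar.json"), ("pubchem", "pubchem.csv"),
        ("chembl", "chembl.csv"), ("id_map", "id_map.tsv"),
        ("gene_map", "gene_map.tsv"), ("gmt", "gene_sets.gmt"),
        ("manifest", "manifest.csv"), ("manifest_summary", "manifest_summary.json"),
    ]}
    return ScreenBundle(spec=spec, out_dir=out_dir, paths=paths,
                        hit_ids=hits_sorted, surviving_pairs=surviving_pairs,
                        planted_accessions=[target_accession(j) for j, _ in spec.planted_targets],
                        manifest=manifest)


@dataclass
class NullScreen:
    """In-memory null campaign: one association per compound, uniform hits."""

    associations: list
    hit_ids: set

    def pairs(self) -> list[CompoundTargetPair]:
        return associations_to_pairs(self.associations)


def generate_null_screen(n_compounds: int, n_targets: int, hit_fraction: float,
                         seed: int, out_dir: str | Path | None = None) -> NullScreen:
    """Exchangeable null design for type-I-error calibration.

    Every compound carries exactly one association with a uniformly drawn
    target, and hits are a uniform subset, so no target is truly
    overrepresented. When ``out_dir`` is given the design is also
    materialized as a minimal file bundle (library, hits, ChEMBL-style
    dump, id and gene maps) through :func:`generate_screen` machinery.
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be positive")
    if hit_fraction * n_compounds < 1:
        raise ValueError("hit_fraction * n_compounds must be at least 1")
    rng = _rng(seed, "null")
    targets = rng.integers(0, n_targets, size=n_compounds)
    n_hits = int(round(hit_fraction * n_compounds))
    hit_idx = set(rng.choice(n_compounds, size=n_hits, replace=False).tolist())
    associations = [(sample_name(i), target_accession(int(j)))
                    for i, j in enumerate(targets)]
    hit_ids = {sample_name(i) for i in hit_idx}
    screen = NullScreen(associations=associations, hit_ids=hit_ids)
    if out_dir is not None:
        _write_null_bundle(screen, n_compounds, n_targets, Path(out_dir))
    return screen


def _write_null_bundle(screen: NullScreen, n: int, t: int, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    smiles = [smiles_for_compound(i) for i in range(n)]
    pd.DataFrame({"SMILES": smiles,
                  "Sample ID": [sample_name(i) for i in range(n)],
                  "Gene Symbol": [""] * n}).to_csv(out_dir / "library.csv", index=False)
    (out_dir / "hits.txt").write_text("\n".join(sorted(screen.hit_ids)) + "\n")
    map_rows, chembl_rows = [], []
    for i, (sid, acc) in enumerate(screen.associations):
        canonical, _ = chem.standardize_structure(smiles[i])
        key, _ = chem.make_inchikeys(canonical, canonical)
        chembl_id = f"CHEMBL{100000 + i}"
        map_rows.append((key, "chembl", chembl_id))
        chembl_rows.append((chembl_id, acc, "Homo sapiens", "SINGLE PROTEIN",
                            "B", "IC50", 6.0, ""))
    pd.DataFrame(map_rows, columns=["inchikey", "source", "source_id"]).to_csv(
        out_dir / "id_map.tsv", sep="\t", index=False)
    pd.DataFrame(chembl_rows, columns=[
        "molecule_chembl_id", "target_accession", "target_organism",
        "target_type", "assay_type", "standard_type", "pchembl_value",
        "action_type"]).to_csv(out_dir / "chembl.csv", index=False)
    pd.DataFrame([(target_symbol(j), target_accession(j)) for j in range(t)],
                 columns=["symbol", "uniprot"]).to_csv(
        out_dir / "gene_map.tsv", sep="\t", index=False)
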