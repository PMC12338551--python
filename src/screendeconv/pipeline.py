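"""End-to-end pipeline driver: standardize -> map -> parse -> collate ->
enrich -> classify -> pathways, with a machine-readable run report.

The pipeline is strictly offline and deterministic: no stage draws
random numbers, and every output CSV carries a provenance header comment
with the package version and a hash of the configuration. Timestamps
appear only in the run report, never in data files, so two runs of the
same configuration on the same inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import io
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__, actions, adapters, chem, collate, enrichment, pathways


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with the reported defaults.

    ``activity_cutoff_molar`` (10 uM) and ``pchembl_min`` (5, the same
    cutoff on the -log10 scale) gate bioactivity evidence; ``fdr_level``
    and ``p_level`` are the two enrichment-reporting thresholds; the
    pathway universe defaults to all genes mapped for the screening
    background.
    """

    library: str
    hits: str
    id_map: str
    gene_map: str
    out_dir: str
    drugbank: Optional[str] = None
    pharmgkb: Optional[str] = None
    iuphar: Optional[str] = None
    pubchem: Optional[str] = None
    chembl: Optional[str] = None
    gmt: Optional[str] = None
    activity_cutoff_molar: float = 1.0e-5
    pchembl_min: float = 5.0
    fdr_level: float = 0.05
    p_level: float = 0.05
    classify_threshold: str = "fdr"       # enriched set used downstream: fdr | p
    pathway_universe: str = "background"  # background | path to a gene list file
    offline: bool = True
    require_gene_column: bool = False

    def __post_init__(self) -> None:
        for name in ("activity_cutoff_molar", "pchembl_min", "fdr_level", "p_level"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.classify_threshold not in {"fdr", "p"}:
            raise ValueError("classify_threshold must be 'fdr' or 'p'")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        # out_dir is excluded: where results land must not change what they are
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _read_hits(path: str | Path) -> set[str]:
    ids = {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}
    return ids


def _write_csv(df: pd.DataFrame, path: Path, provenance: str, index: bool = False) -> None:
    buf = io.StringIO()
    df.to_csv(buf, index=index)
    path.write_text(f"# {provenance}\n" + buf.getvalue())


def read_output_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a pipeline output CSV, skipping the provenance comment line."""
    return pd.read_csv(path, comment="#", **kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the run report dictionary.

    Any stage failure raises :class:`StageError` naming the stage. The
    report records counts at every stage: compounds in/parsed/resolved,
    evidence per source, pairs after deduplication, targets tested and
    enriched at both thresholds, action calls per class, and enriched
    pathways.
    """
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prov = f"screendeconv {__version__} config={config.config_hash()}"
    report: dict = {"config_hash": config.config_hash(), "version": __version__,
                    "stages": {}}
    stats: dict = {}

    # -- standardize ------------------------------------------------------
    try:
        library = chem.load_library(config.library, config.require_gene_column)
        library = chem.standardize_library(library)
        chem.write_standardized_csv(library, out_dir / "standardized_compounds.csv")
    except Exception as exc:
        raise StageError("standardize", str(exc)) from exc
    report["stages"]["standardize"] = {
        "compounds_in": len(library),
        "parse_ok": sum(r.parse_ok for r in library),
        "parse_failed": sum(not r.parse_ok for r in library),
    }

    # -- hits (validated early so enrichment never starts undefined) ------
    try:
        hit_ids = _read_hits(config.hits)
        if not hit_ids:
            raise ValueError("hit list is empty")
        library_ids = {r.sample_id for r in library}
        unknown = sorted(hit_ids - library_ids)
        if unknown:
            raise ValueError(f"hit ids absent from library: {', '.join(unknown[:5])}")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("hits", str(exc)) from exc
    report["stages"]["hits"] = {"hit_ids": len(hit_ids)}

    # -- map identifiers --------------------------------------------------
    try:
        id_map = adapters.map_identifiers(library, config.id_map, stats)
        gene_map = adapters.load_gene_map(config.gene_map)
    except Exception as exc:
        raise StageError("map", str(exc)) from exc
    report["stages"]["map"] = {
        "compounds_with_source_ids": len(id_map.resolved_sample_ids()),
        "malformed_mapping_rows": stats.get("malformed_mapping_rows", 0),
    }

    # -- parse annotation sources ----------------------------------------
    try:
        source_paths = {s: getattr(config, s) for s in
                        ("drugbank", "pharmgkb", "iuphar", "pubchem", "chembl")
                        if getattr(config, s)}
        records = adapters.parse_all_sources(
            source_paths, id_map, library, gene_map, stats,
            activity_cutoff_molar=config.activity_cutoff_molar,
            pchembl_min=config.pchembl_min)
        adapters.write_source_metadata(records, out_dir)
    except Exception as exc:
        raise StageError("annotate", str(exc)) from exc
    per_source = {s: sum(1 for r in records if r.source == s) for s in adapters.SOURCES}
    report["stages"]["annotate"] = {"evidence_records": len(records),
                                    "per_source": per_source,
                                    "dropped": dict(sorted(stats.items()))}

    # -- collate ----------------------------------------------------------
    try:
        pairs = collate.collate_pairs(records)
        _write_csv(collate.pairs_to_frame(pairs), out_dir / "pairs.csv", prov)
        targets_tbl = collate.summarize_targets(pairs)
        _write_csv(targets_tbl, out_dir / "targets_by_source.csv", prov)
        resolved, unresolved = collate.summarize_compounds(pairs, library)
        _write_csv(resolved, out_dir / "compound_source_counts.csv", prov)
        _write_csv(unresolved, out_dir / "unresolved_compounds.csv", prov)
        _write_csv(collate.upset_counts([frozenset(p.sources) for p in pairs]),
                   out_dir / "upset_counts.csv", prov)
        _write_csv(collate.evidence_to_frame(pairs), out_dir / "evidence.csv", prov)
    except Exception as exc:
        raise StageError("collate", str(exc)) from exc
    report["stages"]["collate"] = {
        "pairs": len(pairs),
        "unique_targets": len(targets_tbl),
        "resolved_compounds": len(resolved),
        "unresolved_compounds": len(unresolved),
    }

    # -- target enrichment -------------------------------------------------
    try:
        results = enrichment.enrich_targets(
            pairs, hit_ids, fdr_level=config.fdr_level, p_level=config.p_level,
            library_ids=library_ids)
        _write_csv(enrichment.results_to_frame(results),
                   out_dir / "target_enrichment.csv", prov)
    except Exception as exc:
        raise StageError("enrich", str(exc)) from exc
    hit_pairs = [p for p in pairs if p.sample_id in hit_ids]
    report["stages"]["enrich"] = {
        "hit_pairs": len(hit_pairs),
        "hit_targets": len({p.uniprot_acc for p in hit_pairs}),
        "targets_tested": len(results),
        "enriched_fdr": sum(r.enriched_fdr for r in results),
        "enriched_p": sum(r.enriched_p for r in results),
    }

    # -- action classification --------------------------------------------
    try:
        flag = "enriched_fdr" if config.classify_threshold == "fdr" else "enriched_p"
        enriched_accs = [r.uniprot_acc for r in results if getattr(r, flag)]
        calls = actions.classify_hit_pairs(pairs, hit_ids, enriched_accs)
        _write_csv(actions.calls_to_frame(calls), out_dir / "action_calls.csv", prov)
        _write_csv(actions.build_action_matrix(calls, hit_ids, enriched_accs),
                   out_dir / "action_matrix.csv", prov, index=True)
    except Exception as exc:
        raise StageError("classify", str(exc)) from exc
    per_class = {c: sum(1 for x in calls if x.call == c)
                 for c in (actions.INHIBITOR, actions.ACTIVATOR, actions.MIXED,
                           actions.INCONCLUSIVE, actions.UNKNOWN)}
    report["stages"]["classify"] = {
        "enriched_targets_used": len(enriched_accs),
        "classified_hits": len({c.sample_id for c in calls}),
        "calls": len(calls),
        "per_class": per_class,
    }

    # -- pathway enrichment ------------------------------------------------
    if config.gmt:
        try:
            gene_sets = pathways.read_gmt(config.gmt)
            acc_to_symbol = {r.uniprot_acc: r.gene_symbol
                             for r in targets_tbl.itertuples(index=False) if r.gene_symbol}
            if config.pathway_universe == "background":
                universe = {s for s in acc_to_symbol.values() if s}
            else:
                universe = {line.strip() for line in
                            Path(config.pathway_universe).read_text().splitlines()
                            if line.strip()}
            query = {acc_to_symbol.get(a, "") for a in enriched_accs} - {""}
            query &= universe
            if query:
                presults = pathways.enrich_pathways(query, gene_sets, universe)
                _write_csv(pathways.pathway_results_to_frame(presults),
                           out_dir / "pathway_enrichment.csv", prov)
                n_sig = sum(1 for r in presults
                            if r.q_value is not None and r.q_value <= config.fdr_level)
                report["stages"]["pathways"] = {
                    "gene_sets": len(gene_sets), "universe": len(universe),
                    "query_genes": len(query), "terms_tested":
                        sum(1 for r in presults if r.observed >= 1),
                    "enriched_terms_fdr": n_sig,
                }
            else:
                report["stages"]["pathways"] = {
                    "gene_sets": len(gene_sets), "universe": len(universe),
                    "query_genes": 0, "skipped": "no enriched targets to query",
                }
        except StageError:
            raise
        except Exception as exc:
            raise StageError("pathways", str(exc)) from exc

    report["runtime_seconds"] = round(time.time() - t0, 3)
    with open(out_dir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
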