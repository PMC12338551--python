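"""Merge per-source evidence into deduplicated compound-target pairs.

The unit of all downstream statistics is the unique (sample_id, target)
pair — the same target reported by three databases counts once — but the
underlying evidence rows are preserved on each pair so the mechanism
classifier can re-inspect activity parameters after enrichment.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .adapters import SOURCES, CompoundTargetRecord
from .chem import CompoundRecord


@dataclass
class CompoundTargetPair:
    sample_id: str
    uniprot_acc: str
    sources: set = field(default_factory=set)
    evidence: list = field(default_factory=list)

    def key(self) -> tuple[str, str]:
        return (self.sample_id, self.uniprot_acc)


def collate_pairs(records: Iterable[CompoundTargetRecord]) -> list[CompoundTargetPair]:
    """One pair per distinct (sample_id, uniprot_acc), provenance unioned.

    Output order is deterministic (sorted by key) regardless of the input
    record order.
    """
    by_key: dict[tuple[str, str], CompoundTargetPair] = {}
    for rec in records:
        pair = by_key.get(rec.key())
        if pair is None:
            pair = by_key[rec.key()] = CompoundTargetPair(rec.sample_id, rec.uniprot_acc)
        pair.sources.add(rec.source)
        pair.evidence.append(rec)
    return [by_key[k] for k in sorted(by_key)]


def summarize_targets(pairs: list[CompoundTargetPair]) -> pd.DataFrame:
    """One row per unique target with a boolean provenance column per source."""
    flags: dict[str, dict[str, bool]] = defaultdict(lambda: {s: False for s in SOURCES})
    symbols: dict[str, str] = {}
    for pair in pairs:
        row = flags[pair.uniprot_acc]
        for s in pair.sources:
            row[s] = True
        for ev in pair.evidence:
            if ev.gene_symbol and pair.uniprot_acc not in symbols:
                symbols[pair.uniprot_acc] = ev.gene_symbol
    out = pd.DataFrame(
        [[acc, symbols.get(acc, "")] + [flags[acc][s] for s in SOURCES]
         for acc in sorted(flags)],
        columns=["uniprot_acc", "gene_symbol", *SOURCES],
    )
    return out


def summarize_compounds(pairs: list[CompoundTargetPair],
                        library: list[CompoundRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-compound distinct-target counts per source, plus the unresolved list.

    Every library entry lands in exactly one of the two outputs, so the
    two row counts always partition the library size. Counts are distinct
    targets per source for that compound, not raw evidence rows.
    """
    per_compound: dict[str, dict[str, set]] = defaultdict(lambda: {s: set() for s in SOURCES})
    for pair in pairs:
        for ev in pair.evidence:
            per_compound[pair.sample_id][ev.source].add(pair.uniprot_acc)
    resolved_rows = []
    unresolved_rows = []
    for rec in library:
        if rec.sample_id in per_compound:
            counts = per_compound[rec.sample_id]
            resolved_rows.append([rec.sample_id] + [len(counts[s]) for s in SOURCES]
                                 + [len(set().union(*counts.values()))])
        else:
            reason = "invalid_structure" if not rec.parse_ok else "no_target_annotation"
            unresolved_rows.append([rec.sample_id, rec.smiles_raw, reason])
    resolved = pd.DataFrame(resolved_rows, columns=["sample_id", *SOURCES, "total_targets"])
    unresolved = pd.DataFrame(unresolved_rows, columns=["sample_id", "smiles_raw", "reason"])
    return resolved, unresolved


def upset_counts(source_sets: Iterable[frozenset | set]) -> pd.DataFrame:
    """Exact source-combination counts (the data behind an upset plot).

    Returns one row per observed combination, combination rendered as a
    ``+``-joined sorted label; counts sum to the number of input items.
    """
    counter: dict[tuple[str, ...], int] = defaultdict(int)
    for s in source_sets:
        counter[tuple(sorted(s))] += 1
    rows = [["+".join(combo), len(combo), n]
            for combo, n in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))]
    return pd.DataFrame(rows, columns=["sources", "degree", "count"])


def pairs_to_frame(pairs: list[CompoundTargetPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [[p.sample_id, p.uniprot_acc, "+".join(sorted(p.sources)), len(p.evidence)]
         for p in pairs],
        columns=["sample_id", "uniprot_acc", "sources", "n_evidence"],
    )


def evidence_to_frame(pairs: list[CompoundTargetPair]) -> pd.DataFrame:
    from .adapters import records_to_frame
    return records_to_frame([ev for p in pairs for ev in p.evidence])


def write_collation_outputs(pairs: list[CompoundTargetPair],
                            library: list[CompoundRecord],
                            out_dir: str | Path) -> dict[str, int]:
    """Write the three summary tables, upset counts and evidence to CSV.

    Returns the headline counts used in the run report.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs_to_frame(pairs).to_csv(out_dir / "pairs.csv", index=False)
    targets = summarize_targets(pairs)
    targets.to_csv(out_dir / "targets_by_source.csv", index=False)
    resolved, unresolved = summarize_compounds(pairs, library)
    resolved.to_csv(out_dir / "compound_source_counts.csv", index=False)
    unresolved.to_csv(out_dir / "unresolved_compounds.csv", index=False)
    upset_counts([frozenset(p.sources) for p in pairs]).to_csv(
        out_dir / "upset_counts.csv", index=False)
    evidence_to_frame(pairs).to_csv(out_dir / "evidence.csv", index=False)
    return {
        "pairs": len(pairs),
        "unique_targets": len(targets),
        "resolved_compounds": len(resolved),
        "unresolved_compounds": len(unresolved),
    }
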