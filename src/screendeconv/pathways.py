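"""Gene-set (pathway) overrepresentation for a target list.

Reuses the exact hypergeometric right tail from target enrichment with
the roles recast: the universe of genes plays the background, the query
(e.g. the enriched targets) plays the hit list, and each gene set plays
a target. Alongside p/q the enrichment strength log10(observed/expected)
is reported — the magnitude measure used to rank pathways, where
``expected`` is |members in universe| * |query| / |universe|.

A client for a remote functional-enrichment web service is declared as
an interface only: the request/response schema and a parser for canned
responses ship here, but no network transport. Offline use raises
:class:`RemoteUnavailableError` explicitly, never silently falling back
to the local computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Optional

import pandas as pd

from .enrichment import ContingencyTable, bh_adjust, fisher_right_tail


@dataclass
class GeneSet:
    term_id: str
    term_name: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.term_id} has no members")


@dataclass
class PathwayEnrichmentResult:
    term_id: str
    term_name: str
    observed: int
    expected: float
    strength: Optional[float]  # None when observed == 0
    p_value: float
    q_value: Optional[float]   # None for untested (observed == 0) terms


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: term, description, members... per tab-separated line."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
            term_id, term_name = fields[0], fields[1]
            if term_id in seen:
                raise ValueError(f"GMT line {lineno}: duplicate term id {term_id!r}")
            seen.add(term_id)
            members = frozenset(m for m in fields[2:] if m.strip())
            sets.append(GeneSet(term_id=term_id, term_name=term_name, members=members))
    return sets


def strength_metric(observed: int, expected: float) -> Optional[float]:
    """log10(observed / expected); undefined (None) when observed is zero."""
    if observed < 1 or expected <= 0:
        return None
    return math.log10(observed / expected)


def enrich_pathways(query: set, gene_sets: list[GeneSet],
                    universe: set) -> list[PathwayEnrichmentResult]:
    """Hypergeometric ORA of ``query`` genes over ``gene_sets``.

    Query genes outside the universe are dropped with a warning count;
    terms with zero observed members are reported with strength and q
    absent and excluded from the BH family. Results sort by descending
    strength (observed-zero terms last), ties by term id.
    """
    if not universe:
        raise ValueError("empty universe")
    query_in = set(query) & set(universe)
    if not query_in:
        raise ValueError("empty query (no query genes in universe)")

    results: list[PathwayEnrichmentResult] = []
    tested_idx: list[int] = []
    p_tested: list[float] = []
    for gs in gene_sets:
        members = gs.members & universe
        observed = len(query_in & members)
        expected = len(members) * len(query_in) / len(universe)
        table = ContingencyTable(NB=len(universe), Nhl=len(query_in),
                                 Tic=len(members), Tihlc=observed)
        p = fisher_right_tail(table)
        res = PathwayEnrichmentResult(
            term_id=gs.term_id, term_name=gs.term_name, observed=observed,
            expected=expected, strength=strength_metric(observed, expected),
            p_value=p, q_value=None)
        if observed >= 1:
            tested_idx.append(len(results))
            p_tested.append(p)
        results.append(res)
    if p_tested:
        for i, q in zip(tested_idx, bh_adjust(p_tested)):
            results[i].q_value = float(q)
    results.sort(key=lambda r: (-(r.strength if r.strength is not None else -math.inf),
                                r.term_id))
    return results


def pathway_results_to_frame(results: Iterable[PathwayEnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [[r.term_id, r.term_name, r.observed, round(r.expected, 6),
          "" if r.strength is None else round(r.strength, 6),
          r.p_value, "" if r.q_value is None else r.q_value]
         for r in results],
        columns=["term_id", "term_name", "observed", "expected",
                 "strength", "p_value", "q_value"],
    )


class RemoteUnavailableError(RuntimeError):
    """The remote functional-enrichment service cannot be reached (or offline)."""


@dataclass
class RemoteEnrichmentRequest:
    """Declared request schema for a remote functional-enrichment service."""

    genes: tuple
    species: int = 9606
    caller_identity: str = "screendeconv"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("remote enrichment request refused: empty gene list")

    def to_params(self) -> dict:
        return {"identifiers": "%0d".join(self.genes),
                "species": self.species,
                "caller_identity": self.caller_identity}


class RemoteEnrichmentClient:
    """Interface-only client: transport must be injected, never bundled.

    ``fetcher`` is a callable taking the request params dict and
    returning the service's JSON payload (a list of per-term records).
    Without a fetcher, or in offline mode, every call raises
    :class:`RemoteUnavailableError`.
    """

    def __init__(self, fetcher: Optional[Callable[[dict], list]] = None,
                 offline: bool = True):
        self.fetcher = fetcher
        self.offline = offline

    def enrich(self, genes: Iterable[str]) -> list[PathwayEnrichmentResult]:
        request = RemoteEnrichmentRequest(genes=tuple(genes))
        if self.offline or self.fetcher is None:
            raise RemoteUnavailableError(
                "remote functional enrichment requested in offline mode")
        return parse_remote_response(self.fetcher(request.to_params()))


def parse_remote_response(payload: list) -> list[PathwayEnrichmentResult]:
    """Parse a canned remote-service JSON payload into local result objects.

    Expected per-term fields: ``term``, ``description``,
    ``number_of_genes`` (observed), ``number_of_genes_in_background``,
    ``p_value``, ``fdr``; ``expected`` is taken verbatim when present.
    """
    results = []
    for row in payload:
        observed = int(row["number_of_genes"])
        expected = float(row.get("expected", float("nan")))
        results.append(PathwayEnrichmentResult(
            term_id=str(row["term"]), term_name=str(row.get("description", "")),
            observed=observed, expected=expected,
            strength=strength_metric(observed, expected) if expected == expected else None,
            p_value=float(row["p_value"]),
            q_value=float(row["fdr"]) if "fdr" in row else None))
    return results
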