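"""Target overrepresentation analysis against the screening background.

Whether a target shows up often among hit compounds means little on its
own: the screening collection itself is biased toward well-annotated
pharmacology, so a target's prevalence in the hit list must be judged
against its prevalence across all compound-target associations of the
library. For each target i a 2x2 contingency table is built from
deduplicated pairs,

                      in hit list    not in hit list    total
    target i assoc.      Tihlc        Tic - Tihlc        Tic
    other assoc.      Nhl - Tihlc   NB - Tic - Nhl + Tihlc
    total                 Nhl          NB - Nhl           NB

where NB is the total number of compound-target associations in the
background, Nhl the number in the hit list, Tic the associations of
target i in the background and Tihlc those in the hit list. The p-value
is the right tail of Fisher's exact test (overrepresentation is
one-sided), i.e. the hypergeometric tail P(X >= Tihlc) with population
NB, Tic successes and Nhl draws, and p-values are Benjamini-Hochberg
adjusted over the tested targets (those with at least one hit
association; a target never hit cannot be overrepresented).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .collate import CompoundTargetPair


@dataclass(frozen=True)
class ContingencyTable:
    """The four overrepresentation counts for one target."""

    NB: int
    Nhl: int
    Tic: int
    Tihlc: int

    def __post_init__(self) -> None:
        ok = (0 <= self.Tihlc <= min(self.Tic, self.Nhl)
              and self.Tic <= self.NB and self.Nhl <= self.NB
              and self.NB - self.Tic - self.Nhl + self.Tihlc >= 0)
        if not ok:
            raise ValueError(f"inconsistent contingency counts: {self}")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        """(a, b, c, d) reading the 2x2 table row-wise."""
        return (self.Tihlc, self.Tic - self.Tihlc,
                self.Nhl - self.Tihlc, self.NB - self.Tic - self.Nhl + self.Tihlc)

    @property
    def odds_ratio(self) -> float:
        a, b, c, d = self.cells
        if b * c == 0:
            return float("inf") if a * d > 0 else float("nan")
        return (a * d) / (b * c)


@dataclass
class TargetEnrichmentResult:
    uniprot_acc: str
    gene_symbol: str
    table: ContingencyTable
    odds_ratio: float
    p_value: float
    q_value: float
    enriched_fdr: bool
    enriched_p: bool


def fisher_right_tail(table: ContingencyTable) -> float:
    """Exact one-sided (overrepresentation) Fisher p-value.

    P(X >= Tihlc) for X hypergeometric with population NB, Tic successes
    and Nhl draws; computed exactly, never simulated.
    """
    return float(hypergeom.sf(table.Tihlc - 1, table.NB, table.Tic, table.Nhl))


def fisher_right_tail_many(tables: Sequence[ContingencyTable]) -> np.ndarray:
    """Vectorized right-tail p-values for many tables (same formula)."""
    if not tables:
        return np.empty(0)
    t = np.array([[c.Tihlc, c.NB, c.Tic, c.Nhl] for c in tables])
    return hypergeom.sf(t[:, 0] - 1, t[:, 1], t[:, 2], t[:, 3])


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_contingency(pairs: list[CompoundTargetPair], hit_ids: set[str],
                      target: str,
                      library_ids: Optional[set[str]] = None) -> ContingencyTable:
    """Counts for one target from deduplicated pairs.

    When ``library_ids`` is given, every hit id must be a library sample
    id; an unknown id raises with the offending id named. (Hit compounds
    without annotations are legitimate, so the check cannot be made
    against the pair list alone.)
    """
    if library_ids is not None:
        unknown = sorted(set(hit_ids) - set(library_ids))
        if unknown:
            raise ValueError(f"hit ids absent from library: {', '.join(unknown[:5])}")
    nb = len(pairs)
    nhl = sum(1 for p in pairs if p.sample_id in hit_ids)
    tic = sum(1 for p in pairs if p.uniprot_acc == target)
    tihlc = sum(1 for p in pairs if p.uniprot_acc == target and p.sample_id in hit_ids)
    return ContingencyTable(NB=nb, Nhl=nhl, Tic=tic, Tihlc=tihlc)


def enrich_targets(pairs: list[CompoundTargetPair], hit_ids: set[str],
                   fdr_level: float = 0.05, p_level: float = 0.05,
                   library_ids: Optional[set[str]] = None,
                   two_sided: bool = False) -> list[TargetEnrichmentResult]:
    """Per-target overrepresentation results sorted by ascending p.

    Tested targets are those with at least one hit-list association;
    m for the BH adjustment is the number of tested targets. Ties in p
    are broken by accession so ordering is deterministic. Raises if the
    hit list is empty, contains ids outside the library, or maps to no
    pairs at all (enrichment undefined).
    """
    if not hit_ids:
        raise ValueError("empty hit list: enrichment undefined")
    if library_ids is not None:
        unknown = sorted(set(hit_ids) - set(library_ids))
        if unknown:
            raise ValueError(f"hit ids absent from library: {', '.join(unknown[:5])}")

    nb = len(pairs)
    nhl = sum(1 for p in pairs if p.sample_id in hit_ids)
    if nhl == 0:
        raise ValueError("no compound-target pairs for any hit compound")

    tic: dict[str, int] = {}
    tihlc: dict[str, int] = {}
    symbols: dict[str, str] = {}
    for p in pairs:
        tic[p.uniprot_acc] = tic.get(p.uniprot_acc, 0) + 1
        if p.sample_id in hit_ids:
            tihlc[p.uniprot_acc] = tihlc.get(p.uniprot_acc, 0) + 1
        if p.uniprot_acc not in symbols:
            for ev in p.evidence:
                if ev.gene_symbol:
                    symbols[p.uniprot_acc] = ev.gene_symbol
                    break

    tested = sorted(acc for acc, k in tihlc.items() if k >= 1)
    tables = [ContingencyTable(NB=nb, Nhl=nhl, Tic=tic[acc], Tihlc=tihlc[acc])
              for acc in tested]
    p_right = fisher_right_tail_many(tables)
    if two_sided:
        from scipy.stats import fisher_exact
        p_vals = np.array([fisher_exact(np.reshape(t.cells, (2, 2)))[1] for t in tables])
    else:
        p_vals = p_right
    q_vals = bh_adjust(p_vals) if len(p_vals) else np.empty(0)

    results = [
        TargetEnrichmentResult(
            uniprot_acc=acc, gene_symbol=symbols.get(acc, ""), table=t,
            odds_ratio=t.odds_ratio, p_value=float(pv), q_value=float(qv),
            enriched_fdr=bool(qv <= fdr_level), enriched_p=bool(pv <= p_level),
        )
        for acc, t, pv, qv in zip(tested, tables, p_vals, q_vals)
    ]
    results.sort(key=lambda r: (r.p_value, r.uniprot_acc))
    return results


def results_to_frame(results: Iterable[TargetEnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [[r.uniprot_acc, r.gene_symbol, r.table.Tihlc, r.table.Tic,
          r.table.Nhl, r.table.NB, r.odds_ratio, r.p_value, r.q_value,
          r.enriched_fdr, r.enriched_p] for r in results],
        columns=["uniprot_acc", "gene_symbol", "Tihlc", "Tic", "Nhl", "NB",
                 "odds_ratio", "p_value", "q_value", "enriched_fdr", "enriched_p"],
    )
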