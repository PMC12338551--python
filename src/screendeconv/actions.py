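"""Rule-based mechanism-of-action classification for hit-target pairs.

The parameter type under which an activity was reported hints at the
direction of action: inhibitory-concentration values (IC50, IC20, ...),
Ki/pKi and the INH token suggest inhibition; effective-concentration
values (EC50, EC20, ...) suggest activation; pure binding or kinetic
constants (Kd, Kb, Km, Ka) say nothing about direction. Because Ki-type
parameters are also reported for agonists, a curator-assigned mechanism
string — IUPHAR's "Action" field or ChEMBL's "Action Type" — overrides
the parameter-based guess whenever it maps to a direction. Evidence from
curated association databases (DrugBank, PharmGKB, user annotations)
carries no activity parameters at all and yields "unknown".

Per (compound, target) pair the evidence labels aggregate to one call:
both directions present -> mixed; one direction -> that direction
(definite evidence is not diluted by inconclusive/unknown co-evidence);
otherwise inconclusive beats unknown.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .adapters import CURATED_SOURCES, CompoundTargetRecord
from .collate import CompoundTargetPair

logger = logging.getLogger(__name__)

INHIBITOR, ACTIVATOR, MIXED, INCONCLUSIVE, UNKNOWN, NONE = (
    "inhibitor", "activator", "mixed", "inconclusive", "unknown", "none")

#: default curator-vocabulary overrides; keys are casefolded action strings
DEFAULT_ACTION_VOCAB: dict[str, str] = {
    "agonist": ACTIVATOR, "partial agonist": ACTIVATOR,
    "full agonist": ACTIVATOR, "activator": ACTIVATOR,
    "positive modulator": ACTIVATOR, "positive allosteric modulator": ACTIVATOR,
    "antagonist": INHIBITOR, "inhibitor": INHIBITOR,
    "inverse agonist": INHIBITOR, "blocker": INHIBITOR,
    "channel blocker": INHIBITOR, "negative modulator": INHIBITOR,
    "negative allosteric modulator": INHIBITOR,
}

_IC_RE = re.compile(r"^IC\d+$", re.I)
_EC_RE = re.compile(r"^EC\d+$", re.I)
_INHIBITOR_TOKENS = {"KI", "PKI", "INH"}
_INCONCLUSIVE_TOKENS = {"KD", "KB", "KM", "KA"}


@dataclass
class ActionCall:
    sample_id: str
    uniprot_acc: str
    call: str
    basis: list = field(default_factory=list)  # (record, preliminary label, overridden)


def label_evidence(record: CompoundTargetRecord,
                   action_vocab: Optional[Mapping[str, str]] = None) -> tuple[str, bool]:
    """Preliminary direction label for one evidence record.

    Returns ``(label, override_applied)``. The parameter-type rule runs
    first; a mappable curator action string then overrides it. Tokens not
    in the rule table are treated as direction-free (inconclusive) and
    logged.
    """
    vocab = DEFAULT_ACTION_VOCAB if action_vocab is None else action_vocab
    token = (record.activity_type or "").strip().upper()
    if not token:
        label = UNKNOWN if record.source in CURATED_SOURCES else INCONCLUSIVE
    elif _IC_RE.match(token) or token in _INHIBITOR_TOKENS:
        label = INHIBITOR
    elif _EC_RE.match(token):
        label = ACTIVATOR
    elif token in _INCONCLUSIVE_TOKENS:
        label = INCONCLUSIVE
    else:
        logger.debug("unrecognized activity parameter token %r", token)
        label = INCONCLUSIVE
    if record.action_field:
        direction = vocab.get(record.action_field.strip().casefold())
        if direction is not None:
            return direction, direction != label
    return label, False


def classify_pair(evidence: list[CompoundTargetRecord],
                  action_vocab: Optional[Mapping[str, str]] = None) -> ActionCall:
    """Aggregate evidence labels for one (compound, target) pair.

    Both directions -> mixed; exactly one -> that call; neither but some
    direction-free activity -> inconclusive; curated-only evidence ->
    unknown. Empty evidence is an error.
    """
    if not evidence:
        raise ValueError("cannot classify a pair with no evidence")
    keys = {r.key() for r in evidence}
    if len(keys) != 1:
        raise ValueError(f"evidence spans multiple pairs: {sorted(keys)}")
    basis = []
    labels = set()
    for rec in evidence:
        label, overridden = label_evidence(rec, action_vocab)
        basis.append((rec, label, overridden))
        labels.add(label)
    labels.discard(NONE)
    if INHIBITOR in labels and ACTIVATOR in labels:
        call = MIXED
    elif INHIBITOR in labels:
        call = INHIBITOR
    elif ACTIVATOR in labels:
        call = ACTIVATOR
    elif INCONCLUSIVE in labels:
        call = INCONCLUSIVE
    else:
        call = UNKNOWN
    sample_id, acc = next(iter(keys))
    return ActionCall(sample_id=sample_id, uniprot_acc=acc, call=call, basis=basis)


def classify_hit_pairs(pairs: list[CompoundTargetPair], hit_ids: set[str],
                       enriched_targets: Iterable[str],
                       action_vocab: Optional[Mapping[str, str]] = None) -> list[ActionCall]:
    """Classify every (hit compound, enriched target) pair with evidence."""
    enriched = set(enriched_targets)
    calls = []
    for pair in pairs:
        if pair.sample_id in hit_ids and pair.uniprot_acc in enriched:
            calls.append(classify_pair(pair.evidence, action_vocab))
    calls.sort(key=lambda c: (c.sample_id, c.uniprot_acc))
    return calls


def build_action_matrix(calls: list[ActionCall], hit_ids: set[str],
                        enriched_targets: Iterable[str]) -> pd.DataFrame:
    """Hit x enriched-target matrix of calls (empty string where no pair).

    Rows are hits with at least one call on an enriched target; columns
    are all enriched targets, sorted.
    """
    targets = sorted(set(enriched_targets))
    rows = sorted({c.sample_id for c in calls if c.sample_id in hit_ids})
    matrix = pd.DataFrame("", index=rows, columns=targets)
    for c in calls:
        if c.sample_id in hit_ids and c.uniprot_acc in targets:
            matrix.loc[c.sample_id, c.uniprot_acc] = c.call
    matrix.index.name = "sample_id"
    return matrix


def calls_to_frame(calls: list[ActionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        labels = ";".join(f"{rec.source}:{label}{'*' if ov else ''}"
                          for rec, label, ov in c.basis)
        rows.append([c.sample_id, c.uniprot_acc, c.call, len(c.basis), labels])
    return pd.DataFrame(rows, columns=["sample_id", "uniprot_acc", "call",
                                       "n_evidence", "evidence_labels"])


def load_action_vocab(path: str | Path) -> dict[str, str]:
    """Read a two-column CSV (action, direction) override vocabulary."""
    df = pd.read_csv(path, dtype=str)
    out = {}
    for row in df.itertuples(index=False):
        direction = row.direction.strip().lower()
        if direction not in {INHIBITOR, ACTIVATOR}:
            raise ValueError(f"direction must be inhibitor/activator, got {direction!r}")
        out[row.action.strip().casefold()] = direction
    return out
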