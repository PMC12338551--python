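# Methods

## Problem and approach

A phenotypic screen yields a library of compounds (identified by SMILES
and an opaque sample id) and a hit list — the subset showing the
phenotype. The package infers mechanism hypotheses in four steps:
harmonize compound–target evidence from offline annotation dumps,
test per-target overrepresentation of hit associations against the
library's own association background, classify the direction of each
hit's action on the enriched targets, and test the enriched targets for
gene-set (pathway) overrepresentation.

## Compound standardization

Structures are normalized with the RDKit cleanup transformations
(explicit-hydrogen removal, functional-group normalization, metal
disconnection, reionization) and canonicalized; standardization is a
fixed point (re-standardizing returns the same string). Two InChIKeys
are produced per compound: one for the normalized structure including
salt fragments, one for the salt-stripped parent. The parent is the
largest organic fragment — most heavy atoms among fragments containing
at least one carbon, ties broken by canonical-SMILES lexicographic
order — and simple protonation states are neutralized *after* fragment
selection, so counter-ion charges leave with their fragments. The
ordering of neutralization relative to salt removal is a design choice
of this package; both orders are defensible, and the chosen one keeps
fragment selection independent of protonation state. Structures whose
only fragments are carbon-free (e.g. table salt) have no parent and
keep only the full-structure key. Invalid SMILES are retained with
`parse_ok=False` — record counts are conserved everywhere — and appear
in the unresolved-compounds report. Duplicate sample ids are treated as
distinct library entries; no structure-level deduplication is done,
because screening collections legitimately contain the same structure
under several plate ids.

## Identifier mapping and source adapters

A UniChem-style table maps InChIKeys to per-source compound ids. Per
compound and per source the full key is consulted first, the parent key
only if the full key has no entry, so a source that registered the free
base still matches a salt-form library entry.

Each source dump is parsed in a minimal faithful dialect of its public
schema (see `docs/fixture_dialects.md`) with these filters:

| source   | kind        | filters                                                              |
|----------|-------------|----------------------------------------------------------------------|
| DrugBank | curated     | `known-action` ≠ "unknown"; human targets; UniProt id present        |
| PharmGKB | curated     | chemical–gene rows; gene symbol resolvable to UniProt                |
| IUPHAR   | bioactivity | human; affinity (pKi-scale → 10^(−p) mol/L) ≤ 10 µM                  |
| PubChem  | bioactivity | human; concentration-typed parameter; value (→ mol/L) ≤ 10 µM        |
| ChEMBL   | bioactivity | human; SINGLE PROTEIN; binding/functional assay; pChEMBL ≥ 5         |
| user     | curated     | non-blank Gene Symbol column, resolvable symbol                      |

Both cutoffs are inclusive: 10 µM exactly survives, as does pChEMBL
exactly 5 (the same threshold on the −log10 molar scale). The PubChem
filter is restricted to concentration-typed potency parameters
(IC*n*/EC*n*/AC*n*/XC*n*, Ki, Kd, Kb, Km, Ka, Potency) because a molar
cutoff is undefined for qualitative outcomes; IUPHAR rows without a
numeric affinity are dropped. Curated sources carry no activity fields.
Records failing a filter are counted per reason in the run log, never
silently lost. Tightening the activity cutoff can only shrink the
output (monotonicity), and parsing is row-order independent.

Networked retrieval (the identifier-mapping and annotation services the
dumps mimic) is deliberately out of the tested surface: the pipeline is
offline-first for reproducibility, and the remote functional-enrichment
client ships as a request/response schema with an injectable transport
that raises a remote-unavailable error otherwise.

## Collation and enrichment

Evidence rows collapse to unique (sample id, UniProt accession) pairs
with full provenance retained, so the classifier can later re-inspect
activity parameters. All statistics run on deduplicated pairs. For each
target the 2×2 table (N_B, N_hl, T_ic, T_ihlc) is built as in the
README; the bottom-middle cell is N_B − T_ic − N_hl + T_ihlc, the
unique value consistent with the margins. The p-value is the exact
hypergeometric right tail (one-sided, because the question is
overrepresentation; a two-sided variant is available behind a flag),
computed with `scipy.stats.hypergeom.sf`, never simulated. Only targets
with at least one hit association are tested — a target never hit
cannot be overrepresented, and including its p = 1 would only inflate
the multiple-testing burden — and m for Benjamini–Hochberg is the
number of tested targets. Results are ordered by ascending p with ties
broken by accession. Two report thresholds are first-class
configuration: an FDR level on q and a raw-p level (defaults 0.05
each); which set feeds classification and pathway analysis is
configurable (`classify_threshold`, default FDR). The odds ratio is the
unadjusted cross-product ratio, infinite when a zero cell makes it so;
no continuity correction, since inference comes from the exact test.

## Action classification

Per evidence record, a preliminary direction comes from the activity
parameter type: IC*n* (pattern `IC` + number), Ki, pKi and INH →
inhibitor; EC*n* → activator; Kd, Kb, Km, Ka → inconclusive;
unrecognized tokens → inconclusive (logged); curated records without
parameters → unknown. Because Ki-type values are also reported for
agonists, a curator action string (IUPHAR "Action", ChEMBL "Action
Type") overrides the parameter rule when it maps to a direction through
the shipped vocabulary ({agonist, partial/full agonist, activator,
positive (allosteric) modulator} → activator; {antagonist, inhibitor,
inverse agonist, (channel) blocker, negative (allosteric) modulator} →
inhibitor; anything else → no override; the table is replaceable via a
CSV). Pair aggregation: both directions present → mixed; exactly one →
that call, *not* diluted by co-occurring inconclusive/unknown evidence;
otherwise inconclusive beats unknown. The no-dilution precedence is an
interpretation this package fixes explicitly (single call per pair);
the truth table is enforced against an exhaustive oracle in the tests.
ChEMBL rows contribute a direction only through their underlying
standard-type token (or an action-type override), never by virtue of
carrying a pChEMBL value alone.

## Pathway enrichment

Gene sets come from GMT files. For query Q, universe U and set S:
observed = |Q ∩ S ∩ U|, expected = |S ∩ U|·|Q|/|U|, strength =
log₁₀(observed/expected), p = the same hypergeometric right tail with
(N_B, N_hl, T_ic, T_ihlc) = (|U|, |Q|, |S ∩ U|, observed), q = BH over
terms with observed ≥ 1. Terms with observed = 0 are reported with
strength and q absent (not −∞) and excluded from the BH family. The
default universe is the set of genes mapped for the screening
background — consistent with the library-as-background philosophy — and
a whole-genome list can be supplied instead; results sort by descending
strength.

## Synthetic campaigns and what they show

The generator emits every input the pipeline consumes, from a single
seed through fixed per-purpose substreams (bundles are byte-reproducible
file by file). The association model: each (compound, target) pair
exists independently with probability `baseline_rate`; hits are a
uniform random subset of size `hit_fraction·n`; for each planted target
the association probability among hits is multiplied by its fold
factor. Defaults (n = 2,000 compounds, 100 targets, baseline 0.02,
hit fraction 0.05, one planted target at fold 5) describe a mid-size
bioactive-collection screen with ~2 annotations per compound. Around
this, the bundle adds the texture of real inputs: ~10 % salt forms
(carbon-free counter-ions, so parent selection is unambiguous), ~2 %
invalid SMILES, ~5 % unmappable compounds, multi-source duplicate
evidence, sub-threshold/non-human/malformed decoy rows for every filter,
and two guaranteed boundary records (exactly 10 µM; pChEMBL exactly 5).
A manifest marks each emitted row as surviving or filtered with the
reason; running the real pipeline on a bundle must reproduce the
surviving pair set exactly. Structures are composed from a curated
alphabet of valid fragments with varying chain lengths, so
standardization exercises real chemistry offline — but the generator
does not emulate realistic pharmacology (correlated target profiles,
affinity distributions, chemotype clustering), so passing tests
demonstrate correctness of the machinery, not biological recall on
real screens.

A separate exchangeable null design (one association per compound,
uniform target, uniform hits) makes per-target tables exchangeable
draws for type-I calibration: pooled over replicates, the fraction of
tested targets with p < 0.05 stays below 0.05 plus three binomial
standard errors (the exact test is conservative on discrete support).

### Statistical power at the default conditions

At the defaults the planted target's hit-association count is
Binomial(100, 0.1), mean 10, while the background expectation is ≈2.5.
The raw p-value falls below 0.05 in ≈94 % of campaigns and the planted
target ranks first in ≈85 %, but clearing q < 0.05 requires roughly
T_ihlc ≥ 10 once ≈88 targets are tested, which happens in only ≈60 %
of campaigns — an inherent property of BH correction with a single true
signal at these sizes, not an implementation artifact. Detection at the
FDR level needs a larger library, a stronger fold, or more planted
targets sharing the mechanism.

## Numerical and procedural choices

- Exact tails from `scipy.stats.hypergeom.sf`; BH from
  `statsmodels.stats.multitest.multipletests`; both are cross-checked
  in the tests against independent brute-force oracles (integer pmf
  enumeration; hand-coded step-up).
- Unit conversion: pM/nM/µM/mM/M → mol/L; mass-per-volume units are
  unconvertible without molecular weight and drop the row with a count.
- Empty hit lists, hit ids absent from the library, empty pathway
  universes/queries, and evidence-free pairs are hard errors, not
  silent empties; pipeline failures name their stage.
- Output CSVs carry a provenance comment (package version + hash of the
  analysis-relevant configuration, excluding the output directory);
  timestamps are confined to the run report, so repeated runs are
  byte-identical.
- Test problem sizes: the session-shared bundle uses 150 compounds ×
  25 targets; calibration uses 1,000 null replicates of 500 × 50;
  planted-recovery uses 200 campaigns of 2,000 × 100 via the in-memory
  association sampler (file emission and chemistry are exercised
  separately at the smaller size).

## Known limitations

- Annotation coverage limits recall: compounds without database
  presence (or failing standardization) contribute nothing and are
  reported as unresolved, mirroring real campaigns where a third or
  more of a library may be unannotated.
- The classifier is rule-based on parameter tokens and curator strings;
  it does not weigh potency, dose-dependence or assay quality, and
  inherits any curation errors in the sources.
- Gene-symbol-keyed pathway analysis ignores targets whose evidence
  carries no symbol.
- Fixture dialects cover the fields the pipeline consumes, not the full
  source schemas; real dumps may need light column mapping first.
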