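# Methods

## The annotation model

An EQ phenotype statement has two mandatory slots and four optional ones:

| slot | type | meaning |
|---|---|---|
| entity (E) | anatomy term or post-composition | the structure the quality inheres in |
| quality (Q) | quality-ontology term | the value the variable attribute takes |
| related entity (RE) | anatomy term or post-composition | second participant of a relational quality (*fused with*, *separated from*) |
| count (C) | integer range | literal value for count characters; a single value is min = max |
| measurement + unit | decimal string + unit term | literal value for measured characters |
| comment | free text | curator notes |

The attribute of a traditional character ("shape" in "opercle shape") is
not stored: in the quality ontology every value quality is a subtype of
its attribute quality (*triangular* is_a *shape*), so recording the value
alone is sufficient and non-redundant.

Post-composed entities cover structures absent from the anatomy ontology:
a genus term plus one or more (relation, filler) differentia, nested
fillers allowed. The canonical text rendering is
`GENUS^rel(FILLER)` with nested fillers parenthesized; rendering followed
by parsing is the identity, and the rendering doubles as the equality and
serialization key.

Measurements are kept verbatim as decimal strings end to end: converting
through binary floats could change the digits a curator typed.
Count ranges render with an ASCII hyphen (`40-42`) rather than the
typographic en-dash common in print, for robustness across file
encodings and tools.

## Character categories

A state's category set is computed from its phenotypes against the
quality ontology:

- **relational** — some phenotype names a related entity, or its quality
  descends (is_a) from *quality of related physical entities*
  (PATO:0001238). Both triggers are applied, so the classification works
  even when a curator omitted the RE or when a reduced ontology slice
  lacks the root.
- **monadic** — some phenotype lacks a related entity and its quality
  descends from *quality of single physical entity* (PATO:0001237).
- **composite** — the state carries two or more phenotypes.
- **quantitative** — some phenotype carries a count or measurement.

Categories are not exclusive; a state may fall in several. In the
bundled toy quality ontology the *count* quality sits directly under
*quality* rather than under the single-entity root, so count characters
classify as quantitative only; this keeps the four categories cleanly
separable in fixtures and mirrors how count characters are described as
their own category in the systematics literature.

## Validation

`validate()` is pure and idempotent: it returns a list of issues, each
with a location path and severity, and never mutates the dataset.
Error severity (unknown term, matrix cell referencing an undefined state
symbol, unknown taxon/character in the matrix) blocks NeXML export;
warnings (obsolete term with its replacement hint, field-filter
violation, related entity paired with a single-entity quality, count
paired with a non-count quality, state with no phenotypes) do not.
States with zero phenotypes are legal — matrices are routinely imported
long before annotation — but are flagged so unfinished work is visible.
Obsolete terms are excluded from search but retained in the ontology
graph, so a stored annotation that references one is flagged with its
`replaced_by` pointer instead of silently disappearing.

## Ontology handling

Only the OBO 1.2 flat file is parsed (the dominant format for biological
ontologies; OWL input would be a separate front end). Supported term
tags: id, name, namespace, def, synonym, subset, is_a, relationship,
is_obsolete, replaced_by; unknown tags are skipped with a notice, and
the header's default-namespace applies to terms without an explicit one.
Multiple ontologies merge by term-id union, last-loaded wins on
duplicates (with a warning); edges whose endpoints are not loaded are
kept but reported as dangling references, since multi-ontology
configurations routinely cross-reference.

Closure (`ancestors`/`descendants`) is plain reachability over the edge
subset whose predicates are in the requested relation set, computed on a
networkx digraph. A chain mixing is_a and part_of propagates, which is
exactly what "phenotypes of the pectoral fin, parts included" needs.
There is no further reasoning (no property chains, no OWL semantics).

Search ranks case-folded matches in five tiers — exact name, name
prefix, synonym prefix, name substring, synonym substring — with ties
broken by term id, so results are deterministic. Synonym scopes
(EXACT/BROAD/...) are parsed but do not affect ranking. Case folding is
plain `str.casefold()`; no further Unicode normalization is applied.
Field filters restrict by namespace, by subset ("slim"), and/or by
required ancestor, and an empty filter admits every non-obsolete term.

## File formats

**NEXUS (input).** Only TAXA/CHARACTERS/DATA blocks are read; TREES and
other blocks are skipped with a notice. DIMENSIONS, FORMAT (SYMBOLS,
MISSING and GAP with `?`/`-` defaults, INTERLEAVE), TAXLABELS,
CHARSTATELABELS (or CHARLABELS + STATELABELS) and MATRIX are supported;
comments are stripped, quoted labels kept verbatim, underscores in
unquoted tokens become spaces. State symbols are single characters.
Parse errors (missing `#NEXUS`, wrong row length, duplicate taxon) carry
line numbers. When a file lacks SYMBOLS, the symbol set is inferred from
the matrix. State labels align positionally with the SYMBOLS order;
labels beyond the symbol count are dropped with a warning. NEXUS export
is out of scope — the annotated native format is NeXML.

**NeXML (native).** The writer emits a fixed skeleton (otus/otu,
characters/format/states/state + char, matrix/row/cell) with RDFa-style
`meta` elements: literal values in `content`, resources in `href`,
PhenoXML as embedded XML children. The publication taxon name is the
`otu` label; specimens are nested resource metadata (individualID →
collectionID + catalogNumber). OBO terms appear as CURIEs in PhenoXML
`typeref/@about` and as OBO PURLs in resource-valued metadata.
Polymorphic cells reference `polymorphic_state_set` entries with
explicit members; missing and gap cells reference `uncertain_state_set`
entries with symbols `?` and `-`. Writing is deterministic
(byte-identical output for equal datasets). Counts serialize as
`count_min`/`count_max` and measurements as `measurement`/`unit`
attributes on the PhenoXML quality element; differentia serialize as
`qualifier` elements with a `relation` attribute and a nested `typeref`.
These attribute choices are this library's documented dialect — the
round-trip is exact, but byte-compatibility with other PhenoXML writers
is not claimed. Multiple curators are repeated `dc:creator` elements.
On read, unrecognized metadata properties are preserved (exclusive-c14n
serialized) in `Dataset.extras` and re-emitted at document level, so
foreign annotations survive an edit cycle. Structural well-formedness is
always checked; full schema validation is left to external tools.

## Queries

`exhibits()` materializes one (taxon, character, state, phenotype)
record per matrix cell/state/phenotype combination, in (taxon order,
character order, phenotype order). Missing and gap cells contribute
nothing; polymorphic cells contribute a record per contained symbol,
flagged `polymorphic`. Rows for higher taxa are annotated as-is — no
taxonomic expansion to contained species is attempted.
`phenotypes_of_entity()` matches on the entity's genus only (differentia
fillers are not traversed; traversing them is a possible extension, off
by default) via is_a, plus part_of when `include_parts` is set, and its
results are checked in the test suite against an independent plain-dict
BFS oracle. `summarize()` counts datasets, taxa, characters, states,
distinct phenotypes and annotation records; per-category character
tallies use the full quality-ontology classification when one is
supplied and structure-only rules (RE ⇒ relational, count/measurement ⇒
quantitative, ≥2 phenotypes ⇒ composite) otherwise.

## Synthetic fixtures

The fixture generator emulates a working curation setup end to end: an
anatomy partonomy whose pectoral-fin subtree supports the closure-query
demonstration, a quality ontology with the attribute/value hierarchy
under the single-entity and relational roots, a small taxonomy, museum
collection codes, units, a toy NEXUS matrix ("opercle shape":
triangular/round), and a worked-examples dataset covering all four
character categories plus a post-composed character. Term ids that the
literature ties to specific names keep those CURIEs (TAO:0000250
opercle, PATO:0001875 triangular, PATO:0001237/0001238 roots,
PATO:0000070 count, PATO:0000642 fused with); everything else is an
invented stable id. Random generators (seeded `random.Random`) produce
ontology DAGs (edges only to earlier terms, hence acyclic), NEXUS files
with polymorphic/missing/gap cells and optional interleaving, and fully
annotated datasets exercising every serializable field.

What the fixtures do **not** model: real ontologies' scale (tens of
thousands of terms), cross-ontology logical definitions, free-text noise
of legacy publications, or taxonomic synonymy resolution. Passing tests
therefore demonstrate correctness of parsing, modelling, serialization
and closure logic — not curation quality on real literature, which
depends on curator judgment and complete ontologies.

## Problem sizes and determinism

Default verification sizes were chosen to exercise the combinatorics
while keeping runs quick: 100 random datasets for the NeXML round-trip,
random NEXUS files up to 50 taxa × 100 characters, 50 random DAGs up to
200 terms for closure checks. All randomness flows from a single integer
seed; the acceptance script reproduces its numbers exactly for a given
seed. Property tests use seeded RNGs or derandomized hypothesis profiles
so the suite is deterministic.

## Known limitations

- OBO 1.2 only; no OWL, no live ontology fetching.
- No NEXUS export, no tree blocks, no continuous characters or step
  matrices.
- PhenoXML dialect is round-trip-safe but not validated against the
  historical schema (referenced only by URL, unavailable offline).
- Closure is relation-chain reachability; no reasoner.
- No persistent knowledgebase; cross-dataset queries operate on the
  in-memory annotation records of whatever files are loaded.
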