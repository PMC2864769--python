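"""Taxon-to-phenotype "exhibits" derivation and ontology-closure queries.

The character-by-taxon matrix implicitly links every taxon to the EQ
phenotypes of the state recorded in each of its cells.  :func:`exhibits`
makes those links explicit as :class:`AnnotationTriple` records; the
closure queries then exploit the anatomy ontology so that lexically
unrelated annotations (say, on the *dorsal arrector* and on
*pectoral-fin spine serrations*) can be retrieved together as phenotypes
of the structure they are both part of (the *pectoral fin*).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from typing import Iterable, Optional

from .datamodel import Category, CellKind, Dataset, Phenotype, State, Taxon, classify
from .ontology import IS_A, PART_OF, Ontology, TermId, TermLookupError


@dataclass(frozen=True)
class AnnotationTriple:
    """One derived (taxon, state, phenotype) "exhibits" record."""

    taxon: Taxon
    character_index: int
    state_symbol: str
    phenotype: Phenotype
    source: str = ""
    polymorphic: bool = False


def exhibits(dataset: Dataset) -> list[AnnotationTriple]:
    """Derive all annotation triples from the matrix.

    One triple per (cell, matched state, phenotype).  Missing and gap
    cells contribute nothing; polymorphic cells contribute triples for
    every listed symbol, flagged ``polymorphic=True``.  Output order is
    (taxon order, character order, state phenotype order).
    """
    triples: list[AnnotationTriple] = []
    for taxon in dataset.taxa:
        for char in dataset.characters:
            cell = dataset.matrix.get((taxon.publication_name, char.index))
            if cell is None or cell.kind in (CellKind.MISSING, CellKind.GAP):
                continue
            poly = cell.kind is CellKind.POLYMORPHIC
            for symbol in cell.symbols:
                state = char.state_by_symbol(symbol)
                if state is None:
                    continue
                for phenotype in state.phenotypes:
                    triples.append(
                        AnnotationTriple(
                            taxon=taxon,
                            character_index=char.index,
                            state_symbol=symbol,
                            phenotype=phenotype,
                            source=dataset.publication,
                            polymorphic=poly,
                        )
                    )
    return triples


def phenotypes_of_entity(
    triples: Iterable[AnnotationTriple],
    ontology: Ontology,
    target: TermId,
    include_parts: bool = True,
) -> list[AnnotationTriple]:
    """Triples whose phenotype entity is the target or lies below it.

    The entity's genus (for post-compositions, the genus term) matches if
    it equals ``target`` or has ``target`` among its ancestors via is_a
    edges — and via part_of edges too when ``include_parts`` is set.
    Related entities are not considered.
    """
    if target not in ontology:
        raise TermLookupError(f"unknown term: {target}")
    relations = {IS_A, PART_OF} if include_parts else {IS_A}
    out = []
    for triple in triples:
        genus = triple.phenotype.entity.genus
        if genus == target:
            out.append(triple)
            continue
        if genus in ontology and target in ontology.ancestors(genus, relations):
            out.append(triple)
    return out


@dataclass(frozen=True)
class Summary:
    datasets: int = 0
    taxa: int = 0
    characters: int = 0
    states: int = 0
    distinct_phenotypes: int = 0
    annotations: int = 0
    # character tallies per category name; None when no quality ontology
    # was supplied and only structural rules were applied
    category_tallies: Optional[dict[str, int]] = None


def summarize(
    datasets: list[Dataset], quality_ontology: Optional[Ontology] = None
) -> Summary:
    """Corpus-style counts over a collection of annotated datasets.

    With a quality ontology the per-category character tallies use the
    full classification (quality-ontology descent); without one they fall
    back to structure-only rules (related entity present -> relational,
    count or measurement -> quantitative, >=2 phenotypes -> composite).
    A character is tallied under every category any of its states falls
    into.
    """
    n_taxa = n_chars = n_states = n_annot = 0
    distinct: set[Phenotype] = set()
    tallies = {c.value: 0 for c in Category}
    for ds in datasets:
        n_taxa += len(ds.taxa)
        n_chars += len(ds.characters)
        n_annot += len(exhibits(ds))
        for char in ds.characters:
            char_cats: set[Category] = set()
            for state in char.states:
                n_states += 1
                distinct.update(state.phenotypes)
                if quality_ontology is not None:
                    char_cats |= classify(state, quality_ontology)
                else:
                    char_cats |= _structural_categories(state)
            for cat in char_cats:
                tallies[cat.value] += 1
    return Summary(
        datasets=len(datasets),
        taxa=n_taxa,
        characters=n_chars,
        states=n_states,
        distinct_phenotypes=len(distinct),
        annotations=n_annot,
        category_tallies=tallies,
    )


def _structural_categories(state: State) -> set[Category]:
    cats: set[Category] = set()
    for p in state.phenotypes:
        if p.related_entity is not None:
            cats.add(Category.RELATIONAL)
        if p.count is not None or p.measurement is not None:
            cats.add(Category.QUANTITATIVE)
    if len(state.phenotypes) >= 2:
        cats.add(Category.COMPOSITE)
    return cats


TSV_COLUMNS = [
    "taxon",
    "valid_taxon",
    "character",
    "state",
    "entity",
    "quality",
    "related_entity",
    "count",
    "source",
]


def triples_to_tsv(triples: Iterable[AnnotationTriple]) -> str:
    """Render triples as a tab-separated table (one row per annotation)."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(TSV_COLUMNS)
    for t in triples:
        p = t.phenotype
        writer.writerow(
            [
                t.taxon.publication_name,
                t.taxon.valid_taxon or "",
                t.character_index,
                t.state_symbol,
                p.entity.render(),
                p.quality,
                p.related_entity.render() if p.related_entity else "",
                p.count.render() if p.count else "",
                t.source,
            ]
        )
    return buf.getvalue()
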