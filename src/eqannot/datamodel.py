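"""Entity-Quality phenotype model and character/taxon/matrix model.

The central object is :class:`Phenotype`, one EQ statement: an entity (an
ontology term or a post-composition), a quality term, and optionally a
related entity (for relational qualities such as *fused with*), a count
range, or a measurement with unit.  States carry ordered lists of
phenotypes; characters carry ordered states; a :class:`Dataset` ties taxa,
characters and the character-by-taxon matrix together with publication
metadata.

Character-category classification follows the standard reading of the
quality ontology: value qualities under *quality of single physical
entity* (PATO:0001237) mark monadic states, those under *quality of
related physical entities* (PATO:0001238) mark relational states, two or
more phenotypes on one state make it composite, and counts or
measurements make it quantitative.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Union

from .ontology import IS_A, Ontology, TermFilter, TermId, TermLookupError

# Quality-ontology roots used for category classification (PATO CURIEs).
SINGLE_ENTITY_QUALITY: TermId = "PATO:0001237"
RELATIONAL_QUALITY: TermId = "PATO:0001238"
COUNT_QUALITY: TermId = "PATO:0000070"


# ---------------------------------------------------------------------------
# Post-compositions


@dataclass(frozen=True)
class PostComposition:
    """A term composed on the fly: a genus constrained by relation-filler
    differentia, e.g. *process* part_of *epiotic*."""

    genus: TermId
    differentia: tuple[tuple[str, Union[TermId, "PostComposition"]], ...]

    def __post_init__(self) -> None:
        if not self.differentia:
            raise ValueError("post-composition requires at least one differentia")

    def render(self) -> str:
        parts = "^".join(
            f"{rel}({filler.render() if isinstance(filler, PostComposition) else filler})"
            for rel, filler in self.differentia
        )
        return f"{self.genus}^{parts}"


def compose(
    genus: TermId,
    differentia: list[tuple[str, Union[TermId, PostComposition]]],
) -> PostComposition:
    """Build a post-composition; ``differentia`` must be non-empty."""
    if not differentia:
        raise ValueError("post-composition requires at least one differentia")
    return PostComposition(genus=genus, differentia=tuple(differentia))


_PC_TOKEN = re.compile(r"[^\^()]+|[\^()]")


def parse_postcomposition(text: str) -> Union[TermId, PostComposition]:
    """Inverse of :meth:`PostComposition.render`; a bare CURIE parses to itself."""
    tokens = _PC_TOKEN.findall(text.strip())
    pos = 0

    def parse_expr() -> Union[TermId, PostComposition]:
        nonlocal pos
        if pos >= len(tokens):
            raise ValueError(f"truncated post-composition: {text!r}")
        head = tokens[pos]
        pos += 1
        diffs: list[tuple[str, Union[TermId, PostComposition]]] = []
        while pos < len(tokens) and tokens[pos] == "^":
            pos += 1
            rel = tokens[pos]
            pos += 1
            if pos >= len(tokens) or tokens[pos] != "(":
                raise ValueError(f"expected '(' after relation in {text!r}")
            pos += 1
            filler = parse_expr()
            if pos >= len(tokens) or tokens[pos] != ")":
                raise ValueError(f"unbalanced parentheses in {text!r}")
            pos += 1
            diffs.append((rel, filler))
        if not diffs:
            return head
        return PostComposition(genus=head, differentia=tuple(diffs))

    result = parse_expr()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in post-composition: {text!r}")
    return result


@dataclass(frozen=True)
class EntityRef:
    """Entity slot of an EQ statement: a plain term or a post-composition,
    with an optional curator comment (e.g. interpretation difficulties)."""

    term: Optional[TermId] = None
    composed: Optional[PostComposition] = None
    comment: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.term is None) == (self.composed is None):
            raise ValueError("EntityRef holds exactly one of term / composed")

    @property
    def genus(self) -> TermId:
        """The headmost term: the term itself, or the post-composition genus."""
        return self.term if self.term is not None else self.composed.genus

    def render(self) -> str:
        return self.term if self.term is not None else self.composed.render()


@dataclass(frozen=True)
class CountRange:
    """An integer count or closed range (e.g. vertebrae 40-42)."""

    min: int
    max: int

    def __post_init__(self) -> None:
        if self.min > self.max:
            raise ValueError(f"count range min {self.min} > max {self.max}")

    def render(self) -> str:
        return str(self.min) if self.min == self.max else f"{self.min}-{self.max}"

    @classmethod
    def parse(cls, text: str) -> "CountRange":
        lo, sep, hi = text.partition("-")
        return cls(int(lo), int(hi)) if sep else cls(int(text), int(text))


@dataclass(frozen=True)
class Phenotype:
    """One EQ statement: E entity, Q quality, optional RE related entity,
    optional C count, optional measurement with unit."""

    entity: EntityRef
    quality: TermId
    related_entity: Optional[EntityRef] = None
    count: Optional[CountRange] = None
    measurement: Optional[str] = None  # decimal kept verbatim as a string
    unit: Optional[TermId] = None
    comment: Optional[str] = None

    def __post_init__(self) -> None:
        if self.measurement is not None and self.unit is None:
            raise ValueError("a measurement requires a unit")


# ---------------------------------------------------------------------------
# Characters, taxa, matrix


@dataclass(frozen=True)
class State:
    """A character state: matrix symbol, free-text label, and its EQ phenotypes."""

    symbol: str
    label: str = ""
    comment: Optional[str] = None
    figures: tuple[str, ...] = ()
    phenotypes: tuple[Phenotype, ...] = ()


def attach_phenotype(state: State, phenotype: Phenotype) -> State:
    """Append one phenotype to a state (order of prior phenotypes preserved)."""
    return replace(state, phenotypes=state.phenotypes + (phenotype,))


@dataclass(frozen=True)
class Character:
    """A numbered character; ``index`` matches the publication's numbering."""

    index: int
    label: str = ""
    comment: Optional[str] = None
    figures: tuple[str, ...] = ()
    states: tuple[State, ...] = ()

    def state_by_symbol(self, symbol: str) -> Optional[State]:
        for st in self.states:
            if st.symbol == symbol:
                return st
        return None


@dataclass(frozen=True)
class Specimen:
    """A voucher specimen: museum collection code term + catalog number."""

    collection: TermId
    catalog_number: str

    def __post_init__(self) -> None:
        if not self.collection or not self.catalog_number:
            raise ValueError("specimen requires collection and catalog number")


@dataclass(frozen=True)
class Taxon:
    publication_name: str
    valid_taxon: Optional[TermId] = None
    matrix_name: Optional[str] = None
    specimens: tuple[Specimen, ...] = ()
    comment: Optional[str] = None
    figures: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.publication_name:
            raise ValueError("taxon requires a publication name")


class CellKind(Enum):
    SINGLE = "single"
    POLYMORPHIC = "polymorphic"
    MISSING = "missing"
    GAP = "gap"


@dataclass(frozen=True)
class CellValue:
    kind: CellKind
    symbols: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind is CellKind.SINGLE and len(self.symbols) != 1:
            raise ValueError("single cell holds exactly one symbol")
        if self.kind is CellKind.POLYMORPHIC and len(self.symbols) < 2:
            raise ValueError("polymorphic cell holds at least two symbols")
        if self.kind in (CellKind.MISSING, CellKind.GAP) and self.symbols:
            raise ValueError(f"{self.kind.value} cell holds no symbols")

    @classmethod
    def single(cls, symbol: str) -> "CellValue":
        return cls(CellKind.SINGLE, (symbol,))

    @classmethod
    def polymorphic(cls, symbols) -> "CellValue":
        return cls(CellKind.POLYMORPHIC, tuple(sorted(set(symbols))))

    @classmethod
    def missing(cls) -> "CellValue":
        return cls(CellKind.MISSING)

    @classmethod
    def gap(cls) -> "CellValue":
        return cls(CellKind.GAP)


@dataclass
class Dataset:
    """An annotated character-by-taxon matrix with publication metadata.

    ``matrix`` maps (taxon publication name, 1-based character index) to a
    :class:`CellValue`.  ``extras`` holds opaque metadata payloads carried
    through file round-trips.
    """

    curators: list[str] = field(default_factory=list)
    publication: str = ""
    publication_notes: str = ""
    taxa: list[Taxon] = field(default_factory=list)
    characters: list[Character] = field(default_factory=list)
    matrix: dict[tuple[str, int], CellValue] = field(default_factory=dict)
    extras: list[str] = field(default_factory=list)

    def taxon(self, publication_name: str) -> Taxon:
        for t in self.taxa:
            if t.publication_name == publication_name:
                return t
        raise KeyError(publication_name)

    def character(self, index: int) -> Character:
        return self.characters[index - 1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.curators == other.curators
            and self.publication == other.publication
            and self.publication_notes == other.publication_notes
            and self.taxa == other.taxa
            and self.characters == other.characters
            and self.matrix == other.matrix
            and self.extras == other.extras
        )


# ---------------------------------------------------------------------------
# Character-category classification


class Category(Enum):
    MONADIC = "monadic"
    RELATIONAL = "relational"
    COMPOSITE = "composite"
    QUANTITATIVE = "quantitative"


def _quality_under(quality: TermId, root: TermId, pato: Ontology) -> bool:
    if quality == root:
        return True
    try:
        return root in pato.ancestors(quality, {IS_A})
    except TermLookupError:
        raise TermLookupError(f"quality term not in ontology: {quality}") from None


def classify(state: State, pato: Ontology) -> set[Category]:
    """Category set for one character state given the quality ontology.

    A state may fall in more than one category: relational if any phenotype
    names a related entity or uses a relational quality; monadic if any
    phenotype lacks one and its quality sits under the single-entity root;
    composite if it carries two or more phenotypes; quantitative if any
    phenotype has a count or measurement.
    """
    cats: set[Category] = set()
    for p in state.phenotypes:
        relational_quality = _quality_under(p.quality, RELATIONAL_QUALITY, pato)
        if p.related_entity is not None or relational_quality:
            cats.add(Category.RELATIONAL)
        if p.related_entity is None and _quality_under(
            p.quality, SINGLE_ENTITY_QUALITY, pato
        ):
            cats.add(Category.MONADIC)
        if p.count is not None or p.measurement is not None:
            cats.add(Category.QUANTITATIVE)
    if len(state.phenotypes) >= 2:
        cats.add(Category.COMPOSITE)
    return cats


# ---------------------------------------------------------------------------
# Validation


class Severity(Enum):
    ERROR = "error"
    WARNING = "warning"


@dataclass(frozen=True)
class Issue:
    severity: Severity
    code: str
    message: str
    location: str

    def __str__(self) -> str:
        return f"{self.severity.value}: {self.location}: {self.message} [{self.code}]"


def _entity_terms(ref: EntityRef) -> list[TermId]:
    """All TermIds mentioned by an entity reference, genus first."""
    if ref.term is not None:
        return [ref.term]
    out: list[TermId] = []

    def walk(pc: PostComposition) -> None:
        out.append(pc.genus)
        for _, filler in pc.differentia:
            if isinstance(filler, PostComposition):
                walk(filler)
            else:
                out.append(filler)

    walk(ref.composed)
    return out


def validate(
    dataset: Dataset,
    ontology: Ontology,
    filters: Optional[dict[str, TermFilter]] = None,
) -> list[Issue]:
    """Check a dataset against the loaded ontologies and field filters.

    Returns issues rather than raising; each carries a location string
    (taxon / character / state path) and a severity.  ``filters`` keys are
    field names: "entity", "quality", "related_entity", "unit", "taxon",
    "collection".
    """
    filters = filters or {}
    issues: list[Issue] = []

    def check_term(term_id: TermId, fieldname: str, location: str) -> None:
        if term_id not in ontology:
            issues.append(
                Issue(Severity.ERROR, "unknown-term",
                      f"term {term_id} not found in loaded ontologies", location)
            )
            return
        term = ontology.term(term_id)
        if term.obsolete:
            hint = f"; replaced by {term.replaced_by}" if term.replaced_by else ""
            issues.append(
                Issue(Severity.WARNING, "obsolete-term",
                      f"term {term_id} is obsolete{hint}", location)
            )
            return
        f = filters.get(fieldname)
        if f is not None and not f.admits(term, ontology):
            issues.append(
                Issue(Severity.WARNING, "filter-violation",
                      f"term {term_id} violates the {fieldname} field filter", location)
            )

    def check_entity(ref: EntityRef, fieldname: str, location: str) -> None:
        for tid in _entity_terms(ref):
            check_term(tid, fieldname, location)

    for taxon in dataset.taxa:
        loc = f"taxon {taxon.publication_name!r}"
        if taxon.valid_taxon is not None:
            check_term(taxon.valid_taxon, "taxon", loc)
        for sp in taxon.specimens:
            check_term(sp.collection, "collection", f"{loc} specimen {sp.catalog_number}")

    for char in dataset.characters:
        for state in char.states:
            loc = f"character {char.index} state {state.symbol!r}"
            if not state.phenotypes:
                issues.append(
                    Issue(Severity.WARNING, "no-phenotypes",
                          "state has no EQ phenotypes", loc)
                )
            for p in state.phenotypes:
                check_entity(p.entity, "entity", loc)
                check_term(p.quality, "quality", loc)
                if p.related_entity is not None:
                    check_entity(p.related_entity, "related_entity", loc)
                if p.unit is not None:
                    check_term(p.unit, "unit", loc)
                if p.quality in ontology:
                    quality_obsolete = ontology.term(p.quality).obsolete
                    if not quality_obsolete:
                        if p.related_entity is not None and _quality_under(
                            p.quality, SINGLE_ENTITY_QUALITY, ontology
                        ):
                            issues.append(
                                Issue(Severity.WARNING, "relational-mismatch",
                                      f"related entity given but quality {p.quality} "
                                      "is a single-entity quality", loc)
                            )
                        if p.count is not None and not _quality_under(
                            p.quality, COUNT_QUALITY, ontology
                        ):
                            issues.append(
                                Issue(Severity.WARNING, "count-mismatch",
                                      f"count given but quality {p.quality} "
                                      "is not a count quality", loc)
                            )

    for (taxon_name, char_index), cell in dataset.matrix.items():
        loc = f"cell ({taxon_name!r}, {char_index})"
        try:
            dataset.taxon(taxon_name)
        except KeyError:
            issues.append(
                Issue(Severity.ERROR, "unknown-taxon",
                      f"matrix row references unknown taxon {taxon_name!r}", loc)
            )
        if not 1 <= char_index <= len(dataset.characters):
            issues.append(
                Issue(Severity.ERROR, "unknown-character",
                      f"matrix cell references unknown character {char_index}", loc)
            )
            continue
        char = dataset.character(char_index)
        for sym in cell.symbols:
            if char.state_by_symbol(sym) is None:
                issues.append(
                    Issue(Severity.ERROR, "undefined-state",
                          f"cell uses symbol {sym!r} not defined for character "
                          f"{char_index}", loc)
                )
    return issues
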