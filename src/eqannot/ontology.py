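"""OBO ontology parsing, merging, filtered search, and relation closure.

Supports the OBO 1.2 flat-file format only (the prevalent format for
biological ontologies).  The object model is deliberately small: terms with
names, synonyms, namespaces and subset ("slim") membership, plus a typed
edge list over ``is_a``, ``part_of`` and any other relationship tags found
in the file.  Reasoning is limited to transitive closure over a chosen set
of relations, which is what entity-parthood queries over anatomy
ontologies require.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Union

import networkx as nx

logger = logging.getLogger("eqannot")

IS_A = "is_a"
PART_OF = "part_of"

#: TermIds are CURIE strings "PREFIX:LOCAL", e.g. "TAO:0000250".
TermId = str


class OboParseError(ValueError):
    """Raised for malformed OBO input; message names the offending line."""


class TermLookupError(KeyError):
    """Raised when a TermId is not present in an ontology."""


def split_curie(curie: TermId) -> tuple[str, str]:
    """Split ``PREFIX:LOCAL`` and validate both parts are non-empty."""
    prefix, sep, local = curie.partition(":")
    if not sep or not prefix or not local or ":" in local:
        raise ValueError(f"not a valid CURIE: {curie!r}")
    return prefix, local


def curie_to_purl(curie: TermId) -> str:
    """OBO library PURL for a CURIE: http://purl.obolibrary.org/obo/PREFIX_LOCAL."""
    prefix, local = split_curie(curie)
    return f"http://purl.obolibrary.org/obo/{prefix}_{local}"


def purl_to_curie(purl: str) -> TermId:
    m = re.fullmatch(r"http://purl\.obolibrary\.org/obo/([^_/]+)_(.+)", purl)
    if not m:
        raise ValueError(f"not an OBO PURL: {purl!r}")
    return f"{m.group(1)}:{m.group(2)}"


@dataclass(frozen=True)
class Term:
    id: TermId
    name: str = ""
    namespace: str = ""
    synonyms: tuple[str, ...] = ()
    subsets: tuple[str, ...] = ()
    obsolete: bool = False
    replaced_by: Optional[TermId] = None
    definition: Optional[str] = None


@dataclass(frozen=True)
class TermFilter:
    """Restricts which terms a data-entry field may draw from.

    An empty filter admits every non-obsolete term.  ``ancestor_constraint``
    admits only terms having a given ancestor via the given relations
    (e.g. "descendants of *portion of organism substance* via is_a").
    """

    namespaces: Optional[frozenset[str]] = None
    subsets: Optional[frozenset[str]] = None
    ancestor_constraint: Optional[tuple[TermId, frozenset[str]]] = None

    def admits(self, term: Term, ontology: "Ontology") -> bool:
        if term.obsolete:
            return False
        if self.namespaces is not None and term.namespace not in self.namespaces:
            return False
        if self.subsets is not None and not set(term.subsets) & self.subsets:
            return False
        if self.ancestor_constraint is not None:
            root, relations = self.ancestor_constraint
            if term.id != root and root not in ontology.ancestors(term.id, relations):
                return False
        return True


EMPTY_FILTER = TermFilter()


@dataclass
class Ontology:
    """A term set plus a typed edge list (subject, predicate, object)."""

    terms: dict[TermId, Term] = field(default_factory=dict)
    edges: list[tuple[TermId, str, TermId]] = field(default_factory=list)
    sources: list[str] = field(default_factory=list)

    def __contains__(self, term_id: TermId) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def term(self, term_id: TermId) -> Term:
        try:
            return self.terms[term_id]
        except KeyError:
            raise TermLookupError(f"unknown term: {term_id}") from None

    def dangling_references(self) -> list[tuple[TermId, str, TermId]]:
        """Edges whose endpoints do not resolve to a loaded term."""
        return [
            e for e in self.edges if e[0] not in self.terms or e[2] not in self.terms
        ]

    # -- closure ---------------------------------------------------------

    def _graph(self, relations: frozenset[str]) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(
            (s, o) for s, p, o in self.edges if p in relations
        )
        return g

    def ancestors(
        self, start: TermId, relations: Iterable[str] = (IS_A, PART_OF)
    ) -> set[TermId]:
        """All terms reachable from ``start`` via chains of ``relations`` edges.

        ``start`` itself is excluded.  A chain mixing ``is_a`` and
        ``part_of`` still propagates: reachability is over the union of the
        requested edge types.
        """
        if start not in self.terms:
            raise TermLookupError(f"unknown term: {start}")
        g = self._graph(frozenset(relations))
        return nx.descendants(g, start) - {start}

    def descendants(
        self, start: TermId, relations: Iterable[str] = (IS_A, PART_OF)
    ) -> set[TermId]:
        """Inverse of :meth:`ancestors`: terms from which ``start`` is reachable."""
        if start not in self.terms:
            raise TermLookupError(f"unknown term: {start}")
        g = self._graph(frozenset(relations))
        return nx.ancestors(g, start) - {start}

    def is_ancestor(
        self, ancestor: TermId, of: TermId, relations: Iterable[str] = (IS_A,)
    ) -> bool:
        return ancestor in self.ancestors(of, relations)

    # -- search ----------------------------------------------------------

    def search(
        self,
        query: str,
        term_filter: TermFilter = EMPTY_FILTER,
        limit: int = 20,
    ) -> list[Term]:
        """Ranked, case-insensitive term lookup for autocomplete.

        Ranking tiers: exact name match > name prefix > synonym prefix >
        name substring > synonym substring.  Obsolete terms are never
        returned.  Ties break lexicographically on TermId, so results are
        deterministic.
        """
        q = query.strip().casefold()
        if not q:
            raise ValueError("search query is empty")
        ranked: list[tuple[int, TermId, Term]] = []
        for term in self.terms.values():
            if not term_filter.admits(term, self):
                continue
            tier = _match_tier(term, q)
            if tier is not None:
                ranked.append((tier, term.id, term))
        ranked.sort(key=lambda r: (r[0], r[1]))
        return [t for _, _, t in ranked[:limit]]


def _match_tier(term: Term, q: str) -> Optional[int]:
    name = term.name.casefold()
    if name == q:
        return 0
    if name.startswith(q):
        return 1
    syns = [s.casefold() for s in term.synonyms]
    if any(s.startswith(q) for s in syns):
        return 2
    if q in name:
        return 3
    if any(q in s for s in syns):
        return 4
    return None


# ---------------------------------------------------------------------------
# OBO 1.2 flat-file parsing


_SYNONYM_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"')

_KNOWN_TAGS = {
    "id",
    "name",
    "namespace",
    "def",
    "synonym",
    "subset",
    "is_a",
    "relationship",
    "is_obsolete",
    "replaced_by",
}


def _strip_obo_comment(line: str) -> str:
    # an unescaped "!" starts a comment
    out = []
    escaped = False
    for ch in line:
        if escaped:
            out.append(ch)
            escaped = False
        elif ch == "\\":
            out.append(ch)
            escaped = True
        elif ch == "!":
            break
        else:
            out.append(ch)
    return "".join(out).strip()


def _unescape(value: str) -> str:
    return re.sub(r"\\(.)", r"\1", value)


def parse_obo(source: Union[str, bytes, IO], source_name: str = "<obo>") -> Ontology:
    """Parse an OBO 1.2 flat file into an :class:`Ontology`.

    Recognised tags inside ``[Term]`` stanzas: id, name, namespace, def,
    synonym, subset, is_a, relationship, is_obsolete, replaced_by.  Unknown
    tags are skipped with a logged notice.  The header's
    ``default-namespace`` applies to terms without an explicit namespace.
    ``relationship: part_of X`` (and any other relation) become typed edges.
    """
    if hasattr(source, "read"):
        source = source.read()
    if isinstance(source, bytes):
        source = source.decode("utf-8")

    default_namespace = ""
    terms: dict[TermId, Term] = {}
    edges: list[tuple[TermId, str, TermId]] = []
    unknown_tags: set[str] = set()

    stanza: Optional[str] = None  # current stanza type, e.g. "Term"
    cur: Optional[dict] = None
    cur_line = 0

    def finish() -> None:
        nonlocal cur
        if cur is None:
            return
        if stanza == "Term":
            if cur["id"] is None:
                raise OboParseError(
                    f"{source_name}:{cur_line}: [Term] stanza has no id tag"
                )
            term = Term(
                id=cur["id"],
                name=cur["name"],
                namespace=cur["namespace"] or default_namespace,
                synonyms=tuple(cur["synonyms"]),
                subsets=tuple(cur["subsets"]),
                obsolete=cur["obsolete"],
                replaced_by=cur["replaced_by"],
                definition=cur["definition"],
            )
            if term.id in terms:
                logger.warning("%s: duplicate term %s, keeping last", source_name, term.id)
            terms[term.id] = term
            edges.extend(cur["edges"])
        cur = None

    for lineno, raw in enumerate(source.splitlines(), start=1):
        line = _strip_obo_comment(raw)
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            finish()
            stanza = line[1:-1]
            cur_line = lineno
            if stanza == "Term":
                cur = {
                    "id": None,
                    "name": "",
                    "namespace": "",
                    "synonyms": [],
                    "subsets": [],
                    "obsolete": False,
                    "replaced_by": None,
                    "definition": None,
                    "edges": [],
                }
            else:
                cur = {}  # non-Term stanza: contents ignored
            continue

        tag, sep, value = line.partition(":")
        if not sep:
            raise OboParseError(f"{source_name}:{lineno}: expected 'tag: value', got {raw!r}")
        tag = tag.strip()
        value = value.strip()

        if stanza is None:
            # header clause
            if tag == "default-namespace":
                default_namespace = value
            continue
        if stanza != "Term":
            continue
        assert cur is not None

        if tag == "id":
            cur["id"] = value
        elif tag == "name":
            cur["name"] = _unescape(value)
        elif tag == "namespace":
            cur["namespace"] = value
        elif tag == "def":
            m = _SYNONYM_RE.match(value)
            cur["definition"] = _unescape(m.group("text")) if m else value
        elif tag == "synonym":
            m = _SYNONYM_RE.match(value)
            if not m:
                raise OboParseError(
                    f"{source_name}:{lineno}: malformed synonym value {value!r}"
                )
            cur["synonyms"].append(_unescape(m.group("text")))
        elif tag == "subset":
            cur["subsets"].append(value)
        elif tag == "is_a":
            if cur["id"] is None:
                raise OboParseError(f"{source_name}:{lineno}: is_a before id")
            cur["edges"].append((cur["id"], IS_A, value))
        elif tag == "relationship":
            parts = value.split()
            if len(parts) < 2:
                raise OboParseError(
                    f"{source_name}:{lineno}: malformed relationship {value!r}"
                )
            if cur["id"] is None:
                raise OboParseError(f"{source_name}:{lineno}: relationship before id")
            cur["edges"].append((cur["id"], parts[0], parts[1]))
        elif tag == "is_obsolete":
            cur["obsolete"] = value.lower() == "true"
        elif tag == "replaced_by":
            cur["replaced_by"] = value
        elif tag not in _KNOWN_TAGS:
            if tag not in unknown_tags:
                unknown_tags.add(tag)
                logger.info("%s:%d: ignoring unknown OBO tag %r", source_name, lineno, tag)

    finish()

    onto = Ontology(terms=terms, edges=edges, sources=[source_name])
    for s, p, o in onto.dangling_references():
        logger.warning("%s: edge (%s %s %s) references unknown term", source_name, s, p, o)
    return onto


def load_obo(path: str) -> Ontology:
    with open(path, "rb") as fh:
        return parse_obo(fh, source_name=path)


def merge(ontologies: Iterable[Ontology]) -> Ontology:
    """Union of terms and edges; duplicate TermIds resolve last-loaded-wins."""
    out = Ontology()
    seen_edges: set[tuple[TermId, str, TermId]] = set()
    for onto in ontologies:
        for term_id, term in onto.terms.items():
            if term_id in out.terms:
                logger.warning("merge: duplicate term %s, keeping last-loaded", term_id)
            out.terms[term_id] = term
        for edge in onto.edges:
            if edge not in seen_edges:
                seen_edges.add(edge)
                out.edges.append(edge)
        out.sources.extend(onto.sources)
    return out


def write_obo(ontology: Ontology, default_namespace: str = "") -> str:
    """Serialize back to OBO 1.2 (primarily for fixtures and round-trip tests)."""
    lines = ["format-version: 1.2"]
    if default_namespace:
        lines.append(f"default-namespace: {default_namespace}")
    by_subject: dict[TermId, list[tuple[str, TermId]]] = {}
    for s, p, o in ontology.edges:
        by_subject.setdefault(s, []).append((p, o))
    for term_id in sorted(ontology.terms):
        t = ontology.terms[term_id]
        lines.append("")
        lines.append("[Term]")
        lines.append(f"id: {t.id}")
        if t.name:
            lines.append(f"name: {t.name}")
        if t.namespace and t.namespace != default_namespace:
            lines.append(f"namespace: {t.namespace}")
        if t.definition:
            lines.append(f'def: "{t.definition}" []')
        for syn in t.synonyms:
            lines.append(f'synonym: "{syn}" EXACT []')
        for sub in t.subsets:
            lines.append(f"subset: {sub}")
        for p, o in by_subject.get(term_id, []):
            if p == IS_A:
                lines.append(f"is_a: {o}")
            else:
                lines.append(f"relationship: {p} {o}")
        if t.obsolete:
            lines.append("is_obsolete: true")
        if t.replaced_by:
            lines.append(f"replaced_by: {t.replaced_by}")
    return "\n".join(lines) + "\n"
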