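"""NeXML read/write with RDFa-style metadata and embedded PhenoXML.

The native on-disk format is NeXML (http://www.nexml.org): taxa as
``otus/otu``, characters as ``characters/format/states/state`` plus
``char`` elements, cells as ``matrix/row/cell``.  Annotations ride along
as ``meta`` elements in the RDFa style — literal values in a ``content``
attribute, resource values in an ``href`` attribute, and EQ phenotype
blocks as embedded PhenoXML children of a ``describesPhenotype`` meta.

The metadata vocabulary is fixed: Dublin Core for document-level fields
(creator, references, description), Darwin Core for taxon and specimen
identifiers (taxonID, individualID, collectionID, catalogNumber),
rdfs:comment for curator comments, Phenoscape vocabulary terms
(hasMatrixName, inFigure, describesPhenotype) for the remaining fields,
and the PhenoXML element set (phenotype, phenotype_character, bearer,
quality, related_entity, typeref) for EQ statements.  OBO terms appear as
CURIEs in ``typeref`` ``about`` attributes and as OBO PURLs
(http://purl.obolibrary.org/obo/PREFIX_LOCAL) in resource-valued
metadata.

Writing is deterministic: the same dataset always yields byte-identical
output (fixed element order, fixed attribute order, fixed prefix
declarations), which makes files diffable under version control.

Counts serialize as ``count_min``/``count_max`` attributes and
measurements as ``measurement``/``unit`` attributes on the PhenoXML
``quality`` element; post-composition differentia serialize as
``qualifier`` children of ``typeref`` carrying a ``relation`` attribute
and a nested ``typeref`` filler.  This encoding is this library's
documented dialect; it round-trips exactly but makes no claim of byte
compatibility with files written by other tools.
"""

from __future__ import annotations

import logging
from typing import IO, Optional, Union

from lxml import etree

from .datamodel import (
    CellKind,
    CellValue,
    Character,
    CountRange,
    Dataset,
    EntityRef,
    Phenotype,
    PostComposition,
    Specimen,
    State,
    Taxon,
    validate,
)
from .ontology import Ontology, TermId, curie_to_purl, purl_to_curie

logger = logging.getLogger("eqannot")

NS_NEX = "http://www.nexml.org/2009"
NS_XSI = "http://www.w3.org/2001/XMLSchema-instance"
NS_DC = "http://purl.org/dc/terms/"
NS_DWC = "http://rs.tdwg.org/dwc/terms/"
NS_RDFS = "http://www.w3.org/2000/01/rdf-schema#"
NS_PS = "http://vocab.phenoscape.org/"
NS_PHENO = "http://www.bioontologies.org/obd/schema/pheno"

NSMAP = {
    "nex": NS_NEX,
    "xsi": NS_XSI,
    "dc": NS_DC,
    "dwc": NS_DWC,
    "rdfs": NS_RDFS,
    "ps": NS_PS,
    "pheno": NS_PHENO,
}

#: The full metadata vocabulary this writer may emit, as
#: (local name, namespace URI) pairs.
METADATA_VOCABULARY: frozenset[tuple[str, str]] = frozenset(
    {
        ("creator", NS_DC),
        ("references", NS_DC),
        ("description", NS_DC),
        ("taxonID", NS_DWC),
        ("individualID", NS_DWC),
        ("collectionID", NS_DWC),
        ("catalogNumber", NS_DWC),
        ("comment", NS_RDFS),
        ("hasMatrixName", NS_PS),
        ("inFigure", NS_PS),
        ("describesPhenotype", NS_PS),
        ("phenotype", NS_PHENO),
        ("phenotype_character", NS_PHENO),
        ("bearer", NS_PHENO),
        ("quality", NS_PHENO),
        ("related_entity", NS_PHENO),
        ("typeref", NS_PHENO),
    }
)


class NexmlError(ValueError):
    pass


class NexmlValidationError(NexmlError):
    """Writing was refused because the dataset has validation errors."""

    def __init__(self, issues):
        self.issues = issues
        super().__init__(
            "dataset has validation errors:\n"
            + "\n".join(str(i) for i in issues)
        )


def _nex(tag: str) -> str:
    return f"{{{NS_NEX}}}{tag}"


def _pheno(tag: str) -> str:
    return f"{{{NS_PHENO}}}{tag}"


def _literal_meta(parent, prop: str, content: str):
    el = etree.SubElement(parent, _nex("meta"), nsmap=None)
    el.set(f"{{{NS_XSI}}}type", "nex:LiteralMeta")
    el.set("property", prop)
    el.set("content", content)
    return el


def _resource_meta(parent, rel: str, href: Optional[str] = None):
    el = etree.SubElement(parent, _nex("meta"))
    el.set(f"{{{NS_XSI}}}type", "nex:ResourceMeta")
    el.set("rel", rel)
    if href is not None:
        el.set("href", href)
    return el


# ---------------------------------------------------------------------------
# Writing


def write_nexml(
    dataset: Dataset,
    ontology: Optional[Ontology] = None,
    filters=None,
) -> bytes:
    """Serialize a dataset to NeXML bytes.

    When an ontology is supplied the dataset is validated first and
    writing is refused (:class:`NexmlValidationError`) if any
    error-severity issue is found; warnings do not block.
    """
    if ontology is not None:
        from .datamodel import Severity

        issues = [
            i for i in validate(dataset, ontology, filters)
            if i.severity is Severity.ERROR
        ]
        if issues:
            raise NexmlValidationError(issues)

    root = etree.Element(_nex("nexml"), nsmap=NSMAP)
    root.set("version", "0.9")

    for curator in dataset.curators:
        _literal_meta(root, "dc:creator", curator)
    if dataset.publication:
        _literal_meta(root, "dc:references", dataset.publication)
    if dataset.publication_notes:
        _literal_meta(root, "dc:description", dataset.publication_notes)
    for extra in dataset.extras:
        root.append(etree.fromstring(extra.encode("utf-8")))

    otus = etree.SubElement(root, _nex("otus"))
    otus.set("id", "otus1")
    otu_ids: dict[str, str] = {}
    for j, taxon in enumerate(dataset.taxa, start=1):
        otu = etree.SubElement(otus, _nex("otu"))
        otu.set("id", f"t{j}")
        otu.set("label", taxon.publication_name)
        otu_ids[taxon.publication_name] = f"t{j}"
        if taxon.valid_taxon is not None:
            _resource_meta(otu, "dwc:taxonID", curie_to_purl(taxon.valid_taxon))
        if taxon.matrix_name is not None:
            _literal_meta(otu, "ps:hasMatrixName", taxon.matrix_name)
        for sp in taxon.specimens:
            ind = _resource_meta(otu, "dwc:individualID")
            _resource_meta(ind, "dwc:collectionID", curie_to_purl(sp.collection))
            _literal_meta(ind, "dwc:catalogNumber", sp.catalog_number)
        if taxon.comment is not None:
            _literal_meta(otu, "rdfs:comment", taxon.comment)
        for fig in taxon.figures:
            _literal_meta(otu, "ps:inFigure", fig)

    characters = etree.SubElement(root, _nex("characters"))
    characters.set("id", "chars1")
    characters.set("otus", "otus1")
    characters.set(f"{{{NS_XSI}}}type", "nex:StandardCells")
    fmt = etree.SubElement(characters, _nex("format"))

    # state ids per character: symbol -> element id
    state_ids: dict[int, dict[str, str]] = {}
    poly_ids: dict[int, dict[tuple[str, ...], str]] = {}
    special_ids: dict[int, dict[CellKind, str]] = {}

    for char in dataset.characters:
        states_el = etree.SubElement(fmt, _nex("states"))
        states_el.set("id", f"states{char.index}")
        ids: dict[str, str] = {}
        for k, state in enumerate(char.states):
            sid = f"s{char.index}_{k}"
            ids[state.symbol] = sid
            st_el = etree.SubElement(states_el, _nex("state"))
            st_el.set("id", sid)
            st_el.set("symbol", state.symbol)
            if state.label:
                st_el.set("label", state.label)
            if state.phenotypes:
                meta = etree.SubElement(st_el, _nex("meta"))
                meta.set(f"{{{NS_XSI}}}type", "nex:LiteralMeta")
                meta.set("property", "ps:describesPhenotype")
                meta.append(_encode_phenotype_block(state.phenotypes))
            if state.comment is not None:
                _literal_meta(st_el, "rdfs:comment", state.comment)
            for fig in state.figures:
                _literal_meta(st_el, "ps:inFigure", fig)
        state_ids[char.index] = ids

        # polymorphic / missing / gap sets actually used in this column
        used_poly: dict[tuple[str, ...], str] = {}
        used_special: dict[CellKind, str] = {}
        for (taxon_name, idx), cell in sorted(
            dataset.matrix.items(), key=lambda kv: (kv[0][1], _taxon_order(dataset, kv[0][0]))
        ):
            if idx != char.index:
                continue
            if cell.kind is CellKind.POLYMORPHIC and cell.symbols not in used_poly:
                pid = f"s{char.index}_p{len(used_poly)}"
                used_poly[cell.symbols] = pid
                pel = etree.SubElement(states_el, _nex("polymorphic_state_set"))
                pel.set("id", pid)
                pel.set("symbol", "".join(cell.symbols))
                for sym in cell.symbols:
                    mel = etree.SubElement(pel, _nex("member"))
                    mel.set("state", ids[sym])
            elif cell.kind is CellKind.MISSING and CellKind.MISSING not in used_special:
                uid = f"s{char.index}_missing"
                used_special[CellKind.MISSING] = uid
                uel = etree.SubElement(states_el, _nex("uncertain_state_set"))
                uel.set("id", uid)
                uel.set("symbol", "?")
            elif cell.kind is CellKind.GAP and CellKind.GAP not in used_special:
                uid = f"s{char.index}_gap"
                used_special[CellKind.GAP] = uid
                uel = etree.SubElement(states_el, _nex("uncertain_state_set"))
                uel.set("id", uid)
                uel.set("symbol", "-")
        poly_ids[char.index] = used_poly
        special_ids[char.index] = used_special

    for char in dataset.characters:
        char_el = etree.SubElement(fmt, _nex("char"))
        char_el.set("id", f"c{char.index}")
        char_el.set("states", f"states{char.index}")
        char_el.set("label", char.label)
        if char.comment is not None:
            _literal_meta(char_el, "rdfs:comment", char.comment)
        for fig in char.figures:
            _literal_meta(char_el, "ps:inFigure", fig)

    matrix_el = etree.SubElement(characters, _nex("matrix"))
    for j, taxon in enumerate(dataset.taxa, start=1):
        cells = [
            (idx, cell)
            for (name, idx), cell in dataset.matrix.items()
            if name == taxon.publication_name
        ]
        if not cells:
            continue
        row = etree.SubElement(matrix_el, _nex("row"))
        row.set("id", f"r{j}")
        row.set("otu", f"t{j}")
        for idx, cell in sorted(cells):
            cel = etree.SubElement(row, _nex("cell"))
            cel.set("char", f"c{idx}")
            if cell.kind is CellKind.SINGLE:
                cel.set("state", state_ids[idx][cell.symbols[0]])
            elif cell.kind is CellKind.POLYMORPHIC:
                cel.set("state", poly_ids[idx][cell.symbols])
            else:
                cel.set("state", special_ids[idx][cell.kind])

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def _taxon_order(dataset: Dataset, name: str) -> int:
    for i, t in enumerate(dataset.taxa):
        if t.publication_name == name:
            return i
    return len(dataset.taxa)


def _encode_phenotype_block(phenotypes) -> etree._Element:
    block = etree.Element(_pheno("phenotype"))
    for p in phenotypes:
        pc = etree.SubElement(block, _pheno("phenotype_character"))
        if p.comment is not None:
            pc.set("comment", p.comment)
        bearer = etree.SubElement(pc, _pheno("bearer"))
        bearer.append(encode_entityref(p.entity))
        quality = etree.SubElement(pc, _pheno("quality"))
        if p.count is not None:
            quality.set("count_min", str(p.count.min))
            quality.set("count_max", str(p.count.max))
        if p.measurement is not None:
            quality.set("measurement", p.measurement)
        if p.unit is not None:
            quality.set("unit", p.unit)
        qref = etree.SubElement(quality, _pheno("typeref"))
        qref.set("about", p.quality)
        if p.related_entity is not None:
            rel = etree.SubElement(pc, _pheno("related_entity"))
            rel.append(encode_entityref(p.related_entity))
    return block


def encode_entityref(ref: EntityRef) -> etree._Element:
    el = encode_postcomposition(ref.composed) if ref.composed is not None \
        else _plain_typeref(ref.term)
    if ref.comment is not None:
        el.set("comment", ref.comment)
    return el


def _plain_typeref(term: TermId) -> etree._Element:
    el = etree.Element(_pheno("typeref"))
    el.set("about", term)
    return el


def encode_postcomposition(pc: PostComposition) -> etree._Element:
    """A ``typeref`` whose ``about`` is the genus, with one ``qualifier``
    child per differentia holding the relation and the (recursive) filler."""
    el = _plain_typeref(pc.genus)
    for relation, filler in pc.differentia:
        q = etree.SubElement(el, _pheno("qualifier"))
        q.set("relation", relation)
        if isinstance(filler, PostComposition):
            q.append(encode_postcomposition(filler))
        else:
            q.append(_plain_typeref(filler))
    return el


# ---------------------------------------------------------------------------
# Reading


def read_nexml(source: Union[str, bytes, IO]) -> Dataset:
    """Full inverse of :func:`write_nexml`.

    Unrecognized metadata properties produce a warning; their XML payload
    is preserved verbatim in ``Dataset.extras`` and re-emitted (at document
    level) on the next write.
    """
    if hasattr(source, "read"):
        source = source.read()
    if isinstance(source, str):
        source = source.encode("utf-8")
    root = etree.fromstring(source)
    if etree.QName(root).localname != "nexml":
        raise NexmlError(f"not a NeXML document: root is {root.tag}")

    ds = Dataset()
    for meta in _metas(root):
        prop = _meta_property(meta)
        if prop == ("creator", NS_DC):
            ds.curators.append(meta.get("content", ""))
        elif prop == ("references", NS_DC):
            ds.publication = meta.get("content", "")
        elif prop == ("description", NS_DC):
            ds.publication_notes = meta.get("content", "")
        else:
            _stash_extra(ds, meta)

    for otu in root.iter(_nex("otu")):
        ds.taxa.append(_read_taxon(otu, ds))

    characters_el = root.find(_nex("characters"))
    id_to_symbols: dict[str, CellValue] = {}
    if characters_el is not None:
        fmt = characters_el.find(_nex("format"))
        states_blocks = {s.get("id"): s for s in fmt.findall(_nex("states"))}
        char_states: dict[str, tuple[int, dict[str, CellValue]]] = {}
        for index, char_el in enumerate(fmt.findall(_nex("char")), start=1):
            states_el = states_blocks[char_el.get("states")]
            states, id_map = _read_states(states_el, ds)
            ds.characters.append(
                Character(
                    index=index,
                    label=char_el.get("label", ""),
                    comment=_read_comment(char_el, ds),
                    figures=_read_figures(char_el, ds),
                    states=tuple(states),
                )
            )
            char_states[char_el.get("id")] = (index, id_map)

        otu_labels = {
            otu.get("id"): otu.get("label", "") for otu in root.iter(_nex("otu"))
        }
        matrix_el = characters_el.find(_nex("matrix"))
        if matrix_el is not None:
            for row in matrix_el.findall(_nex("row")):
                taxon_name = otu_labels[row.get("otu")]
                for cel in row.findall(_nex("cell")):
                    index, id_map = char_states[cel.get("char")]
                    ds.matrix[(taxon_name, index)] = id_map[cel.get("state")]
    return ds


def _metas(el) -> list:
    return el.findall(_nex("meta"))


def _meta_property(meta) -> Optional[tuple[str, str]]:
    """(local name, namespace URI) of a meta's property/rel, if the prefix
    is declared in scope."""
    qname = meta.get("property") or meta.get("rel")
    if qname is None:
        return None
    prefix, _, local = qname.rpartition(":")
    ns = meta.nsmap.get(prefix or None)
    if ns is None:
        return None
    return (local, ns)


def _stash_extra(ds: Dataset, meta) -> None:
    prop = meta.get("property") or meta.get("rel") or "?"
    logger.warning("preserving unrecognized metadata property %r", prop)
    # exclusive c14n, so the stored string is independent of which
    # namespace declarations happen to be in scope at the original site
    data = etree.tostring(meta, method="c14n", exclusive=True)
    ds.extras.append(data.decode("utf-8").strip())


def _read_comment(el, ds: Dataset) -> Optional[str]:
    for meta in _metas(el):
        if _meta_property(meta) == ("comment", NS_RDFS):
            return meta.get("content", "")
    return None


def _read_figures(el, ds: Dataset) -> tuple[str, ...]:
    return tuple(
        meta.get("content", "")
        for meta in _metas(el)
        if _meta_property(meta) == ("inFigure", NS_PS)
    )


_TAXON_PROPS = {
    ("taxonID", NS_DWC),
    ("hasMatrixName", NS_PS),
    ("individualID", NS_DWC),
    ("comment", NS_RDFS),
    ("inFigure", NS_PS),
}


def _read_taxon(otu, ds: Dataset) -> Taxon:
    valid_taxon = None
    matrix_name = None
    specimens = []
    for meta in _metas(otu):
        prop = _meta_property(meta)
        if prop == ("taxonID", NS_DWC):
            valid_taxon = purl_to_curie(meta.get("href"))
        elif prop == ("hasMatrixName", NS_PS):
            matrix_name = meta.get("content", "")
        elif prop == ("individualID", NS_DWC):
            collection = None
            catalog = ""
            for sub in _metas(meta):
                sprop = _meta_property(sub)
                if sprop == ("collectionID", NS_DWC):
                    collection = purl_to_curie(sub.get("href"))
                elif sprop == ("catalogNumber", NS_DWC):
                    catalog = sub.get("content", "")
            specimens.append(Specimen(collection=collection, catalog_number=catalog))
        elif prop in (("comment", NS_RDFS), ("inFigure", NS_PS)):
            pass
        else:
            _stash_extra(ds, meta)
    return Taxon(
        publication_name=otu.get("label", ""),
        valid_taxon=valid_taxon,
        matrix_name=matrix_name,
        specimens=tuple(specimens),
        comment=_read_comment(otu, ds),
        figures=_read_figures(otu, ds),
    )


def _read_states(states_el, ds: Dataset) -> tuple[list[State], dict[str, CellValue]]:
    states: list[State] = []
    id_map: dict[str, CellValue] = {}
    for st_el in states_el.findall(_nex("state")):
        phenotypes: tuple[Phenotype, ...] = ()
        for meta in _metas(st_el):
            prop = _meta_property(meta)
            if prop == ("describesPhenotype", NS_PS):
                block = meta.find(_pheno("phenotype"))
                if block is not None:
                    phenotypes = decode_phenotype_block(block)
            elif prop in (("comment", NS_RDFS), ("inFigure", NS_PS)):
                pass
            else:
                _stash_extra(ds, meta)
        symbol = st_el.get("symbol")
        states.append(
            State(
                symbol=symbol,
                label=st_el.get("label", ""),
                comment=_read_comment(st_el, ds),
                figures=_read_figures(st_el, ds),
                phenotypes=phenotypes,
            )
        )
        id_map[st_el.get("id")] = CellValue.single(symbol)
    symbol_of = {sid: cv.symbols[0] for sid, cv in id_map.items()}
    for pel in states_el.findall(_nex("polymorphic_state_set")):
        members = [symbol_of[m.get("state")] for m in pel.findall(_nex("member"))]
        id_map[pel.get("id")] = CellValue.polymorphic(members)
    for uel in states_el.findall(_nex("uncertain_state_set")):
        kind = CellValue.gap() if uel.get("symbol") == "-" else CellValue.missing()
        id_map[uel.get("id")] = kind
    return states, id_map


def decode_phenotype_block(block) -> tuple[Phenotype, ...]:
    out = []
    for pc_el in block.findall(_pheno("phenotype_character")):
        bearer = pc_el.find(_pheno("bearer"))
        entity = decode_entityref(bearer.find(_pheno("typeref")))
        quality_el = pc_el.find(_pheno("quality"))
        quality = quality_el.find(_pheno("typeref")).get("about")
        count = None
        if quality_el.get("count_min") is not None:
            count = CountRange(
                int(quality_el.get("count_min")), int(quality_el.get("count_max"))
            )
        related = None
        rel_el = pc_el.find(_pheno("related_entity"))
        if rel_el is not None:
            related = decode_entityref(rel_el.find(_pheno("typeref")))
        out.append(
            Phenotype(
                entity=entity,
                quality=quality,
                related_entity=related,
                count=count,
                measurement=quality_el.get("measurement"),
                unit=quality_el.get("unit"),
                comment=pc_el.get("comment"),
            )
        )
    return tuple(out)


def decode_entityref(typeref) -> EntityRef:
    comment = typeref.get("comment")
    decoded = decode_postcomposition(typeref)
    if isinstance(decoded, PostComposition):
        return EntityRef(composed=decoded, comment=comment)
    return EntityRef(term=decoded, comment=comment)


def decode_postcomposition(typeref) -> Union[TermId, PostComposition]:
    """Inverse of :func:`encode_postcomposition`; a qualifier-free typeref
    decodes to its bare TermId."""
    about = typeref.get("about")
    qualifiers = typeref.findall(_pheno("qualifier"))
    if not qualifiers:
        return about
    differentia = []
    for q in qualifiers:
        filler = decode_postcomposition(q.find(_pheno("typeref")))
        differentia.append((q.get("relation"), filler))
    return PostComposition(genus=about, differentia=tuple(differentia))


def metadata_vocabulary(document: bytes) -> set[tuple[str, str]]:
    """All (local name, namespace URI) pairs used as metadata in a document:
    every meta property/rel plus every PhenoXML element name.  Useful for
    checking vocabulary conformance of generated files."""
    root = etree.fromstring(document)
    pairs: set[tuple[str, str]] = set()
    for meta in root.iter(_nex("meta")):
        prop = _meta_property(meta)
        if prop is not None:
            pairs.add(prop)
    for el in root.iter():
        qn = etree.QName(el)
        if qn.namespace == NS_PHENO and qn.localname != "qualifier":
            pairs.add((qn.localname, qn.namespace))
    return pairs


def load_nexml(path: str) -> Dataset:
    with open(path, "rb") as fh:
        return read_nexml(fh)


def save_nexml(dataset: Dataset, path: str, ontology=None, filters=None) -> None:
    data = write_nexml(dataset, ontology=ontology, filters=filters)
    with open(path, "wb") as fh:
        fh.write(data)
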