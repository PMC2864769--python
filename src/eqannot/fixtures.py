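"""Deterministic synthetic fixtures: toy ontologies, matrices, datasets.

Everything the test suite and the command-line interface need to run
offline is generated here.  The toy ontologies are miniature analogues of
the real curation stack: an anatomy partonomy with a pectoral-fin
subtree, a quality ontology with the attribute/value hierarchy (shape ->
triangular) rooted in the single-entity and relational quality roots, a
small fish taxonomy, a museum-collection code list, and a unit ontology.
Terms the literature names explicitly keep their real CURIEs (opercle
TAO:0000250, triangular PATO:0001875, the PATO:0001237/0001238 category
roots, count PATO:0000070, fused-with PATO:0000642); every other
identifier is an invented, stable fixture id.

The worked-example dataset bundles the four classic character categories:
a monadic shape character (opercle: triangular vs. round), a composite
caudal-fin character whose state 0 needs three EQ statements, a
relational hypural-fusion character, a quantitative vertebra-count
character, and a post-composed "epiotic process" character.

Random generators (seeded) produce ontology DAGs, NEXUS files and fully
annotated datasets for property tests; they model curated matrices with
polymorphic, missing and gap cells but not real publications' free text.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .config import Config
from .datamodel import (
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
)
from .ontology import IS_A, PART_OF, Ontology, Term, TermId, merge, parse_obo

# ---------------------------------------------------------------------------
# Toy ontology sources (OBO text, parsed on demand)

ANATOMY_OBO = """\
format-version: 1.2
default-namespace: teleost_anatomy

[Term]
id: TAO:0000001
name: anatomical structure

[Term]
id: TAO:0000100
name: bone
is_a: TAO:0000001

[Term]
id: TAO:0000101
name: muscle
is_a: TAO:0000001

[Term]
id: TAO:0000250
name: opercle
synonym: "gill cover" EXACT []
is_a: TAO:0000100

[Term]
id: TAO:0000102
name: fin
subset: major_slim
is_a: TAO:0000001

[Term]
id: TAO:0000103
name: paired fin
is_a: TAO:0000102

[Term]
id: TAO:0000110
name: pectoral fin
subset: major_slim
is_a: TAO:0000103

[Term]
id: TAO:0000111
name: dorsal arrector
is_a: TAO:0000101
relationship: part_of TAO:0000110

[Term]
id: TAO:0000112
name: pectoral fin spine
is_a: TAO:0000100
relationship: part_of TAO:0000110

[Term]
id: TAO:0000113
name: posterior pectoral-spine serrae
is_a: TAO:0000001
relationship: part_of TAO:0000112

[Term]
id: TAO:0000120
name: caudal fin
subset: major_slim
is_a: TAO:0000102

[Term]
id: TAO:0000121
name: caudal fin upper lobe
is_a: TAO:0000001
relationship: part_of TAO:0000120

[Term]
id: TAO:0000122
name: caudal fin lower lobe
is_a: TAO:0000001
relationship: part_of TAO:0000120

[Term]
id: TAO:0000130
name: hypural
is_a: TAO:0000100
relationship: part_of TAO:0000120

[Term]
id: TAO:0000131
name: hypural 2
is_a: TAO:0000130

[Term]
id: TAO:0000132
name: hypural 3
is_a: TAO:0000130

[Term]
id: TAO:0000140
name: vertebra
is_a: TAO:0000100

[Term]
id: TAO:0000150
name: epiotic
is_a: TAO:0000100

[Term]
id: TAO:0000160
name: process
synonym: "projection" EXACT []
is_a: TAO:0000001

[Term]
id: TAO:0000900
name: archipterygium
is_obsolete: true
replaced_by: TAO:0000103
"""

QUALITY_OBO = """\
format-version: 1.2
default-namespace: quality

[Term]
id: PATO:0000001
name: quality

[Term]
id: PATO:0001237
name: quality of single physical entity
is_a: PATO:0000001

[Term]
id: PATO:0001238
name: quality of related physical entities
is_a: PATO:0000001

[Term]
id: PATO:0000052
name: shape
is_a: PATO:0001237

[Term]
id: PATO:0001875
name: triangular
synonym: "three-sided" EXACT []
is_a: PATO:0000052

[Term]
id: PATO:0000411
name: round
is_a: PATO:0000052

[Term]
id: PATO:0001784
name: bifurcated
is_a: PATO:0000052

[Term]
id: PATO:0001419
name: sharp
is_a: PATO:0000052

[Term]
id: PATO:0002097
name: pointed
is_a: PATO:0000052

[Term]
id: PATO:0000117
name: size
is_a: PATO:0001237

[Term]
id: PATO:0000586
name: increased size
is_a: PATO:0000117

[Term]
id: PATO:0000642
name: fused with
is_a: PATO:0001238

[Term]
id: PATO:0001505
name: separated from
is_a: PATO:0001238

[Term]
id: PATO:0000070
name: count
is_a: PATO:0000001
"""

TAXONOMY_OBO = """\
format-version: 1.2
default-namespace: taxonomy

[Term]
id: TTO:0000001
name: Teleostei

[Term]
id: TTO:1000
name: Siluriformes
is_a: TTO:0000001

[Term]
id: TTO:1001
name: Ictaluridae
is_a: TTO:1000

[Term]
id: TTO:1002
name: Ictalurus punctatus
is_a: TTO:1001

[Term]
id: TTO:2000
name: Cypriniformes
is_a: TTO:0000001

[Term]
id: TTO:2001
name: Danio rerio
is_a: TTO:2000

[Term]
id: TTO:3000
name: Gonorynchiformes
is_a: TTO:0000001

[Term]
id: TTO:3001
name: Gonorynchus greyi
is_a: TTO:3000
"""

COLLECTION_OBO = """\
format-version: 1.2
default-namespace: museum

[Term]
id: COLLECTION:0000001
name: ANSP

[Term]
id: COLLECTION:0000002
name: USNM

[Term]
id: COLLECTION:0000003
name: AMNH
"""

UNIT_OBO = """\
format-version: 1.2
default-namespace: unit

[Term]
id: UO:0000000
name: unit

[Term]
id: UO:0000016
name: millimeter
is_a: UO:0000000

[Term]
id: UO:0000022
name: milligram
is_a: UO:0000000
"""

TOY_NEXUS = """\
#NEXUS
BEGIN TAXA;
    DIMENSIONS NTAX=3;
    TAXLABELS Ictalurus_punctatus Danio_rerio 'Gonorynchus greyi';
END;
BEGIN CHARACTERS;
    DIMENSIONS NCHAR=2;
    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;
    CHARSTATELABELS
        1 'opercle shape' / triangular round,
        2 'caudal fin shape' / forked rounded;
    MATRIX
        Ictalurus_punctatus   00
        Danio_rerio           1?
        'Gonorynchus greyi'   {01}1
    ;
END;
"""


def anatomy_ontology() -> Ontology:
    return parse_obo(ANATOMY_OBO, source_name="anatomy.obo")


def quality_ontology() -> Ontology:
    return parse_obo(QUALITY_OBO, source_name="quality.obo")


def taxonomy_ontology() -> Ontology:
    return parse_obo(TAXONOMY_OBO, source_name="taxonomy.obo")


def collection_ontology() -> Ontology:
    return parse_obo(COLLECTION_OBO, source_name="collection.obo")


def unit_ontology() -> Ontology:
    return parse_obo(UNIT_OBO, source_name="unit.obo")


def merged_ontology() -> Ontology:
    return merge(
        [
            anatomy_ontology(),
            quality_ontology(),
            taxonomy_ontology(),
            collection_ontology(),
            unit_ontology(),
        ]
    )


# Shorthand CURIEs used throughout fixtures and tests
OPERCLE = "TAO:0000250"
CAUDAL_FIN = "TAO:0000120"
CAUDAL_FIN_UPPER_LOBE = "TAO:0000121"
CAUDAL_FIN_LOWER_LOBE = "TAO:0000122"
HYPURAL_2 = "TAO:0000131"
HYPURAL_3 = "TAO:0000132"
VERTEBRA = "TAO:0000140"
EPIOTIC = "TAO:0000150"
PROCESS = "TAO:0000160"
PECTORAL_FIN = "TAO:0000110"
DORSAL_ARRECTOR = "TAO:0000111"
SPINE_SERRAE = "TAO:0000113"

TRIANGULAR = "PATO:0001875"
ROUND = "PATO:0000411"
BIFURCATED = "PATO:0001784"
SHARP = "PATO:0001419"
POINTED = "PATO:0002097"
FUSED_WITH = "PATO:0000642"
SEPARATED_FROM = "PATO:0001505"
COUNT = "PATO:0000070"
INCREASED_SIZE = "PATO:0000586"


def _eq(entity: TermId, quality: TermId, **kw) -> Phenotype:
    return Phenotype(entity=EntityRef(term=entity), quality=quality, **kw)


def opercle_state_triangular() -> State:
    """The monadic worked example: opercle shape, state 'triangular'."""
    return State(symbol="0", label="triangular",
                 phenotypes=(_eq(OPERCLE, TRIANGULAR),))


def caudal_fin_state_forked_pointed() -> State:
    """The composite worked example: catfish caudal fin 'forked with
    pointed lobes' needs three EQ statements."""
    return State(
        symbol="0",
        label="forked with pointed lobes",
        phenotypes=(
            _eq(CAUDAL_FIN, BIFURCATED),
            _eq(CAUDAL_FIN_UPPER_LOBE, SHARP),
            _eq(CAUDAL_FIN_LOWER_LOBE, SHARP),
        ),
    )


def hypural_state_fused() -> State:
    """The relational worked example: hypural 2 fused with hypural 3."""
    return State(
        symbol="1",
        label="hypurals 2 and 3 fused",
        phenotypes=(
            _eq(HYPURAL_2, FUSED_WITH, related_entity=EntityRef(term=HYPURAL_3)),
        ),
    )


def vertebra_state_40_42() -> State:
    """The quantitative worked example: vertebra count 40-42."""
    return State(
        symbol="0",
        label="40-42",
        phenotypes=(_eq(VERTEBRA, COUNT, count=CountRange(40, 42)),),
    )


def epiotic_process() -> PostComposition:
    """The post-composition worked example: *process* part_of *epiotic*."""
    return PostComposition(genus=PROCESS, differentia=((PART_OF, EPIOTIC),))


def worked_examples_dataset() -> Dataset:
    """One dataset holding the four classic character categories plus a
    post-composed character, with taxa, vouchers and matrix filled in."""
    taxa = [
        Taxon(
            publication_name="Ictalurus punctatus",
            valid_taxon="TTO:1002",
            matrix_name="Ictalurus",
            specimens=(Specimen("COLLECTION:0000001", "12345"),
                       Specimen("COLLECTION:0000002", "998"),),
            comment="channel catfish",
            figures=("fig. 2",),
        ),
        Taxon(publication_name="Danio rerio", valid_taxon="TTO:2001"),
        Taxon(publication_name="Gonorynchus greyi", valid_taxon="TTO:3001",
              specimens=(Specimen("COLLECTION:0000003", "G-77"),)),
    ]
    characters = [
        Character(
            index=1,
            label="Opercle shape",
            figures=("fig. 1A",),
            states=(
                opercle_state_triangular(),
                State(symbol="1", label="round",
                      phenotypes=(_eq(OPERCLE, ROUND),)),
            ),
        ),
        Character(
            index=2,
            label="Caudal fin shape",
            comment="composite states after the catfish example",
            states=(
                caudal_fin_state_forked_pointed(),
                State(
                    symbol="1",
                    label="forked with rounded lobes",
                    phenotypes=(
                        _eq(CAUDAL_FIN, BIFURCATED),
                        _eq(CAUDAL_FIN_UPPER_LOBE, ROUND),
                        _eq(CAUDAL_FIN_LOWER_LOBE, ROUND),
                    ),
                ),
                State(symbol="2", label="scarcely emarginate to rounded",
                      phenotypes=(_eq(CAUDAL_FIN, ROUND),)),
            ),
        ),
        Character(
            index=3,
            label="Hypural 2 and hypural 3",
            states=(
                State(
                    symbol="0",
                    label="separate",
                    phenotypes=(
                        _eq(HYPURAL_2, SEPARATED_FROM,
                            related_entity=EntityRef(term=HYPURAL_3)),
                    ),
                ),
                hypural_state_fused(),
            ),
        ),
        Character(
            index=4,
            label="Number of vertebrae",
            states=(
                vertebra_state_40_42(),
                State(symbol="1", label="43",
                      phenotypes=(_eq(VERTEBRA, COUNT, count=CountRange(43, 43)),)),
                State(symbol="2", label="44-45",
                      phenotypes=(_eq(VERTEBRA, COUNT, count=CountRange(44, 45)),)),
            ),
        ),
        Character(
            index=5,
            label="Epiotic process",
            states=(
                State(
                    symbol="0",
                    label="pointed",
                    phenotypes=(
                        Phenotype(
                            entity=EntityRef(composed=epiotic_process(),
                                             comment="epiotic process"),
                            quality=POINTED,
                        ),
                    ),
                ),
                State(
                    symbol="1",
                    label="bifurcated distally",
                    phenotypes=(
                        Phenotype(
                            entity=EntityRef(composed=epiotic_process()),
                            quality=BIFURCATED,
                        ),
                    ),
                ),
            ),
        ),
    ]
    matrix = {
        ("Ictalurus punctatus", 1): CellValue.single("0"),
        ("Ictalurus punctatus", 2): CellValue.single("0"),
        ("Ictalurus punctatus", 3): CellValue.single("1"),
        ("Ictalurus punctatus", 4): CellValue.single("0"),
        ("Ictalurus punctatus", 5): CellValue.single("0"),
        ("Danio rerio", 1): CellValue.single("1"),
        ("Danio rerio", 2): CellValue.single("2"),
        ("Danio rerio", 3): CellValue.single("0"),
        ("Danio rerio", 4): CellValue.polymorphic(("1", "2")),
        ("Danio rerio", 5): CellValue.missing(),
        ("Gonorynchus greyi", 1): CellValue.polymorphic(("0", "1")),
        ("Gonorynchus greyi", 2): CellValue.single("0"),
        ("Gonorynchus greyi", 3): CellValue.missing(),
        ("Gonorynchus greyi", 4): CellValue.gap(),
        ("Gonorynchus greyi", 5): CellValue.single("1"),
    }
    return Dataset(
        curators=["Fixture Curator"],
        publication="Synthetic worked-examples matrix (fixture)",
        publication_notes="Synthetic dataset exercising all character categories.",
        taxa=taxa,
        characters=characters,
        matrix=matrix,
    )


def pectoral_fin_dataset() -> Dataset:
    """Closure-query fixture: two lexically unrelated characters whose
    entities (dorsal arrector; posterior pectoral-spine serrae) are both
    parts of the pectoral fin."""
    taxa = [
        Taxon(publication_name="Ictalurus punctatus", valid_taxon="TTO:1002"),
        Taxon(publication_name="Gonorynchus greyi", valid_taxon="TTO:3001"),
    ]
    characters = [
        Character(
            index=1,
            label="Dorsal arrector size",
            states=(
                State(symbol="0", label="hypertrophied",
                      phenotypes=(_eq(DORSAL_ARRECTOR, INCREASED_SIZE),)),
                State(symbol="1", label="not hypertrophied"),
            ),
        ),
        Character(
            index=2,
            label="Posterior pectoral-spine serrae",
            states=(
                State(symbol="0", label="3-10 serrae",
                      phenotypes=(_eq(SPINE_SERRAE, COUNT,
                                      count=CountRange(3, 10)),)),
                State(symbol="1", label="absent"),
            ),
        ),
    ]
    matrix = {
        ("Ictalurus punctatus", 1): CellValue.single("0"),
        ("Ictalurus punctatus", 2): CellValue.single("0"),
        ("Gonorynchus greyi", 1): CellValue.single("1"),
        ("Gonorynchus greyi", 2): CellValue.single("1"),
    }
    return Dataset(
        curators=["Fixture Curator"],
        publication="Synthetic pectoral-fin query matrix (fixture)",
        taxa=taxa,
        characters=characters,
        matrix=matrix,
    )


# ---------------------------------------------------------------------------
# Random generators (seeded) for property tests


def random_ontology(
    rng: random.Random, n_terms: int = 50, prefix: str = "RND"
) -> Ontology:
    """A random ontology DAG: edges only point to earlier-created terms,
    so the is_a edge set is acyclic by construction."""
    terms: dict[str, Term] = {}
    edges: list[tuple[str, str, str]] = []
    ids = [f"{prefix}:{i:07d}" for i in range(1, n_terms + 1)]
    for i, term_id in enumerate(ids):
        terms[term_id] = Term(
            id=term_id,
            name=f"term {i + 1}",
            namespace=rng.choice(["alpha", "beta"]),
            synonyms=(f"syn {i + 1}",) if rng.random() < 0.3 else (),
            subsets=("slim_a",) if rng.random() < 0.2 else (),
        )
        for parent in rng.sample(ids[:i], k=min(i, rng.randint(0, 2))):
            edges.append((term_id, rng.choice([IS_A, PART_OF]), parent))
    return Ontology(terms=terms, edges=edges, sources=[f"random({prefix})"])


_SYMBOL_POOL = "0123456789"


def random_nexus(
    rng: random.Random,
    ntax: int = 5,
    nchar: int = 8,
    interleave: bool = False,
) -> tuple[str, int]:
    """A random NEXUS file with polymorphic / missing / gap cells.

    Returns (text, expected total cell count = ntax * nchar).
    """
    nstates = rng.randint(2, 4)
    symbols = _SYMBOL_POOL[:nstates]
    taxa = [f"Taxon_{i}" for i in range(1, ntax + 1)]

    def cell() -> str:
        r = rng.random()
        if r < 0.08:
            return "?"
        if r < 0.12:
            return "-"
        if r < 0.2 and nstates >= 2:
            k = rng.randint(2, nstates)
            return "{" + "".join(sorted(rng.sample(symbols, k))) + "}"
        return rng.choice(symbols)

    rows = {t: [cell() for _ in range(nchar)] for t in taxa}
    lines = [
        "#NEXUS",
        "BEGIN TAXA;",
        f"  DIMENSIONS NTAX={ntax};",
        "  TAXLABELS " + " ".join(taxa) + ";",
        "END;",
        "BEGIN CHARACTERS;",
        f"  DIMENSIONS NCHAR={nchar};",
        f"  FORMAT DATATYPE=STANDARD SYMBOLS=\"{symbols}\" MISSING=? GAP=-"
        + (" INTERLEAVE" if interleave else "") + ";",
        "  CHARSTATELABELS",
        "    "
        + ", ".join(
            f"{i} char_{i} / " + " ".join(f"state_{i}_{s}" for s in symbols)
            for i in range(1, nchar + 1)
        )
        + ";",
        "  MATRIX",
    ]
    if interleave:
        half = nchar // 2
        for t in taxa:
            lines.append(f"    {t} " + "".join(rows[t][:half]))
        for t in taxa:
            lines.append(f"    {t} " + "".join(rows[t][half:]))
    else:
        for t in taxa:
            lines.append(f"    {t} " + "".join(rows[t]))
    lines += ["  ;", "END;", ""]
    return "\n".join(lines), ntax * nchar


def random_dataset(rng: random.Random, max_taxa: int = 5, max_chars: int = 4) -> Dataset:
    """A random annotated dataset drawing terms from the toy ontologies.

    Exercises every serializable field: post-compositions (nested with
    probability 0.3), counts, measurements with units, specimens,
    comments, figures, matrix cell kinds.
    """
    anatomy_terms = [
        OPERCLE, CAUDAL_FIN, CAUDAL_FIN_UPPER_LOBE, CAUDAL_FIN_LOWER_LOBE,
        HYPURAL_2, HYPURAL_3, VERTEBRA, EPIOTIC, PROCESS, PECTORAL_FIN,
        DORSAL_ARRECTOR, SPINE_SERRAE,
    ]
    qualities = [TRIANGULAR, ROUND, BIFURCATED, SHARP, POINTED, COUNT,
                 INCREASED_SIZE, FUSED_WITH]
    valid_taxa = ["TTO:1002", "TTO:2001", "TTO:3001", "TTO:1001"]
    collections = ["COLLECTION:0000001", "COLLECTION:0000002", "COLLECTION:0000003"]
    relations = [PART_OF, IS_A]

    def maybe(p: float, value):
        return value if rng.random() < p else None

    def entity_ref(depth: int = 0) -> EntityRef:
        if rng.random() < 0.3 and depth < 2:
            filler = (
                entity_ref(depth + 1).composed
                if rng.random() < 0.3 and depth < 1
                else rng.choice(anatomy_terms)
            )
            if filler is None:
                filler = rng.choice(anatomy_terms)
            pc = PostComposition(
                genus=rng.choice(anatomy_terms),
                differentia=((rng.choice(relations), filler),),
            )
            return EntityRef(composed=pc, comment=maybe(0.3, "pc comment"))
        return EntityRef(term=rng.choice(anatomy_terms))

    def phenotype() -> Phenotype:
        count = maybe(0.25, CountRange(rng.randint(1, 20), rng.randint(20, 60)))
        measurement = maybe(0.2, f"{rng.randint(1, 99)}.{rng.randint(0, 9)}")
        return Phenotype(
            entity=entity_ref(),
            quality=rng.choice(qualities),
            related_entity=maybe(0.3, entity_ref()),
            count=count,
            measurement=measurement,
            unit="UO:0000016" if measurement is not None else maybe(0.05, "UO:0000022"),
            comment=maybe(0.2, f"note {rng.randint(0, 999)}"),
        )

    n_taxa = rng.randint(2, max_taxa)
    n_chars = rng.randint(1, max_chars)
    taxa = []
    for i in range(n_taxa):
        taxa.append(
            Taxon(
                publication_name=f"Taxon {i + 1}",
                valid_taxon=maybe(0.7, rng.choice(valid_taxa)),
                matrix_name=maybe(0.4, f"matrix taxon {i + 1}"),
                specimens=tuple(
                    Specimen(rng.choice(collections), f"cat-{rng.randint(1, 9999)}")
                    for _ in range(rng.randint(0, 2))
                ),
                comment=maybe(0.3, f"taxon comment {i + 1}"),
                figures=tuple(f"fig. {k}" for k in range(rng.randint(0, 2))),
            )
        )
    characters = []
    for ci in range(1, n_chars + 1):
        n_states = rng.randint(2, 3)
        states = tuple(
            State(
                symbol=str(si),
                label=maybe(0.8, f"state {ci}.{si}") or "",
                comment=maybe(0.2, "state comment"),
                figures=tuple(f"fig. {ci}-{k}" for k in range(rng.randint(0, 2))),
                phenotypes=tuple(phenotype() for _ in range(rng.randint(0, 3))),
            )
            for si in range(n_states)
        )
        characters.append(
            Character(
                index=ci,
                label=f"Character {ci} label",
                comment=maybe(0.3, "char comment"),
                figures=tuple(f"fig. c{ci}" for _ in range(rng.randint(0, 1))),
                states=states,
            )
        )
    matrix: dict[tuple[str, int], CellValue] = {}
    for t in taxa:
        for c in characters:
            r = rng.random()
            symbols = [s.symbol for s in c.states]
            if r < 0.08:
                matrix[(t.publication_name, c.index)] = CellValue.missing()
            elif r < 0.12:
                matrix[(t.publication_name, c.index)] = CellValue.gap()
            elif r < 0.25 and len(symbols) >= 2:
                matrix[(t.publication_name, c.index)] = CellValue.polymorphic(
                    rng.sample(symbols, 2)
                )
            else:
                matrix[(t.publication_name, c.index)] = CellValue.single(
                    rng.choice(symbols)
                )
    return Dataset(
        curators=[f"Curator {k}" for k in range(1, rng.randint(2, 3))],
        publication=f"Synthetic random dataset {rng.randint(0, 10**6)}",
        publication_notes=maybe(0.5, "random notes") or "",
        taxa=taxa,
        characters=characters,
        matrix=matrix,
    )


# ---------------------------------------------------------------------------
# Bundle


@dataclass
class FixtureBundle:
    """Everything needed for an offline end-to-end run."""

    seed: int
    obo_files: dict[str, str] = field(default_factory=dict)
    nexus_files: dict[str, str] = field(default_factory=dict)
    datasets: dict[str, Dataset] = field(default_factory=dict)
    config: Config = field(default_factory=Config)

    def write_to(self, directory) -> Path:
        """Materialize the bundle (OBO, NEXUS, NeXML, config.yaml)."""
        from .nexml_io import write_nexml

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, text in {**self.obo_files, **self.nexus_files}.items():
            (directory / name).write_text(text, encoding="utf-8")
        ontology = merged_ontology()
        for name, ds in self.datasets.items():
            (directory / f"{name}.xml").write_bytes(write_nexml(ds, ontology))
        # sources relative to the config file, so bundles are portable and
        # byte-identical for a given seed regardless of target directory
        config = Config(
            ontology_sources={
                "entity": ["anatomy.obo"],
                "quality": ["quality.obo"],
                "taxonomy": ["taxonomy.obo"],
                "unit": ["unit.obo"],
                "collection": ["collection.obo"],
            },
            field_filters=self.config.field_filters,
        )
        (directory / "config.yaml").write_text(config.to_yaml(), encoding="utf-8")
        return directory


def generate_fixtures(seed: int = 0, ntax: int = 6, nchar: int = 10) -> FixtureBundle:
    """Build the deterministic fixture bundle for a given seed.

    The ontologies and worked-example datasets are fixed; the extra NEXUS
    matrices are drawn from a generator seeded with ``seed``, so the same
    seed always yields a byte-identical bundle.
    """
    rng = random.Random(seed)
    random_plain, _ = random_nexus(rng, ntax=ntax, nchar=nchar, interleave=False)
    random_inter, _ = random_nexus(rng, ntax=ntax, nchar=nchar, interleave=True)
    from .ontology import TermFilter

    bundle = FixtureBundle(
        seed=seed,
        obo_files={
            "anatomy.obo": ANATOMY_OBO,
            "quality.obo": QUALITY_OBO,
            "taxonomy.obo": TAXONOMY_OBO,
            "collection.obo": COLLECTION_OBO,
            "unit.obo": UNIT_OBO,
        },
        nexus_files={
            "toy.nex": TOY_NEXUS,
            "random_plain.nex": random_plain,
            "random_interleaved.nex": random_inter,
        },
        datasets={
            "worked_examples": worked_examples_dataset(),
            "pectoral_fin": pectoral_fin_dataset(),
        },
        config=Config(
            field_filters={
                "entity": TermFilter(namespaces=frozenset({"teleost_anatomy"})),
                "quality": TermFilter(namespaces=frozenset({"quality"})),
                "taxon": TermFilter(namespaces=frozenset({"taxonomy"})),
                "unit": TermFilter(namespaces=frozenset({"unit"})),
                "collection": TermFilter(namespaces=frozenset({"museum"})),
            }
        ),
    )
    return bundle
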