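# eqannot

Ontology-backed **Entity–Quality (EQ) annotation** of phylogenetic
character-by-taxon matrices.

Systematists describe variable organismal features as natural-language
*characters* ("opercle shape") with *character states* ("triangular",
"round"), coded numerically in a character-by-taxon matrix. Free text is
fine for humans but opaque to computers: annotations from different
publications cannot be compared or pooled. The EQ formalism fixes this by
pairing an **entity** term from an anatomy ontology with a **quality**
term from the Phenotype and Trait Ontology (PATO) — e.g. the state
"opercle triangular" becomes *triangular* (PATO:0001875) *inheres_in*
*opercle* (TAO:0000250). Because value qualities are subtypes of attribute
qualities (*triangular* is_a *shape*), and anatomical terms form an
is_a/part_of graph, annotations made by different authors on different
structures become queryable through the ontologies' closure.

`eqannot` is a headless curation toolkit for this workflow, aimed at
morphologists and data curators:

- **ontology** — parse OBO 1.2 ontologies (anatomy, qualities, taxonomy,
  units, museum-collection codes), merge multiple sources, filtered
  autocomplete-style search, and transitive closure over chosen relations;
- **datamodel** — EQ phenotypes (entity E, quality Q, optional related
  entity RE, count C, measurement + unit), post-composed entities
  (*process* part_of *epiotic*), characters/states/taxa/specimens/matrix,
  character-category classification (monadic / relational / composite /
  quantitative), and ontology-aware validation;
- **nexus_io** — import taxa, characters, state labels and the matrix from
  NEXUS files (CHARSTATELABELS, polymorphic `{01}` cells, missing `?`,
  gap `-`, interleaved matrices);
- **nexml_io** — the native file format: deterministic NeXML with
  Dublin Core / Darwin Core / RDF-Schema / Phenoscape-vocabulary metadata
  and EQ statements embedded as PhenoXML;
- **query** — derive taxon→phenotype "exhibits" records from the matrix
  and answer entity-closure queries ("all phenotypes of the pectoral fin
  or any of its parts");
- **cli / fixtures** — `eqannot convert | validate | query | stats |
  fixtures`, plus a deterministic synthetic fixture generator so the whole
  pipeline runs offline.

## Worked example

Import a small NEXUS matrix, annotate one state with an EQ statement,
write NeXML, and derive the taxon annotations:

```python
from dataclasses import replace
from eqannot import (fixtures, parse_nexus, to_dataset, attach_phenotype,
                     Phenotype, EntityRef, write_nexml, read_nexml,
                     exhibits, triples_to_tsv)

ds = to_dataset(parse_nexus(fixtures.TOY_NEXUS))
print("characters:", [c.label for c in ds.characters])

char = ds.characters[0]                    # "opercle shape"
state0 = attach_phenotype(char.states[0],  # state "0" = triangular
    Phenotype(entity=EntityRef(term="TAO:0000250"),   # opercle
              quality="PATO:0001875"))                # triangular
ds.characters[0] = replace(char, states=(state0,) + char.states[1:])

xml = write_nexml(ds, fixtures.merged_ontology())
print("round-trip identical:", read_nexml(xml) == ds)

triples = exhibits(ds)
print("annotation triples:", len(triples))
print(triples_to_tsv(triples))
```

Output:

```
characters: ['opercle shape', 'caudal fin shape']
round-trip identical: True
annotation triples: 2
taxon	valid_taxon	character	state	entity	quality	related_entity	count	source
Ictalurus punctatus		1	0	TAO:0000250	PATO:0001875
Gonorynchus greyi		1	0	TAO:0000250	PATO:0001875
```

Two taxa exhibit the phenotype: *Ictalurus punctatus* scored `0`
directly, and *Gonorynchus greyi* scored polymorphic `{01}`, which
contributes an annotation for each contained symbol. The matrix supplies
the taxon→phenotype mapping automatically — annotating the state once
annotates every taxon that exhibits it.

The same flow from a shell:

```sh
eqannot fixtures bundle --seed 1          # synthetic ontologies + matrices
eqannot convert bundle/toy.nex --config bundle/config.yaml -o toy.xml
eqannot validate bundle/worked_examples.xml --config bundle/config.yaml
eqannot query bundle/pectoral_fin.xml --config bundle/config.yaml \
        --entity TAO:0000110              # pectoral fin, parts included
```

The query returns annotations on the *dorsal arrector* and the
*posterior pectoral-spine serrae* — lexically unrelated entities that the
anatomy ontology knows are both parts of the pectoral fin.

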