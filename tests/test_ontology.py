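"""OBO parsing, merging, search ranking, and relation closure."""

import random

import pytest

from eqannot import fixtures
from eqannot.fixtures import random_ontology
from eqannot.ontology import (
    IS_A,
    PART_OF,
    EMPTY_FILTER,
    OboParseError,
    Term,
    TermFilter,
    TermLookupError,
    merge,
    parse_obo,
    write_obo,
)

from conftest import bfs_ancestors

MINIMAL_OBO = """\
format-version: 1.2
default-namespace: teleost_anatomy

[Term]
id: TAO:0000250
name: opercle
"""


class TestParseObo:
    def test_single_term(self):
        onto = parse_obo(MINIMAL_OBO)
        assert onto.terms["TAO:0000250"].name == "opercle"
        assert onto.terms["TAO:0000250"].namespace == "teleost_anatomy"

    def test_header_only_file_is_empty(self):
        onto = parse_obo("format-version: 1.2\n")
        assert len(onto.terms) == 0 and len(onto.edges) == 0

    def test_edge_count_matches_text_scan_oracle(self, rng):
        # oracle: count raw is_a / relationship lines in the serialized text
        onto = random_ontology(rng, n_terms=50)
        text = write_obo(onto)
        expected = sum(
            1
            for line in text.splitlines()
            if line.startswith("is_a:") or line.startswith("relationship:")
        )
        assert len(parse_obo(text).edges) == expected == len(onto.edges)

    def test_fixture_parse_agrees_with_obonet(self):
        obonet = pytest.importorskip("obonet")
        import io

        graph = obonet.read_obo(io.StringIO(fixtures.ANATOMY_OBO))
        onto = fixtures.anatomy_ontology()
        # obonet drops obsolete terms by default; we retain them
        non_obsolete = {t.id for t in onto.terms.values() if not t.obsolete}
        assert non_obsolete == set(graph.nodes)
        for term_id in non_obsolete:
            assert onto.terms[term_id].name == graph.nodes[term_id]["name"]
        obonet_edges = {(u, k, v) for u, v, k in graph.edges(keys=True)}
        ours = {(s, p, o) for s, p, o in onto.edges if s in non_obsolete}
        assert ours == obonet_edges

    def test_missing_id_raises_with_line(self):
        with pytest.raises(OboParseError, match=":3:"):
            parse_obo("format-version: 1.2\n\n[Term]\nname: nameless\n")

    def test_unknown_tag_is_ignored(self, caplog):
        onto = parse_obo(MINIMAL_OBO + "xref: FMA:12345\n")
        assert "TAO:0000250" in onto

    def test_obsolete_term_retained_with_replacement(self, anatomy):
        term = anatomy.terms["TAO:0000900"]
        assert term.obsolete and term.replaced_by == "TAO:0000103"

    def test_roundtrip_preserves_content(self, rng):
        onto = random_ontology(rng, n_terms=40)
        again = parse_obo(write_obo(onto))
        for term_id, term in onto.terms.items():
            t2 = again.terms[term_id]
            assert (term.name, term.synonyms, term.subsets) == (
                t2.name,
                t2.synonyms,
                t2.subsets,
            )
        assert sorted(onto.edges) == sorted(again.edges)


class TestMerge:
    def test_identity(self, anatomy):
        merged = merge([anatomy])
        assert merged.terms == anatomy.terms
        assert merged.edges == anatomy.edges

    def test_disjoint_union_counts(self, anatomy, pato):
        merged = merge([anatomy, pato])
        assert len(merged) == len(anatomy) + len(pato)

    def test_self_merge_is_identity(self, anatomy):
        merged = merge([anatomy, anatomy])
        assert merged.terms == anatomy.terms
        assert sorted(merged.edges) == sorted(anatomy.edges)


class TestSearch:
    def test_exact_match_ranks_first(self, pato):
        results = pato.search("triangular", EMPTY_FILTER, 10)
        assert results[0].id == "PATO:0001875"

    def test_no_match_is_empty(self, merged):
        assert merged.search("zzz-not-present") == []

    def test_namespace_filter_matches_linear_scan(self, merged):
        flt = TermFilter(namespaces=frozenset({"teleost_anatomy"}))
        results = merged.search("fin", flt, limit=100)
        assert results
        assert all(t.namespace == "teleost_anatomy" for t in results)
        # brute-force scan over all terms, same tiering rules applied by hand
        brute = {
            t.id
            for t in merged.terms.values()
            if not t.obsolete
            and t.namespace == "teleost_anatomy"
            and ("fin" in t.name.lower() or any("fin" in s.lower() for s in t.synonyms))
        }
        assert {t.id for t in results} == brute

    def test_synonym_prefix_beats_name_substring(self, anatomy):
        # "gill cover" is a synonym of opercle; "fin" is a substring of many names
        results = anatomy.search("gill", EMPTY_FILTER, 10)
        assert results[0].id == "TAO:0000250"

    def test_obsolete_terms_never_returned(self, anatomy):
        assert all(not t.obsolete for t in anatomy.search("archipterygium", EMPTY_FILTER, 10))

    def test_ranking_is_deterministic(self, merged):
        first = [t.id for t in merged.search("a", EMPTY_FILTER, 25)]
        for _ in range(3):
            assert [t.id for t in merged.search("a", EMPTY_FILTER, 25)] == first

    def test_subset_filter(self, anatomy):
        flt = TermFilter(subsets=frozenset({"major_slim"}))
        results = anatomy.search("fin", flt, 10)
        assert results and all("major_slim" in t.subsets for t in results)


class TestAncestors:
    def test_part_of_chain(self, anatomy):
        assert "TAO:0000110" in anatomy.ancestors("TAO:0000111", {IS_A, PART_OF})

    def test_root_has_no_ancestors(self, anatomy):
        assert anatomy.ancestors("TAO:0000001", {IS_A, PART_OF}) == set()

    def test_unknown_start_raises(self, anatomy):
        with pytest.raises(TermLookupError):
            anatomy.ancestors("TAO:9999999")

    def test_matches_bfs_oracle_on_random_dags(self, rng):
        for trial in range(20):
            onto = random_ontology(rng, n_terms=rng.randint(10, 200))
            for _ in range(5):
                start = rng.choice(list(onto.terms))
                relations = rng.choice([{IS_A}, {PART_OF}, {IS_A, PART_OF}])
                assert onto.ancestors(start, relations) == bfs_ancestors(
                    onto.edges, start, relations
                )

    def test_monotone_in_relations(self, rng):
        onto = random_ontology(rng, n_terms=60)
        for start in list(onto.terms)[:20]:
            assert onto.ancestors(start, {IS_A}) <= onto.ancestors(
                start, {IS_A, PART_OF}
            )

    def test_mixed_chain_propagates(self, anatomy):
        # serrae -part_of-> spine -part_of-> pectoral fin -is_a-> paired fin
        anc = anatomy.ancestors("TAO:0000113", {IS_A, PART_OF})
        assert {"TAO:0000112", "TAO:0000110", "TAO:0000103"} <= anc
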