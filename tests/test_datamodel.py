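"""EQ phenotype model: attachment, classification, validation, composition."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from eqannot import fixtures
from eqannot.datamodel import (
    Category,
    CountRange,
    Dataset,
    EntityRef,
    Phenotype,
    PostComposition,
    State,
    Severity,
    attach_phenotype,
    classify,
    compose,
    parse_postcomposition,
    validate,
)
from eqannot.fixtures import (
    CAUDAL_FIN,
    HYPURAL_2,
    HYPURAL_3,
    OPERCLE,
    TRIANGULAR,
    random_dataset,
)
from eqannot.ontology import PART_OF, TermFilter


def eq(entity, quality, **kw):
    return Phenotype(entity=EntityRef(term=entity), quality=quality, **kw)


class TestAttachPhenotype:
    def test_catfish_composite_state_has_three_phenotypes(self):
        state = State(symbol="0", label="forked with pointed lobes")
        for p in fixtures.caudal_fin_state_forked_pointed().phenotypes:
            state = attach_phenotype(state, p)
        assert len(state.phenotypes) == 3

    def test_single_attach(self):
        state = attach_phenotype(State(symbol="0"), eq(CAUDAL_FIN, TRIANGULAR))
        assert len(state.phenotypes) == 1

    def test_order_preserved(self, rng):
        qualities = [fixtures.TRIANGULAR, fixtures.ROUND, fixtures.SHARP]
        phenotypes = [
            eq(OPERCLE, rng.choice(qualities)) for _ in range(rng.randint(5, 15))
        ]
        state = State(symbol="0")
        for p in phenotypes:
            state = attach_phenotype(state, p)
        assert list(state.phenotypes) == phenotypes


class TestClassify:
    def test_monadic_example(self, pato):
        assert classify(fixtures.opercle_state_triangular(), pato) == {Category.MONADIC}

    def test_relational_example(self, pato):
        assert classify(fixtures.hypural_state_fused(), pato) == {Category.RELATIONAL}

    def test_quantitative_example(self, pato):
        assert classify(fixtures.vertebra_state_40_42(), pato) == {
            Category.QUANTITATIVE
        }

    def test_composite_example(self, pato):
        assert classify(fixtures.caudal_fin_state_forked_pointed(), pato) == {
            Category.MONADIC,
            Category.COMPOSITE,
        }

    def test_relational_quality_without_related_entity(self, pato):
        # a relational quality alone marks the state relational
        state = State(symbol="0", phenotypes=(eq(HYPURAL_2, fixtures.FUSED_WITH),))
        assert Category.RELATIONAL in classify(state, pato)

    def test_distributes_over_attachment(self, pato, rng):
        full = fixtures.caudal_fin_state_forked_pointed()
        union = set()
        for p in full.phenotypes:
            union |= classify(State(symbol="0", phenotypes=(p,)), pato)
        union.add(Category.COMPOSITE)  # n >= 2
        assert classify(full, pato) == union


class TestCompose:
    def test_epiotic_process_rendering(self):
        pc = compose("TAO:0000160", [(PART_OF, "TAO:0000150")])
        assert pc.render() == "TAO:0000160^part_of(TAO:0000150)"

    def test_empty_differentia_rejected(self):
        with pytest.raises(ValueError):
            compose("TAO:0000160", [])

    def test_nested_roundtrip(self):
        inner = compose("TAO:0000121", [(PART_OF, "TAO:0000120")])
        outer = compose("TAO:0000160", [(PART_OF, inner)])
        assert parse_postcomposition(outer.render()) == outer

    def test_random_roundtrip(self, rng):
        terms = [f"TAO:{i:07d}" for i in range(1, 20)]
        relations = ["part_of", "is_a", "develops_from"]

        def rand_pc(depth=0):
            n = rng.randint(1, 3)
            diffs = []
            for _ in range(n):
                if depth < 2 and rng.random() < 0.3:
                    diffs.append((rng.choice(relations), rand_pc(depth + 1)))
                else:
                    diffs.append((rng.choice(relations), rng.choice(terms)))
            return PostComposition(rng.choice(terms), tuple(diffs))

        for _ in range(100):
            pc = rand_pc()
            assert parse_postcomposition(pc.render()) == pc


class TestCountRange:
    @given(lo=st.integers(0, 500), span=st.integers(0, 100))
    @settings(max_examples=50, derandomize=True)
    def test_render_parse_roundtrip(self, lo, span):
        cr = CountRange(lo, lo + span)
        assert CountRange.parse(cr.render()) == cr

    def test_single_value_renders_plain(self):
        assert CountRange(43, 43).render() == "43"

    def test_range_renders_hyphenated(self):
        assert CountRange(40, 42).render() == "40-42"

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            CountRange(5, 4)


class TestValidate:
    def test_clean_fixture_has_no_issues(self, merged):
        assert validate(fixtures.worked_examples_dataset(), merged) == []

    def test_unknown_entity_reported(self, merged):
        ds = fixtures.worked_examples_dataset()
        bad = eq("TAO:9999999", TRIANGULAR)
        ds.characters[0] = ds.characters[0].__class__(
            index=1,
            label=ds.characters[0].label,
            states=(attach_phenotype(ds.characters[0].states[0], bad),)
            + ds.characters[0].states[1:],
        )
        issues = [i for i in validate(ds, merged) if i.code == "unknown-term"]
        assert len(issues) == 1 and issues[0].severity is Severity.ERROR

    def test_corruption_count_oracle(self, merged, rng):
        # corrupt k distinct quality ids -> exactly k unknown-term issues
        ds = random_dataset(rng)
        from dataclasses import replace

        count = 0
        new_chars = []
        for char in ds.characters:
            new_states = []
            for state in char.states:
                new_ph = []
                for p in state.phenotypes:
                    if rng.random() < 0.4:
                        count += 1
                        p = replace(p, quality=f"PATO:99{count:05d}")
                    new_ph.append(p)
                new_states.append(replace(state, phenotypes=tuple(new_ph)))
            new_chars.append(replace(char, states=tuple(new_states)))
        ds.characters = new_chars
        issues = [i for i in validate(ds, merged) if i.code == "unknown-term"]
        assert len(issues) == count

    def test_obsolete_term_warns_with_replacement(self, merged):
        ds = Dataset(
            taxa=[],
            characters=[
                fixtures.worked_examples_dataset().characters[0].__class__(
                    index=1,
                    states=(State(symbol="0", phenotypes=(eq("TAO:0000900", TRIANGULAR),)),),
                )
            ],
        )
        issues = validate(ds, merged)
        obsolete = [i for i in issues if i.code == "obsolete-term"]
        assert len(obsolete) == 1
        assert "TAO:0000103" in obsolete[0].message
        assert obsolete[0].severity is Severity.WARNING

    def test_field_filter_violation(self, merged):
        # quality term used in the entity slot violates the entity filter
        ds = fixtures.worked_examples_dataset()
        filters = {"entity": TermFilter(namespaces=frozenset({"quality"}))}
        issues = validate(ds, merged, filters)
        assert any(i.code == "filter-violation" for i in issues)

    def test_undefined_matrix_symbol(self, merged):
        ds = fixtures.worked_examples_dataset()
        from eqannot.datamodel import CellValue

        ds.matrix[("Danio rerio", 1)] = CellValue.single("9")
        issues = validate(ds, merged)
        assert any(i.code == "undefined-state" for i in issues)

    def test_idempotent_and_side_effect_free(self, merged):
        ds = fixtures.worked_examples_dataset()
        before = ds.characters[:]
        first = validate(ds, merged)
        second = validate(ds, merged)
        assert first == second and ds.characters == before

    def test_count_with_non_count_quality_warns(self, merged):
        state = State(
            symbol="0",
            phenotypes=(eq(OPERCLE, TRIANGULAR, count=CountRange(2, 2)),),
        )
        ds = Dataset(characters=[fixtures.worked_examples_dataset().characters[0].__class__(index=1, states=(state,))])
        assert any(i.code == "count-mismatch" for i in validate(ds, merged))

    def test_related_entity_with_single_entity_quality_warns(self, merged):
        state = State(
            symbol="0",
            phenotypes=(
                eq(HYPURAL_2, TRIANGULAR, related_entity=EntityRef(term=HYPURAL_3)),
            ),
        )
        ds = Dataset(characters=[fixtures.worked_examples_dataset().characters[0].__class__(index=1, states=(state,))])
        assert any(i.code == "relational-mismatch" for i in validate(ds, merged))
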