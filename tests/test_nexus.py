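"""NEXUS import: tokenization, matrix expansion, Dataset construction."""

import re

import pytest

from eqannot import fixtures
from eqannot.datamodel import CellKind
from eqannot.fixtures import random_nexus
from eqannot.nexus_io import NexusParseError, expand_row, parse_nexus, to_dataset


def text_scan_cell_count(nexus_text: str) -> int:
    """Independent oracle: count matrix cells straight off the raw text.

    Finds the MATRIX command, drops the leading taxon token of each line,
    and counts symbols, treating {...} / (...) groups as one cell.
    """
    m = re.search(r"MATRIX(.*?);", nexus_text, re.S | re.I)
    total = 0
    for line in m.group(1).splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("'"):
            data = line[line.index("'", 1) + 1 :]
        else:
            data = line.split(None, 1)[1] if len(line.split(None, 1)) > 1 else ""
        data = re.sub(r"\{[^}]*\}|\([^)]*\)", "#", data.replace(" ", ""))
        total += len(data)
    return total


class TestParseNexus:
    def test_toy_file_charstatelabels(self):
        doc = parse_nexus(fixtures.TOY_NEXUS)
        assert doc.charstatelabels[1] == ("opercle shape", ["triangular", "round"])
        assert doc.taxa_labels == [
            "Ictalurus punctatus",
            "Danio rerio",
            "Gonorynchus greyi",
        ]

    def test_missing_and_gap_defaults(self):
        doc = parse_nexus(fixtures.TOY_NEXUS)
        cells = doc.row_cells("Danio rerio")
        assert cells == ["1", "?"]
        ds = to_dataset(doc)
        assert ds.matrix[("Danio rerio", 2)].kind is CellKind.MISSING

    def test_polymorphic_expansion(self):
        assert expand_row("0{01}1?", "?", "-") == ["0", "{01}", "1", "?"]

    def test_cell_count_matches_text_scan_oracle(self, rng):
        for trial in range(10):
            interleave = bool(trial % 2)
            text, expected = random_nexus(
                rng,
                ntax=rng.randint(2, 12),
                nchar=rng.randint(2, 30),
                interleave=interleave,
            )
            doc = parse_nexus(text)
            parsed = sum(len(doc.row_cells(t)) for t in doc.taxa_labels)
            assert parsed == expected == text_scan_cell_count(text)

    def test_sentinel_required(self):
        with pytest.raises(NexusParseError, match="#NEXUS"):
            parse_nexus("BEGIN TAXA; END;")

    def test_row_length_mismatch_cites_line(self):
        bad = fixtures.TOY_NEXUS.replace("Danio_rerio           1?", "Danio_rerio 1")
        with pytest.raises(NexusParseError, match=r"line \d+.*Danio"):
            parse_nexus(bad)

    def test_duplicate_taxon_rejected(self):
        bad = fixtures.TOY_NEXUS.replace("Danio_rerio", "Ictalurus_punctatus", 1)
        with pytest.raises(NexusParseError, match="duplicate"):
            parse_nexus(bad)

    def test_keyword_case_insensitive(self):
        lowered = re.sub(
            r"\b(BEGIN|END|DIMENSIONS|FORMAT|TAXLABELS|CHARSTATELABELS|MATRIX|TAXA|CHARACTERS)\b",
            lambda m: m.group(0).lower(),
            fixtures.TOY_NEXUS,
        )
        assert parse_nexus(lowered).taxa_labels == parse_nexus(fixtures.TOY_NEXUS).taxa_labels

    def test_comments_stripped_and_quotes_preserved(self):
        text = fixtures.TOY_NEXUS.replace("#NEXUS", "#NEXUS\n[a [nested] comment]")
        doc = parse_nexus(text)
        assert "Gonorynchus greyi" in doc.taxa_labels

    def test_unknown_blocks_skipped(self):
        text = fixtures.TOY_NEXUS + "\nBEGIN TREES;\n  TREE t = (a,b);\nEND;\n"
        assert parse_nexus(text).nchar == 2

    def test_interleaved_rows_concatenated(self, rng):
        text, _ = random_nexus(rng, ntax=4, nchar=11, interleave=True)
        doc = parse_nexus(text)
        for taxon in doc.taxa_labels:
            assert len(doc.row_cells(taxon)) == 11

    def test_agrees_with_dendropy_on_toy_file(self):
        dendropy = pytest.importorskip("dendropy")
        mat = dendropy.StandardCharacterMatrix.get(
            data=fixtures.TOY_NEXUS, schema="nexus"
        )
        doc = parse_nexus(fixtures.TOY_NEXUS)
        assert sorted(t.label for t in mat.taxon_namespace) == sorted(doc.taxa_labels)
        for taxon in mat.taxon_namespace:
            assert len(mat[taxon]) == doc.nchar


class TestToDataset:
    def test_toy_counts(self):
        ds = to_dataset(parse_nexus(fixtures.TOY_NEXUS))
        assert (len(ds.taxa), len(ds.characters), len(ds.matrix)) == (3, 2, 6)

    def test_missing_charstatelabel_falls_back(self):
        text = fixtures.TOY_NEXUS.replace(
        "        2 'caudal fin shape' / forked rounded;", "        ;"
        ).replace(
            "        1 'opercle shape' / triangular round,",
            "        1 'opercle shape' / triangular round",
        )
        ds = to_dataset(parse_nexus(text))
        assert ds.characters[1].label == "Character 2"

    def test_state_symbols_follow_symbols_order(self):
        ds = to_dataset(parse_nexus(fixtures.TOY_NEXUS))
        assert [s.symbol for s in ds.characters[0].states] == ["0", "1"]
        assert [s.label for s in ds.characters[0].states] == ["triangular", "round"]

    def test_cell_conservation_on_random_files(self, rng):
        text, expected = random_nexus(rng, ntax=8, nchar=15)
        ds = to_dataset(parse_nexus(text))
        assert len(ds.matrix) == expected

    def test_all_phenotype_lists_start_empty(self):
        ds = to_dataset(parse_nexus(fixtures.TOY_NEXUS))
        assert all(
            not state.phenotypes for c in ds.characters for state in c.states
        )

    def test_labels_traceable_to_source(self, rng):
        # every character/state label traces to a token in the file
        # (unquoted tokens have underscores converted to spaces on parse)
        text, _ = random_nexus(rng, ntax=3, nchar=6)
        ds = to_dataset(parse_nexus(text))
        for char in ds.characters:
            assert char.label in text or char.label.replace(" ", "_") in text
            for state in char.states:
                if state.label:
                    assert state.label.replace(" ", "_") in text
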