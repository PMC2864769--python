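"""NEXUS import: taxa, characters, state labels, and the matrix.

Reads the subset of NEXUS (Maddison et al. dialect, as emitted by
Mesquite) needed to seed annotation work: TAXA and CHARACTERS/DATA blocks
with DIMENSIONS, FORMAT (SYMBOLS / MISSING / GAP / INTERLEAVE),
TAXLABELS, CHARSTATELABELS (or CHARLABELS + STATELABELS) and MATRIX.
Square-bracket comments are stripped, quoted labels are preserved
verbatim, and underscores in unquoted tokens become spaces, per the NEXUS
convention.  Other block types (TREES, ASSUMPTIONS, application-private
blocks) are skipped with a logged notice.

Export is deliberately absent: the annotated native format is NeXML
(see :mod:`eqannot.nexml_io`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Optional, Union

from .datamodel import Character, CellValue, Dataset, State, Taxon

logger = logging.getLogger("eqannot")

DEFAULT_MISSING = "?"
DEFAULT_GAP = "-"


class NexusParseError(ValueError):
    """Malformed NEXUS input; the message carries a line number."""


@dataclass
class NexusDocument:
    """Raw parse result, one step away from a :class:`Dataset`."""

    taxa_labels: list[str] = field(default_factory=list)
    nchar: int = 0
    symbols: str = ""
    missing: str = DEFAULT_MISSING
    gap: str = DEFAULT_GAP
    # char index (1-based) -> (character label or None, ordered state labels)
    charstatelabels: dict[int, tuple[Optional[str], list[str]]] = field(
        default_factory=dict
    )
    matrix_rows: dict[str, str] = field(default_factory=dict)

    def row_cells(self, taxon_label: str) -> list[str]:
        """Cell tokens for a row: "0", "{01}", "?", "-", ..."""
        return expand_row(self.matrix_rows[taxon_label], self.missing, self.gap)


def expand_row(row: str, missing: str, gap: str) -> list[str]:
    """Split a packed matrix row into cell tokens, honouring {} and () groups."""
    cells: list[str] = []
    i = 0
    while i < len(row):
        ch = row[i]
        if ch in "{(":
            close = "}" if ch == "{" else ")"
            j = row.find(close, i + 1)
            if j < 0:
                raise NexusParseError(f"unclosed polymorphic group in row {row!r}")
            cells.append("{" + row[i + 1 : j] + "}")
            i = j + 1
        else:
            cells.append(ch)
            i += 1
    return cells


# ---------------------------------------------------------------------------
# Tokenizer

_PUNCT = set(";=,/")


@dataclass(frozen=True)
class _Token:
    text: str
    line: int
    quoted: bool = False

    def upper(self) -> str:
        return self.text.upper()


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    line = 1
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "\n":
            line += 1
            i += 1
        elif ch.isspace():
            i += 1
        elif ch == "[":
            depth = 1
            i += 1
            while i < n and depth:
                if text[i] == "[":
                    depth += 1
                elif text[i] == "]":
                    depth -= 1
                elif text[i] == "\n":
                    line += 1
                i += 1
            if depth:
                raise NexusParseError(f"line {line}: unterminated comment")
        elif ch in "'\"":
            # single quotes are the NEXUS convention ('' escapes a quote);
            # double quotes appear in practice around FORMAT values
            quote = ch
            start_line = line
            buf = []
            i += 1
            while True:
                if i >= n:
                    raise NexusParseError(f"line {start_line}: unterminated quote")
                if text[i] == quote:
                    if quote == "'" and i + 1 < n and text[i + 1] == "'":
                        buf.append("'")
                        i += 2
                        continue
                    i += 1
                    break
                if text[i] == "\n":
                    line += 1
                buf.append(text[i])
                i += 1
            tokens.append(_Token("".join(buf), start_line, quoted=True))
        elif ch in _PUNCT:
            tokens.append(_Token(ch, line))
            i += 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in _PUNCT \
                    and text[j] not in "['\"":
                j += 1
            tokens.append(_Token(text[i:j], line))
            i = j
    return tokens


def _label(tok: _Token) -> str:
    """Label text of a token: quoted verbatim, unquoted underscores -> spaces."""
    return tok.text if tok.quoted else tok.text.replace("_", " ")


class _Cursor:
    def __init__(self, tokens: list[_Token]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> Optional[_Token]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise NexusParseError("unexpected end of file")
        self.pos += 1
        return tok

    def expect(self, text: str) -> _Token:
        tok = self.next()
        if tok.upper() != text.upper():
            raise NexusParseError(
                f"line {tok.line}: expected {text!r}, found {tok.text!r}"
            )
        return tok

    def until_semicolon(self) -> list[_Token]:
        out = []
        while True:
            tok = self.next()
            if tok.text == ";" and not tok.quoted:
                return out
            out.append(tok)


# ---------------------------------------------------------------------------
# Parser


def parse_nexus(source: Union[str, bytes, IO]) -> NexusDocument:
    """Parse a NEXUS byte stream into a :class:`NexusDocument`.

    Raises :class:`NexusParseError` (with a line number) for a missing
    ``#NEXUS`` sentinel, rows whose expanded length differs from NCHAR, or
    duplicate taxon labels.
    """
    if hasattr(source, "read"):
        source = source.read()
    if isinstance(source, bytes):
        source = source.decode("utf-8")
    stripped = source.lstrip()
    if not stripped.upper().startswith("#NEXUS"):
        raise NexusParseError("line 1: file does not begin with #NEXUS")
    body = stripped[len("#NEXUS"):]

    doc = NexusDocument()
    interleave = False
    row_last_line: dict[str, int] = {}
    cur = _Cursor(_tokenize(body))

    while cur.peek() is not None:
        tok = cur.next()
        if tok.upper() != "BEGIN":
            continue
        block_tok = cur.next()
        block = block_tok.upper()
        cur.expect(";")
        if block in ("TAXA", "CHARACTERS", "DATA"):
            _parse_data_block(cur, block, doc, row_last_line)
        else:
            logger.info("skipping NEXUS block %r", block_tok.text)
            _skip_block(cur)

    if not doc.symbols:
        seen = set()
        for row in doc.matrix_rows.values():
            for cell in expand_row(row, doc.missing, doc.gap):
                for sym in (cell[1:-1] if cell.startswith("{") else cell):
                    if sym not in (doc.missing, doc.gap):
                        seen.add(sym)
        doc.symbols = "".join(sorted(seen))

    for label, row in doc.matrix_rows.items():
        ncells = len(expand_row(row, doc.missing, doc.gap))
        if doc.nchar and ncells != doc.nchar:
            raise NexusParseError(
                f"line {row_last_line.get(label, 0)}: row for taxon {label!r} has "
                f"{ncells} cells, expected NCHAR={doc.nchar}"
            )
    return doc


def _skip_block(cur: _Cursor) -> None:
    while True:
        tok = cur.next()
        if tok.upper() in ("END", "ENDBLOCK"):
            cur.expect(";")
            return


def _parse_data_block(
    cur: _Cursor, block: str, doc: NexusDocument, row_last_line: dict[str, int]
) -> None:
    interleave = False
    while True:
        tok = cur.next()
        cmd = tok.upper()
        if cmd in ("END", "ENDBLOCK"):
            cur.expect(";")
            return
        if cmd == "DIMENSIONS":
            for key, value in _parse_assignments(cur.until_semicolon()):
                if key == "NCHAR":
                    doc.nchar = int(value)
                # NTAX is implied by TAXLABELS / matrix rows; NEWTAXA ignored
        elif cmd == "FORMAT":
            for key, value in _parse_assignments(cur.until_semicolon()):
                if key == "SYMBOLS":
                    doc.symbols = "".join(value.split())
                elif key == "MISSING":
                    doc.missing = value
                elif key == "GAP":
                    doc.gap = value
                elif key == "INTERLEAVE" and value in ("", "YES"):
                    interleave = True
        elif cmd == "TAXLABELS":
            for t in cur.until_semicolon():
                label = _label(t)
                if label in doc.taxa_labels:
                    raise NexusParseError(
                        f"line {t.line}: duplicate taxon label {label!r}"
                    )
                doc.taxa_labels.append(label)
        elif cmd == "CHARSTATELABELS":
            _parse_charstatelabels(cur.until_semicolon(), doc)
        elif cmd == "CHARLABELS":
            for idx, t in enumerate(cur.until_semicolon(), start=1):
                prev = doc.charstatelabels.get(idx, (None, []))
                doc.charstatelabels[idx] = (_label(t), prev[1])
        elif cmd == "STATELABELS":
            _parse_statelabels(cur.until_semicolon(), doc)
        elif cmd == "MATRIX":
            _parse_matrix(cur, doc, interleave, row_last_line)
        else:
            cur.until_semicolon()  # unknown command: skip


def _parse_assignments(tokens: list[_Token]) -> list[tuple[str, str]]:
    """FORMAT/DIMENSIONS style ``KEY=VALUE`` pairs; bare keywords get ""."""
    out: list[tuple[str, str]] = []
    i = 0
    while i < len(tokens):
        key = tokens[i].upper()
        if i + 1 < len(tokens) and tokens[i + 1].text == "=":
            if i + 2 >= len(tokens):
                raise NexusParseError(
                    f"line {tokens[i].line}: missing value for {key}"
                )
            out.append((key, tokens[i + 2].text))
            i += 3
        else:
            out.append((key, ""))
            i += 1
    return out


def _split_on_commas(tokens: list[_Token]) -> list[list[_Token]]:
    groups: list[list[_Token]] = [[]]
    for t in tokens:
        if t.text == "," and not t.quoted:
            groups.append([])
        else:
            groups[-1].append(t)
    return [g for g in groups if g]


def _parse_charstatelabels(tokens: list[_Token], doc: NexusDocument) -> None:
    # "1 'opercle shape' / triangular round, 2 ..." — label and "/ states" optional
    for group in _split_on_commas(tokens):
        idx_tok = group[0]
        try:
            idx = int(idx_tok.text)
        except ValueError:
            raise NexusParseError(
                f"line {idx_tok.line}: expected character number, found {idx_tok.text!r}"
            ) from None
        rest = group[1:]
        label: Optional[str] = None
        states: list[str] = []
        if rest and rest[0].text == "/" and not rest[0].quoted:
            states = [_label(t) for t in rest[1:]]
        elif rest:
            label = _label(rest[0])
            tail = rest[1:]
            if tail and tail[0].text == "/" and not tail[0].quoted:
                states = [_label(t) for t in tail[1:]]
        doc.charstatelabels[idx] = (label, states)


def _parse_statelabels(tokens: list[_Token], doc: NexusDocument) -> None:
    for group in _split_on_commas(tokens):
        idx = int(group[0].text)
        prev = doc.charstatelabels.get(idx, (None, []))
        doc.charstatelabels[idx] = (prev[0], [_label(t) for t in group[1:]])


def _parse_matrix(
    cur: _Cursor, doc: NexusDocument, interleave: bool, row_last_line: dict[str, int]
) -> None:
    tokens = cur.until_semicolon()
    known_taxa = bool(doc.taxa_labels)
    # group tokens into physical lines
    lines: list[list[_Token]] = []
    for t in tokens:
        if lines and lines[-1][0].line == t.line:
            lines[-1].append(t)
        else:
            lines.append([t])

    if interleave:
        for line_toks in lines:
            label = _label(line_toks[0])
            chunk = "".join(t.text for t in line_toks[1:])
            doc.matrix_rows[label] = doc.matrix_rows.get(label, "") + chunk
            row_last_line[label] = line_toks[0].line
            if label not in doc.taxa_labels:
                if known_taxa and doc.matrix_rows[label] == chunk:
                    raise NexusParseError(
                        f"line {line_toks[0].line}: matrix taxon {label!r} "
                        "not in TAXLABELS"
                    )
                if not known_taxa:
                    doc.taxa_labels.append(label)
        return

    # non-interleaved: a taxon label token starts a row; data may wrap lines
    flat = [t for line_toks in lines for t in line_toks]
    i = 0
    while i < len(flat):
        label_tok = flat[i]
        label = _label(label_tok)
        if label in doc.matrix_rows:
            raise NexusParseError(
                f"line {label_tok.line}: duplicate matrix row for taxon {label!r}"
            )
        i += 1
        chunk = ""
        while i < len(flat):
            if doc.nchar and len(expand_row(chunk, doc.missing, doc.gap)) >= doc.nchar:
                break
            nxt = flat[i]
            # a quoted token or a declared taxon label starts the next row
            if nxt.quoted or (known_taxa and _label(nxt) in doc.taxa_labels):
                break
            chunk += nxt.text
            row_last_line[label] = nxt.line
            i += 1
        row_last_line.setdefault(label, label_tok.line)
        doc.matrix_rows[label] = chunk
        if label not in doc.taxa_labels:
            if known_taxa:
                raise NexusParseError(
                    f"line {label_tok.line}: matrix taxon {label!r} not in TAXLABELS"
                )
            doc.taxa_labels.append(label)


# ---------------------------------------------------------------------------
# NexusDocument -> Dataset


def to_dataset(doc: NexusDocument) -> Dataset:
    """Build an unannotated :class:`Dataset` from a parsed NEXUS document.

    Characters are numbered 1..NCHAR with CHARSTATELABELS labels (fallback
    "Character N"); one state per SYMBOLS entry with state labels aligned
    positionally.  All phenotype lists start empty — annotation is the
    downstream curation step.
    """
    taxa = [Taxon(publication_name=lbl) for lbl in doc.taxa_labels]
    characters: list[Character] = []
    for idx in range(1, doc.nchar + 1):
        label, state_labels = doc.charstatelabels.get(idx, (None, []))
        if len(state_labels) > len(doc.symbols):
            logger.warning(
                "character %d has %d state labels for %d symbols; extras dropped",
                idx, len(state_labels), len(doc.symbols),
            )
            state_labels = state_labels[: len(doc.symbols)]
        states = tuple(
            State(
                symbol=sym,
                label=state_labels[i] if i < len(state_labels) else "",
            )
            for i, sym in enumerate(doc.symbols)
        )
        characters.append(
            Character(index=idx, label=label or f"Character {idx}", states=states)
        )

    matrix: dict[tuple[str, int], CellValue] = {}
    for taxon_label in doc.taxa_labels:
        if taxon_label not in doc.matrix_rows:
            continue
        for char_idx, cell in enumerate(doc.row_cells(taxon_label), start=1):
            matrix[(taxon_label, char_idx)] = _cell_value(cell, doc)
    return Dataset(taxa=taxa, characters=characters, matrix=matrix)


def _cell_value(cell: str, doc: NexusDocument) -> CellValue:
    if cell == doc.missing:
        return CellValue.missing()
    if cell == doc.gap:
        return CellValue.gap()
    if cell.startswith("{"):
        return CellValue.polymorphic(cell[1:-1])
    return CellValue.single(cell)


def load_nexus(path: str) -> NexusDocument:
    with open(path, "rb") as fh:
        return parse_nexus(fh)
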