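"""Alignment and tree I/O: FASTA, PHYLIP (strict/relaxed, sequential/interleaved),
a small validatable XML dialect, and Newick output.

All readers accept text streams so the tools compose over pipes; all readers
preserve record order and normalize sequences to upper case (with RNA ``U``
mapped to ``T`` for DNA). The PHYLIP strict dialect uses the classic
10-character name field; the relaxed dialect (the writing default) is
whitespace-delimited and supports identifiers of any length, as does the XML
dialect.
"""

from __future__ import annotations

import io
import sys
from dataclasses import dataclass
from typing import Iterator, TextIO, Union

import numpy as np
from Bio import SeqIO
from lxml import etree

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    EmptyInputError,
    IdentifierCollisionError,
    ParseError,
    PhylokitError,
    ValidationError,
)
from .matrix import DistanceMatrix
from .tree import Tree

# IUPAC nucleotide codes: symbol -> set of compatible bases
IUPAC_DNA: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
DNA_SYMBOLS = frozenset(IUPAC_DNA) | {"-"}
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"  # canonical PAML residue order
PROTEIN_SYMBOLS = frozenset(AMINO_ACIDS) | {"X", "-"}
GAP = "-"


@dataclass
class Alignment:
    """Named, equal-length sequences over a declared alphabet."""

    taxa: list[str]
    rows: list[str]
    alphabet: str  # "dna" | "protein"

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise AlignmentShapeError("taxa and rows differ in count")
        if not self.taxa:
            raise EmptyInputError("alignment has no records")
        seen: set[str] = set()
        for t in self.taxa:
            if not t:
                raise IdentifierCollisionError("empty taxon identifier")
            if t in seen:
                raise IdentifierCollisionError(f"duplicate identifier {t!r}")
            seen.add(t)
        length = len(self.rows[0])
        symbols = DNA_SYMBOLS if self.alphabet == "dna" else PROTEIN_SYMBOLS
        if self.alphabet not in ("dna", "protein"):
            raise PhylokitError(f"unknown alphabet {self.alphabet!r}")
        for t, row in zip(self.taxa, self.rows):
            if len(row) != length:
                raise AlignmentShapeError(
                    f"record {t!r} has length {len(row)}, expected {length}"
                )
            bad = set(row) - symbols
            if bad:
                raise AlphabetError(
                    f"record {t!r} contains non-{self.alphabet} symbols: "
                    f"{''.join(sorted(bad))}"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])


def _normalize(seq: str, alphabet_hint: str | None = None) -> str:
    seq = seq.upper()
    if alphabet_hint != "protein":
        # RNA input is accepted and canonicalized; harmless for protein since
        # U is not a standard residue symbol.
        if alphabet_hint == "dna" or set(seq) <= DNA_SYMBOLS | {"U"}:
            seq = seq.replace("U", "T")
    return seq


def infer_alphabet(rows: list[str]) -> str:
    symbols = set().union(*(set(r) for r in rows))
    return "dna" if symbols <= DNA_SYMBOLS | {"U"} else "protein"


def _make_alignment(taxa: list[str], rows: list[str], alphabet: str | None) -> Alignment:
    rows = [_normalize(r, alphabet) for r in rows]
    if alphabet is None:
        alphabet = infer_alphabet(rows)
    return Alignment(taxa, rows, alphabet)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(stream: TextIO, alphabet: str | None = None) -> Alignment:
    """Parse an aligned FASTA stream.

    The identifier is the header text up to the first whitespace. All records
    must have equal length; unequal lengths raise an alignment-shape error
    naming the offending record.
    """
    taxa: list[str] = []
    rows: list[str] = []
    for record in SeqIO.parse(stream, "fasta"):
        taxa.append(record.id)
        rows.append(str(record.seq))
    if not taxa:
        raise EmptyInputError("no FASTA records in input")
    length = len(rows[0])
    for t, r in zip(taxa, rows):
        if len(r) != length:
            raise AlignmentShapeError(
                f"record {t!r} has length {len(r)}, expected {length}"
            )
    return _make_alignment(taxa, rows, alphabet)


def write_fasta(aln: Alignment, stream: TextIO, width: int = 60) -> None:
    for taxon, row in zip(aln.taxa, aln.rows):
        stream.write(f">{taxon}\n")
        for i in range(0, len(row), width):
            stream.write(row[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PHYLIP alignments
# ---------------------------------------------------------------------------

STRICT_NAME_WIDTH = 10


def _split_strict(line: str, lineno: int) -> tuple[str, str]:
    if len(line) <= STRICT_NAME_WIDTH:
        raise ParseError(f"line {lineno}: strict PHYLIP record shorter than name field")
    return line[:STRICT_NAME_WIDTH].strip(), line[STRICT_NAME_WIDTH:].replace(" ", "")


def _split_relaxed(line: str, lineno: int) -> tuple[str, str]:
    parts = line.split(None, 1)
    if len(parts) != 2:
        raise ParseError(f"line {lineno}: expected name and sequence")
    return parts[0], parts[1].replace(" ", "")


def read_phylip_alignment(
    stream: TextIO, dialect: str = "relaxed", alphabet: str | None = None
) -> Alignment:
    """Parse a PHYLIP alignment, auto-detecting sequential vs interleaved layout.

    If the first n records already carry full-length sequences the file is
    sequential; otherwise the remaining lines are treated as interleaved
    continuation blocks (name-less, cycling through the taxa in order).
    """
    if dialect not in ("strict", "relaxed"):
        raise PhylokitError(f"unknown PHYLIP dialect {dialect!r}")
    lines = stream.read().splitlines()
    numbered = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not numbered:
        raise EmptyInputError("empty PHYLIP input")
    header_no, header = numbered[0]
    try:
        n, n_sites = map(int, header.split()[:2])
    except ValueError:
        raise ParseError(f"line {header_no}: malformed PHYLIP header {header!r}")
    body = numbered[1:]
    if len(body) < n:
        raise ParseError(
            f"line {header_no}: header declares {n} taxa but only "
            f"{len(body)} record lines follow"
        )
    split = _split_strict if dialect == "strict" else _split_relaxed
    taxa: list[str] = []
    parts: list[list[str]] = []
    for lineno, line in body[:n]:
        name, frag = split(line, lineno)
        taxa.append(name)
        parts.append([frag])
    if len(set(taxa)) != n:
        raise IdentifierCollisionError(
            "duplicate PHYLIP names"
            + (" (possibly truncated to 10 characters)" if dialect == "strict" else "")
        )
    sequential = all(len(p[0]) == n_sites for p in parts)
    if sequential:
        if len(body) != n:
            raise ParseError(
                f"line {body[n][0]}: unexpected trailing lines after "
                f"{n} full-length sequential records"
            )
    else:
        for k, (lineno, line) in enumerate(body[n:]):
            parts[k % n].append(line.replace(" ", ""))
    rows = ["".join(p) for p in parts]
    for t, r, (lineno, _) in zip(taxa, rows, body[:n]):
        if len(r) != n_sites:
            raise ParseError(
                f"line {lineno}: record {t!r} has {len(r)} sites, header says {n_sites}"
            )
    return _make_alignment(taxa, rows, alphabet)


def write_phylip_alignment(
    aln: Alignment,
    stream: TextIO,
    dialect: str = "relaxed",
    interleaved: bool = False,
    block_width: int = 60,
) -> None:
    stream.write(f" {aln.n_taxa} {aln.n_sites}\n")
    if dialect == "strict":
        names = [t[:STRICT_NAME_WIDTH].ljust(STRICT_NAME_WIDTH) for t in aln.taxa]
        if len({nm.strip() for nm in names}) != aln.n_taxa:
            raise IdentifierCollisionError(
                "identifiers collide when truncated to 10 characters"
            )
    else:
        pad = max(len(t) for t in aln.taxa) + 2
        names = [t.ljust(pad) for t in aln.taxa]
    if not interleaved:
        for name, row in zip(names, aln.rows):
            stream.write(f"{name}{row}\n")
        return
    blank = " " * len(names[0])
    for start in range(0, aln.n_sites, block_width):
        first = start == 0
        for name, row in zip(names, aln.rows):
            prefix = name if first else blank
            stream.write(f"{prefix}{row[start : start + block_width]}\n")
        if start + block_width < aln.n_sites:
            stream.write("\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree: Tree, precision: int = 6) -> str:
    """Serialize a tree to Newick with branch lengths at the given number of
    significant digits. Labels containing metacharacters are single-quoted."""
    tree.validate()
    return tree.newick(precision=precision)


# ---------------------------------------------------------------------------
# XML dialect
# ---------------------------------------------------------------------------

# Minimal self-describing schema: a <run> holds one <alignment> of
# <seq id=...> elements, or one or more <matrix> elements (taxon ids followed
# by whitespace-separated square rows), or one or more <tree> elements
# holding Newick text.
XML_SCHEMA = """\
<grammar xmlns="http://relaxng.org/ns/structure/1.0">
  <start>
    <element name="run">
      <choice>
        <element name="alignment">
          <optional><attribute name="alphabet"/></optional>
          <oneOrMore>
            <element name="seq"><attribute name="id"/><text/></element>
          </oneOrMore>
        </element>
        <oneOrMore>
          <element name="matrix">
            <oneOrMore>
              <element name="taxon"><attribute name="id"/></element>
            </oneOrMore>
            <oneOrMore>
              <element name="row"><text/></element>
            </oneOrMore>
          </element>
        </oneOrMore>
        <oneOrMore>
          <element name="tree"><text/></element>
        </oneOrMore>
      </choice>
    </element>
  </start>
</grammar>
"""

_relaxng = None


def _schema() -> etree.RelaxNG:
    global _relaxng
    if _relaxng is None:
        _relaxng = etree.RelaxNG(etree.fromstring(XML_SCHEMA.encode()))
    return _relaxng


def print_schema(stream: TextIO | None = None) -> None:
    (stream or sys.stdout).write(XML_SCHEMA)


def _element_path(elem: etree._Element) -> str:
    return elem.getroottree().getpath(elem)


def read_xml_input(
    stream: Union[TextIO, io.RawIOBase], alphabet: str | None = None
) -> Union[Alignment, DistanceMatrix, list[DistanceMatrix]]:
    """Parse a suite XML document into an Alignment or DistanceMatrix.

    A document holding several <matrix> elements (bootstrap output) returns a
    list of matrices.
    """
    data = stream.read()
    if isinstance(data, str):
        data = data.encode()
    if not data.strip():
        raise EmptyInputError("empty XML input")
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ValidationError(f"not well-formed XML: {exc}") from exc
    schema = _schema()
    if not schema.validate(root):
        err = schema.error_log.last_error
        raise ValidationError(
            f"schema violation at {err.path or '/run'}: {err.message}"
        )
    aln_elem = root.find("alignment")
    if aln_elem is not None:
        taxa = [s.get("id") for s in aln_elem.findall("seq")]
        rows = [(s.text or "").strip() for s in aln_elem.findall("seq")]
        declared = aln_elem.get("alphabet") or alphabet
        return _make_alignment(taxa, rows, declared)
    matrices = []
    for m in root.findall("matrix"):
        taxa = [t.get("id") for t in m.findall("taxon")]
        rows = m.findall("row")
        n = len(taxa)
        if len(rows) != n:
            raise ValidationError(
                f"schema violation at {_element_path(m)}: "
                f"{n} taxa but {len(rows)} rows"
            )
        values = np.empty((n, n))
        for i, r in enumerate(rows):
            entries = (r.text or "").split()
            if len(entries) != n:
                raise ValidationError(
                    f"schema violation at {_element_path(r)}: "
                    f"row has {len(entries)} entries, expected {n}"
                )
            values[i] = [float(x) for x in entries]
        matrices.append(DistanceMatrix(taxa, values))
    return matrices[0] if len(matrices) == 1 else matrices


def write_xml_output(
    obj: Union[Alignment, DistanceMatrix, list[DistanceMatrix]],
    stream: TextIO,
) -> None:
    root = etree.Element("run")
    if isinstance(obj, Alignment):
        aln_elem = etree.SubElement(root, "alignment", alphabet=obj.alphabet)
        for taxon, row in zip(obj.taxa, obj.rows):
            seq = etree.SubElement(aln_elem, "seq", id=taxon)
            seq.text = row
    elif isinstance(obj, Tree) or (
        isinstance(obj, list) and obj and isinstance(obj[0], Tree)
    ):
        trees = [obj] if isinstance(obj, Tree) else obj
        for t in trees:
            elem = etree.SubElement(root, "tree")
            elem.text = t.newick().strip()
    else:
        matrices = [obj] if isinstance(obj, DistanceMatrix) else list(obj)
        for m in matrices:
            m_elem = etree.SubElement(root, "matrix")
            for taxon in m.taxa:
                etree.SubElement(m_elem, "taxon", id=taxon)
            for row in m.values:
                r = etree.SubElement(m_elem, "row")
                r.text = " ".join(repr(float(x)) for x in row)
    stream.write(etree.tostring(root, pretty_print=True).decode())


def write_newick_to(tree: Tree, stream: TextIO, precision: int = 6) -> None:
    stream.write(write_newick(tree, precision=precision))


def as_iterator(obj) -> Iterator:
    """Uniform iteration over one object or a list of them."""
    if isinstance(obj, list):
        return iter(obj)
    return iter([obj])
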