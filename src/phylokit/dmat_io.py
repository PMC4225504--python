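"""Distance-matrix serialization: PHYLIP text, XML, and a compact binary
upper-triangular format.

The binary format stores a header (magic ``FPB1``, a version byte, the taxon
count, and length-prefixed UTF-8 identifiers) followed by the strict upper
triangle — n(n-1)/2 entries, diagonal excluded — as little-endian IEEE-754
single precision. Writing is strictly sequential, so a producer holding one
matrix row at a time can stream straight to disk or a pipe; a reader can
likewise iterate rows without materializing the matrix. For 100,000 taxa the
payload is 4 * n(n-1)/2 ~ 18.6 GiB, versus n^2 printed decimals for square
PHYLIP text.

NaN entries (saturated distances) are not representable; substitute a finite
distance first.
"""

from __future__ import annotations

import struct
from typing import BinaryIO, Iterable, Iterator, TextIO

import numpy as np

from .errors import FormatError, ParseError, PhylokitError
from .matrix import DistanceMatrix

MAGIC = b"FPB1"
VERSION = 1
ELEMENT_WIDTH = 4  # IEEE-754 single precision


def header_bytes(taxa: list[str]) -> int:
    return 4 + 1 + 4 + sum(4 + len(t.encode("utf-8")) for t in taxa)


def predict_binary_size(n: int, taxa: list[str]) -> int:
    """Exact on-disk size in bytes of a binary matrix for these taxa."""
    if n < 2:
        raise PhylokitError("need at least 2 taxa")
    if len(taxa) != n:
        raise PhylokitError(f"{len(taxa)} identifiers for n={n}")
    return header_bytes(taxa) + ELEMENT_WIDTH * n * (n - 1) // 2


def write_binary_dm(
    rows: Iterable[np.ndarray], taxa: list[str], sink: BinaryIO
) -> int:
    """Write header then upper-triangle rows; returns total bytes written."""
    n = len(taxa)
    if n < 2:
        raise PhylokitError("need at least 2 taxa")
    written = 0

    def put(data: bytes) -> None:
        nonlocal written
        sink.write(data)
        written += len(data)

    put(MAGIC)
    put(struct.pack("<B", VERSION))
    put(struct.pack("<I", n))
    for t in taxa:
        raw = t.encode("utf-8")
        put(struct.pack("<I", len(raw)))
        put(raw)
    count = 0
    for i, row in enumerate(rows):
        row = np.asarray(row, dtype=float)
        if row.shape != (n - 1 - i,):
            raise PhylokitError(
                f"row {i} has {row.size} entries, expected {n - 1 - i}"
            )
        if not np.isfinite(row).all():
            raise FormatError(
                f"row {i} contains a non-finite entry; substitute saturated "
                "distances before binary encoding"
            )
        put(row.astype("<f4").tobytes())
        count += 1
    if count != n - 1:
        raise PhylokitError(f"expected {n - 1} rows, got {count}")
    return written


def _read_exact(stream: BinaryIO, size: int, what: str) -> bytes:
    data = stream.read(size)
    if len(data) != size:
        raise FormatError(
            f"truncated {what}: expected {size} bytes, got {len(data)}"
        )
    return data


def read_binary_dm_header(stream: BinaryIO) -> list[str]:
    magic = stream.read(4)
    if len(magic) < 4 or magic != MAGIC:
        raise FormatError(f"bad magic {magic!r}, expected {MAGIC!r}")
    (version,) = struct.unpack("<B", _read_exact(stream, 1, "version"))
    if version != VERSION:
        raise FormatError(f"unsupported version {version}")
    (n,) = struct.unpack("<I", _read_exact(stream, 4, "taxon count"))
    taxa = []
    for _ in range(n):
        (ln,) = struct.unpack("<I", _read_exact(stream, 4, "identifier length"))
        taxa.append(_read_exact(stream, ln, "identifier").decode("utf-8"))
    return taxa


def iter_binary_dm(stream: BinaryIO) -> tuple[list[str], Iterator[np.ndarray]]:
    """Read the header, then yield upper-triangle rows one at a time."""
    taxa = read_binary_dm_header(stream)
    n = len(taxa)

    def rows() -> Iterator[np.ndarray]:
        for i in range(n - 1):
            width = (n - 1 - i) * ELEMENT_WIDTH
            data = _read_exact(stream, width, f"payload row {i}")
            yield np.frombuffer(data, dtype="<f4").astype(float)

    return taxa, rows()


def read_binary_dm(stream: BinaryIO) -> DistanceMatrix:
    taxa, rows = iter_binary_dm(stream)
    return DistanceMatrix.from_upper_rows(taxa, rows)


def read_binary_dms(stream: BinaryIO) -> list[DistanceMatrix]:
    """Read concatenated framed binary matrices (bootstrap output) until EOF."""
    out = []
    while True:
        peek = stream.read(1)
        if not peek:
            break
        # push the byte back by reconstructing: streams here are plain files
        # or BytesIO, both seekable
        stream.seek(-1, 1)
        out.append(read_binary_dm(stream))
    if not out:
        raise FormatError("empty binary matrix stream")
    return out


# ---------------------------------------------------------------------------
# PHYLIP text matrices
# ---------------------------------------------------------------------------

STRICT_NAME_WIDTH = 10


def write_phylip_dm(
    m: DistanceMatrix,
    stream: TextIO,
    layout: str = "square",
    dialect: str = "relaxed",
    precision: int = 6,
) -> None:
    if m.has_missing():
        raise PhylokitError(
            "matrix has saturated/missing entries; substitute a finite "
            "distance before writing"
        )
    if layout not in ("square", "upper"):
        raise PhylokitError(f"unknown layout {layout!r}")
    if dialect == "strict":
        names = [t[:STRICT_NAME_WIDTH].ljust(STRICT_NAME_WIDTH) for t in m.taxa]
    else:
        pad = max(len(t) for t in m.taxa) + 2
        names = [t.ljust(pad) for t in m.taxa]
    stream.write(f"{m.n}\n")
    for i, name in enumerate(names):
        entries = m.values[i] if layout == "square" else m.values[i, i + 1 :]
        text = " ".join(f"{x:.{precision}f}" for x in entries)
        stream.write(f"{name}{text}".rstrip() + "\n")


def _iter_phylip_dm_blocks(lines: list[tuple[int, str]]) -> Iterator[DistanceMatrix]:
    pos = 0
    while pos < len(lines):
        lineno, header = lines[pos]
        parts = header.split()
        if len(parts) != 1:
            raise ParseError(f"line {lineno}: expected a taxon count, got {header!r}")
        try:
            n = int(parts[0])
        except ValueError:
            raise ParseError(f"line {lineno}: bad taxon count {parts[0]!r}")
        rows_raw = lines[pos + 1 : pos + 1 + n]
        if len(rows_raw) != n:
            raise ParseError(
                f"line {lineno}: header declares {n} taxa but only "
                f"{len(rows_raw)} rows follow"
            )
        taxa: list[str] = []
        row_vals: list[list[float]] = []
        for k, (rl, line) in enumerate(rows_raw):
            name, vals = _parse_dm_row(line, rl)
            taxa.append(name)
            row_vals.append(vals)
        counts = [len(v) for v in row_vals]
        if all(c == n for c in counts):  # square
            values = np.array(row_vals)
        elif counts == [n - 1 - i for i in range(n)]:  # upper, no diagonal
            values = np.zeros((n, n))
            for i, vals in enumerate(row_vals):
                values[i, i + 1 :] = vals
                values[i + 1 :, i] = vals
        elif counts == [n - i for i in range(n)]:  # upper with diagonal
            values = np.zeros((n, n))
            for i, vals in enumerate(row_vals):
                values[i, i:] = vals
                values[i:, i] = vals
        else:
            # report the first row that breaks the layout suggested by row 0
            if counts[0] == n:
                expect = [n] * n
            elif counts[0] == n - 1:
                expect = [n - 1 - i for i in range(n)]
            else:
                expect = [n - i for i in range(n)]
            bad = next(
                (i for i, (c, e) in enumerate(zip(counts, expect)) if c != e), 0
            )
            raise ParseError(
                f"line {rows_raw[bad][0]}: row has {counts[bad]} entries, "
                f"expected {expect[bad]} for n={n}"
            )
        yield DistanceMatrix(taxa, values)
        pos += 1 + n


def _parse_dm_row(line: str, lineno: int) -> tuple[str, list[float]]:
    parts = line.split()
    if not parts:
        raise ParseError(f"line {lineno}: empty matrix row")
    name, rest = parts[0], parts[1:]
    try:
        vals = [float(x) for x in rest]
    except ValueError:
        # strict dialect: the name occupies the first 10 columns and may
        # contain spaces
        name = line[:STRICT_NAME_WIDTH].strip()
        try:
            vals = [float(x) for x in line[STRICT_NAME_WIDTH:].split()]
        except ValueError:
            raise ParseError(f"line {lineno}: unparseable matrix row {line!r}")
    return name, vals


def read_phylip_dms(stream: TextIO) -> list[DistanceMatrix]:
    """Read one or more concatenated PHYLIP matrices (square or upper)."""
    lines = [
        (i + 1, ln) for i, ln in enumerate(stream.read().splitlines()) if ln.strip()
    ]
    if not lines:
        raise ParseError("empty distance-matrix input")
    return list(_iter_phylip_dm_blocks(lines))


def read_phylip_dm(stream: TextIO) -> DistanceMatrix:
    return read_phylip_dms(stream)[0]
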