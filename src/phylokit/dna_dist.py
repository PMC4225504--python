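"""Pairwise evolutionary distances from DNA alignments.

Four estimators are provided: p-distance (Hamming proportion), Jukes-Cantor,
Kimura two-parameter (the default), and Tamura-Nei 1993. Counting supports
IUPAC ambiguity codes: an ambiguous pair with candidate sets S_a, S_b spreads
unit weight uniformly over S_a x S_b, so each site still contributes exactly
one unit split across the match / transition / transversion categories. Sites
where either sequence has a gap are excluded (pairwise deletion); with
ambiguity disabled, any non-ACGT symbol also excludes the site.

Saturated or undefined entries (a correction-formula logarithm evaluated at a
non-positive argument, or a pair with no comparable sites) are recorded as
NaN; callers that need finite matrices substitute a fixed large distance.

A row-streaming mode computes the upper-triangular matrix one row at a time
so that peak retained matrix state is a single row; it produces values
bit-identical to the in-memory mode but, mirroring the counting backend's
packed representation, does not support ambiguity codes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterator

import numpy as np

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    DegenerateCompositionError,
    PhylokitError,
    UnsupportedCombinationError,
)
from .matrix import DistanceMatrix
from .seqio import GAP, IUPAC_DNA, Alignment

MODELS = ("p", "jc", "k2p", "tn93")
DEFAULT_MODEL = "k2p"

# --- symbol coding ----------------------------------------------------------

_SYMBOLS = "ACGTRYSWKMBDHVN"  # codes 0..14; gap is code 15
_GAP_CODE = 15
_CODE_OF = {s: i for i, s in enumerate(_SYMBOLS)}
_CODE_OF[GAP] = _GAP_CODE

_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _s, _c in _CODE_OF.items():
    _ENCODE_LUT[ord(_s)] = _c


def _category(x: str, y: str) -> str:
    if x == y:
        return "match"
    pair = {x, y}
    if pair == {"A", "G"}:
        return "ts_AG"
    if pair == {"C", "T"}:
        return "ts_CT"
    return "tv"


def _build_tables() -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-symbol-pair fractional weights for each count category, and
    per-symbol fractional base composition."""
    cats = {k: np.zeros((16, 16)) for k in ("match", "ts_AG", "ts_CT", "tv")}
    comp = np.zeros((16, 4))
    for sa, ca in _CODE_OF.items():
        if sa == GAP:
            continue
        cand_a = IUPAC_DNA[sa]
        for b in cand_a:
            comp[ca, "ACGT".index(b)] += 1.0 / len(cand_a)
        for sb, cb in _CODE_OF.items():
            if sb == GAP:
                continue
            cand_b = IUPAC_DNA[sb]
            w = 1.0 / (len(cand_a) * len(cand_b))
            for x in cand_a:
                for y in cand_b:
                    cats[_category(x, y)][ca, cb] += w
    return cats, comp


_CAT_TABLES, _COMP_TABLE = _build_tables()
_CAT_FLAT = {k: v.ravel() for k, v in _CAT_TABLES.items()}


def encode_dna(seq: str) -> np.ndarray:
    codes = _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = sorted({seq[i] for i in np.nonzero(codes == 255)[0]})
        raise AlphabetError(f"non-IUPAC DNA symbols: {''.join(bad)}")
    return codes


@dataclass
class PairCountsDNA:
    """Sufficient statistics for one sequence pair.

    ``ts_AG`` and ``ts_CT`` are the class-specific transition weights (P1 and
    P2 in the Tamura-Nei parameterization), ``tv`` the transversion weight,
    and ``freq`` the fractional base tallies over both sequences at the
    comparable sites (sums to 2 x valid_sites).
    """

    valid_sites: float
    matches: float
    ts_AG: float
    ts_CT: float
    tv: float
    freq: np.ndarray  # shape (4,): A, C, G, T


def _counts_from_codes(
    codes_a: np.ndarray, codes_b: np.ndarray, ambiguity: bool
) -> PairCountsDNA:
    if codes_a.shape != codes_b.shape:
        raise AlignmentShapeError(
            f"sequence lengths differ: {codes_a.size} vs {codes_b.size}"
        )
    if ambiguity:
        valid = (codes_a != _GAP_CODE) & (codes_b != _GAP_CODE)
    else:
        valid = (codes_a < 4) & (codes_b < 4)
    ca = codes_a[valid].astype(np.intp)
    cb = codes_b[valid].astype(np.intp)
    pair_hist = np.bincount(ca * 16 + cb, minlength=256).astype(float)
    matches = float(pair_hist @ _CAT_FLAT["match"])
    ts_ag = float(pair_hist @ _CAT_FLAT["ts_AG"])
    ts_ct = float(pair_hist @ _CAT_FLAT["ts_CT"])
    tv = float(pair_hist @ _CAT_FLAT["tv"])
    hist_a = np.bincount(ca, minlength=16).astype(float)
    hist_b = np.bincount(cb, minlength=16).astype(float)
    freq = (hist_a + hist_b) @ _COMP_TABLE
    return PairCountsDNA(
        valid_sites=float(ca.size),
        matches=matches,
        ts_AG=ts_ag,
        ts_CT=ts_ct,
        tv=tv,
        freq=freq,
    )


def count_pair(row_a: str, row_b: str, ambiguity: bool = True) -> PairCountsDNA:
    """Tally match / transition / transversion weights for one aligned pair."""
    return _counts_from_codes(encode_dna(row_a), encode_dna(row_b), ambiguity)


# --- estimators -------------------------------------------------------------

def p_distance(c: PairCountsDNA) -> float:
    if c.valid_sites == 0:
        return math.nan
    return (c.valid_sites - c.matches) / c.valid_sites


def jc_distance(c: PairCountsDNA) -> float:
    p = p_distance(c)
    if math.isnan(p):
        return math.nan
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return math.nan  # saturated
    return -0.75 * math.log(arg)


def k2p_distance(c: PairCountsDNA) -> float:
    if c.valid_sites == 0:
        return math.nan
    P = (c.ts_AG + c.ts_CT) / c.valid_sites
    Q = c.tv / c.valid_sites
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    if a1 <= 0.0 or a2 <= 0.0:
        return math.nan
    return -0.5 * math.log(a1) - 0.25 * math.log(a2)


def tn93_distance(c: PairCountsDNA, pi: np.ndarray | None = None) -> float:
    """Tamura-Nei 1993 distance. Base frequencies default to the pair's own
    composition; pass ``pi`` to use alignment-global frequencies instead."""
    if c.valid_sites == 0:
        return math.nan
    pi = c.freq / c.freq.sum() if pi is None else np.asarray(pi, dtype=float)
    pi_a, pi_c, pi_g, pi_t = pi
    if (pi <= 0).any():
        raise DegenerateCompositionError(
            "TN93 requires all four bases present in the pair"
        )
    pi_r = pi_a + pi_g
    pi_y = pi_c + pi_t
    P1 = c.ts_AG / c.valid_sites
    P2 = c.ts_CT / c.valid_sites
    Q = c.tv / c.valid_sites
    k1 = 2.0 * pi_a * pi_g / pi_r
    k2 = 2.0 * pi_t * pi_c / pi_y
    k3 = 2.0 * (
        pi_r * pi_y - pi_a * pi_g * pi_y / pi_r - pi_t * pi_c * pi_r / pi_y
    )
    a1 = 1.0 - P1 / k1 - Q / (2.0 * pi_r)
    a2 = 1.0 - P2 / k2 - Q / (2.0 * pi_y)
    a3 = 1.0 - Q / (2.0 * pi_r * pi_y)
    if a1 <= 0.0 or a2 <= 0.0 or a3 <= 0.0:
        return math.nan
    return -k1 * math.log(a1) - k2 * math.log(a2) - k3 * math.log(a3)


_ESTIMATORS: dict[str, Callable[[PairCountsDNA], float]] = {
    "p": p_distance,
    "jc": jc_distance,
    "k2p": k2p_distance,
    "tn93": tn93_distance,
}


# --- matrix computation -----------------------------------------------------

def _check_dna(aln: Alignment) -> None:
    if aln.alphabet != "dna":
        raise AlphabetError("DNA distance estimation requires a DNA alignment")
    if aln.n_taxa < 2:
        raise PhylokitError("need at least 2 taxa")


def global_base_frequencies(aln: Alignment) -> np.ndarray:
    """Fractional A/C/G/T composition over all non-gap sites of the alignment
    (ambiguity codes spread uniformly over their candidate bases)."""
    total = np.zeros(4)
    for row in aln.rows:
        codes = encode_dna(row)
        hist = np.bincount(codes[codes != _GAP_CODE], minlength=16).astype(float)
        total += hist @ _COMP_TABLE
    return total / total.sum()


def iter_distance_rows(
    aln: Alignment,
    model: str = DEFAULT_MODEL,
    ambiguity: bool = True,
    saturation_distance: float | None = None,
    global_freqs: bool = False,
) -> Iterator[np.ndarray]:
    """Yield upper-triangle rows (row i has entries against j > i)."""
    _check_dna(aln)
    if model not in _ESTIMATORS:
        raise PhylokitError(f"unknown model {model!r}; choose from {MODELS}")
    est = _ESTIMATORS[model]
    if model == "tn93" and global_freqs:
        pi_global = global_base_frequencies(aln)
        est = lambda c: tn93_distance(c, pi=pi_global)  # noqa: E731
    codes = [encode_dna(r) for r in aln.rows]
    n = aln.n_taxa
    for i in range(n - 1):
        row = np.empty(n - 1 - i)
        for k, j in enumerate(range(i + 1, n)):
            d = est(_counts_from_codes(codes[i], codes[j], ambiguity))
            if math.isnan(d) and saturation_distance is not None:
                d = saturation_distance
            row[k] = d
        yield row


def distance_matrix(
    aln: Alignment,
    model: str = DEFAULT_MODEL,
    ambiguity: bool = True,
    row_sink: Callable[[int, np.ndarray], None] | None = None,
    saturation_distance: float | None = None,
    global_freqs: bool = False,
) -> DistanceMatrix | None:
    """Compute the pairwise distance matrix.

    With ``row_sink`` given, rows are delivered to the sink as they are
    produced and nothing is retained (streaming mode, returns None); the
    streamed values are bit-identical to the in-memory result. Streaming
    requires ``ambiguity=False``.
    """
    if row_sink is not None and ambiguity:
        raise UnsupportedCombinationError(
            "row streaming does not support ambiguity symbols; "
            "pass ambiguity=False"
        )
    rows = iter_distance_rows(
        aln, model=model, ambiguity=ambiguity,
        saturation_distance=saturation_distance, global_freqs=global_freqs,
    )
    if row_sink is not None:
        for i, row in enumerate(rows):
            row_sink(i, row)
        return None
    return DistanceMatrix.from_upper_rows(aln.taxa, rows)


def partition_rows(n: int, blocks: int) -> list[tuple[int, int]]:
    """Split rows [0, n) into contiguous blocks of near-equal upper-triangle
    workload (row i costs n-1-i pair computations).

    A hook for external parallelization: each block can be computed and
    streamed independently.
    """
    if not 1 <= blocks <= n:
        raise PhylokitError(f"blocks must be in [1, {n}], got {blocks}")
    work = np.arange(n - 1, -1, -1, dtype=float)
    cum = np.cumsum(work)
    total = cum[-1]
    bounds = [0]
    for k in range(1, blocks):
        target = total * k / blocks
        j = int(np.searchsorted(cum, target))
        bounds.append(max(j + 1, bounds[-1] + 1))
    bounds.append(n)
    bounds = [min(b, n) for b in bounds]
    return [(bounds[k], bounds[k + 1]) for k in range(blocks)]
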