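"""Pairwise protein distances.

Two families of estimators are provided:

* correction formulas applied to the observed proportion of differing sites:
  a 20-state Jukes-Cantor analogue (``jc``) and Kimura's approximation to the
  PAM-based distance (``jck``);

* model-based estimators under an empirical replacement model (WAG, JTT,
  Dayhoff, MVR/VT, LG): the maximum-likelihood distance
  ``argmax_d Pr(a, b | d)`` and the posterior-expected distance
  ``E[d | a, b]`` under a prior on d.

For two aligned sequences the likelihood at distance d factors over sites:
``Pr(a, b | d) = prod_sites pi(a) P(d)[a, b]`` where ``P(d) = expm(Q d)`` and
Q is the model's reversible rate generator, scaled so one unit of distance
equals one expected substitution per site. Time reversibility makes the
likelihood independent of which sequence is treated as ancestral. P(d) and
its derivatives are evaluated through the spectral decomposition of the
symmetrized generator, so the Newton-Raphson iteration of the ML estimator
uses analytic first and second derivatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Callable, Iterator

import numpy as np

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    DegeneratePosteriorError,
    PhylokitError,
)
from .matrix import DistanceMatrix
from .seqio import AMINO_ACIDS, Alignment

MODEL_NAMES = ("wag", "jtt", "day", "mvr", "lg")
ESTIMATOR_NAMES = ("jc", "jck") + MODEL_NAMES
DEFAULT_ESTIMATOR = "wag"
DEFAULT_METHOD = "ml"

D_MIN = 1e-6
D_MAX = 10.0
NR_TOL = 1e-8
NR_MAX_ITER = 50

_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _s in enumerate(AMINO_ACIDS):
    _ENCODE_LUT[ord(_s)] = _i
_INVALID = 255  # gap, X: excluded from pair counts


def encode_protein(seq: str) -> np.ndarray:
    """Residue codes 0..19 in PAML order; gaps and X map to an excluded code."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    known = (codes != 255) | (raw == ord("-")) | (raw == ord("X"))
    if not known.all():
        bad = sorted({chr(b) for b in raw[~known]})
        raise AlphabetError(f"non-protein symbols: {''.join(bad)}")
    return codes


@dataclass
class PairCountsProtein:
    """20x20 site-pattern counts N[a][b] for one aligned pair."""

    table: np.ndarray
    valid_sites: float


def count_pair_protein(row_a: str, row_b: str) -> PairCountsProtein:
    return _counts_from_codes(encode_protein(row_a), encode_protein(row_b))


def _counts_from_codes(codes_a: np.ndarray, codes_b: np.ndarray) -> PairCountsProtein:
    if codes_a.shape != codes_b.shape:
        raise AlignmentShapeError(
            f"sequence lengths differ: {codes_a.size} vs {codes_b.size}"
        )
    valid = (codes_a != _INVALID) & (codes_b != _INVALID)
    ca = codes_a[valid].astype(np.intp)
    cb = codes_b[valid].astype(np.intp)
    table = np.bincount(ca * 20 + cb, minlength=400).astype(float).reshape(20, 20)
    return PairCountsProtein(table=table, valid_sites=float(ca.size))


# ---------------------------------------------------------------------------
# Empirical models
# ---------------------------------------------------------------------------

@dataclass
class AminoAcidModel:
    """An empirical replacement model with its normalized generator.

    ``exchangeabilities`` is the symmetric factor S of the reversible
    generator Q[i, j] = S[i, j] * pi[j]; Q is scaled so the expected
    substitution rate at stationarity is 1 (distances are expected
    substitutions per site). The spectral decomposition of the symmetrized
    generator gives P(d) = left @ diag(exp(lam * d)) @ right.
    """

    name: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    generator: np.ndarray = field(init=False)
    eigenvalues: np.ndarray = field(init=False)
    _left: np.ndarray = field(init=False, repr=False)
    _right: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if S.shape != (20, 20) or not np.allclose(S, S.T):
            raise PhylokitError(f"model {self.name}: exchangeabilities not symmetric")
        if (pi <= 0).any():
            raise PhylokitError(f"model {self.name}: non-positive frequency")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(pi @ np.diag(Q))  # expected rate at stationarity
        Q /= mu
        self.frequencies = pi
        self.generator = Q
        sqrt_pi = np.sqrt(pi)
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        lam, U = np.linalg.eigh((B + B.T) / 2.0)
        self.eigenvalues = lam
        self._left = U / sqrt_pi[:, None]
        self._right = U.T * sqrt_pi[None, :]

    def transition_matrix(self, d: float) -> np.ndarray:
        """P(d) = expm(Q d), a stochastic matrix for every d >= 0."""
        if d < 0:
            raise PhylokitError("distance must be non-negative")
        return (self._left * np.exp(self.eigenvalues * d)) @ self._right

    def _p_derivatives(self, d: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        e = np.exp(self.eigenvalues * d)
        P = (self._left * e) @ self._right
        P1 = (self._left * (self.eigenvalues * e)) @ self._right
        P2 = (self._left * (self.eigenvalues**2 * e)) @ self._right
        return P, P1, P2


def _parse_rate_file(text: str) -> tuple[np.ndarray, np.ndarray]:
    values = [
        float(tok)
        for line in text.splitlines()
        if not line.lstrip().startswith("#")
        for tok in line.split()
    ]
    if len(values) != 210:
        raise PhylokitError(
            f"rate file holds {len(values)} numbers, expected 190 + 20"
        )
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = values[k]
            k += 1
    pi = np.array(values[190:])
    if not math.isclose(pi.sum(), 1.0, abs_tol=1e-5):
        raise PhylokitError("frequencies do not sum to 1")
    return S, pi


@lru_cache(maxsize=None)
def load_model(name: str) -> AminoAcidModel:
    """Load a bundled empirical model (wag, jtt, day, mvr, lg) by name."""
    key = name.lower()
    if key not in MODEL_NAMES:
        raise PhylokitError(
            f"unknown model {name!r}; bundled models: {', '.join(MODEL_NAMES)}"
        )
    text = resources.files("phylokit.data").joinpath(f"{key}.dat").read_text()
    S, pi = _parse_rate_file(text)
    return AminoAcidModel(name=key, exchangeabilities=S, frequencies=pi)


# ---------------------------------------------------------------------------
# Likelihood and estimators
# ---------------------------------------------------------------------------

_LOG_FLOOR = 1e-300


def pair_log_likelihood(c: PairCountsProtein, m: AminoAcidModel, d: float) -> float:
    """log Pr(a, b | d) = sum_ab N[a][b] * log(pi_a * P(d)[a, b])."""
    if d < 0:
        raise PhylokitError("distance must be non-negative")
    P = m.transition_matrix(d)
    joint = m.frequencies[:, None] * np.maximum(P, _LOG_FLOOR)
    return float(np.sum(c.table * np.log(joint)))


def _loglik_derivatives(c: PairCountsProtein, m: AminoAcidModel, d: float) -> tuple[float, float]:
    P, P1, P2 = m._p_derivatives(d)
    P = np.maximum(P, _LOG_FLOOR)
    r = P1 / P
    g = float(np.sum(c.table * r))
    h = float(np.sum(c.table * (P2 / P - r * r)))
    return g, h


def _golden_section_max(
    f: Callable[[float], float], lo: float, hi: float, tol: float = 1e-10
) -> float:
    inv_phi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c1 = b - inv_phi * (b - a)
    c2 = a + inv_phi * (b - a)
    f1, f2 = f(c1), f(c2)
    while b - a > tol:
        if f1 < f2:
            a, c1, f1 = c1, c2, f2
            c2 = a + inv_phi * (b - a)
            f2 = f(c2)
        else:
            b, c2, f2 = c2, c1, f1
            c1 = b - inv_phi * (b - a)
            f1 = f(c1)
    return (a + b) / 2.0


def ml_distance(
    c: PairCountsProtein,
    m: AminoAcidModel,
    d_min: float = D_MIN,
    d_max: float = D_MAX,
    tol: float = NR_TOL,
    max_iter: int = NR_MAX_ITER,
    full_output: bool = False,
):
    """Maximum-likelihood distance by Newton-Raphson on the score function.

    The iteration starts from the Kimura correction of the observed
    p-distance and falls back to golden-section search when a step leaves the
    bracket or the curvature has the wrong sign. Identical sequences return
    ``d_min``; a likelihood still increasing at ``d_max`` returns ``d_max``
    (saturation).
    """
    if c.valid_sites <= 0:
        raise PhylokitError("pair has no comparable sites")
    diff = c.valid_sites - float(np.trace(c.table))
    status = "ok"
    if diff == 0:
        result = d_min
        status = "identical"
    else:
        g_max, _ = _loglik_derivatives(c, m, d_max)
        g_min, _ = _loglik_derivatives(c, m, d_min)
        if g_min <= 0:
            result, status = d_min, "minimum"
        elif g_max >= 0:
            result, status = d_max, "saturated"
        else:
            p = diff / c.valid_sites
            x = kimura_protein_distance(p)
            if math.isnan(x):
                x = d_max / 2.0
            x = min(max(x, d_min), d_max)
            result = None
            for _ in range(max_iter):
                g, h = _loglik_derivatives(c, m, x)
                if abs(g) < tol:
                    result = x
                    break
                if h >= 0:
                    break
                step = g / h
                x_new = x - step
                if not d_min <= x_new <= d_max:
                    break
                x = x_new
            if result is None:
                result = _golden_section_max(
                    lambda d: pair_log_likelihood(c, m, d), d_min, d_max
                )
                status = "fallback"
    if full_output:
        return result, status
    return result


@dataclass
class DistancePrior:
    """Discrete prior over evolutionary distances for the expected estimator."""

    grid: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.grid.ndim != 1 or (np.diff(self.grid) <= 0).any():
            raise PhylokitError("prior grid must be strictly increasing")
        if (self.weights < 0).any() or self.weights.sum() <= 0:
            raise PhylokitError("prior weights must be non-negative with positive sum")
        self.weights = self.weights / self.weights.sum()


def default_prior(n_points: int = 400, d_min: float = 1e-4, d_max: float = D_MAX) -> DistancePrior:
    """Flat prior on a geometric grid over (0, d_max]."""
    grid = np.geomspace(d_min, d_max, n_points)
    return DistancePrior(grid=grid, weights=np.full(n_points, 1.0 / n_points))


def expected_distance(
    c: PairCountsProtein, m: AminoAcidModel, prior: DistancePrior | None = None
) -> float:
    """Posterior-mean distance E[d | a, b] over the prior grid (log-sum-exp)."""
    if c.valid_sites <= 0:
        raise PhylokitError("pair has no comparable sites")
    if prior is None:
        prior = default_prior()
    loglik = np.array([pair_log_likelihood(c, m, d) for d in prior.grid])
    finite = np.isfinite(loglik)
    if not finite.any():
        raise DegeneratePosteriorError("likelihood underflowed on the whole grid")
    shift = loglik[finite].max()
    post = np.where(finite, prior.weights * np.exp(loglik - shift), 0.0)
    total = post.sum()
    if total <= 0:
        raise DegeneratePosteriorError("posterior mass is numerically zero")
    return float((prior.grid * post).sum() / total)


# ---------------------------------------------------------------------------
# Correction formulas
# ---------------------------------------------------------------------------

def jc20_distance(p: float) -> float:
    """20-state Jukes-Cantor correction: d = -(19/20) ln(1 - 20 p / 19)."""
    arg = 1.0 - 20.0 * p / 19.0
    if arg <= 0.0:
        return math.nan
    return -(19.0 / 20.0) * math.log(arg)


def kimura_protein_distance(p: float) -> float:
    """Kimura's PAM approximation: d = -ln(1 - p - 0.2 p^2)."""
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0.0:
        return math.nan
    return -math.log(arg)


# ---------------------------------------------------------------------------
# Matrix computation
# ---------------------------------------------------------------------------

def iter_protein_distance_rows(
    aln: Alignment,
    estimator: str = DEFAULT_ESTIMATOR,
    method: str = DEFAULT_METHOD,
    prior: DistancePrior | None = None,
    saturation_distance: float | None = None,
) -> Iterator[np.ndarray]:
    if aln.alphabet != "protein":
        raise AlphabetError("protein distance estimation requires a protein alignment")
    if aln.n_taxa < 2:
        raise PhylokitError("need at least 2 taxa")
    est = estimator.lower()
    if est not in ESTIMATOR_NAMES:
        raise PhylokitError(
            f"unknown estimator {estimator!r}; valid names: "
            + ", ".join(ESTIMATOR_NAMES)
        )
    if method not in ("ml", "expected"):
        raise PhylokitError(f"unknown method {method!r}; use 'ml' or 'expected'")
    codes = [encode_protein(r) for r in aln.rows]
    n = aln.n_taxa
    if est in ("jc", "jck"):
        corr = jc20_distance if est == "jc" else kimura_protein_distance

        def one(i: int, j: int) -> float:
            c = _counts_from_codes(codes[i], codes[j])
            if c.valid_sites == 0:
                return math.nan
            p = (c.valid_sites - float(np.trace(c.table))) / c.valid_sites
            return corr(p)

    else:
        model = load_model(est)
        if method == "ml":

            def one(i: int, j: int) -> float:
                d, status = ml_distance(
                    _counts_from_codes(codes[i], codes[j]), model, full_output=True
                )
                if status == "saturated":
                    return math.nan
                return d

        else:
            the_prior = prior if prior is not None else default_prior()

            def one(i: int, j: int) -> float:
                return expected_distance(
                    _counts_from_codes(codes[i], codes[j]), model, the_prior
                )

    for i in range(n - 1):
        row = np.empty(n - 1 - i)
        for k, j in enumerate(range(i + 1, n)):
            d = one(i, j)
            if math.isnan(d) and saturation_distance is not None:
                d = saturation_distance
            row[k] = d
        yield row


def protein_distance_matrix(
    aln: Alignment,
    estimator: str = DEFAULT_ESTIMATOR,
    method: str = DEFAULT_METHOD,
    prior: DistancePrior | None = None,
    row_sink: Callable[[int, np.ndarray], None] | None = None,
    saturation_distance: float | None = None,
) -> DistanceMatrix | None:
    """Pairwise protein distance matrix; streaming contract as in dna_dist."""
    rows = iter_protein_distance_rows(
        aln, estimator=estimator, method=method, prior=prior,
        saturation_distance=saturation_distance,
    )
    if row_sink is not None:
        for i, row in enumerate(rows):
            row_sink(i, row)
        return None
    return DistanceMatrix.from_upper_rows(aln.taxa, rows)
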