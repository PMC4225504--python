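"""Column-resampling bootstrap for alignments.

Replicates draw alignment columns i.i.d. uniformly with replacement. Each
replicate r is generated from its own RNG substream derived from
``(seed, r)`` (NumPy ``default_rng([seed, r])``), so replicate 57 can be
recomputed independently of the other 56 — the contract that lets bootstrap
replicates run as separate parallel jobs. When no seed is given, a
clock-derived seed is drawn and reported on the log channel.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Callable, Iterator

import numpy as np

from .errors import PhylokitError
from .matrix import DistanceMatrix
from .seqio import Alignment

logger = logging.getLogger("phylokit")


@dataclass
class BootstrapSpec:
    replicates: int = 0
    keep_original: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.replicates < 0:
            raise PhylokitError("replicate count must be >= 0")

    def resolved_seed(self) -> int:
        if self.seed is not None:
            return self.seed
        seed = time.time_ns() % (2**31)
        logger.info("bootstrap: no seed given, using clock-derived seed %d", seed)
        return seed


def replicate_rng(seed: int, index: int) -> np.random.Generator:
    """The RNG substream for replicate ``index`` under ``seed``."""
    return np.random.default_rng([seed, index])


def resample_columns(aln: Alignment, rng: np.random.Generator) -> Alignment:
    """One bootstrap replicate: same taxa, same n_sites, resampled columns."""
    chars = np.array(
        [np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in aln.rows]
    )
    idx = rng.integers(0, aln.n_sites, size=aln.n_sites)
    resampled = chars[:, idx]
    rows = [bytes(row).decode("ascii") for row in resampled]
    return Alignment(list(aln.taxa), rows, aln.alphabet)


def bootstrap_alignments(
    aln: Alignment, spec: BootstrapSpec
) -> Iterator[tuple[str, Alignment]]:
    """Yield ("original", aln) first (unless dropped), then
    ("replicate-r", resampled) for r = 0..B-1 in seed-deterministic order."""
    seed = spec.resolved_seed() if spec.replicates else None
    if spec.keep_original:
        yield "original", aln
    for r in range(spec.replicates):
        yield f"replicate-{r}", resample_columns(aln, replicate_rng(seed, r))


def bootstrap_matrices(
    aln: Alignment,
    spec: BootstrapSpec,
    estimator: Callable[[Alignment], DistanceMatrix],
) -> Iterator[DistanceMatrix]:
    """Distance matrices for the original data (optional) and B replicates."""
    for _, a in bootstrap_alignments(aln, spec):
        yield estimator(a)
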