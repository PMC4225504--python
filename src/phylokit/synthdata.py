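"""Synthetic data: random trees, additive matrices, and sequences evolved
under the supported substitution models.

Every generator is seed-deterministic. Trees are drawn uniformly over
labeled unrooted topologies by sequential random edge attachment, with
branch lengths i.i.d. exponential. Sequences evolve site-independently down
the tree: the root is drawn from the model's stationary frequencies and each
edge applies the transition matrix at its branch length. DNA generators
cover JC, K2P (transition/transversion ratio kappa), and the full TN93
parameterization; protein sequences evolve under any bundled empirical
model. Generators are normalized to one expected substitution per site per
unit branch length, so estimated distances are directly comparable to branch
lengths.

The simulated families these defaults emulate are modest gene families —
DNA sequences of 2,000 sites and protein sequences of 350 residues with
exponential branch lengths of mean 0.1 — not genome-scale alignments;
indels are not simulated (gaps only enter via ambiguity injection options).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import PhylokitError
from .matrix import DistanceMatrix
from .prot_dist import MODEL_NAMES as PROTEIN_MODELS
from .prot_dist import load_model
from .seqio import AMINO_ACIDS, IUPAC_DNA, Alignment
from .tree import Node, Tree

DNA_MODELS = ("jc", "k2p", "tn93")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Branch lengths are exponential with mean ``branch_length_mean`` (expected
    substitutions per site). ``kappa`` is the K2P transition/transversion
    rate ratio; the TN93 parameters are the two transition rates (``alpha1``
    for A<->G, ``alpha2`` for C<->T) relative to the transversion rate
    ``beta``, plus base frequencies ``pi``. ``ambiguity_rate`` replaces that
    fraction of DNA leaf bases with a compatible IUPAC code.
    """

    n_taxa: int
    seq_length: int = 2000
    seed: int = 0
    branch_length_mean: float = 0.1
    model: str = "jc"
    kappa: float = 2.0
    alpha1: float = 4.0
    alpha2: float = 2.0
    beta: float = 1.0
    pi: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    ambiguity_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise PhylokitError("n_taxa must be >= 2")
        if self.seq_length < 1 or self.branch_length_mean <= 0:
            raise PhylokitError("sequence length and branch lengths must be positive")
        if self.model not in DNA_MODELS + PROTEIN_MODELS:
            raise PhylokitError(
                f"unknown model {self.model!r}; DNA: {DNA_MODELS}, "
                f"protein: {PROTEIN_MODELS}"
            )

    @property
    def alphabet(self) -> str:
        return "dna" if self.model in DNA_MODELS else "protein"


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def random_tree(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> Tree:
    """Uniform random unrooted topology by sequential random edge attachment;
    branch lengths i.i.d. exponential with the configured mean."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_taxa
    labels = [f"t{i + 1}" for i in range(n)]
    adj: dict[int, set[int]] = {}

    def connect(a: int, b: int) -> None:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    next_internal = n
    if n == 2:
        # single edge, represented as a midpoint node with two leaf children
        e = float(rng.exponential(cfg.branch_length_mean))
        root = Node()
        root.children = [
            Node(label=labels[0], length=e / 2.0),
            Node(label=labels[1], length=e / 2.0),
        ]
        return Tree(root)
    else:
        hub = next_internal
        next_internal += 1
        for leaf in (0, 1, 2):
            connect(leaf, hub)
        edges = [(0, hub), (1, hub), (2, hub)]
        for leaf in range(3, n):
            k = rng.integers(0, len(edges))
            u, v = edges.pop(int(k))
            w = next_internal
            next_internal += 1
            adj[u].discard(v)
            adj[v].discard(u)
            connect(u, w)
            connect(v, w)
            connect(leaf, w)
            edges.extend([(u, w), (v, w), (leaf, w)])
    lengths = {}
    for u in sorted(adj):
        for v in sorted(adj[u]):
            if u < v:
                lengths[(u, v)] = float(rng.exponential(cfg.branch_length_mean))

    def edge_len(a: int, b: int) -> float:
        return lengths[(a, b) if a < b else (b, a)]

    # root at an internal node (or leaf 0 for n=2) and build the Node tree
    root_idx = 0 if n == 2 else n  # the first hub
    def build(idx: int, parent: int | None) -> Node:
        node = Node(label=labels[idx] if idx < n else None)
        if parent is not None:
            node.length = edge_len(idx, parent)
        for nbr in sorted(adj[idx]):
            if nbr != parent:
                node.children.append(build(nbr, idx))
        return node

    return Tree(build(root_idx, None))


def additive_matrix(tree: Tree) -> DistanceMatrix:
    """Path-length distances between all leaf pairs (an additive metric)."""
    labels = tree.leaf_labels()
    dist = tree.leaf_distances()
    n = len(labels)
    values = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            la, lb = labels[a], labels[b]
            key = (la, lb) if la < lb else (lb, la)
            values[a, b] = values[b, a] = dist[key]
    return DistanceMatrix(labels, values)


# ---------------------------------------------------------------------------
# Substitution generators
# ---------------------------------------------------------------------------

def dna_generator(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Normalized rate matrix Q and stationary frequencies for a DNA model.

    State order A, C, G, T. JC and K2P use uniform frequencies; TN93 uses the
    configured ones. The matrix is scaled so -sum_i pi_i Q_ii = 1.
    """
    if cfg.model == "jc":
        pi = np.full(4, 0.25)
        alpha1 = alpha2 = beta = 1.0
    elif cfg.model == "k2p":
        pi = np.full(4, 0.25)
        alpha1 = alpha2 = cfg.kappa
        beta = 1.0
    else:
        pi = np.asarray(cfg.pi, dtype=float)
        if pi.shape != (4,) or (pi <= 0).any():
            raise PhylokitError("TN93 needs four positive base frequencies")
        pi = pi / pi.sum()
        alpha1, alpha2, beta = cfg.alpha1, cfg.alpha2, cfg.beta
    A, C, G, T = range(4)
    rate = np.full((4, 4), beta)
    rate[A, G] = rate[G, A] = alpha1
    rate[C, T] = rate[T, C] = alpha2
    Q = rate * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(pi @ np.diag(Q))
    return Q / mu, pi


def _evolve_codes(
    tree: Tree,
    Q: np.ndarray,
    pi: np.ndarray,
    length: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    k = pi.size
    root_seq = rng.choice(k, size=length, p=pi)
    out: dict[str, np.ndarray] = {}

    def descend(node: Node, seq: np.ndarray) -> None:
        if node.is_leaf:
            out[node.label] = seq
            return
        for child in node.children:
            P = scipy.linalg.expm(Q * (child.length or 0.0))
            P = np.clip(P, 0.0, None)
            P /= P.sum(axis=1, keepdims=True)
            cum = np.cumsum(P, axis=1)
            u = rng.random(length)
            child_seq = (u[:, None] > cum[seq]).sum(axis=1)
            descend(child, child_seq.astype(np.intp))

    descend(tree.root, root_seq.astype(np.intp))
    return out


_AMBIG_FOR_BASE = {
    b: [code for code, cand in IUPAC_DNA.items() if b in cand and len(cand) > 1]
    for b in "ACGT"
}


def _inject_ambiguity(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        options = _AMBIG_FOR_BASE[chars[i]]
        chars[i] = options[int(rng.integers(0, len(options)))]
    return "".join(chars)


def evolve_sequences(
    tree: Tree, cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> Alignment:
    """Evolve one alignment down the tree under the configured model."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.alphabet == "dna":
        Q, pi = dna_generator(cfg)
        symbols = "ACGT"
    else:
        model = load_model(cfg.model)
        Q, pi = model.generator, model.frequencies
        symbols = AMINO_ACIDS
    codes = _evolve_codes(tree, Q, pi, cfg.seq_length, rng)
    taxa = tree.leaf_labels()
    rows = []
    for t in taxa:
        row = "".join(symbols[c] for c in codes[t])
        if cfg.alphabet == "dna" and cfg.ambiguity_rate > 0:
            row = _inject_ambiguity(row, cfg.ambiguity_rate, rng)
        rows.append(row)
    return Alignment(taxa, rows, cfg.alphabet)


def simulate_family(
    cfg: SimulationConfig,
) -> tuple[Tree, DistanceMatrix, Alignment]:
    """Convenience bundle: tree, its additive matrix, and evolved sequences,
    all from one seeded RNG."""
    rng = np.random.default_rng(cfg.seed)
    tree = random_tree(cfg, rng)
    return tree, additive_matrix(tree), evolve_sequences(tree, cfg, rng)
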