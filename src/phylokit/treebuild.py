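"""Distance-based tree reconstruction: NJ, FNJ, and BioNJ.

All three methods agglomerate a working matrix over "active" nodes, joining
one pair per step, and share the neighbor-joining selection criterion

    S(i, j) = (m - 2) D(i, j) - R(i) - R(j),      R(i) = sum_k D(i, k),

minimized over candidate pairs (m = number of active nodes), and the NJ
branch-length rule l_i = D(i,j)/2 + (R(i) - R(j)) / (2(m - 2)).

* ``nj_tree`` evaluates S over every active pair each step (cubic total).
* ``fnj_tree`` keeps a *visibility set* — one stored candidate partner per
  active node, found by a single linear scan when the node is created and
  refreshed by a rescan when the partner has been consumed — and joins the
  minimal-S pair among visible pairs, for quadratic total work.
* ``bionj_tree`` selects pairs like NJ but propagates a variance-weighted
  matrix reduction controlled by a mixing weight lambda in [0, 1].

On an additive (tree) metric all three reconstruct the generating tree
exactly, including branch lengths. Ties in S are broken toward the
lexicographically smallest pair of original node indices. Negative branch
lengths are kept by default; an optional minimum-length clamp transfers the
deficit to the sibling edge so the joined pair's path length is preserved.
"""

from __future__ import annotations

import numpy as np

from .errors import PhylokitError
from .matrix import DistanceMatrix
from .tree import Node, Tree

METHODS = ("fnj", "nj", "bionj")
DEFAULT_METHOD = "fnj"


class AgglomerationState:
    """Working state of an agglomerative build over node indices.

    Leaves get indices 0..n-1; each join creates a new index. ``D`` and ``R``
    are maintained over the active index set; ``V`` (BioNJ's variance store)
    only when requested.
    """

    def __init__(self, dm: DistanceMatrix, track_variance: bool = False):
        dm.validate()
        if not np.isfinite(dm.values).all():
            raise PhylokitError(
                "distance matrix has non-finite entries; substitute saturated "
                "distances before tree building"
            )
        n = dm.n
        if n < 2:
            raise PhylokitError("need at least 2 taxa")
        cap = 2 * n
        self.n = n
        self.D = np.zeros((cap, cap))
        self.D[:n, :n] = dm.values
        self.V = self.D.copy() if track_variance else None
        self.mask = np.zeros(cap, dtype=bool)
        self.mask[:n] = True
        self.R = np.zeros(cap)
        self.R[:n] = dm.values.sum(axis=1)
        self.nodes: dict[int, Node] = {
            i: Node(label=t) for i, t in enumerate(dm.taxa)
        }
        self.next_id = n
        self.s_evaluations = 0

    @property
    def active(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    @property
    def m(self) -> int:
        return int(self.mask.sum())

    def s_value(self, i: int, j: int) -> float:
        cap = self.mask.size
        if not (0 <= i < cap and 0 <= j < cap):
            raise PhylokitError(f"({i}, {j}) is not an active pair")
        if not (self.mask[i] and self.mask[j]) or i == j:
            raise PhylokitError(f"({i}, {j}) is not an active pair")
        self.s_evaluations += 1
        return (self.m - 2) * self.D[i, j] - self.R[i] - self.R[j]

    def branch_lengths(self, i: int, j: int) -> tuple[float, float]:
        m = self.m
        li = self.D[i, j] / 2.0 + (self.R[i] - self.R[j]) / (2.0 * (m - 2))
        return li, self.D[i, j] - li

    def join(self, i: int, j: int, li: float, lj: float) -> int:
        """Create the parent of i and j; the caller sets the reduced row."""
        u = self.next_id
        self.next_id += 1
        node = Node()
        child_i = self.nodes.pop(i)
        child_j = self.nodes.pop(j)
        child_i.length = li
        child_j.length = lj
        node.children = [child_i, child_j]
        self.nodes[u] = node
        self.mask[i] = self.mask[j] = False
        self.mask[u] = True
        return u

    def set_reduced_row(self, u: int, i: int, j: int, new_row: np.ndarray) -> None:
        """Install D(u, .) for active nodes (excluding u) and update row sums."""
        act = self.active
        others = act[act != u]
        self.D[u, others] = new_row
        self.D[others, u] = new_row
        self.R[others] -= self.D[others, i] + self.D[others, j]
        self.R[others] += new_row
        self.R[u] = new_row.sum()


def nj_selection(state: AgglomerationState, i: int, j: int) -> float:
    """The NJ Q-criterion S(i, j); lower is better."""
    return state.s_value(i, j)


def _finish(state: AgglomerationState, min_branch_length: float | None) -> Tree:
    act = list(map(int, state.active))
    root = Node()
    if len(act) == 2:
        a, b = act
        d = state.D[a, b]
        la, lb = d / 2.0, d / 2.0
    else:
        a, b, c = act
        D = state.D
        la = (D[a, b] + D[a, c] - D[b, c]) / 2.0
        lb = (D[a, b] + D[b, c] - D[a, c]) / 2.0
        lc = (D[a, c] + D[b, c] - D[a, b]) / 2.0
    lengths = [la, lb] if len(act) == 2 else [la, lb, lc]
    if min_branch_length is not None:
        lengths = [max(x, min_branch_length) for x in lengths]
    for idx, length in zip(act, lengths):
        child = state.nodes.pop(idx)
        child.length = length
        root.children.append(child)
    return Tree(root)


def _clamp(li: float, lj: float, floor: float | None) -> tuple[float, float]:
    # Kuhner-Felsenstein style: clamp a negative estimate and transfer the
    # deficit to the sibling edge, preserving the pair's path length.
    if floor is None:
        return li, lj
    if li < floor:
        lj += li - floor
        li = floor
    if lj < floor:
        li += lj - floor
        lj = floor
        li = max(li, floor)
    return li, lj


def _pick_min_pair(
    state: AgglomerationState, pairs_i: np.ndarray, pairs_j: np.ndarray
) -> tuple[int, int]:
    """Minimal-S pair among candidates; ties go to the smallest (i, j)."""
    m = state.m
    s = (m - 2) * state.D[pairs_i, pairs_j] - state.R[pairs_i] - state.R[pairs_j]
    state.s_evaluations += s.size
    winners = np.flatnonzero(s == s.min())
    lo = np.minimum(pairs_i[winners], pairs_j[winners])
    hi = np.maximum(pairs_i[winners], pairs_j[winners])
    order = np.lexsort((hi, lo))
    k = winners[order[0]]
    i, j = int(pairs_i[k]), int(pairs_j[k])
    return (i, j) if i < j else (j, i)


def nj_tree(
    dm: DistanceMatrix, min_branch_length: float | None = None
) -> Tree:
    """Canonical neighbor joining: global minimal-S pair each step."""
    state = AgglomerationState(dm)
    while state.m > 3:
        act = state.active
        ii, jj = np.triu_indices(act.size, k=1)
        i, j = _pick_min_pair(state, act[ii], act[jj])
        li, lj = state.branch_lengths(i, j)
        li, lj = _clamp(li, lj, min_branch_length)
        others = act[(act != i) & (act != j)]
        new_row = (state.D[i, others] + state.D[j, others] - state.D[i, j]) / 2.0
        u = state.join(i, j, li, lj)
        state.set_reduced_row(u, i, j, new_row)
    return _finish(state, min_branch_length)


def fnj_tree(
    dm: DistanceMatrix,
    min_branch_length: float | None = None,
    return_stats: bool = False,
):
    """Fast neighbor joining with a visibility set.

    Each active node stores one candidate partner (its best under S at the
    time of the scan); the join is the minimal-S pair among the visible pairs
    {(i, vis(i))}, with S recomputed under the current m and R. When a node's
    stored partner is consumed by a join, the node rescans its row; the new
    node scans once at creation. Total S evaluations are quadratic in n.
    """
    state = AgglomerationState(dm)

    def scan(i: int) -> int:
        act = state.active
        others = act[act != i]
        s = (state.m - 2) * state.D[i, others] - state.R[i] - state.R[others]
        state.s_evaluations += s.size
        winners = others[s == s.min()]
        return int(winners.min())

    vis: dict[int, int] = {}
    if state.m > 3:
        for i in map(int, state.active):
            vis[i] = scan(i)
    while state.m > 3:
        for i in list(vis):
            if not state.mask[vis[i]]:
                vis[i] = scan(i)
        cand_i = np.array(list(vis), dtype=int)
        cand_j = np.array([vis[i] for i in cand_i], dtype=int)
        i, j = _pick_min_pair(state, cand_i, cand_j)
        li, lj = state.branch_lengths(i, j)
        li, lj = _clamp(li, lj, min_branch_length)
        act = state.active
        others = act[(act != i) & (act != j)]
        new_row = (state.D[i, others] + state.D[j, others] - state.D[i, j]) / 2.0
        u = state.join(i, j, li, lj)
        state.set_reduced_row(u, i, j, new_row)
        vis.pop(i, None)
        vis.pop(j, None)
        if state.m > 3:
            vis[u] = scan(u)
    tree = _finish(state, min_branch_length)
    if return_stats:
        return tree, {"s_evaluations": state.s_evaluations}
    return tree


def bionj_tree(
    dm: DistanceMatrix, min_branch_length: float | None = None
) -> Tree:
    """BioNJ: NJ pair selection with variance-weighted matrix reduction."""
    state = AgglomerationState(dm, track_variance=True)
    V = state.V
    while state.m > 3:
        act = state.active
        ii, jj = np.triu_indices(act.size, k=1)
        i, j = _pick_min_pair(state, act[ii], act[jj])
        li, lj = state.branch_lengths(i, j)
        li, lj = _clamp(li, lj, min_branch_length)
        others = act[(act != i) & (act != j)]
        m = state.m
        if V[i, j] > 0 and m > 3:
            lam = 0.5 + float(np.sum(V[j, others] - V[i, others])) / (
                2.0 * (m - 2) * V[i, j]
            )
            lam = min(max(lam, 0.0), 1.0)
        else:
            lam = 0.5
        new_row = lam * (state.D[i, others] - li) + (1.0 - lam) * (
            state.D[j, others] - lj
        )
        new_var = lam * V[i, others] + (1.0 - lam) * V[j, others] - lam * (
            1.0 - lam
        ) * V[i, j]
        u = state.join(i, j, li, lj)
        state.set_reduced_row(u, i, j, new_row)
        V[u, others] = new_var
        V[others, u] = new_var
    return _finish(state, min_branch_length)


_BUILDERS = {"nj": nj_tree, "fnj": fnj_tree, "bionj": bionj_tree}


def build_tree(
    dm: DistanceMatrix,
    method: str = DEFAULT_METHOD,
    min_branch_length: float | None = None,
) -> Tree:
    key = method.lower()
    if key not in _BUILDERS:
        raise PhylokitError(f"unknown method {method!r}; choose from {METHODS}")
    return _BUILDERS[key](dm, min_branch_length=min_branch_length)
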