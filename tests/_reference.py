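"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's own data structures and numeric
shortcuts: the neighbor-joining reference recomputes every row sum and every
selection value from scratch at each step (O(n^4) total), and the DNA
counting oracle classifies one site at a time with explicit candidate-set
enumeration.
"""

from __future__ import annotations

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def site_category(x: str, y: str) -> str:
    if x == y:
        return "match"
    if {x, y} == {"A", "G"}:
        return "ts_AG"
    if {x, y} == {"C", "T"}:
        return "ts_CT"
    return "tv"


def count_pair_naive(a: str, b: str, ambiguity: bool):
    """Per-site oracle for DNA pair counting."""
    tallies = {"match": 0.0, "ts_AG": 0.0, "ts_CT": 0.0, "tv": 0.0}
    valid = 0.0
    freq = dict.fromkeys("ACGT", 0.0)
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        if not ambiguity and (x not in "ACGT" or y not in "ACGT"):
            continue
        sx, sy = IUPAC[x], IUPAC[y]
        w = 1.0 / (len(sx) * len(sy))
        for cx in sx:
            for cy in sy:
                tallies[site_category(cx, cy)] += w
        for cx in sx:
            freq[cx] += 1.0 / len(sx)
        for cy in sy:
            freq[cy] += 1.0 / len(sy)
        valid += 1.0
    return valid, tallies, np.array([freq[b] for b in "ACGT"])


def nj_reference(taxa: list[str], matrix: np.ndarray):
    """Direct translation of canonical neighbor joining, O(n^4).

    Returns the unrooted tree as a dict of path-length distances between
    leaf-label pairs, plus the join order, so it can be compared with any
    implementation regardless of node layout. Ties break toward the smallest
    lexicographic pair of node indices.
    """
    n = len(taxa)
    D = {(i, j): float(matrix[i, j]) for i in range(n) for j in range(n)}
    active = list(range(n))
    # adjacency with branch lengths
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    next_id = n
    joins = []

    def dist(i, j):
        return D[(i, j)] if i <= j else D[(j, i)]

    def setdist(i, j, v):
        if i > j:
            i, j = j, i
        D[(i, j)] = v

    while len(active) > 3:
        m = len(active)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                ri = sum(dist(i, k) for k in active)
                rj = sum(dist(j, k) for k in active)
                s = (m - 2) * dist(i, j) - ri - rj
                key = (s, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        m = len(active)
        ri = sum(dist(i, k) for k in active)
        rj = sum(dist(j, k) for k in active)
        li = dist(i, j) / 2 + (ri - rj) / (2 * (m - 2))
        lj = dist(i, j) - li
        u = next_id
        next_id += 1
        adj[u] = []
        adj[u].append((i, li))
        adj[i].append((u, li))
        adj[u].append((j, lj))
        adj[j].append((u, lj))
        joins.append((i, j))
        for k in active:
            if k not in (i, j):
                setdist(u, k, (dist(i, k) + dist(j, k) - dist(i, j)) / 2)
        setdist(u, u, 0.0)
        active = [k for k in active if k not in (i, j)] + [u]
    if len(active) == 3:
        a, b, c = active
        la = (dist(a, b) + dist(a, c) - dist(b, c)) / 2
        lb = (dist(a, b) + dist(b, c) - dist(a, c)) / 2
        lc = (dist(a, c) + dist(b, c) - dist(a, b)) / 2
        u = next_id
        adj[u] = []
        for node, ln in ((a, la), (b, lb), (c, lc)):
            adj[u].append((node, ln))
            adj[node].append((u, ln))
    else:  # two nodes left
        a, b = active
        adj[a].append((b, dist(a, b)))
        adj[b].append((a, dist(a, b)))
    # path lengths between leaves by BFS
    out = {}
    for s in range(n):
        seen = {s: 0.0}
        stack = [s]
        while stack:
            v = stack.pop()
            for w, ln in adj[v]:
                if w not in seen:
                    seen[w] = seen[v] + ln
                    stack.append(w)
        for t in range(s + 1, n):
            key = tuple(sorted((taxa[s], taxa[t])))
            out[key] = seen[t]
    return out, joins


def tree_path_metric(tree) -> dict:
    """Leaf-pair path lengths of a phylokit Tree, keyed by sorted label pair."""
    return tree.leaf_distances()


def same_tree(tree_a, tree_b, tol=1e-9) -> bool:
    """Two unrooted trees are equal iff their leaf path metrics agree."""
    da, db = tree_a.leaf_distances(), tree_b.leaf_distances()
    if set(da) != set(db):
        return False
    return all(abs(da[k] - db[k]) <= tol for k in da)
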