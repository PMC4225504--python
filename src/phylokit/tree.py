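"""Unrooted phylogenies with branch lengths, serializable to Newick.

Trees are stored as rooted node structures purely for serialization
convenience; the root of a finished tree is an arbitrary internal node with
three children (the usual unrooted convention), or the midpoint node of the
single edge for two taxa. Branch lengths are in expected substitutions per
site and may be negative (canonical neighbor joining can produce negative
estimates).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from .errors import PhylokitError

_NEEDS_QUOTE = re.compile(r"[\s()\[\]:;,'\"]")


@dataclass
class Node:
    label: str | None = None
    length: float | None = None  # branch to parent; None at the root
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        self.children.append(child)
        return child


def _fmt_label(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


class Tree:
    """An unrooted phylogeny represented as a rooted node structure."""

    def __init__(self, root: Node):
        self.root = root

    # -- inspection ---------------------------------------------------------

    def leaves(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def n_edges(self) -> int:
        count = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            count += len(node.children)
            stack.extend(node.children)
        return count

    def total_length(self) -> float:
        total = 0.0
        stack = [self.root]
        while stack:
            node = stack.pop()
            for c in node.children:
                total += c.length or 0.0
            stack.extend(node.children)
        return total

    def validate(self) -> None:
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            raise PhylokitError("duplicate leaf labels in tree")
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node is not self.root and node.length is not None and not math.isfinite(node.length):
                raise PhylokitError("non-finite branch length")
            stack.extend(node.children)

    # -- distances ----------------------------------------------------------

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path-length distances between every unordered pair of leaves."""
        dist: dict[tuple[str, str], float] = {}

        def walk(node: Node) -> dict[str, float]:
            if node.is_leaf:
                return {node.label: 0.0}
            child_maps = [
                {k: v + (c.length or 0.0) for k, v in walk(c).items()}
                for c in node.children
            ]
            for idx, cm in enumerate(child_maps):
                for other in child_maps[idx + 1 :]:
                    for la, da in cm.items():
                        for lb, db in other.items():
                            key = (la, lb) if la < lb else (lb, la)
                            dist[key] = da + db
            merged: dict[str, float] = {}
            for cm in child_maps:
                merged.update(cm)
            return merged

        walk(self.root)
        return dist

    # -- serialization ------------------------------------------------------

    def newick(self, precision: int = 6) -> str:
        def fmt_len(x: float | None) -> str:
            if x is None:
                return ""
            return f":{x:.{precision}g}"

        def render(node: Node) -> str:
            if node.is_leaf:
                return _fmt_label(node.label or "") + fmt_len(node.length)
            inner = ",".join(render(c) for c in node.children)
            lab = _fmt_label(node.label) if node.label else ""
            return f"({inner}){lab}{fmt_len(node.length)}"

        return render(self.root) + ";\n"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({self.newick().strip()})"
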