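"""Minimal unrooted phylogenetic tree container.

Trees produced by neighbour joining are unrooted; we represent them as a
rooted data structure whose root is the final three-way (or two-way) join.
Bipartitions therefore describe unrooted splits and are canonicalised as a
frozenset-of-frozensets over the leaf label set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional


@dataclass
class TreeNode:
    name: Optional[str] = None
    length: float = 0.0          # branch length to parent
    support: Optional[int] = None  # bootstrap count for the edge to parent
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]


@dataclass
class PhyloTree:
    root: TreeNode

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def to_newick(self, with_support: bool = True) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(render(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = str(node.support)
            return f"({inner}){label}:{node.length:.6g}"

        inner = ",".join(render(c) for c in self.root.children)
        return f"({inner});"

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Map each internal edge's unrooted split to the child node below it.

        A split is {side, complement-side} of the full leaf set; trivial
        splits (single leaf) are excluded.
        """
        all_leaves = frozenset(self.leaf_names())
        splits: dict[frozenset, TreeNode] = {}
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            other = all_leaves - side
            if len(side) >= 2 and len(other) >= 2:
                splits[frozenset({side, other})] = node
        return splits

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf patristic distances, keyed by sorted name pairs."""
        dist: dict[tuple[str, str], float] = {}

        def below(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            partial: list[dict[str, float]] = []
            for child in node.children:
                d = {k: v + child.length for k, v in below(child).items()}
                partial.append(d)
            for i in range(len(partial)):
                for j in range(i + 1, len(partial)):
                    for a, da in partial[i].items():
                        for b, db in partial[j].items():
                            key = (a, b) if a < b else (b, a)
                            dist[key] = da + db
            merged: dict[str, float] = {}
            for d in partial:
                merged.update(d)
            return merged

        below(self.root)
        return dist

    def find_leaf(self, name: str) -> TreeNode:
        for node in self.root.walk():
            if node.is_leaf and node.name == name:
                return node
        raise KeyError(name)
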