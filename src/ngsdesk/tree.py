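"""A minimal rooted-tree structure shared by the clustering tools."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional


@dataclass
class TreeNode:
    """A rooted tree node; ``length`` is the branch to the parent."""

    label: Optional[str] = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    height: float = 0.0  # distance from this node down to its leaves

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> Iterator["TreeNode"]:
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path length per leaf label."""
        out: dict[str, float] = {}

        def walk(node: TreeNode, depth: float) -> None:
            if node.is_leaf:
                out[node.label] = depth
            for child in node.children:
                walk(child, depth + child.length)

        walk(self, 0.0)
        return out

    def cophenetic(self) -> dict[frozenset, float]:
        """Leaf-pair path lengths through the tree, keyed by label pair."""
        out: dict[frozenset, float] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.label: 0.0}
            sub = [walk(c) for c in node.children]
            for i, ci in enumerate(node.children):
                for j in range(i + 1, len(node.children)):
                    cj = node.children[j]
                    for la, da in sub[i].items():
                        for lb, db in sub[j].items():
                            out[frozenset((la, lb))] = (
                                da + ci.length + db + cj.length
                            )
            merged: dict[str, float] = {}
            for c, s in zip(node.children, sub):
                for lab, d in s.items():
                    merged[lab] = d + c.length
            return merged

        walk(self)
        return out

    def splits(self) -> set[frozenset]:
        """Non-trivial unrooted bipartitions, each as the smaller-side label set."""
        all_leaves = frozenset(self.leaf_labels())
        out: set[frozenset] = set()

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset((node.label,))
            below = frozenset().union(*(walk(c) for c in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                out.add(min(below, other, key=lambda s: (len(s), sorted(s))))
            return below

        walk(self)
        return out
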