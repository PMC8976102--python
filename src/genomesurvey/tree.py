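"""Phylogenetic tree container with Newick round-trip and split utilities.

The tree is a plain rooted node structure; "unrooted" trees are represented
with a trifurcating root, the usual convention for distance trees.  Internal
nodes may carry integer bootstrap supports (0-100) which serialize as
internal node labels in Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Iterator

import numpy as np


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.walk()


class PhyloTree:
    """A (possibly trifurcating-rooted) tree with branch lengths and supports."""

    def __init__(self, root: TreeNode):
        self.root = root
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            raise ValueError("leaf labels must be unique")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        from Bio import Phylo

        bt = Phylo.read(StringIO(text), "newick")

        def conv(clade) -> TreeNode:
            node = TreeNode(
                name=clade.name,
                length=float(clade.branch_length or 0.0),
                children=[conv(c) for c in clade.clades],
            )
            if node.children and clade.confidence is not None:
                node.support = int(clade.confidence)
            return node

        return cls(conv(bt.root))

    # -- inspection --------------------------------------------------------

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.name or "" for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial unrooted splits, each as the frozenset of leaf labels
        on the child side, normalized to the lexicographically smaller side."""
        all_leaves = frozenset(self.leaf_labels())
        splits = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(n.name for n in node.walk() if n.is_leaf)
            other = all_leaves - side
            if len(side) < 2 or len(other) < 2:
                continue
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return splits

    def support_of_splits(self) -> dict[frozenset, int | None]:
        all_leaves = frozenset(self.leaf_labels())
        out = {}
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(n.name for n in node.walk() if n.is_leaf)
            other = all_leaves - side
            if len(side) < 2 or len(other) < 2:
                continue
            out[min(side, other, key=lambda s: (len(s), sorted(s)))] = node.support
        return out

    def path_length_matrix(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf patristic distances (sums of branch lengths)."""
        labels = self.leaf_labels()
        idx = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def below(node) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            merged: dict[str, float] = {}
            groups = []
            for c in node.children:
                g = {l: v + c.length for l, v in below(c).items()}
                groups.append(g)
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for la, va in groups[a].items():
                        for lb, vb in groups[b].items():
                            d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = va + vb
                merged.update(groups[a])
            return merged

        below(self.root)
        return labels, d

    # -- serialization -----------------------------------------------------

    def to_newick(self, with_supports: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_supports and node.support is not None:
                label = str(node.support)
            return f"({inner}){label}:{node.length:.6g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        label = ""
        if with_supports and self.root.support is not None:
            label = str(self.root.support)
        return f"({inner}){label};"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloTree({self.n_leaves} leaves)"


def random_tree(labels: list[str], rng: np.random.Generator,
                mean_branch: float = 0.05) -> PhyloTree:
    """Random binary topology with exponential branch lengths (guide trees
    for the mitogenome simulator)."""
    nodes = [TreeNode(name=l) for l in labels]
    for n in nodes:
        n.length = float(rng.exponential(mean_branch))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(children=[nodes[i], nodes[j]],
                          length=float(rng.exponential(mean_branch)))
        nodes = [n for t, n in enumerate(nodes) if t not in (i, j)] + [parent]
    root = TreeNode(children=nodes)
    return PhyloTree(root)
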