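"""Rooted annotated phylogeny container.

A deliberately small tree class used throughout the pipeline.  Nodes carry
branch lengths, optional internal-node support, and free-form annotations
(host state, age, lineage).  Newick parsing is delegated to :mod:`dendropy`;
serialization is direct.
"""

from __future__ import annotations

from typing import Callable, Iterator, Optional

import dendropy
import numpy as np

from hostflux.errors import InputError

__all__ = ["Node", "Tree"]


class Node:
    """One node of a rooted tree.

    Attributes
    ----------
    name:
        Tip label, or a stable internal-node id.
    length:
        Branch length to the parent (``None`` for the root).
    support:
        Bootstrap support percentage, internal nodes only.
    host, age, lineage:
        Optional annotations set by pipeline stages.  ``age`` is time
        before present (tips of an ultrametric tree have age 0).
    """

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.support: Optional[float] = None
        self.host: Optional[str] = None
        self.age: Optional[float] = None
        self.lineage: Optional[str] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.name!r} {kind}>"


class Tree:
    """A rooted tree with named tips."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ #
    # traversal
    # ------------------------------------------------------------------ #

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def find(self, name: str) -> Node:
        for node in self.postorder():
            if node.name == name:
                return node
        raise InputError(f"no node named {name!r} in tree")

    def mrca(self, names: list[str]) -> Node:
        """Most recent common ancestor of the named tips."""
        want = set(names)
        below: dict[Node, set[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = {node.name}
            else:
                below[node] = set().union(*(below[c] for c in node.children))
            if want <= below[node]:
                return node
        raise InputError(f"tips {sorted(want)} not all present in tree")

    # ------------------------------------------------------------------ #
    # metrics
    # ------------------------------------------------------------------ #

    def depths(self) -> dict[Node, float]:
        """Root-to-node path lengths (root depth 0; missing lengths = 0)."""
        out: dict[Node, float] = {self.root: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            out[node] = out[node.parent] + (node.length or 0.0)
        return out

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n is not self.root)

    def set_ages_from_depths(self) -> None:
        """Annotate ``age`` = max tip depth − node depth (ultrametric trees)."""
        depths = self.depths()
        height = max(depths[t] for t in self.tips())
        for node, d in depths.items():
            node.age = height - d

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = self.depths()
        tip_depths = [depths[t] for t in self.tips()]
        return max(tip_depths) - min(tip_depths) <= tol

    def cophenetic(self) -> tuple[list[str], np.ndarray]:
        """Pairwise tip-to-tip path-length matrix (tips in postorder)."""
        names = self.tip_names()
        index = {n: i for i, n in enumerate(names)}
        size = len(names)
        dist = np.zeros((size, size))
        below: dict[Node, list[tuple[str, float]]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = [(node.name, 0.0)]
                continue
            parts = []
            for child in node.children:
                part = [(nm, d + (child.length or 0.0)) for nm, d in below[child]]
                parts.append(part)
            for a in range(len(parts)):
                for b in range(a + 1, len(parts)):
                    for nm1, d1 in parts[a]:
                        for nm2, d2 in parts[b]:
                            i, j = index[nm1], index[nm2]
                            dist[i, j] = dist[j, i] = d1 + d2
            below[node] = [pair for part in parts for pair in part]
        return names, dist

    def bipartitions(self) -> set[frozenset[str]]:
        """Unrooted bipartitions as canonical tip-name sets.

        Each internal edge splits the tips in two; the side not containing
        the alphabetically first tip is the canonical representative.
        Trivial splits (single tip / all tips) are excluded.
        """
        all_tips = set(self.tip_names())
        anchor = min(all_tips)
        out: set[frozenset[str]] = set()
        below: dict[Node, set[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = {node.name}
                continue
            clade = set().union(*(below[c] for c in node.children))
            below[node] = clade
            if node is self.root:
                continue
            side = clade if anchor not in clade else all_tips - clade
            if len(side) >= 2 and len(all_tips) - len(side) >= 2:
                out.add(frozenset(side))
        return out

    # ------------------------------------------------------------------ #
    # copy / IO
    # ------------------------------------------------------------------ #

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length)
            new.support = node.support
            new.host = node.host
            new.age = node.age
            new.lineage = node.lineage
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Tree(clone(self.root))

    def to_newick(self, lengths: bool = True, support: bool = True,
                  length_fmt: str = "{:.10g}") -> str:
        def render(node: Node) -> str:
            if node.is_leaf:
                label = node.name or ""
            else:
                inner = ",".join(render(c) for c in node.children)
                if support and node.support is not None:
                    label = f"({inner}){length_fmt.format(node.support)}"
                elif node.name and node is not self.root:
                    label = f"({inner}){node.name}"
                else:
                    label = f"({inner})"
            if lengths and node.length is not None and node is not self.root:
                label += ":" + length_fmt.format(node.length)
            return label

        return render(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True)

        def convert(dnode: dendropy.Node) -> Node:
            if dnode.is_leaf():
                name = dnode.taxon.label if dnode.taxon else dnode.label
                node = Node(name=name, length=dnode.edge.length)
            else:
                node = Node(length=dnode.edge.length)
                label = dnode.label
                if label is not None:
                    try:
                        node.support = float(label)
                    except ValueError:
                        node.name = label
                for dchild in dnode.child_nodes():
                    node.add_child(convert(dchild))
            return node

        return cls(convert(dtree.seed_node))

    @classmethod
    def from_scipy_linkage(cls, linkage: np.ndarray, labels: list[str]) -> "Tree":
        """Build an ultrametric tree from a scipy hierarchical linkage matrix.

        Cluster heights are merge distances; branch lengths are half-heights
        so cophenetic distances equal linkage distances.
        """
        n = len(labels)
        nodes: dict[int, Node] = {i: Node(name=labels[i]) for i in range(n)}
        heights: dict[int, float] = {i: 0.0 for i in range(n)}
        for k, (a, b, dist, _) in enumerate(linkage):
            a, b = int(a), int(b)
            parent = Node()
            h = dist / 2.0
            for child_id in (a, b):
                child = nodes.pop(child_id)
                child.length = h - heights[child_id]
                parent.add_child(child)
            nodes[n + k] = parent
            heights[n + k] = h
        (root,) = nodes.values()
        tree = cls(root)
        tree.set_ages_from_depths()
        return tree

    def relabel_internal(self, prefix: str = "n") -> None:
        """Assign deterministic names n1, n2, ... to unnamed internal nodes
        in preorder (root first)."""
        counter = 1
        for node in self.preorder():
            if not node.is_leaf and node.name is None:
                node.name = f"{prefix}{counter}"
                counter += 1

    def __len__(self) -> int:
        return len(self.tips())
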