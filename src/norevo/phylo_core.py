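"""Rooted phylogenetic trees: Newick I/O and traversal utilities.

The tree is stored as flat parallel arrays indexed by integer node ids
assigned in parse order. Branch lengths are in expected substitutions per
site (the unit of the reference tree the downstream likelihoods assume).
Multifurcations are allowed; the pruning code handles arbitrary out-degree.

Newick parsing is delegated to dendropy; serialisation is done locally so
that parse(write(t)) round-trips topology, labels and lengths exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy

__all__ = ["Tree", "parse_newick", "write_newick", "postorder", "NewickError"]

#: branch length substituted when the Newick string omits one
DEFAULT_BRANCH_LENGTH = 1.0


class NewickError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


@dataclass
class Tree:
    """A rooted tree over integer node ids ``0..n_nodes-1``.

    Attributes
    ----------
    parent : list[int]
        Parent id per node; ``-1`` for the root.
    children : list[list[int]]
        Child ids per node, in parse order.
    length : list[float]
        Branch length above each node (ignored for the root).
    label : list[str | None]
        Tip taxon names; ``None`` for internal nodes.
    root : int
        Id of the root node.
    """

    parent: list[int]
    children: list[list[int]]
    length: list[float]
    label: list[str | None]
    root: int
    _clades: dict[int, tuple[str, ...]] = field(default_factory=dict, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tips(self) -> list[int]:
        return [i for i, c in enumerate(self.children) if not c]

    @property
    def tip_labels(self) -> list[str]:
        return [self.label[i] for i in self.tips]

    def is_tip(self, node: int) -> bool:
        return not self.children[node]

    def clade_tips(self, node: int) -> tuple[str, ...]:
        """Sorted tuple of tip labels descending from ``node``.

        This is the parser-independent key used to identify nodes in
        reports and fixtures.
        """
        if node not in self._clades:
            if self.is_tip(node):
                self._clades[node] = (self.label[node],)
            else:
                tips: list[str] = []
                for c in self.children[node]:
                    tips.extend(self.clade_tips(c))
                self._clades[node] = tuple(sorted(tips))
        return self._clades[node]

    def node_by_clade(self, labels) -> int:
        """Return the node whose descendant tip set equals ``labels``.

        Raises ``KeyError`` if no node spans exactly that set.
        """
        want = tuple(sorted(labels))
        for v in range(self.n_nodes):
            if self.clade_tips(v) == want:
                return v
        raise KeyError(f"no node spans clade {want}")

    def depth(self, node: int) -> int:
        """Number of edges between ``node`` and the root."""
        d = 0
        while self.parent[node] >= 0:
            node = self.parent[node]
            d += 1
        return d

    def height(self) -> float:
        """Maximum root-to-tip path length."""
        dist = [0.0] * self.n_nodes
        best = 0.0
        for v in preorder(self):
            if self.parent[v] >= 0:
                dist[v] = dist[self.parent[v]] + self.length[v]
                if self.is_tip(v):
                    best = max(best, dist[v])
        return best

    def validate(self) -> None:
        n = self.n_nodes
        roots = [i for i in range(n) if self.parent[i] < 0]
        if roots != [self.root]:
            raise NewickError(f"expected exactly one root, found {roots}")
        labels = self.tip_labels
        if any(lab is None for lab in labels):
            raise NewickError("unlabelled tip")
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise NewickError(f"duplicate tip labels: {dup}")
        for v in range(n):
            if v != self.root and self.length[v] < 0:
                raise NewickError(f"negative branch length at node {v}")
            for c in self.children[v]:
                if self.parent[c] != v:
                    raise NewickError("inconsistent parent/child links")
        if len(postorder(self)) != n:
            raise NewickError("tree is not connected")


def parse_newick(text: str, default_length: float = DEFAULT_BRANCH_LENGTH) -> Tree:
    """Parse a rooted Newick string into a :class:`Tree`.

    Missing branch lengths default to ``default_length``; negative lengths
    and duplicate tip labels are rejected.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"Newick parse failure: {exc}") from exc

    parent: list[int] = []
    children: list[list[int]] = []
    length: list[float] = []
    label: list[str | None] = []
    ids: dict[int, int] = {}

    for dnode in dtree.preorder_node_iter():
        i = len(parent)
        ids[id(dnode)] = i
        p = -1 if dnode.parent_node is None else ids[id(dnode.parent_node)]
        parent.append(p)
        children.append([])
        if p >= 0:
            children[p].append(i)
        bl = dnode.edge.length
        length.append(default_length if (p >= 0 and bl is None) else (bl or 0.0))
        label.append(dnode.taxon.label if dnode.taxon is not None else None)

    tree = Tree(parent=parent, children=children, length=length, label=label, root=0)
    tree.validate()
    return tree


def _write_node(tree: Tree, node: int, out: io.StringIO) -> None:
    if tree.children[node]:
        out.write("(")
        for k, c in enumerate(tree.children[node]):
            if k:
                out.write(",")
            _write_node(tree, c, out)
        out.write(")")
    else:
        out.write(tree.label[node])
    if tree.parent[node] >= 0:
        out.write(f":{tree.length[node]:.10g}")


def write_newick(tree: Tree) -> str:
    """Serialise ``tree`` to Newick; round-trip stable under :func:`parse_newick`."""
    out = io.StringIO()
    _write_node(tree, tree.root, out)
    out.write(";")
    return out.getvalue()


def postorder(tree: Tree) -> list[int]:
    """Node ids with every child preceding its parent; root last."""
    order: list[int] = []
    stack = [(tree.root, False)]
    while stack:
        node, expanded = stack.pop()
        if expanded or tree.is_tip(node):
            order.append(node)
        else:
            stack.append((node, True))
            for c in reversed(tree.children[node]):
                stack.append((c, False))
    return order


def preorder(tree: Tree) -> list[int]:
    order: list[int] = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        order.append(node)
        for c in reversed(tree.children[node]):
            stack.append(c)
    return order
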