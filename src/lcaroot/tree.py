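"""Phylogenetic trees: rooted, unrooted (basal multifurcation) and star.

An unrooted tree is stored with an internal *basal* node of degree >= 3;
a rooted tree has a root of degree 2. A *star* tree has exactly one
internal node joining all tips — it encodes no resolved relationships and
is the intree used for topology-agnostic ancestral reconstruction.

Newick parsing is delegated to dendropy; writing is a small recursive
serializer (branch lengths as ``:float``, supports as internal-node
labels).
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import dendropy

__all__ = ["Node", "Tree", "star_tree", "TreeError"]


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label=None, length=None, children=None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None
        for child in children or []:
            self.add_child(child)

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, len={self.length}, deg={len(self.children)})"


class Tree:
    """A tree with non-negative branch lengths and a rootedness flag."""

    def __init__(self, root: Node, rooted: bool):
        self.root = root
        self.rooted = rooted
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, rooted: bool | None = None) -> "Tree":
        try:
            dt = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as err:  # normalize dendropy parse errors
            raise TreeError(f"could not parse Newick: {err}") from err

        def convert(dnode) -> Node:
            label = (
                dnode.taxon.label
                if dnode.taxon is not None
                else (dnode.label or None)
            )
            node = Node(label=label, length=dnode.edge.length)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        root = convert(dt.seed_node)
        if rooted is None:
            rooted = len(root.children) == 2
        return cls(root, rooted=rooted)

    def copy(self) -> "Tree":
        def dup(node: Node) -> Node:
            clone = Node(label=node.label, length=node.length)
            for child in node.children:
                clone.add_child(dup(child))
            return clone

        return Tree(dup(self.root), rooted=self.rooted)

    def _validate(self) -> None:
        for node in self.postorder():
            if node is not self.root and node.length is not None and node.length < 0:
                raise TreeError(f"negative branch length on edge above {node.label!r}")
        labels = self.tip_labels()
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate tip labels")
        if self.rooted and len(self.root.children) != 2 and len(labels) > 1:
            raise TreeError("a rooted tree must have a root of degree 2")
        if not self.rooted and len(labels) >= 3 and len(self.root.children) < 3:
            raise TreeError("an unrooted tree needs a basal node of degree >= 3")

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterable[Node]:
        def walk(node):
            for child in node.children:
                yield from walk(child)
            yield node

        return walk(self.root)

    def preorder(self) -> Iterable[Node]:
        def walk(node):
            yield node
            for child in node.children:
                yield from walk(child)

        return walk(self.root)

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def edges(self) -> list[Node]:
        """Every edge, identified by its child node, in postorder."""
        return [n for n in self.postorder() if n is not self.root]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    @property
    def is_star(self) -> bool:
        return (not self.rooted) and all(c.is_tip for c in self.root.children)

    def is_binary(self) -> bool:
        for node in self.postorder():
            if node.is_tip:
                continue
            want = 2 if (node is self.root and self.rooted) else (
                3 if node is self.root else 2
            )
            if node is self.root and not self.rooted:
                if len(node.children) != 3:
                    return False
            elif len(node.children) != want:
                return False
        return True

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.edges())

    def find_tip(self, label: str) -> Node:
        for node in self.postorder():
            if node.is_tip and node.label == label:
                return node
        raise TreeError(f"tip {label!r} not found")

    def clade_labels(self, node: Node) -> frozenset[str]:
        out = []

        def walk(n):
            if n.is_tip:
                out.append(n.label)
            for c in n.children:
                walk(c)

        walk(node)
        return frozenset(out)

    # -- serialization -----------------------------------------------------

    def to_newick(self, lengths: bool = True, internal_labels: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_tip:
                s = node.label or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if internal_labels and node.label is not None:
                    s += str(node.label)
            if lengths and node is not self.root and node.length is not None:
                s += f":{node.length:.10g}"
            return s

        return fmt(self.root) + ";"

    def canonical_newick(self) -> str:
        """Topology-only Newick, unique per (un)rooted topology.

        Unrooted trees are re-hung at the neighbor of the lexicographically
        smallest tip; children are sorted recursively, so two trees share a
        canonical string iff they share a topology.
        """
        if self.rooted:
            tree = self
        else:
            anchor = min(self.tip_labels())
            tree = self._rebuilt_from(self.find_tip(anchor).parent, rooted=False)

        def key(node: Node) -> str:
            if node.is_tip:
                return node.label
            return "(" + ",".join(sorted(key(c) for c in node.children)) + ")"

        return key(tree.root) + ";"

    # -- bipartitions --------------------------------------------------------

    def bipartitions(self) -> frozenset[frozenset[str]]:
        """Non-trivial bipartitions of the underlying unrooted topology.

        Each is represented by the side *not* containing the reference tip
        (the lexicographically smallest label), so representation is unique.
        """
        tree = self.unroot() if self.rooted else self
        all_labels = frozenset(tree.tip_labels())
        ref = min(all_labels)
        out = set()
        for node in tree.postorder():
            if node is tree.root or node.is_tip:
                continue
            clade = tree.clade_labels(node)
            side = clade if ref not in clade else all_labels - clade
            if 2 <= len(side) <= len(all_labels) - 2:
                out.add(side)
        return frozenset(out)

    # -- rerooting -----------------------------------------------------------

    def _rebuilt_from(self, start: Node, rooted: bool) -> "Tree":
        """Re-hang the (copied) tree from ``start`` as the new basal node."""
        return Tree(_rehang(start, None, None), rooted=rooted)

    def unroot(self) -> "Tree":
        """Collapse a degree-2 root, merging its two incident edges."""
        if not self.rooted:
            return self.copy()
        if self.n_tips < 3:
            raise TreeError("cannot unroot a tree with fewer than 3 tips")
        tree = self.copy()
        a, b = tree.root.children
        keep, other = (a, b) if not a.is_tip else (b, a)
        if keep.is_tip:
            raise TreeError("cannot unroot: both root children are tips")
        merged = (a.length or 0.0) + (b.length or 0.0)
        keep.parent = None
        other.parent = None
        other.length = merged
        keep.add_child(other)
        keep.length = None
        return Tree(keep, rooted=False)

    def root_on_edge(self, child: Node, fraction: float = 0.5) -> "Tree":
        """Return a rooted copy with the root splitting the edge above ``child``.

        ``fraction`` is the share of the edge length assigned to the child
        side; the default places the root at the edge midpoint. ``child``
        must be a node of this tree.
        """
        if self.rooted:
            raise TreeError("root_on_edge expects an unrooted tree; unroot() first")
        edges = self.edges()
        try:
            idx = next(i for i, e in enumerate(edges) if e is child)
        except StopIteration:
            raise TreeError("node is not an edge of this tree") from None
        tree = self.copy()
        child = tree.edges()[idx]
        parent = child.parent
        length = child.length
        parent.children = [c for c in parent.children if c is not child]
        child.parent = None
        child.length = None if length is None else length * fraction
        parent_side = _rehang(
            parent, None, None if length is None else length * (1.0 - fraction)
        )
        root = Node(children=[child, parent_side])
        return Tree(root, rooted=True)

    def without_tip(self, label: str) -> "Tree":
        """Remove a tip and suppress the resulting degree-2 node.

        On a rooted tree whose root subtends the removed tip, the other
        child becomes the new root (e.g. stripping the outgroup from an
        outgroup-rooted tree leaves the rooted ingroup tree).
        """
        if self.n_tips < 3:
            raise TreeError("cannot remove a tip from a 2-tip tree")
        tree = self.copy()
        tip = tree.find_tip(label)
        parent = tip.parent
        parent.children = [c for c in parent.children if c is not tip]
        if len(parent.children) == 1:
            lone = parent.children[0]
            if parent is tree.root:
                lone.parent = None
                lone.length = None
                return Tree(lone, rooted=self.rooted and len(lone.children) == 2)
            # splice out the degree-2 node
            lone.length = (lone.length or 0.0) + (parent.length or 0.0)
            grand = parent.parent
            grand.children = [lone if c is parent else c for c in grand.children]
            lone.parent = grand
        if not self.rooted and len(tree.root.children) == 2:
            # collapse the now degree-2 basal node of an unrooted tree
            return Tree(tree.root, rooted=True).unroot()
        return Tree(tree.root, rooted=self.rooted)

    def clades(self) -> set[frozenset[str]]:
        """Non-trivial rooted clades (tip-label sets of internal nodes)."""
        out = set()
        n = self.n_tips
        for node in self.postorder():
            if node.is_tip or node is self.root:
                continue
            clade = self.clade_labels(node)
            if 2 <= len(clade) <= n - 1:
                out.add(clade)
        return out

    def root_with_taxon(self, outgroup_label: str) -> "Tree":
        """Root on the outgroup's pendant edge at its midpoint.

        The ingroup topology is unchanged; for reversible models this is a
        display convention and does not affect the likelihood.
        """
        tree = (self.unroot() if self.rooted else self).copy()
        tip = tree.find_tip(outgroup_label)
        return tree.root_on_edge(tip, fraction=0.5)


def _rehang(node: Node, came_from: Node | None, length: float | None) -> Node:
    """Rebuild the tree hanging from ``node``, arriving from ``came_from``.

    Treats parent links as undirected edges, so the structure can be
    re-rooted anywhere. Produces fresh nodes; internal labels are dropped.
    """
    clone = Node(label=node.label if node.is_tip else None, length=length)
    neighbors: list[tuple[Node, float | None]] = [
        (c, c.length) for c in node.children
    ]
    if node.parent is not None:
        neighbors.append((node.parent, node.length))
    for nbr, edge_len in neighbors:
        if came_from is not None and nbr is came_from:
            continue
        clone.add_child(_rehang(nbr, node, edge_len))
    return clone


def star_tree(taxa: Sequence[str], branch_length: float = 0.1) -> Tree:
    """Star topology: one internal node, one pendant edge per taxon."""
    taxa = list(taxa)
    if len(taxa) < 3:
        raise TreeError(f"a star tree needs at least 3 taxa, got {len(taxa)}")
    root = Node()
    for label in taxa:
        root.add_child(Node(label=label, length=branch_length))
    return Tree(root, rooted=False)
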