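"""Light-weight rooted/unrooted tree container used throughout the package.

Parsimony search and rooting need cheap topological surgery (edge
subdivision, subtree prune/regraft, re-rooting), so trees are held in a
minimal node structure.  Newick parsing and serialization are delegated to
:mod:`dendropy`; :class:`PhyloTree` converts to and from ``dendropy.Tree``
at the boundary.

An *unrooted* tree is stored with a basal polytomy at an arbitrary hub
node (``rooted=False``); this is purely a traversal convenience and never
interpreted as a root.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, Optional

import dendropy

__all__ = ["Node", "PhyloTree"]


class Node:
    """A tree node. ``label`` is the taxon name for leaves (None for most
    internal nodes; internal labels are preserved when present)."""

    __slots__ = ("label", "children", "parent")

    def __init__(self, label: Optional[str] = None):
        self.label = label
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.label or '*'} deg={len(self.children)}>"


class PhyloTree:
    """Rooted or unrooted labeled tree with unique leaf labels."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        self._validate()

    # ------------------------------------------------------------------
    # construction / conversion
    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, source: str, rooted: Optional[bool] = None) -> "PhyloTree":
        """Parse a Newick string or file path.

        Rootedness is taken from the ``[&R]``/``[&U]`` hint when present,
        from ``rooted`` when given, else inferred from the basal degree
        (bifurcation = rooted).
        """
        src = source.strip()
        if "(" not in src:  # looks like a path
            with open(source) as fh:
                src = fh.read()
        try:
            dt = dendropy.Tree.get(data=src, schema="newick",
                                   suppress_internal_node_taxa=False)
        except dendropy.utility.error.DataParseError as e:
            raise ValueError(f"invalid newick: {e}") from e
        tree = cls.from_dendropy(dt, rooted=rooted)
        return tree

    @classmethod
    def from_dendropy(cls, dt: dendropy.Tree, rooted: Optional[bool] = None) -> "PhyloTree":
        def build(dnode) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            n = Node(label)
            for dchild in dnode.child_nodes():
                n.add_child(build(dchild))
            return n

        root = build(dt.seed_node)
        if rooted is None:
            if dt.is_rooted is not None and dt.is_rooted:
                rooted = True
            elif dt.is_rooted is not None and not dt.is_rooted and len(root.children) > 2:
                rooted = False
            else:
                rooted = len(root.children) == 2
        return cls(root, rooted=rooted)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dt = dendropy.Tree(taxon_namespace=taxa)
        dt.is_rooted = self.rooted

        def build(node: Node, dnode):
            if node.is_leaf:
                dnode.taxon = taxa.require_taxon(label=node.label)
            elif node.label:
                dnode.label = node.label
            for child in node.children:
                dchild = dnode.new_child()
                build(child, dchild)

        build(self.root, dt.seed_node)
        return dt

    def to_newick(self, path: Optional[str] = None) -> str:
        s = self.to_dendropy().as_string(
            schema="newick", suppress_rooting=False).strip() + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def copy(self) -> "PhyloTree":
        def rec(node: Node) -> Node:
            n = Node(node.label)
            for c in node.children:
                n.add_child(rec(c))
            return n

        return PhyloTree(rec(self.root), rooted=self.rooted)

    # ------------------------------------------------------------------
    # traversal
    # ------------------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def edges(self) -> list[Node]:
        """Deterministic post-order enumeration of edges.

        Each edge is identified by its child node (every non-root node has
        exactly one parent edge).
        """
        return [n for n in self.postorder() if n.parent is not None]

    def n_leaves(self) -> int:
        return sum(1 for n in self.postorder() if n.is_leaf)

    # ------------------------------------------------------------------
    # queries
    # ------------------------------------------------------------------
    def is_binary(self) -> bool:
        for n in self.postorder():
            if n.is_leaf:
                continue
            want = 2 if (self.rooted or n.parent is not None) else 3
            if len(n.children) != want:
                return False
        return True

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each canonicalized to the side *not*
        containing the lexicographically smallest leaf label."""
        all_leaves = frozenset(self.leaf_labels())
        ref = min(all_leaves)
        splits = set()
        below: dict[int, frozenset] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[id(n)] = frozenset([n.label])
            else:
                below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))
            if n.parent is None:
                continue
            side = below[id(n)]
            if ref in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(side)
        return splits

    # ------------------------------------------------------------------
    # surgery
    # ------------------------------------------------------------------
    def suppress_unifurcations(self) -> None:
        """Collapse degree-2 internal nodes (including a single-child root,
        which is replaced by its child)."""
        changed = True
        while changed:
            changed = False
            for n in list(self.postorder()):
                if n.is_leaf:
                    continue
                if n.parent is not None and len(n.children) == 1:
                    child = n.children[0]
                    parent = n.parent
                    idx = parent.children.index(n)
                    parent.children[idx] = child
                    child.parent = parent
                    changed = True
                elif n.parent is None and len(n.children) == 1:
                    self.root = n.children[0]
                    self.root.parent = None
                    changed = True

    def prune_to(self, keep: Iterable[str]) -> "PhyloTree":
        """Induced subtree on ``keep`` (labels), degree-2 nodes suppressed.

        For a rooted tree the root survives only if it still separates two
        of the kept lineages; otherwise it is collapsed down onto the
        first surviving ancestor (the induced subtree remains rooted).
        """
        keep = set(keep)
        unknown = keep - set(self.leaf_labels())
        if unknown:
            raise ValueError(f"unknown taxa in keep set: {sorted(unknown)}")
        if len(keep) < 2:
            raise ValueError("need at least 2 taxa to prune to")
        t = self.copy()
        # drop leaves not kept, then clean up
        changed = True
        while changed:
            changed = False
            for n in list(t.postorder()):
                if n.is_leaf and n.label not in keep and n.parent is not None:
                    n.parent.remove_child(n)
                    changed = True
                elif not n.children and n.label is None and n.parent is not None:
                    n.parent.remove_child(n)
                    changed = True
        t.suppress_unifurcations()
        return t

    def root_on_edge(self, child: Node) -> "PhyloTree":
        """Return a rooted copy with a new root subdividing the edge above
        ``child`` (a node of *this* tree)."""
        # map nodes of self to nodes of the copy
        t = self.copy()
        pairs = list(zip(self.postorder(), t.postorder()))
        mapping = {id(a): b for a, b in pairs}
        c = mapping[id(child)]
        if c.parent is None:
            raise ValueError("cannot root on the hub node itself")
        u = c.parent
        u.remove_child(c)
        new_root = Node()
        new_root.add_child(c)
        # reverse the path from u up to the old hub
        prev = new_root
        node = u
        while node is not None:
            parent = node.parent
            if parent is not None:
                parent.remove_child(node)
            prev.add_child(node)
            prev = node
            node = parent
        t.root = new_root
        t.rooted = True
        t.suppress_unifurcations()
        return t

    def unroot(self) -> "PhyloTree":
        """Return an unrooted copy (root of degree 2 collapsed into a
        basal trifurcation)."""
        t = self.copy()
        t.rooted = False
        if len(t.root.children) == 2:
            a, b = t.root.children
            donor, keeper = (a, b) if not a.is_leaf else (b, a)
            if donor.is_leaf:
                return t  # two-leaf tree, nothing to collapse
            t.root.remove_child(donor)
            for c in list(donor.children):
                donor.remove_child(c)
                t.root.add_child(c)
        return t

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        labels = [n.label for n in self.postorder() if n.is_leaf]
        if any(l is None for l in labels):
            raise ValueError("all leaves must be labeled")
        dupes = [l for l, g in itertools.groupby(sorted(labels)) if len(list(g)) > 1]
        if dupes:
            raise ValueError(f"duplicate leaf labels: {dupes}")

    def __repr__(self):  # pragma: no cover
        kind = "rooted" if self.rooted else "unrooted"
        return f"<PhyloTree {kind}, {self.n_leaves()} leaves>"
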