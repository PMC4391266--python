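"""Rooted/unrooted tree container shared by every inference method.

The container is a plain rooted node tree.  Unrooted semantics (as used
by neighbor joining, parsimony search and bipartition comparison) are
obtained by ignoring the root: a bipartition is recorded for every edge
whose removal splits the leaf set non-trivially.  Newick text is parsed
with dendropy and re-serialised by the container itself, with numeric
internal-node labels carried as support strings.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

import dendropy


class Node:
    __slots__ = ("name", "length", "label", "children", "parent")

    def __init__(
        self,
        name: str | None = None,
        length: float | None = None,
        label: str | None = None,
    ) -> None:
        self.name = name
        self.length = length
        self.label = label  # support annotation on the edge above this node
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> "Node":
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Node {self.name or '*'} len={self.length}>"


class Tree:
    """A tree with branch lengths and optional per-edge support labels."""

    def __init__(self, root: Node) -> None:
        self.root = root

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )

        def convert(dn) -> Node:
            name = dn.taxon.label if dn.taxon is not None else None
            label = dn.label if dn.label and not dn.is_leaf() else None
            node = Node(name=name, length=dn.edge.length, label=label)
            for c in dn.child_nodes():
                node.add(convert(c))
            return node

        return cls(convert(dt.seed_node))

    def to_newick(self, include_support: bool = True, precision: int = 10) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if include_support and node.label is not None:
                    s += str(node.label)
            if node.length is not None:
                s += f":{node.length:.{precision}g}"
            return s

        return fmt(self.root) + ";"

    def copy(self) -> "Tree":
        def cp(n: Node) -> Node:
            m = Node(n.name, n.length, n.label)
            for c in n.children:
                m.add(cp(c))
            return m

        return Tree(cp(self.root))

    # -- traversal -----------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def __len__(self) -> int:
        return len(self.leaves())

    # -- unrooted semantics --------------------------------------------

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits of the unrooted topology.

        Each split is canonicalised as the side *not* containing the
        lexicographically smallest leaf, so two trees over the same leaf
        set are directly comparable.
        """
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        below: dict[int, frozenset[str]] = {}
        splits: set[frozenset[str]] = set()
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                s = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = s
                if node is self.root:
                    continue
                if 1 < len(s) < len(all_leaves) - 1:
                    side = all_leaves - s if ref in s else s
                    splits.add(side)
        return splits

    def edge_bipartitions(self) -> list[tuple[Node, frozenset[str]]]:
        """(node, canonical split) for every internal edge, postorder."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        below: dict[int, frozenset[str]] = {}
        out: list[tuple[Node, frozenset[str]]] = []
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                s = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = s
                if node is not self.root and 1 < len(s) < len(all_leaves) - 1:
                    side = all_leaves - s if ref in s else s
                    out.append((node, side))
        return out

    # -- re-rooting -----------------------------------------------------

    def rooted_at_edge(self, leaf_name: str | None = None) -> "Tree":
        """Return a copy rooted on the edge leading to the named leaf.

        The result has an unnamed root with two children: the leaf and
        the rest of the tree (the leaf's edge length is split half/half,
        which leaves the unrooted path metric unchanged).  When the
        unrooted topology is binary every other internal node has exactly
        two children — the canonical form the parsimony and likelihood
        machinery expects.
        """
        t = self.copy()
        t._suppress_unifurcations()
        if leaf_name is None:
            leaf_name = min(t.leaf_names())
        x = next(n for n in t.leaves() if n.name == leaf_name)
        # reverse all parent links on the path from x up to the old root
        path = [x]
        while path[-1].parent is not None:
            path.append(path[-1].parent)
        edge_len = [path[i].length for i in range(len(path) - 1)]
        for i in range(len(path) - 1):
            path[i + 1].children.remove(path[i])
        for i in range(len(path) - 1):
            path[i].children.append(path[i + 1])
            path[i + 1].parent = path[i]
            path[i + 1].length = edge_len[i]
            path[i + 1].label = None if i + 1 == len(path) - 1 else path[i + 1].label
        x.parent = None
        if not x.children:  # x was already the root (degenerate input)
            return t
        rest = x.children[0]
        x.children = []
        rest.parent = None
        half = None if rest.length is None else rest.length / 2.0
        x.length = half
        rest.length = half
        root = Node()
        root.add(x)
        root.add(rest)
        out = Tree(root)
        out._suppress_unifurcations()
        return out

    def _suppress_unifurcations(self) -> None:
        """Collapse internal nodes with a single child (merging lengths)."""
        changed = True
        while changed:
            changed = False
            for node in list(self.postorder()):
                if node.is_leaf or len(node.children) != 1:
                    continue
                child = node.children[0]
                if node is self.root:
                    if child.is_leaf:
                        continue  # two-node tree; leave as is
                    child.parent = None
                    child.length = None
                    self.root = child
                else:
                    parent = node.parent
                    length = (node.length or 0.0) + (child.length or 0.0)
                    node.detach()
                    child.parent = None
                    child.length = length
                    parent.add(child)
                changed = True
                break

    # -- editing --------------------------------------------------------

    def clamp_negative_lengths(self) -> int:
        n = 0
        for node in self.postorder():
            if node.length is not None and node.length < 0:
                node.length = 0.0
                n += 1
        return n


def rf_distance(tree1: Tree, tree2: Tree) -> int:
    """Robinson–Foulds distance: bipartitions present in exactly one tree."""
    l1, l2 = set(tree1.leaf_names()), set(tree2.leaf_names())
    if l1 != l2:
        raise ValueError(f"leaf set mismatch: {sorted(l1 ^ l2)}")
    b1, b2 = tree1.bipartitions(), tree2.bipartitions()
    return len(b1 ^ b2)


def has_bipartition(tree: Tree, group: Iterable[str]) -> bool:
    """Does an edge of ``tree`` split ``group`` exactly off the rest?"""
    all_leaves = frozenset(tree.leaf_names())
    g = frozenset(group)
    ref = min(all_leaves)
    side = all_leaves - g if ref in g else g
    return side in tree.bipartitions()
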