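"""Fitch parsimony scoring and NNI hill-climbing search.

Character states are encoded as bitmasks so a column's Fitch step is a
vectorised AND/OR over all columns at once; ``?`` (missing), ``-`` and
``X`` are fully ambiguous.  The score of a tree is invariant to rooting,
so scoring internally uses the canonical leaf-edge-rooted binary form.

The search is steepest-descent nearest-neighbour interchange from a
starting tree (typically neighbor joining), with seeded random-addition
restarts; the reported tree is the best local optimum found.
"""

from __future__ import annotations

import logging

import numpy as np

from .tree import Node, Tree

log = logging.getLogger("guildphylo")

PROTEIN_ORDER = "ACDEFGHIKLMNPQRSTVWY"


def encode_states(taxa: list[str], rows: list[str], alphabet: str) -> dict[str, np.ndarray]:
    """Per-taxon bitmask arrays (width,) for Fitch operations."""
    if alphabet == "protein":
        full = np.uint32((1 << 20) - 1)
        lut = {c: np.uint32(1 << i) for i, c in enumerate(PROTEIN_ORDER)}
    elif alphabet == "binary":
        full = np.uint32(3)
        lut = {"0": np.uint32(1), "1": np.uint32(2)}
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    for c in ("?", "-", "X"):
        lut[c] = full
    out: dict[str, np.ndarray] = {}
    for taxon, row in zip(taxa, rows):
        out[taxon] = np.array([lut[c] for c in row], dtype=np.uint32)
    return out


def encode_matrix(matrix) -> dict[str, np.ndarray]:
    return encode_states(list(matrix.taxa), list(matrix.rows), matrix.alphabet)


def _binary_postorder(tree: Tree) -> list[Node]:
    for node in tree.postorder():
        if not node.is_leaf and len(node.children) != 2:
            raise ValueError("parsimony requires a binary (edge-rooted) tree")
    return list(tree.postorder())


def fitch_score(
    tree: Tree, leaf_masks: dict[str, np.ndarray], weights: np.ndarray | None = None
) -> float:
    """Minimum total state changes over the tree, summed over columns.

    ``weights`` gives a per-column multiplicity (bootstrap resampling);
    unweighted scoring over integer data returns an integer value.
    """
    rooted = tree.rooted_at_edge()
    nodes = _binary_postorder(rooted)
    width = len(next(iter(leaf_masks.values())))
    if weights is None:
        weights = np.ones(width)
    sets: dict[int, np.ndarray] = {}
    total = 0.0
    for node in nodes:
        if node.is_leaf:
            sets[id(node)] = leaf_masks[node.name]
        else:
            a, b = (sets[id(c)] for c in node.children)
            inter = a & b
            empty = inter == 0
            total += float(weights[empty].sum())
            sets[id(node)] = np.where(empty, a | b, inter)
    return total if weights.dtype.kind == "f" else int(total)


def parsimony_score(tree: Tree, matrix) -> int:
    """Fitch parsimony score of a character matrix on a tree."""
    masks = encode_matrix(matrix)
    return int(fitch_score(tree, masks, weights=np.ones(matrix.width, dtype=np.int64)))


# ---------------------------------------------------------------------------
# NNI search
# ---------------------------------------------------------------------------

def _internal_edges(rooted: Tree) -> list[Node]:
    """Nodes v such that (parent(v), v) is an internal edge of the unrooted tree."""
    out = []
    for node in rooted.postorder():
        if (
            not node.is_leaf
            and node.parent is not None
            and node.parent is not rooted.root
            and not node.parent.is_leaf
        ):
            out.append(node)
    return out


def _nni_swap(v: Node, child_idx: int) -> None:
    """Swap v.children[child_idx] with v's sibling (in place, reversible)."""
    u = v.parent
    sib_idx = 1 - u.children.index(v)
    c = u.children[sib_idx]
    g = v.children[child_idx]
    u.children[sib_idx] = g
    g.parent = u
    v.children[child_idx] = c
    c.parent = v


def random_topology(taxa: list[str], rng: np.random.Generator) -> Tree:
    """Random sequential-addition unrooted binary topology (unit lengths)."""
    order = list(taxa)
    rng.shuffle(order)
    if len(order) < 3:
        root = Node()
        for t in order:
            root.add(Node(name=t, length=1.0))
        return Tree(root)
    root = Node()
    for t in order[:3]:
        root.add(Node(name=t, length=1.0))
    tree = Tree(root)
    for t in order[3:]:
        edges = [n for n in tree.postorder() if n.parent is not None]
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        pos = parent.children.index(target)
        mid = Node(length=1.0)
        leaf = Node(name=t, length=1.0)
        parent.children[pos] = mid
        mid.parent = parent
        mid.add(target)
        mid.add(leaf)
    return tree


def _nni_descent(
    rooted: Tree, leaf_masks: dict[str, np.ndarray], weights: np.ndarray | None
) -> tuple[Tree, float]:
    score = fitch_score(rooted, leaf_masks, weights)
    improved = True
    while improved:
        improved = False
        best_move = None
        best_score = score
        for v in _internal_edges(rooted):
            for ci in (0, 1):
                _nni_swap(v, ci)
                s = fitch_score(rooted, leaf_masks, weights)
                _nni_swap(v, ci)
                if s < best_score:
                    best_score = s
                    best_move = (v, ci)
        if best_move is not None:
            _nni_swap(*best_move)
            score = best_score
            improved = True
    return rooted, score


def parsimony_search(
    matrix,
    start: Tree | None = None,
    seed: int = 0,
    restarts: int = 3,
    leaf_masks: dict[str, np.ndarray] | None = None,
    weights: np.ndarray | None = None,
) -> tuple[Tree, float]:
    """Steepest-descent NNI from a start tree plus random-addition restarts.

    Returns ``(tree, score)`` where the tree carries per-edge lengths
    equal to reconstructed changes per character.
    """
    if leaf_masks is None:
        leaf_masks = encode_matrix(matrix)
    taxa = sorted(leaf_masks)
    if start is None:
        from .nj import nj_tree

        start = nj_tree(matrix)
    rng = np.random.default_rng(seed)
    best_tree, best_score = _nni_descent(start.rooted_at_edge(), leaf_masks, weights)
    for _ in range(max(restarts, 0)):
        cand = random_topology(taxa, rng).rooted_at_edge()
        tree, score = _nni_descent(cand, leaf_masks, weights)
        if score < best_score:
            best_tree, best_score = tree, score
    total_w = (
        float(len(next(iter(leaf_masks.values()))))
        if weights is None
        else float(np.sum(weights))
    )
    _assign_change_lengths(best_tree, leaf_masks, weights, total_w)
    return best_tree, best_score


def _assign_change_lengths(
    rooted: Tree,
    leaf_masks: dict[str, np.ndarray],
    weights: np.ndarray | None,
    total_w: float,
) -> None:
    """Set branch lengths to changes-per-character of one MP reconstruction."""
    width = len(next(iter(leaf_masks.values())))
    w = np.ones(width) if weights is None else weights
    sets: dict[int, np.ndarray] = {}
    for node in rooted.postorder():
        if node.is_leaf:
            sets[id(node)] = leaf_masks[node.name]
        else:
            a, b = (sets[id(c)] for c in node.children)
            inter = a & b
            sets[id(node)] = np.where(inter == 0, a | b, inter)

    def lowest_bit(x: np.ndarray) -> np.ndarray:
        return x & (~x + np.uint32(1))

    state: dict[int, np.ndarray] = {id(rooted.root): lowest_bit(sets[id(rooted.root)])}
    for node in rooted.preorder():
        if node is rooted.root:
            continue
        parent_state = state[id(node.parent)]
        own = sets[id(node)]
        keep = (own & parent_state) != 0
        chosen = np.where(keep, parent_state, lowest_bit(own))
        state[id(node)] = chosen.astype(np.uint32)
        changes = float(w[~keep].sum())
        node.length = changes / total_w if total_w > 0 else 0.0
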