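"""Saitou–Nei neighbor joining with deterministic tie handling.

The agglomeration minimises the standard Q criterion
``Q(i,j) = (n-2) d(i,j) - R_i - R_j``; ties are broken by the
lexicographic pair of cluster labels (a cluster is labelled by its
smallest member taxon), so the output is reproducible across runs and
node orderings.  For an additive input matrix the path metric of the
returned tree equals the input exactly (up to float round-off).
"""

from __future__ import annotations

import logging

import numpy as np

from .tree import Node, Tree

log = logging.getLogger("guildphylo")


def neighbor_joining(taxa: list[str], D: np.ndarray) -> Tree:
    """Build an unrooted NJ tree (root is a trifurcation for n >= 3)."""
    D = np.asarray(D, dtype=float)
    n = len(taxa)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    if D.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")

    nodes: list[Node] = [Node(name=t) for t in taxa]
    labels: list[str] = list(taxa)  # smallest member taxon per cluster
    if n == 2:
        root = Node()
        a, b = nodes
        a.length = float(D[0, 1])
        b.length = 0.0
        root.add(a)
        root.add(b)
        return Tree(root)

    active = list(range(n))
    Dw = D.copy()

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = Dw[np.ix_(idx, idx)]
        R = sub.sum(axis=1)
        Q = (m - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((labels[idx[a]], labels[idx[b]]))), (a, b))
            for a, b in ties
            if a < b
        )[1]
        ai, bi = best
        i, j = idx[ai], idx[bi]
        dij = sub[ai, bi]
        li = 0.5 * dij + (R[ai] - R[bi]) / (2 * (m - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            log.warning("negative NJ branch length clamped to 0")
        parent = Node()
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent.add(nodes[i])
        parent.add(nodes[j])
        # distances from the new node to every other active cluster
        new_d = 0.5 * (Dw[i, idx] + Dw[j, idx] - dij)
        k = len(nodes)
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        Dw = np.pad(Dw, ((0, 1), (0, 1)))
        for pos, other in enumerate(idx):
            Dw[k, other] = Dw[other, k] = new_d[pos]
        Dw[k, k] = 0.0
        active = [a for a in active if a not in (i, j)] + [k]

    # join the final three clusters at an unresolved root
    i, j, k = active
    li = 0.5 * (Dw[i, j] + Dw[i, k] - Dw[j, k])
    lj = 0.5 * (Dw[i, j] + Dw[j, k] - Dw[i, k])
    lk = 0.5 * (Dw[i, k] + Dw[j, k] - Dw[i, j])
    if min(li, lj, lk) < 0:
        log.warning("negative NJ branch length clamped to 0")
    root = Node()
    for node, length in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.length = max(length, 0.0)
        root.add(node)
    return Tree(root)


def nj_tree(data, model=None) -> Tree:
    """Convenience: distances + NJ in one call."""
    from .distances import pairwise_distances

    taxa, D = pairwise_distances(data, model)
    return neighbor_joining(taxa, D)


def path_metric(tree: Tree) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length matrix of a tree (for additivity checks)."""
    names = sorted(tree.leaf_names())
    index = {n: i for i, n in enumerate(names)}
    n = len(names)
    D = np.zeros((n, n))
    below: dict[int, list[tuple[int, float]]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = [(index[node.name], 0.0)]
        else:
            groups = []
            for c in node.children:
                grp = [(i, d + (c.length or 0.0)) for i, d in below[id(c)]]
                groups.append(grp)
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for i, di in groups[gi]:
                        for j, dj in groups[gj]:
                            D[i, j] = D[j, i] = di + dj
            below[id(node)] = [x for grp in groups for x in grp]
    return names, D
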