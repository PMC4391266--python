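"""Independent brute-force oracles used to validate the implementations.

Everything here is written from the mathematical definition, with no
shared code paths with the package: quadratic-space dynamic programming
for alignments, exhaustive enumeration for parsimony and likelihood, a
minimal dense Markov-clustering loop, and closed forms where they
exist.  The oracles are deliberately slow and simple.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# alignment oracles (gap of length k costs open + (k-1) * extend)
# ---------------------------------------------------------------------------

def sw_affine_oracle(a: str, b: str, score, gap_open: float, gap_extend: float) -> float:
    """Smith-Waterman affine-gap optimum by plain dynamic programming."""
    la, lb = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0)
            M[i][j] = diag + score(a[i - 1], b[j - 1])
            best = max(best, M[i][j])
    return best


def global_affine_oracle(a: str, b: str, score, gap_open: float, gap_extend: float) -> float:
    """Needleman-Wunsch affine-gap optimum (end gaps penalised)."""
    la, lb = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, lb + 1):
        Y[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + score(
                a[i - 1], b[j - 1]
            )
    return max(M[la][lb], X[la][lb], Y[la][lb])


# ---------------------------------------------------------------------------
# parsimony oracle: exhaustive internal labelling
# ---------------------------------------------------------------------------

def _topology_nodes(tree):
    """(leaves, internals, edges) of a tree rooted anywhere."""
    leaves, internals, edges = [], [], []
    for node in tree.postorder():
        (leaves if node.is_leaf else internals).append(node)
        if node.parent is not None:
            edges.append((node.parent, node))
    return leaves, internals, edges


def parsimony_exhaustive(tree, states: dict[str, int], n_states: int) -> int:
    """Minimum changes over all assignments of states to internal nodes."""
    leaves, internals, edges = _topology_nodes(tree)
    best = math.inf
    for assign in itertools.product(range(n_states), repeat=len(internals)):
        label = {id(n): s for n, s in zip(internals, assign)}
        for leaf in leaves:
            label[id(leaf)] = states[leaf.name]
        changes = sum(1 for u, v in edges if label[id(u)] != label[id(v)])
        best = min(best, changes)
    return int(best)


# ---------------------------------------------------------------------------
# two-state likelihood oracle: exhaustive state enumeration
# ---------------------------------------------------------------------------

def mk2_transition(t: float) -> np.ndarray:
    """Closed-form 2-state symmetric transition matrix (rate normalised
    to one expected substitution per unit time: off-diagonal rate 1)."""
    same = 0.5 + 0.5 * math.exp(-2.0 * t)
    return np.array([[same, 1 - same], [1 - same, same]])


def likelihood_enumeration(tree, columns: dict[str, str]) -> float:
    """Log-likelihood of a binary matrix by summing over every internal
    state assignment (stationary frequencies 1/2 at the root)."""
    rooted = tree.rooted_at_edge()
    leaves, internals, edges = _topology_nodes(rooted)
    width = len(next(iter(columns.values())))
    total = 0.0
    for col in range(width):
        site = 0.0
        for assign in itertools.product((0, 1), repeat=len(internals)):
            label = {id(n): s for n, s in zip(internals, assign)}
            ok = True
            for leaf in leaves:
                c = columns[leaf.name][col]
                if c == "?":
                    label[id(leaf)] = None
                else:
                    label[id(leaf)] = int(c)
            prob = 0.5  # root state prior; root is in `internals`
            for u, v in edges:
                P = mk2_transition(v.length or 0.0)
                su, sv = label[id(u)], label[id(v)]
                if sv is None:  # ambiguous leaf: sum over its states
                    prob *= sum(P[su, s] for s in (0, 1))
                else:
                    prob *= P[su, sv]
            if ok:
                site += prob
        total += math.log(site)
    return total


# ---------------------------------------------------------------------------
# dense MCL oracle
# ---------------------------------------------------------------------------

def mcl_dense_oracle(
    nodes: list, weighted_edges: list[tuple], inflation: float = 2.0
) -> list[frozenset]:
    """Minimal dense Markov clustering run to (near-)convergence."""
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v, w in weighted_edges:
        M[index[u], index[v]] = M[index[v], index[u]] = float(w)
    for i in range(n):
        mx = max(M[i].max(), 0.0)
        M[i, i] = mx if mx > 0 else 1.0
    M = M / M.sum(axis=0)
    for _ in range(10_000):
        prev = M.copy()
        M = M @ M
        M = M**inflation
        M = M / M.sum(axis=0)
        if np.abs(M - prev).max() < 1e-12:
            break
    adj = (M + M.T) > 1e-6
    seen: set[int] = set()
    clusters: list[frozenset] = []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(j for j in range(n) if adj[k, j] and j not in comp)
        seen |= comp
        clusters.append(frozenset(nodes[j] for j in comp))
    return clusters
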