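"""Nonparametric bootstrap over matrix columns, per inference method.

Columns are resampled with replacement to the original width (for the
supermatrix this is site-level resampling that ignores partition
boundaries; for content matrices a column *is* a family, so the same
resampling is family-level).  Resampling is represented as an integer
multiplicity vector, so a replicate costs one weighted distance/Fitch
evaluation instead of materialising a new matrix.

The support of a bipartition is the percentage of replicate trees that
contain it.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np

from .distances import DistanceModel, correct_distance, _empirical_B
from .nj import neighbor_joining
from .parsimony import _nni_descent, encode_matrix
from .tree import Tree

log = logging.getLogger("guildphylo")


def _default_model(matrix) -> DistanceModel:
    return DistanceModel(kind="pam_aa" if matrix.alphabet == "protein" else "p")


def _pair_arrays(matrix) -> tuple[list[tuple[int, int]], np.ndarray, np.ndarray]:
    arr = np.array([list(r) for r in matrix.rows])
    ok = ~np.isin(arr, ["?", "-"])
    pairs = list(combinations(range(len(matrix.taxa)), 2))
    diff = np.zeros((len(pairs), matrix.width))
    comp = np.zeros((len(pairs), matrix.width))
    for k, (i, j) in enumerate(pairs):
        both = ok[i] & ok[j]
        comp[k] = both
        diff[k] = both & (arr[i] != arr[j])
    return pairs, diff, comp


def _weighted_nj(
    matrix, pairs, diff, comp, w: np.ndarray, model: DistanceModel, B: float | None
) -> Tree:
    n = len(matrix.taxa)
    mism = diff @ w
    ncomp = comp @ w
    D = np.zeros((n, n))
    for k, (i, j) in enumerate(pairs):
        if ncomp[k] == 0:
            d = model.d_max
        else:
            d = correct_distance(float(mism[k] / ncomp[k]), model, B)
        D[i, j] = D[j, i] = d
    return neighbor_joining(list(matrix.taxa), D)


def bootstrap(
    matrix,
    method: str = "nj",
    n_reps: int = 1000,
    seed: int = 0,
    model: DistanceModel | None = None,
) -> dict[frozenset, float]:
    """Per-bipartition bootstrap support percentages.

    ``method`` is ``nj`` (distance, model chosen by alphabet unless
    given), ``mp`` (weighted Fitch with NNI descent from the
    replicate's NJ tree) or ``ml`` (weighted pruning likelihood with
    NNI ascent — feasible for small matrices only).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if method not in ("nj", "mp", "ml"):
        raise ValueError(f"unsupported bootstrap method {method!r}")
    model = model or _default_model(matrix)
    rng = np.random.default_rng(seed)
    pairs, diff, comp = _pair_arrays(matrix)
    B = _empirical_B(list(matrix.rows)) if model.kind == "felsenstein_nt" and model.B is None else None
    masks = encode_matrix(matrix) if method == "mp" else None
    sub_model = None
    if method == "ml":
        from .likelihood import model_for_matrix

        sub_model = model_for_matrix(matrix)
    counts: dict[frozenset, int] = {}
    width = matrix.width
    probs = np.full(width, 1.0 / width)
    for _ in range(n_reps):
        w = rng.multinomial(width, probs).astype(float)
        tree = _weighted_nj(matrix, pairs, diff, comp, w, model, B)
        if method == "mp":
            tree, _score = _nni_descent(tree.rooted_at_edge(), masks, w)
        elif method == "ml":
            from .likelihood import ml_search

            tree, _ll = ml_search(matrix, sub_model, start=tree, weights=w)
        for bip in tree.bipartitions():
            counts[bip] = counts.get(bip, 0) + 1
    return {bip: 100.0 * c / n_reps for bip, c in counts.items()}


def gene_jackknife(matrix, method: str, n_reps: int, seed: int,
                   model: DistanceModel | None = None) -> dict[frozenset, float]:
    """Partition-level resampling alternative (off by default in the pipeline).

    Each replicate resamples whole partitions with replacement, expressed
    as column weights, and otherwise follows :func:`bootstrap`.
    """
    model = model or _default_model(matrix)
    rng = np.random.default_rng(seed)
    pairs, diff, comp = _pair_arrays(matrix)
    masks = encode_matrix(matrix) if method == "mp" else None
    parts = matrix.partitions
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        w = np.zeros(matrix.width)
        draws = rng.integers(0, len(parts), size=len(parts))
        for d in draws:
            _, start, end, _ = parts[d]
            w[start:end] += 1.0
        tree = _weighted_nj(matrix, pairs, diff, comp, w, model, None)
        if method == "mp":
            tree, _score = _nni_descent(tree.rooted_at_edge(), masks, w)
        for bip in tree.bipartitions():
            counts[bip] = counts.get(bip, 0) + 1
    return {bip: 100.0 * c / n_reps for bip, c in counts.items()}


def supports_for_tree(tree: Tree, table: dict[frozenset, float]) -> dict[frozenset, float]:
    """Restrict a bootstrap table to the edges of a reference tree.

    Bipartitions of the tree that never occurred in a replicate get 0%.
    """
    return {bip: table.get(bip, 0.0) for bip in tree.bipartitions()}
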