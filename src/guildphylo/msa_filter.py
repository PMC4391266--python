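"""Progressive multiple alignment and conserved-block filtering.

The aligner is a deterministic progressive scheme: a neighbor-joining
guide tree on k-mer distances, then bottom-up profile–profile global
alignment with affine gaps and mean-of-pairs substitution scores.  No
iterative refinement is performed — determinism is prioritised over
accuracy, which is appropriate for the moderately diverged single-copy
families this pipeline aligns.

The block filter is a simplified conserved-block selector in the
GBLOCKS tradition: columns are classified by residue majority (a column
containing a gap is nonconserved unless gap columns are allowed), runs
of nonconserved columns longer than ``max_nonconserved_run`` are
removed, and surviving blocks shorter than ``min_block_len`` are
dropped.  The original's highly-conserved flank rule is folded into the
run/length rules; ``high_conserved_fraction`` is kept to classify
columns in reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger("guildphylo")

GAP = "-"


@dataclass
class Alignment:
    """Equal-width gapped rows with taxon labels."""

    rows: list[tuple[str, str]]  # (label, gapped sequence)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment with no rows")
        widths = {len(seq) for _, seq in self.rows}
        if len(widths) != 1:
            raise ValueError(f"unequal row widths {sorted(widths)}")
        if self.width == 0:
            raise ValueError("zero-width alignment")

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.rows]

    def degapped(self, label: str) -> str:
        for lab, seq in self.rows:
            if lab == label:
                return seq.replace(GAP, "")
        raise KeyError(label)

    def column(self, i: int) -> str:
        return "".join(seq[i] for _, seq in self.rows)


@dataclass
class BlockFilterParams:
    """Column conservation and block selection thresholds.

    A column is conserved when strictly more than half of the rows share
    one residue (``floor(n/2) + 1``); ``min_conserved_count`` may
    override that count explicitly.
    """

    min_conserved_count: int | None = None
    high_conserved_fraction: float = 0.85
    max_nonconserved_run: int = 8
    min_block_len: int = 10
    allow_gap_columns: bool = False

    def __post_init__(self) -> None:
        if not (0.5 <= self.high_conserved_fraction <= 1.0):
            raise ValueError("high_conserved_fraction must be in [0.5, 1]")
        if self.max_nonconserved_run < 1 or self.min_block_len < 1:
            raise ValueError("run/length parameters must be positive")


# ---------------------------------------------------------------------------
# progressive alignment
# ---------------------------------------------------------------------------

def _kmer_distance(a: str, b: str, k: int) -> float:
    ka = {a[i : i + k] for i in range(max(len(a) - k + 1, 1))}
    kb = {b[i : i + k] for i in range(max(len(b) - k + 1, 1))}
    denom = min(len(ka), len(kb))
    if denom == 0:
        return 1.0
    return 1.0 - len(ka & kb) / denom


def _profile_freqs(rows: list[str], scheme) -> np.ndarray:
    """(width, 20) residue frequency counts of a profile (gaps ignored)."""
    order = {c: i for i, c in enumerate("ACDEFGHIKLMNPQRSTVWY")}
    out = np.zeros((len(rows[0]), 20))
    for seq in rows:
        for i, c in enumerate(seq):
            j = order.get(c)
            if j is not None:
                out[i, j] += 1.0
    return out


def _blosum_array(scheme) -> np.ndarray:
    order = "ACDEFGHIKLMNPQRSTVWY"
    S = np.zeros((20, 20))
    for i, a in enumerate(order):
        for j, b in enumerate(order):
            S[i, j] = scheme.matrix_entry(a, b)
    return S


def _align_profiles(
    rows_a: list[str], rows_b: list[str], scheme, S: np.ndarray
) -> tuple[list[str], list[str]]:
    """Global affine profile–profile alignment; returns gapped row lists."""
    la, lb = len(rows_a[0]), len(rows_b[0])
    na, nb = len(rows_a), len(rows_b)
    fa = _profile_freqs(rows_a, scheme)
    fb = _profile_freqs(rows_b, scheme)
    match = (fa @ S @ fb.T) / (na * nb)  # mean-of-pairs column scores
    go, ge = float(scheme.gap_open), float(scheme.gap_extend)
    NEG = -1e30
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B (consume A column)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in A (consume B column)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -go - (i - 1) * ge
    for j in range(1, lb + 1):
        Y[0, j] = -go - (j - 1) * ge
    ptrM = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptrX = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptrY = np.zeros((la + 1, lb + 1), dtype=np.int8)
    for i in range(1, la + 1):
        mrow = match[i - 1]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        # M: diagonal from best of three (tie order M, X, Y)
        prev = np.vstack([Mp[:-1], Xp[:-1], Yp[:-1]])
        best_idx = prev.argmax(axis=0)
        M[i, 1:] = prev[best_idx, np.arange(lb)] + mrow
        ptrM[i, 1:] = best_idx
        # X: gap in B, move down (tie order: open from M before extend)
        open_x = M[i - 1] - go
        ext_x = X[i - 1] - ge
        take_ext = ext_x > open_x
        X[i] = np.where(take_ext, ext_x, open_x)
        ptrX[i] = take_ext.astype(np.int8)
        # Y: gap in A, move right — sequential in j
        for j in range(1, lb + 1):
            open_y = M[i, j - 1] - go
            ext_y = Y[i, j - 1] - ge
            if ext_y > open_y:
                Y[i, j] = ext_y
                ptrY[i, j] = 1
            else:
                Y[i, j] = open_y
                ptrY[i, j] = 0
    # traceback from the best of the three end states (tie order M, X, Y)
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    cols_a: list[int | None] = []
    cols_b: list[int | None] = []
    while i > 0 or j > 0:
        if state == 0:
            cols_a.append(i - 1)
            cols_b.append(j - 1)
            state = int(ptrM[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            cols_a.append(i - 1)
            cols_b.append(None)
            state = 1 if ptrX[i, j] else 0
            i -= 1
        else:
            cols_a.append(None)
            cols_b.append(j - 1)
            state = 2 if ptrY[i, j] else 0
            j -= 1
        if i == 0 and j > 0 and state != 2:
            state = 2
        if j == 0 and i > 0 and state != 1:
            state = 1
    cols_a.reverse()
    cols_b.reverse()
    new_a = [
        "".join(seq[c] if c is not None else GAP for c in cols_a) for seq in rows_a
    ]
    new_b = [
        "".join(seq[c] if c is not None else GAP for c in cols_b) for seq in rows_b
    ]
    return new_a, new_b


def progressive_align(
    sequences: list[tuple[str, str]], scheme=None, k: int = 3
) -> Alignment:
    """Align labelled sequences progressively along an NJ guide tree.

    ``sequences`` is a list of ``(label, sequence)``; a single sequence
    is returned unchanged as a width-L alignment.
    """
    if scheme is None:
        from .similarity import ScoringScheme

        scheme = ScoringScheme()
    if not sequences:
        raise ValueError("no sequences")
    if len(sequences) == 1:
        return Alignment(rows=list(sequences))
    from .trees.nj import neighbor_joining

    labels = [lab for lab, _ in sequences]
    seqs = {lab: s for lab, s in sequences}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _kmer_distance(sequences[i][1], sequences[j][1], k)
    guide = neighbor_joining(labels, D)
    S = _blosum_array(scheme)
    profiles: dict[int, tuple[list[str], list[str]]] = {}  # node -> (labels, rows)
    for node in guide.postorder():
        if node.is_leaf:
            profiles[id(node)] = ([node.name], [seqs[node.name]])
        else:
            children = [profiles[id(c)] for c in node.children]
            labs, rows = children[0]
            for labs2, rows2 in children[1:]:
                rows, rows2 = _align_profiles(rows, rows2, scheme, S)
                labs = labs + labs2
                rows = rows + rows2
            profiles[id(node)] = (labs, rows)
    labs, rows = profiles[id(guide.root)]
    # restore the input row order
    by_label = dict(zip(labs, rows))
    return Alignment(rows=[(lab, by_label[lab]) for lab in labels])


# ---------------------------------------------------------------------------
# block filtering
# ---------------------------------------------------------------------------

def classify_columns(alignment: Alignment, params: BlockFilterParams) -> list[str]:
    """Per-column class: 'high', 'conserved' or 'nonconserved'."""
    n = len(alignment.rows)
    need = params.min_conserved_count if params.min_conserved_count is not None else n // 2 + 1
    classes: list[str] = []
    for i in range(alignment.width):
        col = alignment.column(i)
        if GAP in col and not params.allow_gap_columns:
            classes.append("nonconserved")
            continue
        residues = col.replace(GAP, "")
        if not residues:
            classes.append("nonconserved")
            continue
        counts = {c: residues.count(c) for c in set(residues)}
        top = max(counts.values())
        if top / n >= params.high_conserved_fraction:
            classes.append("high")
        elif top >= need:
            classes.append("conserved")
        else:
            classes.append("nonconserved")
    return classes


def filter_blocks(
    alignment: Alignment, params: BlockFilterParams | None = None
) -> tuple[Alignment | None, list[int]]:
    """Keep conserved blocks; return the filtered alignment and kept columns.

    Kept column indices are strictly increasing and refer to the input
    alignment.  When everything is filtered the alignment is ``None``
    (with a warning), not an error.
    """
    params = params or BlockFilterParams()
    classes = classify_columns(alignment, params)
    width = alignment.width
    has_gap = [GAP in alignment.column(i) for i in range(width)]
    keep = [cls != "nonconserved" for cls in classes]
    # short interior runs of nonconserved columns survive inside a block;
    # runs longer than the maximum (and runs touching the alignment
    # edges) are removed; gap columns are always removed
    i = 0
    while i < width:
        if keep[i]:
            i += 1
            continue
        j = i
        while j < width and not keep[j]:
            j += 1
        if j - i <= params.max_nonconserved_run and i > 0 and j < width:
            for t in range(i, j):
                keep[t] = not has_gap[t] or params.allow_gap_columns
        i = j
    # drop blocks shorter than the minimum length
    kept: list[int] = []
    i = 0
    while i < width:
        if not keep[i]:
            i += 1
            continue
        j = i
        while j < width and keep[j]:
            j += 1
        if j - i >= params.min_block_len:
            kept.extend(range(i, j))
        i = j
    if not kept:
        log.warning("block filter removed every column")
        return None, []
    rows = [
        (lab, "".join(seq[c] for c in kept)) for lab, seq in alignment.rows
    ]
    return Alignment(rows=rows), kept


# ---------------------------------------------------------------------------
# pairwise identity utility
# ---------------------------------------------------------------------------

def min_pairwise_identity(alignment: Alignment, subset: list[str] | None = None) -> float:
    """Minimum percent identity over taxon pairs (gap-free columns only).

    Used for the rank heuristic that a modern order spans roughly >= 85%
    minimum 16S identity.  Pairs with no mutually ungapped column are
    excluded with a warning; if every pair is excluded this is an error.
    """
    labels = subset if subset is not None else alignment.labels
    if len(labels) < 2:
        raise ValueError("need >= 2 taxa")
    rows = {lab: seq for lab, seq in alignment.rows if lab in set(labels)}
    missing = set(labels) - set(rows)
    if missing:
        raise KeyError(f"taxa not in alignment: {sorted(missing)}")
    best: float | None = None
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = rows[labels[i]], rows[labels[j]]
            comp = ident = 0
            for x, y in zip(a, b):
                if x != GAP and y != GAP:
                    comp += 1
                    if x == y:
                        ident += 1
            if comp == 0:
                log.warning(
                    "pair (%s, %s) has no comparable columns; excluded",
                    labels[i], labels[j],
                )
                continue
            pct = 100.0 * ident / comp
            if best is None or pct < best:
                best = pct
    if best is None:
        raise ValueError("no taxon pair with comparable columns")
    return best
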