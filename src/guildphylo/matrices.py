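"""Assembly of the four character matrices used for tree inference.

* **supermatrix** — concatenation of every filtered alignment with at
  least ``min_seqs`` sequences; a genome absent from a partition is
  filled with ``?`` across that partition.
* **reduced supermatrix** — the supermatrix cleaned of relatively
  uninformative partitions by a quartet-resolution information score,
  with the constraint that no taxon may be left without data
  (organism deletion disallowed).
* **core-genes matrix** — concatenation of exactly those alignments
  with one sequence per genome for *every* genome; contains no missing
  symbols by construction.
* **content matrices** — binary presence/absence of each family per
  genome (one column per family), for both homolog and ortholog
  families.

Taxon and partition order are lexicographic throughout, so every matrix
is byte-deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .msa_filter import Alignment

log = logging.getLogger("guildphylo")

MISSING = "?"


@dataclass
class CharacterMatrix:
    """Taxa x characters with an alphabet, partition map and missing symbol."""

    taxa: list[str]
    rows: list[str]
    alphabet: str  # protein | binary
    partitions: list[tuple[str, int, int, str]] = field(default_factory=list)
    # (partition_id, start, end) is 0-based half-open; last element is the
    # source family id

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if self.rows:
            widths = {len(r) for r in self.rows}
            if len(widths) > 1:
                raise ValueError("unequal row widths")
        if self.alphabet not in ("protein", "binary"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if self.alphabet == "binary":
            for t, r in zip(self.taxa, self.rows):
                if set(r) - {"0", "1"}:
                    raise ValueError(f"binary matrix row {t!r} contains non-binary symbols")
        if self.partitions:
            pos = 0
            for pid, start, end, _fam in self.partitions:
                if start != pos or end <= start:
                    raise ValueError(f"partitions do not tile the matrix at {pid!r}")
                pos = end
            if pos != self.width:
                raise ValueError("partitions do not cover the full width")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def nonmissing_width(self, taxon: str) -> int:
        return sum(c != MISSING for c in self.row(taxon))

    def constant_columns(self) -> list[int]:
        """Indices of all-equal columns (flagged, never removed)."""
        out = []
        for i in range(self.width):
            col = {r[i] for r in self.rows}
            if len(col) == 1:
                out.append(i)
        return out


def build_supermatrix(
    alignments: list[tuple[str, Alignment]], min_seqs: int = 4
) -> CharacterMatrix:
    """Concatenate filtered alignments with >= ``min_seqs`` sequences.

    ``alignments`` pairs each family id with its filtered alignment whose
    row labels are genome ids (one sequence per genome — guaranteed after
    inparalog removal; a duplicated genome is a hard error here).
    """
    included = sorted(
        ((fam, aln) for fam, aln in alignments if aln is not None and len(aln.rows) >= min_seqs),
        key=lambda x: x[0],
    )
    taxa: set[str] = set()
    for fam, aln in included:
        labels = aln.labels
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(
                f"family {fam!r} has multiple sequences for genome(s) {dupes} "
                "(inparalog removal missed)"
            )
        taxa.update(labels)
    taxa_order = sorted(taxa)
    parts: list[tuple[str, int, int, str]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa_order}
    pos = 0
    for fam, aln in included:
        rows = dict(aln.rows)
        w = aln.width
        for t in taxa_order:
            chunks[t].append(rows.get(t, MISSING * w))
        parts.append((fam, pos, pos + w, fam))
        pos += w
    return CharacterMatrix(
        taxa=taxa_order,
        rows=["".join(chunks[t]) for t in taxa_order],
        alphabet="protein",
        partitions=parts,
    )


def build_core_matrix(
    alignments: list[tuple[str, Alignment]], genome_set: list[str]
) -> CharacterMatrix:
    """Concatenate alignments with exactly one sequence per genome for all genomes."""
    genomes = sorted(genome_set)
    qualifying = []
    for fam, aln in sorted(alignments, key=lambda x: x[0]):
        if aln is None:
            continue
        labels = sorted(aln.labels)
        if labels == genomes:
            qualifying.append((fam, aln))
    if not qualifying:
        log.warning("no family is single-copy in every genome; core matrix is empty")
        return CharacterMatrix(taxa=genomes, rows=["" for _ in genomes], alphabet="protein")
    parts: list[tuple[str, int, int, str]] = []
    chunks: dict[str, list[str]] = {g: [] for g in genomes}
    pos = 0
    for fam, aln in qualifying:
        rows = dict(aln.rows)
        for g in genomes:
            chunks[g].append(rows[g])
        parts.append((fam, pos, pos + aln.width, fam))
        pos += aln.width
    return CharacterMatrix(
        taxa=genomes,
        rows=["".join(chunks[g]) for g in genomes],
        alphabet="protein",
        partitions=parts,
    )


def build_content_matrix(families, genome_set: list[str]) -> CharacterMatrix:
    """Binary presence/absence matrix: one column per family, by family id."""
    if not families:
        raise ValueError("no families")
    genomes = sorted(genome_set)
    fams = sorted(families, key=lambda f: f.family_id)
    rows = {g: [] for g in genomes}
    parts = []
    for i, fam in enumerate(fams):
        present = fam.genomes()
        for g in genomes:
            rows[g].append("1" if g in present else "0")
        parts.append((fam.family_id, i, i + 1, fam.family_id))
    matrix = CharacterMatrix(
        taxa=genomes,
        rows=["".join(rows[g]) for g in genomes],
        alphabet="binary",
        partitions=parts,
    )
    n_const = len(matrix.constant_columns())
    if n_const:
        log.info("content matrix has %d constant column(s) (retained)", n_const)
    return matrix


# ---------------------------------------------------------------------------
# information filter (simplified MARE-style reduction)
# ---------------------------------------------------------------------------

def _quartet_parsimony_scores(cols: np.ndarray) -> tuple[int, int, int]:
    """Fitch scores of the three quartet topologies on encoded columns.

    ``cols`` is a (4, width) bitmask array for taxa (a, b, c, d); the
    topologies are ab|cd, ac|bd, ad|bc.
    """
    def fitch4(x, y, z, w):
        s = np.zeros(x.shape, dtype=np.int64)
        p = x & y
        e = p == 0
        s += e
        p = np.where(e, x | y, p)
        q = z & w
        e = q == 0
        s += e
        q = np.where(e, z | w, q)
        e = (p & q) == 0
        s += e
        return int(s.sum())

    a, b, c, d = cols
    return (fitch4(a, b, c, d), fitch4(a, c, b, d), fitch4(a, d, b, c))


def partition_information(
    matrix: CharacterMatrix,
    partition: tuple[str, int, int, str],
    quartets_per_partition: int,
    rng: np.random.Generator,
) -> float:
    """Fraction of sampled quartets resolved by a strictly best topology."""
    from .trees.parsimony import encode_states

    _pid, start, end, _fam = partition
    sub_rows = [r[start:end] for r in matrix.rows]
    has_data = [i for i, r in enumerate(sub_rows) if any(c != MISSING for c in r)]
    if len(has_data) < 4:
        return 0.0
    masks = encode_states(
        [matrix.taxa[i] for i in has_data],
        [sub_rows[i] for i in has_data],
        matrix.alphabet,
    )
    arr = np.array([masks[matrix.taxa[i]] for i in has_data])
    n = len(has_data)
    n_all = n * (n - 1) * (n - 2) * (n - 3) // 24
    if n_all <= quartets_per_partition:
        quartets = list(combinations(range(n), 4))
    else:
        quartets = [
            tuple(rng.choice(n, size=4, replace=False))
            for _ in range(quartets_per_partition)
        ]
    resolved = 0
    for q in quartets:
        scores = _quartet_parsimony_scores(arr[list(q)])
        best = min(scores)
        if sum(s == best for s in scores) == 1:
            resolved += 1
    return resolved / len(quartets)


def reduce_matrix(
    matrix: CharacterMatrix,
    quartets_per_partition: int = 100,
    min_info: float = 0.25,
    seed: int = 0,
) -> CharacterMatrix:
    """Drop low-information partitions without ever deleting a taxon.

    Per partition the information score is the fraction of sampled
    4-taxon subsets (among taxa with data in that partition) for which
    exactly one of the three quartet topologies has strictly minimal
    parsimony score.  Partitions scoring below ``min_info`` are dropped
    — except that any partition whose removal would leave some taxon
    with zero non-missing columns is retained.
    """
    if len(matrix.taxa) < 4:
        raise ValueError("need >= 4 taxa to reduce")
    rng = np.random.default_rng(seed)
    scores = {
        p[0]: partition_information(matrix, p, quartets_per_partition, rng)
        for p in matrix.partitions
    }
    kept = [p for p in matrix.partitions if scores[p[0]] >= min_info]
    dropped = [p for p in matrix.partitions if scores[p[0]] < min_info]

    def covered(taxon_idx: int, parts) -> bool:
        row = matrix.rows[taxon_idx]
        return any(
            any(c != MISSING for c in row[start:end]) for _pid, start, end, _f in parts
        )

    # no-organism-deletion rule: re-add the best dropped partition that
    # covers any taxon left without data
    for i, taxon in enumerate(matrix.taxa):
        while not covered(i, kept):
            candidates = [p for p in dropped if covered_one(matrix, i, p)]
            if not candidates:
                raise ValueError(f"taxon {taxon!r} has no data in any partition")
            best = max(candidates, key=lambda p: (scores[p[0]], p[0]))
            log.info(
                "partition %r retained despite score %.3f: removal would delete taxon %r",
                best[0], scores[best[0]], taxon,
            )
            kept.append(best)
            dropped.remove(best)
    kept.sort(key=lambda p: p[1])
    chunks: dict[str, list[str]] = {t: [] for t in matrix.taxa}
    parts: list[tuple[str, int, int, str]] = []
    pos = 0
    for pid, start, end, fam in kept:
        w = end - start
        for t, r in zip(matrix.taxa, matrix.rows):
            chunks[t].append(r[start:end])
        parts.append((pid, pos, pos + w, fam))
        pos += w
    return CharacterMatrix(
        taxa=list(matrix.taxa),
        rows=["".join(chunks[t]) for t in matrix.taxa],
        alphabet=matrix.alphabet,
        partitions=parts,
    )


def covered_one(matrix: CharacterMatrix, taxon_idx: int, part) -> bool:
    _pid, start, end, _fam = part
    row = matrix.rows[taxon_idx]
    return any(c != MISSING for c in row[start:end])
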