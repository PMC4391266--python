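"""All-vs-all protein similarity without an external search tool.

The built-in scorer is an exact Smith–Waterman local alignment with
affine gaps (a gap of length k costs ``gap_open + (k-1) * gap_extend``)
over BLOSUM62, evaluated by Biopython's C pairwise aligner.  Raw scores
are converted to E-values with the Karlin–Altschul formula
``E = k * m * n * exp(-lambda * S)`` using fixed gapped-BLOSUM62
constants.  This is a deterministic, exact stand-in for a heuristic
database search: no seeding, no composition statistics, no masking.

Within-genome hits are computed and retained — the downstream ortholog
stage needs them for inparalog detection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import AA_ALPHABET, Proteome, SimilarityHit

log = logging.getLogger("guildphylo")


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap costs, and E-value constants."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    _matrix: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if min(self.gap_open, self.gap_extend, self.karlin_lambda, self.karlin_k) <= 0:
            raise ValueError("scoring parameters must be positive")
        if self._matrix is None:
            self._matrix = substitution_matrices.load(self.matrix_name)

    @property
    def matrix(self):
        return self._matrix

    def matrix_entry(self, a: str, b: str) -> float:
        return float(self._matrix[a, b])

    def aligner(self, mode: str = "local") -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.mode = mode
        al.substitution_matrix = self._matrix
        al.open_gap_score = -float(self.gap_open)
        al.extend_gap_score = -float(self.gap_extend)
        return al


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)} in sequence")


def local_align_score(
    a: str, b: str, scheme: ScoringScheme | None = None
) -> tuple[float, float]:
    """Optimal Smith–Waterman score and percent identity over aligned columns.

    The score is symmetric in its arguments.  Identity is computed over
    aligned residue pairs of one optimal alignment (identities /
    (identities + mismatches) * 100); an empty optimal alignment (score
    0) has identity 0.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    _check_alphabet(a)
    _check_alphabet(b)
    scheme = scheme or ScoringScheme()
    al = scheme.aligner()
    score = float(al.score(a, b))
    if score <= 0.0:
        return 0.0, 0.0
    counts = al.align(a, b)[0].counts()
    aligned = counts.identities + counts.mismatches
    pident = 100.0 * counts.identities / aligned if aligned else 0.0
    return score, pident


def evalue(raw_score: float, m: int, n: int, scheme: ScoringScheme | None = None) -> float:
    """Karlin–Altschul expect value ``E = k * m * n * exp(-lambda * S)``."""
    if m <= 0 or n <= 0:
        raise ValueError("sequence lengths must be positive")
    scheme = scheme or ScoringScheme()
    return scheme.karlin_k * m * n * math.exp(-scheme.karlin_lambda * raw_score)


def all_vs_all(
    proteomes: Sequence[Proteome],
    scheme: ScoringScheme | None = None,
    e_max: float = 1e-5,
) -> list[SimilarityHit]:
    """Every ordered gene pair (within and between genomes, excluding
    self) whose E-value is at most ``e_max``, in lexicographic order.

    The underlying score is symmetric, so each unordered pair is aligned
    once and reported in both directions.  Bit scores in the output are
    the raw Smith–Waterman scores (the E-value already carries the
    statistical calibration).
    """
    if len(proteomes) < 2:
        raise ValueError("need >= 2 genomes")
    scheme = scheme or ScoringScheme()
    genes: list[tuple[str, str, str]] = []  # (genome_id, gene_id, seq)
    seen_ids: set[str] = set()
    for p in proteomes:
        for gid, seq in p.genes:
            if gid in seen_ids:
                raise ValueError(f"gene id {gid!r} occurs in more than one genome")
            seen_ids.add(gid)
            genes.append((p.genome_id, gid, seq))
    genes.sort(key=lambda g: (g[0], g[1]))
    al = scheme.aligner()
    hits: list[SimilarityHit] = []
    if e_max <= 0:
        return hits
    for i in range(len(genes)):
        gi, idi, si = genes[i]
        for j in range(i + 1, len(genes)):
            gj, idj, sj = genes[j]
            score = float(al.score(si, sj))
            if score <= 0:
                continue
            e = evalue(score, len(si), len(sj), scheme)
            if e > e_max:
                continue
            counts = al.align(si, sj)[0].counts()
            aligned = counts.identities + counts.mismatches
            pident = 100.0 * counts.identities / aligned if aligned else 0.0
            hits.append(
                SimilarityHit(gi, idi, gj, idj, pident, score, e)
            )
            hits.append(
                SimilarityHit(gj, idj, gi, idi, pident, score, e)
            )
    hits.sort(key=lambda h: (h.query_genome, h.query_gene, h.subject_genome, h.subject_gene))
    return hits


def gene_genome_map(proteomes: Iterable[Proteome]) -> dict[str, str]:
    """gene_id -> genome_id over a proteome set (ids must be globally unique)."""
    out: dict[str, str] = {}
    for p in proteomes:
        for gid, _ in p.genes:
            if gid in out:
                raise ValueError(f"gene id {gid!r} occurs in more than one genome")
            out[gid] = p.genome_id
    return out
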