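"""Readers and writers for every external representation the pipeline touches.

Formats handled here: protein FASTA (one file per genome), the 12-column
tabular similarity format (BLAST ``outfmt 6`` dialect), relaxed PHYLIP and
aligned FASTA for character matrices, Newick with numeric internal-node
labels, TSV for content matrices / COG annotations / cluster membership,
and the structured YAML run configuration.

Conventions
-----------
* Partition-file coordinates are 1-based inclusive (RAxML style); all
  in-memory indices are 0-based half-open.
* A terminal ``*`` (stop) in protein FASTA is stripped; an internal ``*``
  is an error.
* ``?`` encodes missing data in protein matrices; binary matrices have no
  missing entries.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from .matrices import CharacterMatrix

log = logging.getLogger("guildphylo")

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

#: The 25 standard single-letter COG functional categories.
COG_CATEGORIES = set("ABCDEFGHIJKLMNOPQRSTUVWYZ")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Proteome:
    """All protein sequences of one genome, with optional COG annotations.

    Parameters
    ----------
    genome_id:
        Short unique label for the genome.
    genes:
        Ordered ``(gene_id, sequence)`` pairs; gene ids are unique within
        the genome and sequences are uppercase amino acids (20 IUPAC
        letters plus ``X``).
    annotations:
        Optional map ``gene_id -> (cog_id, category_letter)``.
    """

    genome_id: str
    genes: list[tuple[str, str]]
    annotations: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gid, seq in self.genes:
            if gid in seen:
                raise FormatError(f"duplicate gene id {gid!r} in genome {self.genome_id!r}")
            seen.add(gid)
            if not seq:
                raise FormatError(f"empty sequence for gene {gid!r} in genome {self.genome_id!r}")
        for gid in self.annotations:
            if gid not in seen:
                raise FormatError(
                    f"annotation for unknown gene {gid!r} in genome {self.genome_id!r}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.genes]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class SimilarityHit:
    """One directed pairwise similarity hit (one row of the tabular format)."""

    query_genome: str
    query_gene: str
    subject_genome: str
    subject_gene: str
    percent_identity: float
    bit_score: float
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be nonnegative")

    @property
    def is_self(self) -> bool:
        return (self.query_genome, self.query_gene) == (self.subject_genome, self.subject_gene)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, genome_id: str | None = None) -> Proteome:
    """Read a protein FASTA file into a :class:`Proteome`.

    The token before the first whitespace of each header becomes the gene
    id.  Sequences are uppercased; a single terminal ``*`` is stripped;
    internal ``*`` raises (likely pseudogene or frameshift artifact).
    """
    path = Path(path)
    genome_id = genome_id if genome_id is not None else path.stem
    genes: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gid = rec.id
        if not gid:
            raise FormatError(f"{path}: record with empty header")
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if "*" in seq:
            raise FormatError(f"{path}: internal stop codon '*' in {gid!r}")
        if not seq:
            raise FormatError(f"{path}: empty sequence for {gid!r}")
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise FormatError(f"{path}: invalid residues {sorted(bad)} in {gid!r}")
        genes.append((gid, seq))
    proteome = Proteome(genome_id=genome_id, genes=genes)
    return proteome


def write_fasta(proteome: Proteome, path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=gid, description="") for gid, seq in proteome.genes
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    _ = width  # Biopython's fasta writer wraps at 60 already


# ---------------------------------------------------------------------------
# 12-column tabular similarity (BLAST outfmt-6 dialect)
# ---------------------------------------------------------------------------

_TAB_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


def read_similarity_table(
    path: str | Path, gene_to_genome: Mapping[str, str]
) -> list[SimilarityHit]:
    """Read tab-separated similarity hits (>= 12 columns per row).

    ``gene_to_genome`` resolves gene ids to genome ids; an unresolvable id
    is a hard error.  Extra columns beyond the standard 12 are ignored;
    rows are preserved in input order.
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise FormatError(
                    f"{path}:{lineno}: expected >=12 tab-separated columns, got {len(parts)}"
                )
            q, s = parts[0], parts[1]
            try:
                pident = float(parts[2])
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable numeric field ({exc})") from None
            for gid in (q, s):
                if gid not in gene_to_genome:
                    raise FormatError(f"{path}:{lineno}: gene id {gid!r} not in gene->genome map")
            hits.append(
                SimilarityHit(
                    query_genome=gene_to_genome[q],
                    query_gene=q,
                    subject_genome=gene_to_genome[s],
                    subject_gene=s,
                    percent_identity=pident,
                    bit_score=bitscore,
                    e_value=evalue,
                )
            )
    return hits


def write_similarity_table(
    hits: Iterable[SimilarityHit],
    path: str | Path,
    aligned_length: Mapping[tuple[str, str], tuple[int, int]] | None = None,
) -> None:
    """Write hits in the 12-column tabular format.

    Alignment coordinates are not tracked by the in-memory hit type, so
    ``length``/``mismatch``/``gapopen`` and the coordinate columns are
    written as 0 unless ``aligned_length`` provides ``(length, mismatch)``
    per ``(query_gene, subject_gene)`` pair.
    """
    with open(path, "w") as fh:
        for h in hits:
            length, mism = (0, 0)
            if aligned_length is not None:
                length, mism = aligned_length.get((h.query_gene, h.subject_gene), (0, 0))
            fh.write(
                "\t".join(
                    [
                        h.query_gene,
                        h.subject_gene,
                        f"{h.percent_identity:.2f}",
                        str(length),
                        str(mism),
                        "0",
                        "0",
                        "0",
                        "0",
                        "0",
                        f"{h.e_value:.3g}",
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# COG annotation TSV
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a gene annotation TSV: gene_id, cog_id, category letter(s).

    A gene may carry several category letters (e.g. ``IQ``); unknown
    letters are rejected at load time.
    """
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            gid, cog, cats = parts[0], parts[1], parts[2]
            bad = set(cats) - COG_CATEGORIES
            if bad:
                raise FormatError(
                    f"{path}:{lineno}: unknown COG category letter(s) {sorted(bad)}"
                )
            out[gid] = (cog, cats)
    return out


def write_annotations(annotations: Mapping[str, tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in annotations:
            cog, cats = annotations[gid]
            fh.write(f"{gid}\t{cog}\t{cats}\n")


# ---------------------------------------------------------------------------
# relaxed PHYLIP / aligned FASTA / partitions for character matrices
# ---------------------------------------------------------------------------

def write_phylip_relaxed(matrix: "CharacterMatrix", path: str | Path) -> None:
    """Write a character matrix as relaxed PHYLIP (name, space, full row)."""
    names = list(matrix.taxa)
    for name in names:
        if any(c.isspace() for c in name):
            raise FormatError(f"taxon name {name!r} contains whitespace")
    if len(set(names)) != len(names):
        raise FormatError("taxon name collision")
    pad = max(len(n) for n in names) + 2
    with open(path, "w") as fh:
        fh.write(f"{len(names)} {matrix.width}\n")
        for name, row in zip(names, matrix.rows):
            fh.write(f"{name.ljust(pad)}{row}\n")


def read_phylip_relaxed(path: str | Path) -> tuple[list[str], list[str]]:
    """Read relaxed PHYLIP, returning (taxa, rows)."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError(f"{path}: bad PHYLIP header")
        ntax, width = int(header[0]), int(header[1])
        taxa: list[str] = []
        rows: list[str] = []
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            seq = seq.replace(" ", "")
            if len(seq) != width:
                raise FormatError(f"{path}: row {name!r} has width {len(seq)} != {width}")
            taxa.append(name)
            rows.append(seq)
    if len(taxa) != ntax:
        raise FormatError(f"{path}: expected {ntax} taxa, found {len(taxa)}")
    return taxa, rows


def write_partitions(matrix: "CharacterMatrix", path: str | Path) -> None:
    """Write the partition table with 1-based inclusive coordinates."""
    model = "WAG" if matrix.alphabet == "protein" else "BIN"
    with open(path, "w") as fh:
        for pid, start, end, fam in matrix.partitions:
            fh.write(f"{model}, {pid} = {start + 1}-{end}\n")
            _ = fam


def read_partitions(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a partitions file back to 0-based half-open ``(id, start, end)``."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            _, rest = line.split(",", 1)
            pid, rng = rest.split("=")
            lo, hi = rng.strip().split("-")
            out.append((pid.strip(), int(lo) - 1, int(hi)))
    return out


# ---------------------------------------------------------------------------
# Newick (delegates to the trees module, which owns the tree type)
# ---------------------------------------------------------------------------

def read_newick(path_or_string: str | Path) -> "object":
    from .trees import Tree

    s = path_or_string
    if isinstance(s, Path) or (isinstance(s, str) and "\n" not in s and Path(s).exists()):
        s = Path(s).read_text()
    return Tree.from_newick(str(s))


def write_newick(tree: "object", path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# generic TSV helpers (cluster membership, guild maps, content matrices)
# ---------------------------------------------------------------------------

def write_tsv(rows: Iterable[Sequence[object]], path: str | Path, header: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        if header is not None:
            fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_tsv(path: str | Path, skip_header: bool = False) -> list[list[str]]:
    out: list[list[str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if skip_header and i == 0:
                continue
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t"))
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not (lo <= value <= hi):
        raise ValueError(f"config: {name}={value} outside [{lo}, {hi}]")


@dataclass
class SimulateConfig:
    n_taxa: int = 20
    mean_branch: float = 0.025
    min_branch: float = 0.004
    n_core: int = 30
    n_accessory: int = 20
    n_biased: int = 12
    bias_high: float = 0.95
    bias_low: float = 0.05
    gain_rate: float = 0.3
    loss_rate: float = 0.3
    dup_prob: float = 0.05
    root_len: int = 100
    guild_mode: str = "clade"  # clade | convergent

    def validate(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("config: n_taxa must be >= 3")
        _check_range("mean_branch", self.mean_branch, 1e-6, 10.0)
        _check_range("min_branch", self.min_branch, 0.0, self.mean_branch)
        _check_range("dup_prob", self.dup_prob, 0.0, 0.999)
        _check_range("gain_rate", self.gain_rate, 0.0, 100.0)
        _check_range("loss_rate", self.loss_rate, 0.0, 100.0)
        if self.root_len < 30:
            raise ValueError("config: root_len must be >= 30")
        if self.guild_mode not in ("clade", "convergent"):
            raise ValueError("config: guild_mode must be 'clade' or 'convergent'")
        _check_range("bias_high", self.bias_high, 0.5, 1.0)
        _check_range("bias_low", self.bias_low, 0.0, 0.5)


@dataclass
class SimilarityConfig:
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    e_max: float = 1e-5

    def validate(self) -> None:
        for n in ("gap_open", "gap_extend", "karlin_lambda", "karlin_k"):
            if getattr(self, n) <= 0:
                raise ValueError(f"config: {n} must be positive")
        if self.e_max < 0:
            raise ValueError("config: e_max must be >= 0")


@dataclass
class ClusterConfig:
    homolog_inflation: float = 2.0
    ortholog_inflation: float = 1.5
    weight_cap: float = 200.0
    prune_below: float = 1e-6
    tol: float = 1e-8
    max_iter: int = 200
    drop_multicopy_families: bool = False

    def validate(self) -> None:
        _check_range("homolog_inflation", self.homolog_inflation, 1.01, 10.0)
        _check_range("ortholog_inflation", self.ortholog_inflation, 1.01, 10.0)
        if self.weight_cap <= 0:
            raise ValueError("config: weight_cap must be positive")


@dataclass
class FilterConfig:
    kmer_k: int = 3
    high_conserved_fraction: float = 0.85
    max_nonconserved_run: int = 8
    min_block_len: int = 10
    allow_gap_columns: bool = False

    def validate(self) -> None:
        _check_range("high_conserved_fraction", self.high_conserved_fraction, 0.5, 1.0)
        if self.max_nonconserved_run < 1 or self.min_block_len < 1:
            raise ValueError("config: run/length parameters must be positive")


@dataclass
class MatrixConfig:
    min_seqs: int = 4
    quartets_per_partition: int = 100
    min_info: float = 0.25

    def validate(self) -> None:
        _check_range("min_info", self.min_info, 0.0, 1.0)
        if self.min_seqs < 1:
            raise ValueError("config: min_seqs must be >= 1")


@dataclass
class TreeConfig:
    bootstrap_reps: int = 100
    nni_restarts: int = 3
    run_ml: bool = False
    gene_jackknife: bool = False

    def validate(self) -> None:
        if self.bootstrap_reps < 1:
            raise ValueError("config: bootstrap_reps must be >= 1")


@dataclass
class CogConfig:
    alpha: float = 0.05
    min_diff: float = 1.0
    marker_cog: str = "COG2124"

    def validate(self) -> None:
        _check_range("alpha", self.alpha, 0.0, 1.0)


_SECTIONS = {
    "simulate": SimulateConfig,
    "similarity": SimilarityConfig,
    "cluster": ClusterConfig,
    "filter": FilterConfig,
    "matrix": MatrixConfig,
    "tree": TreeConfig,
    "cog": CogConfig,
}


@dataclass
class PipelineConfig:
    """Every stage parameter of the pipeline, with validated ranges.

    Unknown keys in a config file are rejected rather than ignored, so a
    typo cannot silently fall back to a default.
    """

    seed: int = 1
    outdir: str = "guildphylo_out"
    input_fastas: list[str] = field(default_factory=list)
    similarity_table: str | None = None
    annotation_tsvs: list[str] = field(default_factory=list)
    guild_map: str | None = None
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    matrix: MatrixConfig = field(default_factory=MatrixConfig)
    tree: TreeConfig = field(default_factory=TreeConfig)
    cog: CogConfig = field(default_factory=CogConfig)

    def validate(self) -> "PipelineConfig":
        for name in _SECTIONS:
            getattr(self, name).validate()
        return self

    @classmethod
    def from_dict(cls, data: Mapping[str, object]) -> "PipelineConfig":
        cfg = cls()
        top_fields = {f.name for f in dataclasses.fields(cls)}
        for key, value in data.items():
            if key not in top_fields:
                raise ValueError(f"config: unknown key {key!r}")
            if key in _SECTIONS:
                section_cls = _SECTIONS[key]
                sec_fields = {f.name for f in dataclasses.fields(section_cls)}
                if not isinstance(value, Mapping):
                    raise ValueError(f"config: section {key!r} must be a mapping")
                for k in value:
                    if k not in sec_fields:
                        raise ValueError(f"config: unknown key {key}.{k!r}")
                setattr(cfg, key, section_cls(**value))
            else:
                setattr(cfg, key, value)
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def setup_logging(level: int = logging.INFO) -> None:
    """Route package logs to stderr with levels (idempotent)."""
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        log.addHandler(handler)
    log.setLevel(level)
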