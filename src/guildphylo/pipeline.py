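"""End-to-end orchestration: simulate -> similarity -> cluster ->
align/filter -> matrices -> trees -> support -> COG comparison.

Each stage receives a seed derived from the single run seed by a fixed
offset, so stages are independently reproducible; re-running with the
same config and seed reproduces byte-identical matrices and trees.  The
manifest records the resolved configuration, every artifact path with a
content digest, matrix dimensions, and stage timings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import clustering, cog_profiles, io_formats, matrices, msa_filter, similarity
from .io_formats import PipelineConfig, Proteome, setup_logging
from .synthetic_genomes import (
    evolve_sequences,
    guild_assignment,
    simulate_families,
    simulate_species_tree,
)
from .trees import (
    DistanceModel,
    Tree,
    annotate_support,
    bootstrap,
    nj_tree,
    parsimony_search,
    supports_for_tree,
)
from .trees.likelihood import ml_search, model_for_matrix

log = logging.getLogger("guildphylo")

# fixed per-stage seed offsets (single global seed fans out)
SEED_TREE, SEED_FAMILIES, SEED_SEQUENCES, SEED_REDUCE, SEED_SEARCH, SEED_BOOT = (
    11, 23, 37, 53, 67, 79
)


@dataclass
class RunManifest:
    config: dict
    seed: int
    artifacts: dict[str, dict] = field(default_factory=dict)
    matrix_shapes: dict[str, tuple[int, int]] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    def record(self, name: str, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
        self.artifacts[name] = {"path": str(path), "sha256": digest}

    def write(self, path: Path) -> None:
        data = dataclasses.asdict(self)
        path.write_text(json.dumps(data, indent=2, default=str) + "\n")


@dataclass
class PipelineResult:
    manifest: RunManifest
    proteomes: list[Proteome]
    truth: object | None
    guild_of: dict[str, str]
    matrices: dict[str, matrices.CharacterMatrix]
    trees: dict[str, Tree]
    supports: dict[str, dict]
    composites: dict[str, object]
    comparison: cog_profiles.GuildComparison | None
    marker: tuple[float, float, float] | None


def convergent_benchmark_config(seed: int) -> PipelineConfig:
    """Study conditions for the content-dichotomy benchmark.

    Guilds are planted orthogonally to the species tree (``convergent``
    mode) with strong guild-biased gene content, emulating two trophic
    guilds that arose from different ancestors: the gene-content tree
    should separate the guilds while the supermatrix tree follows the
    species tree.  Sizes are kept below the default recovery benchmark
    because only the content dichotomy, not fine topology, is at stake.
    """
    cfg = PipelineConfig(seed=seed)
    cfg.simulate.guild_mode = "convergent"
    cfg.simulate.n_taxa = 16
    cfg.simulate.n_core = 20
    cfg.simulate.n_accessory = 16
    cfg.simulate.n_biased = 24
    cfg.simulate.root_len = 80
    return cfg


def simulate_stage(config: PipelineConfig) -> tuple[list[Proteome], object]:
    sim = config.simulate
    tree = simulate_species_tree(
        sim.n_taxa, config.seed + SEED_TREE, sim.mean_branch, sim.min_branch
    )
    guild_of = guild_assignment(tree, sim.guild_mode)
    truth = simulate_families(
        tree,
        guild_of,
        n_core=sim.n_core,
        n_accessory=sim.n_accessory,
        gain_rate=sim.gain_rate,
        loss_rate=sim.loss_rate,
        dup_prob=sim.dup_prob,
        seed=config.seed + SEED_FAMILIES,
        n_biased=sim.n_biased,
        bias_high=sim.bias_high,
        bias_low=sim.bias_low,
    )
    proteomes = evolve_sequences(truth, sim.root_len, config.seed + SEED_SEQUENCES)
    return proteomes, truth


def family_alignments(
    families: list[clustering.GeneFamily],
    proteomes: list[Proteome],
    config: PipelineConfig,
) -> list[tuple[str, msa_filter.Alignment | None]]:
    """Align each family's members (labelled by genome) and filter blocks."""
    seq_of = {
        (p.genome_id, gid): seq for p in proteomes for gid, seq in p.genes
    }
    scheme = similarity.ScoringScheme(
        gap_open=config.similarity.gap_open, gap_extend=config.similarity.gap_extend
    )
    params = msa_filter.BlockFilterParams(
        high_conserved_fraction=config.filter.high_conserved_fraction,
        max_nonconserved_run=config.filter.max_nonconserved_run,
        min_block_len=config.filter.min_block_len,
        allow_gap_columns=config.filter.allow_gap_columns,
    )
    out: list[tuple[str, msa_filter.Alignment | None]] = []
    for fam in families:
        members = sorted(fam.members)
        if len(members) < 2:
            continue
        seqs = [(genome, seq_of[(genome, gid)]) for genome, gid in members]
        aln = msa_filter.progressive_align(seqs, scheme, k=config.filter.kmer_k)
        filtered, _kept = msa_filter.filter_blocks(aln, params)
        out.append((fam.family_id, filtered))
    return out


def infer_trees_for_matrix(
    matrix: matrices.CharacterMatrix,
    config: PipelineConfig,
    seed: int,
) -> tuple[dict[str, Tree], dict[str, dict]]:
    """NJ and MP (optionally ML) trees plus bootstrap support tables."""
    model = DistanceModel(kind="pam_aa" if matrix.alphabet == "protein" else "p")
    trees: dict[str, Tree] = {}
    boots: dict[str, dict] = {}
    trees["nj"] = nj_tree(matrix, model)
    mp_tree, _score = parsimony_search(
        matrix, start=trees["nj"], seed=seed + SEED_SEARCH, restarts=config.tree.nni_restarts
    )
    trees["mp"] = mp_tree
    if config.tree.run_ml:
        if matrix.alphabet == "protein":
            log.info("ML on protein data uses LG+F with discrete gamma (4 categories)")
        ml_tree, _ll = ml_search(matrix, model_for_matrix(matrix), start=trees["nj"])
        trees["ml"] = ml_tree
    for method in ("nj", "mp"):
        boots[method] = bootstrap(
            matrix, method=method, n_reps=config.tree.bootstrap_reps,
            seed=seed + SEED_BOOT, model=model,
        )
    return trees, boots


def run_pipeline(config: PipelineConfig, write_artifacts: bool = True) -> PipelineResult:
    setup_logging()
    config.validate()
    outdir = Path(config.outdir)
    if write_artifacts:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    t_start = time.time()

    def save(name: str, writer) -> None:
        if not write_artifacts:
            return
        path = outdir / name
        writer(path)
        manifest.record(name, path)

    # ------------------------------------------------------------------ input
    truth = None
    if config.input_fastas:
        proteomes = [io_formats.read_fasta(p) for p in config.input_fastas]
        ann_by_genome = {Path(p).stem: p for p in config.annotation_tsvs}
        for prot in proteomes:
            if prot.genome_id in ann_by_genome:
                prot.annotations.update(
                    io_formats.read_annotations(ann_by_genome[prot.genome_id])
                )
        guild_of = {}
        if config.guild_map:
            guild_of = {
                row[0]: row[1] for row in io_formats.read_tsv(config.guild_map)
            }
    else:
        proteomes, truth = simulate_stage(config)
        guild_of = truth.guild_of
        for p in proteomes:
            save(f"{p.genome_id}.faa", lambda path, p=p: io_formats.write_fasta(p, path))
            save(
                f"{p.genome_id}.cogs.tsv",
                lambda path, p=p: io_formats.write_annotations(p.annotations, path),
            )
        save("truth.nwk", lambda path: path.write_text(truth.species_tree.to_newick() + "\n"))
        save(
            "truth_membership.tsv",
            lambda path: io_formats.write_tsv(
                sorted(
                    (fid, g, gid)
                    for fid, members in truth.member_table().items()
                    for g, gid in members
                ),
                path,
                header=["family_id", "genome_id", "gene_id"],
            ),
        )
        save(
            "guilds.tsv",
            lambda path: io_formats.write_tsv(sorted(guild_of.items()), path),
        )
    genome_ids = [p.genome_id for p in proteomes]
    manifest.timings["input"] = time.time() - t_start

    # ------------------------------------------------------------- similarity
    t0 = time.time()
    scheme = similarity.ScoringScheme(
        gap_open=config.similarity.gap_open,
        gap_extend=config.similarity.gap_extend,
        karlin_lambda=config.similarity.karlin_lambda,
        karlin_k=config.similarity.karlin_k,
    )
    if config.similarity_table:
        hits = io_formats.read_similarity_table(
            config.similarity_table, similarity.gene_genome_map(proteomes)
        )
    else:
        hits = similarity.all_vs_all(proteomes, scheme, e_max=config.similarity.e_max)
    save(
        "hits.tsv",
        lambda path: io_formats.write_similarity_table(hits, path),
    )
    manifest.timings["similarity"] = time.time() - t0

    # -------------------------------------------------------------- clustering
    t0 = time.time()
    cl = config.cluster
    homologs = clustering.homolog_families(
        hits, proteomes, e_max=config.similarity.e_max,
        weight_cap=cl.weight_cap, inflation=cl.homolog_inflation,
        prune_below=cl.prune_below, tol=cl.tol, max_iter=cl.max_iter,
    )
    orthologs_raw = clustering.ortholog_families(
        hits, proteomes, inflation=cl.ortholog_inflation,
        e_max=config.similarity.e_max, weight_cap=cl.weight_cap,
        prune_below=cl.prune_below, tol=cl.tol, max_iter=cl.max_iter,
    )
    orthologs = clustering.remove_inparalogs(
        orthologs_raw, hits, drop_multicopy_families=cl.drop_multicopy_families
    )
    for name, fams in (("homolog", homologs), ("ortholog", orthologs)):
        save(
            f"families_{name}.tsv",
            lambda path, fams=fams: io_formats.write_tsv(
                sorted((f.family_id, g, gid) for f in fams for g, gid in f.members),
                path,
                header=["family_id", "genome_id", "gene_id"],
            ),
        )
    manifest.timings["clustering"] = time.time() - t0

    # ---------------------------------------------------------- align + filter
    t0 = time.time()
    alignments = family_alignments(orthologs, proteomes, config)
    manifest.timings["alignment"] = time.time() - t0

    # ---------------------------------------------------------------- matrices
    t0 = time.time()
    mats: dict[str, matrices.CharacterMatrix] = {}
    mats["supermatrix"] = matrices.build_supermatrix(alignments, config.matrix.min_seqs)
    mats["reduced"] = matrices.reduce_matrix(
        mats["supermatrix"],
        quartets_per_partition=config.matrix.quartets_per_partition,
        min_info=config.matrix.min_info,
        seed=config.seed + SEED_REDUCE,
    )
    mats["core"] = matrices.build_core_matrix(alignments, genome_ids)
    mats["gene_content"] = matrices.build_content_matrix(homologs, genome_ids)
    mats["ortholog_content"] = matrices.build_content_matrix(orthologs, genome_ids)
    for name, m in mats.items():
        manifest.matrix_shapes[name] = (len(m.partitions), m.width)
        log.info(
            "%s matrix: %d genes and %d characters over %d genomes",
            name, len(m.partitions), m.width, len(m.taxa),
        )
        if m.alphabet == "protein" and m.width:
            save(f"{name}.phy", lambda path, m=m: io_formats.write_phylip_relaxed(m, path))
            save(f"{name}.partitions", lambda path, m=m: io_formats.write_partitions(m, path))
        elif m.width:
            save(
                f"{name}.tsv",
                lambda path, m=m: io_formats.write_tsv(
                    [[t] + list(r) for t, r in zip(m.taxa, m.rows)],
                    path,
                    header=["genome"] + [p[0] for p in m.partitions],
                ),
            )
    manifest.timings["matrices"] = time.time() - t0

    # -------------------------------------------------------------------- trees
    t0 = time.time()
    all_trees: dict[str, Tree] = {}
    all_boots: dict[str, dict] = {}
    for name, m in mats.items():
        if m.width == 0 or len(m.taxa) < 3:
            log.warning("matrix %s is empty or too small; skipping trees", name)
            continue
        trees_m, boots_m = infer_trees_for_matrix(m, config, config.seed)
        for method, tree in trees_m.items():
            all_trees[f"{name}_{method}"] = tree
            save(f"{name}_{method}.nwk", lambda path, t=tree: io_formats.write_newick(t, path))
        for method, table in boots_m.items():
            all_boots[f"{name}_{method}"] = table
    manifest.timings["trees"] = time.time() - t0

    # --------------------------------------------------- composite support dots
    t0 = time.time()
    composites: dict[str, object] = {}
    protein_methods = [
        k for k in ("supermatrix_nj", "supermatrix_mp", "reduced_nj", "reduced_mp",
                    "core_nj", "core_mp") if k in all_boots
    ]
    content_methods = [
        k for k in ("gene_content_nj", "gene_content_mp",
                    "ortholog_content_nj", "ortholog_content_mp") if k in all_boots
    ]
    for label, methods, ref in (
        ("protein", protein_methods, "supermatrix_nj"),
        ("content", content_methods, "gene_content_nj"),
    ):
        if ref not in all_trees or not methods:
            continue
        ref_tree = all_trees[ref]
        taxa_ref = set(ref_tree.leaf_names())
        usable = [
            m for m in methods
            if set(all_trees[m].leaf_names()) == taxa_ref
        ]
        if not usable:
            continue
        supports = {m: supports_for_tree(ref_tree, all_boots[m]) for m in usable}
        st = annotate_support(ref_tree, supports)
        composites[label] = st
        save(
            f"{label}_support_dots.tsv",
            lambda path, st=st: io_formats.write_tsv(
                st.dot_rows(), path,
                header=["bipartition"] + st.method_order + ["dot", "printed"],
            ),
        )
        save(
            f"{label}_composite.nwk",
            lambda path, st=st: path.write_text(st.newick_with_dots() + "\n"),
        )
    manifest.timings["support"] = time.time() - t0

    # --------------------------------------------------------------------- COG
    t0 = time.time()
    comparison = None
    marker = None
    annotated = [p for p in proteomes if p.annotations]
    guilds_present = {guild_of.get(p.genome_id) for p in annotated}
    if annotated and {"K", "r"} <= guilds_present:
        profiles = [cog_profiles.category_percentages(p) for p in proteomes]
        comparison = cog_profiles.guild_comparison(
            profiles, guild_of, alpha=config.cog.alpha, min_diff=config.cog.min_diff
        )
        save(
            "cog_comparison.tsv",
            lambda path: io_formats.write_tsv(
                cog_profiles.comparison_rows(comparison), path,
                header=["category", "mean_K", "K", "label_K", "mean_r", "r", "label_r", "p"],
            ),
        )
        try:
            marker = cog_profiles.marker_ratio(profiles, config.cog.marker_cog, guild_of)
        except ValueError:
            log.warning("marker COG %s absent; ratio not computed", config.cog.marker_cog)
    manifest.timings["cog"] = time.time() - t0
    manifest.timings["total"] = time.time() - t_start

    if write_artifacts:
        manifest.write(outdir / "manifest.json")
    return PipelineResult(
        manifest=manifest,
        proteomes=proteomes,
        truth=truth,
        guild_of=guild_of,
        matrices=mats,
        trees=all_trees,
        supports=all_boots,
        composites=composites,
        comparison=comparison,
        marker=marker,
    )
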