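"""Assemble the four character matrices from clustered families.

Supermatrix: filtered alignments with >= 4 sequences, missing genomes
padded with '?'.  Core-genes matrix: only families single-copy in every
genome (no missing data).  Content matrices: binary presence/absence.
The information filter drops partitions whose sampled quartets rarely
resolve, but never leaves a taxon without data.
"""

from guildphylo import PipelineConfig, all_vs_all
from guildphylo.clustering import homolog_families, ortholog_families, remove_inparalogs
from guildphylo.matrices import (
    build_content_matrix,
    build_core_matrix,
    build_supermatrix,
    reduce_matrix,
)
from guildphylo.pipeline import family_alignments, simulate_stage

cfg = PipelineConfig(seed=3)
cfg.simulate.n_taxa = 8
cfg.simulate.n_core = 10
cfg.simulate.root_len = 60
proteomes, truth = simulate_stage(cfg)
hits = all_vs_all(proteomes)
orthologs = remove_inparalogs(ortholog_families(hits, proteomes), hits)
homologs = homolog_families(hits, proteomes)
alignments = family_alignments(orthologs, proteomes, cfg)

genomes = [p.genome_id for p in proteomes]
supermatrix = build_supermatrix(alignments, min_seqs=4)
core = build_core_matrix(alignments, genomes)
reduced = reduce_matrix(supermatrix, seed=cfg.seed)
gene_content = build_content_matrix(homologs, genomes)

for name, m in (("supermatrix", supermatrix), ("reduced", reduced),
                ("core", core), ("gene content", gene_content)):
    print(f"{name}: {len(m.partitions)} genes and {m.width} characters "
          f"({m.alphabet}, {len(m.taxa)} genomes)")
print("missing symbols in core matrix:", sum(r.count("?") for r in core.rows))
# The core matrix is a subset of the supermatrix's partitions and has no
# '?' entries; the content matrix has one binary column per family.
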