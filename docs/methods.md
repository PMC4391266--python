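# Methods

This note documents the models and algorithmic choices behind
guildphylo: what each stage computes, the parameters that matter, what
the synthetic-data generator does and does not emulate, and the
numerical conventions.

## Similarity search

The built-in scorer is an exact Smith–Waterman local alignment with
affine gaps, evaluated by Biopython's C pairwise aligner over BLOSUM62.
A gap of length k costs `gap_open + (k−1)·gap_extend` with defaults
11/1.  Raw scores are converted to expect values with the
Karlin–Altschul formula `E = k·m·n·exp(−λS)` using fixed gapped
BLOSUM62 constants (λ = 0.267, k = 0.041).  These constants are
conventional defaults, not estimates; a user with real BLAST output
bypasses the built-in scorer entirely by supplying the 12-column
table.  The search is exhaustive — no seeding heuristics, composition
statistics or masking — so it is deterministic and exactly testable
against a brute-force dynamic-programming oracle, at the price of
quadratic cost that limits it to desk-scale inputs.  Within-genome
hits are computed and kept because inparalog detection needs them.

## Family clustering

**Markov clustering** is implemented from scratch: add self-loops equal
to each node's maximum incident weight (1 for isolated nodes),
column-normalise, then iterate expansion (matrix squaring) and
inflation (entrywise power with renormalisation), pruning entries below
10⁻⁶, until the matrix changes by less than 10⁻⁸ or 200 iterations
(non-convergence clusters the current matrix with a warning).
Clusters are connected components of the converged matrix's nonzero
pattern.  MCL runs independently per connected component of the input
graph — expansion cannot move probability between components — which
keeps matrices small and makes the result invariant under node
relabelling.  Homolog families use edge weights
`min(−log₁₀E, 200)` averaged over the two hit directions (a missing
direction contributes 0; E = 0 counts as the cap), E ≤ 10⁻⁵ and
inflation 2.0; ortholog families use inflation 1.5.

**Ortholog edges** are reciprocal best hits between genome pairs (best
by E-value, ties by bit score, then lexicographic subject id).
**Inparalog edges** join within-genome pairs whose E-value (the better
of the two directions) is at most the worse of the two genes' best
between-genome E-values; a gene with no between-genome hit accepts any
within-genome partner.  After clustering, each genome keeps the member
with the greatest summed bit score to the family's members in other
genomes (ties to the lexicographically smaller gene id); the
alternative reading — discarding whole multi-copy families — is
available as `drop_multicopy_families`.  The inter-genome weight
normalisation of the original ortholog-clustering scheme is omitted: at
desk scale with a single divergence regime it has no testable effect.

## Alignment and block filtering

Progressive alignment builds a neighbor-joining guide tree on
`1 − shared k-mer fraction` distances (k = 3, shared fraction relative
to the smaller k-mer set) and merges profiles bottom-up by global
affine-gap dynamic programming with mean-of-pairs substitution scores;
ties in the DP break in a fixed state order, so the output is
deterministic.  There is no iterative refinement — determinism is
prioritised over accuracy, which is adequate for the moderately
diverged single-copy families this pipeline aligns.

The block filter classifies each column: a column containing a gap is
nonconserved (unless gap columns are allowed); otherwise a column is
conserved when strictly more than half the rows share one residue
(`floor(n/2)+1`), and highly conserved when the majority fraction
reaches 0.85.  Runs of nonconserved columns longer than 8, and runs
touching the alignment edges, are removed; short interior runs survive
inside blocks except for their gap columns, which are always removed;
surviving blocks shorter than 10 columns are dropped.  This is a
simplified variant of the classic conserved-block filter: the
original's highly-conserved-flank rule is folded into the run/length
rules, and `high_conserved_fraction` only affects the reported column
classes.  Kept column indices always refer to the input alignment.

`min_pairwise_identity` reports the minimum over taxon pairs of
identical columns among mutually ungapped columns — the utility behind
the rank-of-order heuristic that members of one order share roughly
≥ 85% 16S identity.

## Character matrices

The supermatrix concatenates filtered alignments with at least 4
sequences in family-id order; a genome absent from a partition is
filled with `?` (missing data, distinct from the indel symbol).  The
core-genes matrix concatenates exactly those alignments with one
sequence per genome for every genome and therefore contains no missing
symbols.  Content matrices have one binary presence/absence column per
family; constant columns are flagged but retained.  Taxon and
partition order are lexicographic, so matrices are byte-deterministic.
Partition files use 1-based inclusive coordinates; all in-memory
indices are 0-based half-open.

The **information filter** replaces an external matrix-reduction tool
whose exact weighting is not reproducible: per partition it samples up
to 100 four-taxon subsets among taxa with data and scores the fraction
for which exactly one of the three quartet topologies has strictly
minimal parsimony; partitions below 0.25 are dropped.  Organism
deletion is disallowed: a partition whose removal would leave a taxon
with zero data is retained (the best-scoring such partition per
affected taxon), with a log notice.

## Tree inference

*Distances.* `p` is the mismatch fraction over columns where both taxa
have data.  The nucleotide correction is the F81-type
`d = −B·ln(1 − p/B)` with `B = 1 − Σπᵢ²` from empirical frequencies
(0.75 when uniform); the protein correction is Kimura's PAM
approximation `d = −ln(1 − p − 0.2p²)`.  Saturated pairs (p at or
beyond the formula's domain) are set to a ceiling of 5.0
substitutions/site with a warning.  These are the conventional
readings of the classic distance-menu labels; both formulas are
config-visible.

*Neighbor joining* is the standard Saitou–Nei agglomeration with the Q
criterion; ties break on the lexicographic pair of cluster labels, and
negative branch lengths are clamped to zero with a warning.  On an
additive matrix the output path metric equals the input to within
1e−9 (tested).

*Parsimony* encodes state sets as bitmasks, so Fitch's
intersection/union step is vectorised across all columns, with `?`,
`-` and `X` fully ambiguous.  The search is steepest-descent
nearest-neighbour interchange from a start tree (default: the NJ tree)
plus 3 seeded random-addition restarts; branch lengths of the reported
tree are reconstructed changes per character.  Column multiplicities
let a bootstrap replicate reuse the encoding.

*Likelihood* uses Felsenstein pruning in linear space with per-column
rescaling.  Binary matrices use the 2-state Mk model; protein matrices
use LG exchangeabilities (the published empirical matrix, bundled as a
plain-text table) with empirical `+F` frequencies.  Rate heterogeneity
is a discrete gamma with 4 equal-probability categories — a
reproducible, standard substitute for implementation-specific rate
approximations; the substitution is logged whenever ML runs on protein
data.  All models are time-reversible and the likelihood is invariant
to root placement (asserted to 1e−8).  Branch lengths are optimised by
iterated bounded one-dimensional search (tolerance 1e−6, ≤ 20 sweeps);
the topology search is NNI steepest ascent.  ML on large supermatrices
is opt-in (`tree.run_ml`) because Python-speed likelihood is the one
stage that can exceed desk scale; NJ and MP always run.

*Bootstrap* resamples columns with replacement to the original width —
site-level on the supermatrix (partition boundaries ignored;
partition-level resampling is available as `gene_jackknife`, off by
default), family-level on content matrices where a column is a family.
Resampling is represented as an integer weight vector, so a replicate
costs one weighted distance or Fitch evaluation.  Support of a
bipartition is the percentage of replicate trees containing it.

*Composite dots.* With `m` methods and `c` of them at ≥ 95% support:
black if `c = m`; white if `⌈2m/3⌉ ≤ c < m`; otherwise hollow if any
method reaches 75%, printing those values in fixed method order; else
nothing.  The white band `⌈2m/3⌉` reconciles the three published
figure conventions (m = 3 → exactly 2, m = 4 → 3, m = 6 → 4 or 5) in
one formula.

## COG guild statistics

A genome's profile is the percentage of its protein-coding genes per
single-letter COG category; unannotated genes count only in the
denominator, and a gene with several letters counts once per letter.
The guild comparison applies a two-sided rank-sum (Mann–Whitney) test
per category and labels `+`/`−` only when p < 0.05 **and** the guild
means differ by at least 1.0 percentage point, the sign following the
larger mean.  The published table this emulates states no labelling
rule and its unrounded values are unavailable, so no threshold can
reproduce it exactly; the declared rule reproduces the labelled /
unlabelled split for large-difference categories and is what the
type-I and power guarantees are stated for.  A guild with fewer than
two genomes suppresses labels.  Marker ratios are guild means of
copies per genome; a zero mean in the denominator guild is reported as
an infinite ratio with a warning.

## The synthetic-data generator

The real study this pipeline descends from is observational — there is
no published generative model for its 60 genomes — so every simulator
parameter is a package design decision, chosen once to produce a
desk-scale dataset with the same *structure*: two trophic guilds,
universal core genes, patchy accessory content, guild-biased families,
within-genome inparalogs, and per-guild COG-category profiles matching
the published per-guild means (lipid metabolism ≈ 7% vs 3%, signal
transduction ≈ 3% vs 6%, etc.), plus a marker family planted at an
11:1 copy ratio.

Defaults (the benchmark conditions): 20 genomes; Yule topology;
branch lengths shifted-exponential with mean 0.025 expected
substitutions/site and a floor of 0.004; 30 core families, 20
accessory families (gain and loss at rate 0.3 events per unit branch
length), 12 guild-biased families (presence 0.95 in the favoured guild
vs 0.05), duplication probability 0.05 per present family per genome,
root sequences of length 100.  The branch-length floor is a
resolvability guarantee: a raw exponential places a few percent of
internal edges so close to zero that no method could recover them from
a matrix of this width, and a benchmark edge that carries under ~2
expected changes measures luck, not the pipeline.  The overall depth
keeps the deepest pairwise divergences below the regime where the
protein distance correction becomes numerically unstable.

Sequences evolve by a stationary i.i.d.-site replacement model:
Poisson(t·L) substitution events at uniform sites with uniform
replacement residues.  This deliberately is not an empirical-matrix
simulation — the clustering and tree stages need divergence structure,
not model realism — and it makes the exact-identifiability analysis
above straightforward.  Inparalog copies branch off the primary
terminal lineage at a uniform point and evolve independently
afterwards.  Category letters are assigned to families by stratified
(largest-remainder) apportionment: core and unbiased accessory
families carry the profile common to both guilds, biased families
carry each guild's excess, so expected per-genome percentages track
the guild profiles.  When family counts are too small to carry the
full annotated mass the weights are rescaled, compressing all
percentages but preserving every between-guild direction.

What the simulator does **not** emulate: indels (alignments of
simulated families are gap-free; the aligner and filter are exercised
on constructed fixtures instead), lateral gene transfer, rate
variation across sites and lineages, genome rearrangement, and
annotation error.  Passing the recovery benchmarks therefore shows the
pipeline's machinery is correct and consistent under its own model
assumptions — not that it is robust to every violation real genomes
exhibit.

In `convergent` mode guilds alternate across the sorted leaf list —
orthogonal to the species tree — emulating guilds that arose from
different ancestors; with strong planting (the
`convergent_benchmark_config` conditions: 16 genomes, 24 biased
families) the gene-content parsimony tree separates the guilds into
two subtrees while the supermatrix tree still follows the species
tree.  This is the testable analogue of the published contrast between
the sequence-based and content-based phylogenies.

## Reproducibility and problem sizes

A single run seed fans out to per-stage seeds by fixed offsets, so
every stage is independently reproducible and byte-identical across
reruns.  The benchmark experiments use 10 seeds at the default
conditions for supermatrix recovery, 10 seeds of the convergent
benchmark for the content dichotomy, 50 profile-level simulations for
the COG error rates, 200 bootstrap replicates (scaled down from the
classical 1000) for the support check, and 200 genomes per guild for
the marker-ratio estimate; `scripts/acceptance.py` runs the same
experiments at 5 seeds where a fraction is reported.  These sizes are
the package's chosen benchmark conditions and are stated alongside
each reported value.

## Known limitations

The exhaustive Smith–Waterman stage is quadratic in total gene count
and is meant for simulated or few-genome datasets; real 60-genome
proteome sets should come in as precomputed tabular hits.  NNI-only
search can miss optima that subtree pruning-regrafting would find.
The likelihood stage at Python speed is for small matrices unless
opted in.  Nucleotide data is supported in the distance/parsimony
path only (no GTR likelihood).  The published log-likelihoods and
matrix dimensions of the original 60-genome study depend on external
data and tools and are not reproduction targets.
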