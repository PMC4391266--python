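"""Synthetic proteome sets with a known species tree and family structure.

The generator emulates the statistical structure assumed of a
genome-scale dataset spanning two trophic guilds (slow-growing
oligotrophic *K*-strategists vs fast-responding copiotrophic
*r*-strategists):

* a Yule species tree with exponential branch lengths;
* universal single-copy **core** families;
* patchily distributed **accessory** families evolving by gain/loss
  along the tree;
* **guild-biased** accessory families, present with high probability in
  one guild and low probability in the other — the source of the
  gene-content dichotomy;
* **guild-marker** families with guild-specific Poisson copy numbers
  (the default emulates a cytochrome-P450-like marker that is an order
  of magnitude more abundant in the K guild);
* per-family COG category letters assigned so that the expected
  per-genome category percentages match guild profiles whose defaults
  follow the published per-guild table of COG-category means;
* within-genome inparalogs (independent duplication per present family);
* protein sequences evolved by a stationary i.i.d.-site replacement
  model (Poisson substitutions, uniform replacement residues), which
  provides divergence structure without claiming model realism.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import Proteome
from .trees.tree import Node, Tree

log = logging.getLogger("guildphylo")

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Per-guild COG category means (percent of protein-coding genes), as
#: published for 17 K-strategist and 9 r-strategist genomes.
TABLE_K = {
    "E": 8.0, "G": 3.0, "D": 1.0, "N": 2.0, "M": 6.0, "H": 5.0, "V": 1.0,
    "C": 7.0, "P": 6.0, "U": 3.0, "I": 7.0, "F": 2.0, "O": 5.0, "L": 5.0,
    "Q": 4.0, "T": 3.0, "K": 5.0, "J": 6.0,
}
TABLE_R = {
    "E": 7.0, "G": 6.0, "D": 1.0, "N": 3.0, "M": 6.0, "H": 5.0, "V": 2.0,
    "C": 6.0, "P": 6.0, "U": 4.0, "I": 3.0, "F": 2.0, "O": 5.0, "L": 4.0,
    "Q": 2.0, "T": 6.0, "K": 7.0, "J": 6.0,
}


@dataclass
class GuildProfile:
    """Expected COG-category percentages per genome, plus marker abundance."""

    categories: dict[str, float]
    marker_mean_copies: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.categories.values()):
            raise ValueError("category percentages must be nonnegative")
        if sum(self.categories.values()) > 100.0 + 1e-9:
            raise ValueError("category percentages sum above 100")


DEFAULT_PROFILES = {
    "K": GuildProfile(categories=dict(TABLE_K), marker_mean_copies=1.1),
    "r": GuildProfile(categories=dict(TABLE_R), marker_mean_copies=0.1),
}

MARKER_COG = "COG2124"


@dataclass
class Family:
    family_id: str
    kind: str  # core_single_copy | accessory | guild_marker
    copies: dict[str, int]  # genome_id -> copy count
    category: str | None = None
    cog_id: str | None = None

    def present_in(self) -> set[str]:
        return {g for g, c in self.copies.items() if c > 0}


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    species_tree: Tree
    guild_of: dict[str, str]
    families: dict[str, Family]

    def __post_init__(self) -> None:
        leaves = set(self.species_tree.leaf_names())
        if set(self.guild_of) != leaves:
            raise ValueError("guild map does not match the tree's leaf set")
        for fam in self.families.values():
            if fam.kind == "core_single_copy":
                missing = leaves - fam.present_in()
                if missing:
                    raise ValueError(
                        f"core family {fam.family_id} absent from {sorted(missing)}"
                    )
            if any(c < 0 for c in fam.copies.values()):
                raise ValueError("negative copy count")

    def gene_ids(self, family: Family, genome: str) -> list[str]:
        return [
            f"{genome}_{family.family_id}_c{k}"
            for k in range(1, family.copies.get(genome, 0) + 1)
        ]

    def member_table(self) -> dict[str, frozenset[tuple[str, str]]]:
        """family_id -> {(genome_id, gene_id)} as clustering should recover it."""
        return {
            fid: frozenset(
                (g, gid) for g in fam.copies for gid in self.gene_ids(fam, g)
            )
            for fid, fam in self.families.items()
            if fam.present_in()
        }

    def presence_table(self) -> dict[str, set[str]]:
        return {fid: fam.present_in() for fid, fam in self.families.items()}


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def simulate_species_tree(
    n_taxa: int, seed: int, mean_branch: float = 0.025, min_branch: float = 0.004
) -> Tree:
    """Yule (pure-birth) topology with i.i.d. exponential branch lengths.

    Branch lengths are shifted-exponential: ``min_branch`` plus an
    exponential draw, with the overall mean equal to ``mean_branch``.
    The floor guarantees every internal edge carries a resolvable number
    of expected substitutions at desk-scale matrix widths; a raw
    exponential places a few percent of edges so close to zero that no
    method could recover them, which would say nothing about the
    pipeline.  Set ``min_branch=0`` for a plain exponential.
    """
    if n_taxa < 3:
        raise ValueError("need >= 3 taxa")
    if mean_branch <= 0 or min_branch < 0:
        raise ValueError("mean_branch must be positive and min_branch nonnegative")
    if min_branch >= mean_branch:
        raise ValueError("min_branch must be below mean_branch")
    rng = np.random.default_rng(seed)
    root = Node()
    tips: list[Node] = [root.add(Node()), root.add(Node())]
    while len(tips) < n_taxa:
        idx = int(rng.integers(len(tips)))
        tip = tips.pop(idx)
        tips.insert(idx, tip.add(Node()))
        tips.insert(idx + 1, tip.add(Node()))
    pad = len(str(n_taxa))
    tree = Tree(root)
    leaves = [n for n in tree.postorder() if n.is_leaf]
    for i, leaf in enumerate(leaves, start=1):
        leaf.name = f"g{i:0{pad}d}"
    for node in tree.postorder():
        if node is not tree.root:
            node.length = min_branch + float(rng.exponential(mean_branch - min_branch))
    return tree


def guild_assignment(tree: Tree, mode: str = "clade") -> dict[str, str]:
    """Default guild map: the two clades flanking the root, or — in
    ``convergent`` mode — an alternating assignment orthogonal to the
    tree, so that content dichotomy cuts across the sequence phylogeny."""
    leaves = sorted(tree.leaf_names())
    if mode == "clade":
        first = tree.root.children[0]
        clade = set(Tree(first).leaf_names()) if not first.is_leaf else {first.name}
        return {g: ("K" if g in clade else "r") for g in leaves}
    if mode == "convergent":
        return {g: ("K" if i % 2 == 0 else "r") for i, g in enumerate(leaves)}
    raise ValueError(f"unknown guild mode {mode!r}")


# ---------------------------------------------------------------------------
# family simulation
# ---------------------------------------------------------------------------

def _evolve_presence(
    tree: Tree, root_present: bool, gain: float, loss: float, rng: np.random.Generator
) -> set[str]:
    """Two-state gain/loss chain along every branch; returns present leaves."""
    state: dict[int, bool] = {id(tree.root): root_present}
    for node in tree.preorder():
        if node is tree.root:
            continue
        s = state[id(node.parent)]
        t = node.length or 0.0
        pos = 0.0
        while True:
            rate = loss if s else gain
            if rate <= 0:
                break
            pos += float(rng.exponential(1.0 / rate))
            if pos >= t:
                break
            s = not s
        state[id(node)] = s
    return {n.name for n in tree.leaves() if state[id(n)]}


def _quota_counts(weights: dict[str, float], total: int) -> dict[str, int]:
    """Largest-remainder apportionment of ``total`` items over categories."""
    cats = sorted(weights)
    raw = {c: weights[c] * total for c in cats}
    counts = {c: int(np.floor(raw[c])) for c in cats}
    left = total - sum(counts.values())
    by_rem = sorted(cats, key=lambda c: (-(raw[c] - counts[c]), c))
    for c in by_rem[:left]:
        counts[c] += 1
    return counts


def _assign_categories(
    families: dict[str, Family],
    profiles: dict[str, GuildProfile],
    n_bK: int,
    n_bR: int,
    bias_high: float,
    bias_low: float,
    shared_genes: float,
) -> None:
    """Give each family a category letter so expected per-genome category
    percentages approximate the guild profiles (stratified assignment)."""
    pk, pr = profiles["K"].categories, profiles["r"].categories
    cats = sorted(set(pk) | set(pr))
    common = {c: min(pk.get(c, 0.0), pr.get(c, 0.0)) for c in cats}
    excess_k = {c: pk.get(c, 0.0) - common[c] for c in cats}
    excess_r = {c: pr.get(c, 0.0) - common[c] for c in cats}
    total = shared_genes + bias_high * (n_bK + n_bR) / 2.0 + bias_low * (n_bK + n_bR) / 2.0

    shared_fams = sorted(
        f.family_id for f in families.values() if f.kind in ("core_single_copy", "accessory")
        and "bias" not in f.family_id
    )
    bk_fams = sorted(f.family_id for f in families.values() if f.family_id.startswith("FbiasK"))
    br_fams = sorted(f.family_id for f in families.values() if f.family_id.startswith("FbiasR"))

    if not bk_fams and not br_fams:
        mean = {c: (pk.get(c, 0.0) + pr.get(c, 0.0)) / 2.0 for c in cats}
        weights = {c: mean[c] / 100.0 * total / max(shared_genes, 1e-9) for c in cats}
        _cap_and_assign(weights, shared_fams, families)
        return

    w_shared = {c: common[c] / 100.0 * total / max(shared_genes, 1e-9) for c in cats}
    _cap_and_assign(w_shared, shared_fams, families)
    if bk_fams:
        w_k = {c: excess_k[c] / 100.0 * total / max(bias_high * len(bk_fams), 1e-9) for c in cats}
        _cap_and_assign(w_k, bk_fams, families)
    if br_fams:
        w_r = {c: excess_r[c] / 100.0 * total / max(bias_high * len(br_fams), 1e-9) for c in cats}
        _cap_and_assign(w_r, br_fams, families)


def _cap_and_assign(weights: dict[str, float], fam_ids: list[str], families: dict[str, Family]) -> None:
    s = sum(weights.values())
    if s > 1.0:
        log.warning("category weights sum to %.2f > 1; rescaling (profiles compressed)", s)
        weights = {c: w / s for c, w in weights.items()}
    counts = _quota_counts(weights, len(fam_ids))
    idx = 0
    for c in sorted(counts):
        for _ in range(counts[c]):
            fam = families[fam_ids[idx]]
            fam.category = c
            if fam.cog_id is None:
                fam.cog_id = f"COG9{idx:03d}"
            idx += 1
    # remaining families stay unannotated


def simulate_families(
    tree: Tree,
    guild_of: dict[str, str] | None,
    n_core: int = 30,
    n_accessory: int = 20,
    gain_rate: float = 0.3,
    loss_rate: float = 0.3,
    dup_prob: float = 0.05,
    guild_profiles: dict[str, GuildProfile] | None = None,
    seed: int = 0,
    n_biased: int = 12,
    bias_high: float = 0.95,
    bias_low: float = 0.05,
    marker_cog: str = MARKER_COG,
) -> SimulationTruth:
    """Plant core, accessory, guild-biased and marker families on a tree.

    ``n_biased`` guild-biased accessory families are split evenly between
    the guilds (present with probability ``bias_high`` in the favoured
    guild and ``bias_low`` in the other); one marker family has
    guild-specific Poisson copy numbers given by the profiles'
    ``marker_mean_copies``.
    """
    if gain_rate < 0 or loss_rate < 0 or not (0 <= dup_prob < 1):
        raise ValueError("rates must be >= 0 and dup_prob in [0, 1)")
    profiles = guild_profiles or DEFAULT_PROFILES
    for g, prof in profiles.items():
        if sum(prof.categories.values()) > 100.0 + 1e-9:
            raise ValueError(f"guild {g!r} profile sums above 100")
    if guild_of is None:
        guild_of = guild_assignment(tree, "clade")
    genomes = sorted(tree.leaf_names())
    rng = np.random.default_rng(seed)
    families: dict[str, Family] = {}

    def dup(count: int) -> int:
        return count + 1 if count > 0 and rng.random() < dup_prob else count

    for i in range(1, n_core + 1):
        fid = f"F{i:04d}"
        families[fid] = Family(fid, "core_single_copy", {g: dup(1) for g in genomes})
    for i in range(1, n_accessory + 1):
        fid = f"Facc{i:04d}"
        present = _evolve_presence(tree, bool(rng.random() < 0.5), gain_rate, loss_rate, rng)
        families[fid] = Family(
            fid, "accessory", {g: (dup(1) if g in present else 0) for g in genomes}
        )
    n_bk = n_biased // 2
    n_br = n_biased - n_bk
    for i in range(1, n_bk + 1):
        fid = f"FbiasK{i:04d}"
        families[fid] = Family(
            fid,
            "accessory",
            {
                g: (dup(1) if rng.random() < (bias_high if guild_of[g] == "K" else bias_low) else 0)
                for g in genomes
            },
        )
    for i in range(1, n_br + 1):
        fid = f"FbiasR{i:04d}"
        families[fid] = Family(
            fid,
            "accessory",
            {
                g: (dup(1) if rng.random() < (bias_high if guild_of[g] == "r" else bias_low) else 0)
                for g in genomes
            },
        )
    if any(p.marker_mean_copies > 0 for p in profiles.values()):
        fid = "Fmarker"
        families[fid] = Family(
            fid,
            "guild_marker",
            {g: int(rng.poisson(profiles[guild_of[g]].marker_mean_copies)) for g in genomes},
            category="Q",
            cog_id=marker_cog,
        )

    shared_genes = n_core + 0.5 * n_accessory
    _assign_categories(families, profiles, n_bk, n_br, bias_high, bias_low, shared_genes)
    return SimulationTruth(species_tree=tree, guild_of=dict(guild_of), families=families)


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _mutate(seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson(t * L) substitutions at uniform sites, stationary residues."""
    out = seq.copy()
    L = len(seq)
    n_events = int(rng.poisson(t * L))
    if n_events:
        sites = rng.integers(0, L, size=n_events)
        residues = rng.integers(0, 20, size=n_events)
        out[sites] = residues
    return out


def evolve_sequences(truth: SimulationTruth, root_len: int = 100, seed: int = 0) -> list[Proteome]:
    """Evolve one protein per family member along the species tree.

    Each family draws a random root sequence; inparalog copies branch off
    the terminal lineage at a uniform point and evolve independently
    afterwards.  Output proteomes carry the COG annotations recorded in
    the truth table.
    """
    if root_len < 30:
        raise ValueError("root_len must be >= 30")
    rng = np.random.default_rng(seed)
    tree = truth.species_tree
    genomes = sorted(tree.leaf_names())
    genes: dict[str, list[tuple[str, str]]] = {g: [] for g in genomes}
    annotations: dict[str, dict[str, tuple[str, str]]] = {g: {} for g in genomes}

    for fid in sorted(truth.families):
        fam = truth.families[fid]
        if not fam.present_in():
            continue
        root_seq = rng.integers(0, 20, size=root_len)
        seq_at: dict[int, np.ndarray] = {id(tree.root): root_seq}
        for node in tree.preorder():
            if node is tree.root:
                continue
            parent_seq = seq_at[id(node.parent)]
            t = node.length or 0.0
            n_copies = fam.copies.get(node.name, 0) if node.is_leaf else 0
            if node.is_leaf and n_copies > 1:
                # duplication points split the terminal branch; each extra
                # copy branches off the primary lineage and then evolves on
                # its own
                points = np.sort(rng.uniform(0.0, 1.0, size=n_copies - 1)) * t
                copies: list[np.ndarray] = []
                current = parent_seq
                pos = 0.0
                for p in points:
                    current = _mutate(current, p - pos, rng)
                    pos = p
                    copies.append(_mutate(current, t - p, rng))
                primary = _mutate(current, t - pos, rng)
                leaf_copies = [primary] + copies
            else:
                primary = _mutate(parent_seq, t, rng)
                leaf_copies = [primary]
            if node.is_leaf:
                if n_copies == 0:
                    continue
                for gid, seq in zip(truth.gene_ids(fam, node.name), leaf_copies):
                    genes[node.name].append((gid, "".join(AMINO_ACIDS[seq])))
                    if fam.category is not None:
                        annotations[node.name][gid] = (fam.cog_id or fid, fam.category)
            else:
                seq_at[id(node)] = primary
    return [
        Proteome(genome_id=g, genes=genes[g], annotations=annotations[g]) for g in genomes
    ]


def simulate_category_profiles(
    profiles: dict[str, GuildProfile],
    n_k: int,
    n_r: int,
    spread: float,
    seed: int,
) -> tuple[list, dict[str, str]]:
    """Directly draw per-genome category percentage vectors.

    A light-weight generator for statistical checks of the guild
    comparison: each genome's category percentages are Gaussian around
    its guild profile with the given spread (truncated at 0).  Returns
    ``(COGProfile list, guild map)``.
    """
    from .cog_profiles import COGProfile

    rng = np.random.default_rng(seed)
    out = []
    guild_of: dict[str, str] = {}
    total_genes = 1000
    for guild, n in (("K", n_k), ("r", n_r)):
        prof = profiles[guild]
        for i in range(n):
            gid = f"{guild}{i + 1:03d}"
            guild_of[gid] = guild
            pcts = {
                c: max(float(rng.normal(mu, spread)), 0.0)
                for c, mu in sorted(prof.categories.items())
            }
            counts = {c: int(round(p / 100.0 * total_genes)) for c, p in pcts.items()}
            out.append(
                COGProfile(
                    genome_id=gid,
                    total_protein_genes=total_genes,
                    counts=counts,
                    marker_copies={},
                )
            )
    return out, guild_of
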