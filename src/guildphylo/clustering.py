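"""Protein families by Markov clustering and reciprocal-best-hit orthology.

Two family notions are produced, mirroring the two content matrices
downstream:

* **homolog families** — TribeMCL-style: an undirected graph whose edge
  weights are symmetrised ``-log10 E`` values (capped), clustered by a
  from-scratch MCL at inflation 2.0;
* **ortholog families** — OrthoMCL-style: reciprocal best hits between
  genome pairs plus within-genome inparalog edges, clustered by MCL at
  inflation 1.5, followed by inparalog removal so each family keeps at
  most one member per genome.

MCL is run independently per connected component (expansion can never
move probability between components), which keeps the matrices small
and the result invariant under node relabelling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io_formats import Proteome, SimilarityHit

log = logging.getLogger("guildphylo")

GeneRef = tuple[str, str]  # (genome_id, gene_id)


@dataclass
class GeneFamily:
    """A cluster of member genes, labelled homolog or ortholog."""

    family_id: str
    kind: str  # homolog | ortholog
    members: frozenset[GeneRef]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty family")

    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}

    def members_in(self, genome_id: str) -> list[GeneRef]:
        return sorted(m for m in self.members if m[0] == genome_id)

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# similarity graph construction
# ---------------------------------------------------------------------------

def _log_weight(e: float, cap: float) -> float:
    if e <= 0.0:
        return cap
    return min(-math.log10(e), cap)


def build_homolog_graph(
    hits: list[SimilarityHit],
    e_max: float = 1e-5,
    weight_cap: float = 200.0,
    nodes: list[GeneRef] | None = None,
) -> nx.Graph:
    """Undirected weighted graph for TribeMCL clustering.

    Edge weight is the mean over the two hit directions of
    ``min(-log10 E, cap)``; a missing direction contributes 0 (half
    weight), ``E = 0`` counts as the cap, and hits with ``E > e_max`` or
    self-hits are excluded.
    """
    directed: dict[tuple[GeneRef, GeneRef], float] = {}
    for h in hits:
        if h.is_self or h.e_value > e_max:
            continue
        key = ((h.query_genome, h.query_gene), (h.subject_genome, h.subject_gene))
        if key not in directed or h.e_value < directed[key]:
            directed[key] = h.e_value
    graph = nx.Graph()
    if nodes is not None:
        graph.add_nodes_from(nodes)
    for (q, s), e in directed.items():
        graph.add_node(q)
        graph.add_node(s)
    for (q, s), e in directed.items():
        if q > s:
            continue
        back = directed.get((s, q))
        w_fwd = _log_weight(e, weight_cap)
        w_back = _log_weight(back, weight_cap) if back is not None else 0.0
        graph.add_edge(q, s, weight=(w_fwd + w_back) / 2.0)
    return graph


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def _mcl_component(
    nodes: list[GeneRef],
    graph: nx.Graph,
    inflation: float,
    expansion: int,
    prune_below: float,
    tol: float,
    max_iter: int,
) -> list[set[GeneRef]]:
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v, data in graph.subgraph(nodes).edges(data=True):
        w = float(data.get("weight", 1.0))
        M[index[u], index[v]] = M[index[v], index[u]] = w
    # self-loops: each node's maximum incident weight (1 for isolated nodes)
    for i in range(n):
        mx = M[i].max()
        M[i, i] = mx if mx > 0 else 1.0
    M /= M.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = M**inflation
        M[M < prune_below] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if np.max(np.abs(M - prev)) < tol:
            converged = True
            break
    if not converged:
        log.warning("MCL did not converge in %d iterations; clustering current matrix", max_iter)
    # clusters = connected components of the attractor structure
    adj = (M + M.T) > prune_below
    np.fill_diagonal(adj, True)
    comp_graph = nx.from_numpy_array(adj)
    return [
        {nodes[i] for i in comp} for comp in nx.connected_components(comp_graph)
    ]


def mcl(
    graph: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    prune_below: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 200,
    kind: str = "homolog",
    id_prefix: str = "F",
) -> list[GeneFamily]:
    """From-scratch Markov clustering of a weighted gene graph.

    The returned families partition the node set; family ids are assigned
    in order of each cluster's smallest member, so the labelling is
    independent of node insertion order.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    clusters: list[set[GeneRef]] = []
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) == 1:
            clusters.append(set(nodes))
        else:
            clusters.extend(
                _mcl_component(nodes, graph, inflation, expansion, prune_below, tol, max_iter)
            )
    clusters.sort(key=lambda c: min(c))
    pad = max(4, len(str(len(clusters))))
    return [
        GeneFamily(family_id=f"{id_prefix}{i:0{pad}d}", kind=kind, members=frozenset(c))
        for i, c in enumerate(clusters, start=1)
    ]


def homolog_families(
    hits: list[SimilarityHit],
    proteomes: list[Proteome] | None = None,
    e_max: float = 1e-5,
    weight_cap: float = 200.0,
    inflation: float = 2.0,
    **mcl_kwargs,
) -> list[GeneFamily]:
    """TribeMCL-style homolog clusters (E <= e_max, inflation 2.0)."""
    nodes = None
    if proteomes is not None:
        nodes = [(p.genome_id, g) for p in proteomes for g in p.gene_ids]
    graph = build_homolog_graph(hits, e_max=e_max, weight_cap=weight_cap, nodes=nodes)
    return mcl(graph, inflation=inflation, kind="homolog", id_prefix="H", **mcl_kwargs)


# ---------------------------------------------------------------------------
# ortholog families (reciprocal best hits + inparalogs)
# ---------------------------------------------------------------------------

def _hit_rank(h: SimilarityHit) -> tuple[float, float, str]:
    # best = smallest E, then largest bit score, then lexicographic subject
    return (h.e_value, -h.bit_score, h.subject_gene)


def ortholog_families(
    hits: list[SimilarityHit],
    proteomes: list[Proteome],
    inflation: float = 1.5,
    e_max: float = 1e-5,
    weight_cap: float = 200.0,
    **mcl_kwargs,
) -> list[GeneFamily]:
    """OrthoMCL-style families (before inparalog removal).

    Ortholog edges are reciprocal best hits between genome pairs;
    inparalog edges are within-genome pairs at least as similar as the
    worse of the two genes' best between-genome E-values (a gene with no
    between-genome hit uses +inf, i.e. accepts any within-genome hit).
    """
    if len(proteomes) < 2:
        raise ValueError("need >= 2 genomes")
    all_nodes: list[GeneRef] = [(p.genome_id, g) for p in proteomes for g in p.gene_ids]
    usable = [h for h in hits if not h.is_self and h.e_value <= e_max]

    best_hit: dict[tuple[GeneRef, str], SimilarityHit] = {}
    best_between_e: dict[GeneRef, float] = {}
    within: dict[tuple[GeneRef, GeneRef], float] = {}
    for h in usable:
        q = (h.query_genome, h.query_gene)
        s = (h.subject_genome, h.subject_gene)
        if h.query_genome == h.subject_genome:
            key = (q, s) if q < s else (s, q)
            if key not in within or h.e_value < within[key]:
                within[key] = h.e_value
            continue
        bk = (q, h.subject_genome)
        if bk not in best_hit or _hit_rank(h) < _hit_rank(best_hit[bk]):
            best_hit[bk] = h
        if q not in best_between_e or h.e_value < best_between_e[q]:
            best_between_e[q] = h.e_value

    edges: set[tuple[GeneRef, GeneRef]] = set()
    for (q, subj_genome), h in best_hit.items():
        s = (h.subject_genome, h.subject_gene)
        back = best_hit.get((s, q[0]))
        if back is not None and (back.subject_genome, back.subject_gene) == q:
            edges.add((q, s) if q < s else (s, q))
    for (a, b), e_pair in within.items():
        thresh = max(best_between_e.get(a, math.inf), best_between_e.get(b, math.inf))
        if e_pair <= thresh:
            edges.add((a, b))

    # weights as in the homolog graph, restricted to the selected edges
    directed: dict[tuple[GeneRef, GeneRef], float] = {}
    for h in usable:
        key = ((h.query_genome, h.query_gene), (h.subject_genome, h.subject_gene))
        if key not in directed or h.e_value < directed[key]:
            directed[key] = h.e_value
    graph = nx.Graph()
    graph.add_nodes_from(all_nodes)
    for a, b in edges:
        w_fwd = _log_weight(directed[(a, b)], weight_cap) if (a, b) in directed else 0.0
        w_back = _log_weight(directed[(b, a)], weight_cap) if (b, a) in directed else 0.0
        present = int((a, b) in directed) + int((b, a) in directed)
        if present == 0:
            continue
        graph.add_edge(a, b, weight=(w_fwd + w_back) / 2.0)
    return mcl(graph, inflation=inflation, kind="ortholog", id_prefix="O", **mcl_kwargs)


def remove_inparalogs(
    families: list[GeneFamily],
    hits: list[SimilarityHit],
    drop_multicopy_families: bool = False,
) -> list[GeneFamily]:
    """Reduce every family to at most one member per genome.

    In each genome with several members the member with the greatest
    summed bit score to the family's members in *other* genomes is kept
    (ties go to the lexicographically smaller gene id).  With
    ``drop_multicopy_families`` the alternative reading is applied:
    families containing any within-genome duplicate are discarded
    entirely.
    """
    pair_bit: dict[tuple[GeneRef, GeneRef], float] = {}
    for h in hits:
        if h.is_self:
            continue
        q = (h.query_genome, h.query_gene)
        s = (h.subject_genome, h.subject_gene)
        key = (q, s) if q < s else (s, q)
        if key not in pair_bit or h.bit_score > pair_bit[key]:
            pair_bit[key] = h.bit_score

    out: list[GeneFamily] = []
    for fam in families:
        per_genome: dict[str, list[GeneRef]] = {}
        for m in sorted(fam.members):
            per_genome.setdefault(m[0], []).append(m)
        if all(len(v) == 1 for v in per_genome.values()):
            out.append(fam)
            continue
        if drop_multicopy_families:
            continue
        kept: set[GeneRef] = set()
        for genome, members in per_genome.items():
            if len(members) == 1:
                kept.add(members[0])
                continue
            others = [m for m in fam.members if m[0] != genome]

            def connectivity(m: GeneRef) -> float:
                total = 0.0
                for o in others:
                    key = (m, o) if m < o else (o, m)
                    total += pair_bit.get(key, 0.0)
                return total

            best = min(members, key=lambda m: (-connectivity(m), m[1]))
            kept.add(best)
        out.append(GeneFamily(fam.family_id, fam.kind, frozenset(kept)))
    return out
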