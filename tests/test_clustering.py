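"""Homolog graph weighting, Markov clustering and ortholog detection."""

import numpy as np
import networkx as nx
import pytest

from guildphylo import Proteome, SimilarityHit
from guildphylo.clustering import (
    build_homolog_graph,
    homolog_families,
    mcl,
    ortholog_families,
    remove_inparalogs,
)
from oracles import mcl_dense_oracle


def hit(qg, q, sg, s, e, bit=100.0):
    return SimilarityHit(qg, q, sg, s, 90.0, bit, e)


class TestHomologGraph:
    def test_symmetric_evalue_weight(self):
        hits = [hit("A", "a", "B", "b", 1e-30), hit("B", "b", "A", "a", 1e-30)]
        g = build_homolog_graph(hits)
        assert g[("A", "a")][("B", "b")]["weight"] == pytest.approx(30.0)

    def test_zero_evalue_capped(self):
        hits = [hit("A", "a", "B", "b", 0.0), hit("B", "b", "A", "a", 0.0)]
        g = build_homolog_graph(hits, weight_cap=200.0)
        assert g[("A", "a")][("B", "b")]["weight"] == 200.0

    def test_missing_direction_half_weight(self):
        g = build_homolog_graph([hit("A", "a", "B", "b", 1e-30)])
        assert g[("A", "a")][("B", "b")]["weight"] == pytest.approx(15.0)

    def test_e_max_and_self_hits_excluded(self):
        hits = [
            hit("A", "a", "B", "b", 1e-3),
            hit("A", "a", "A", "a", 0.0),
        ]
        g = build_homolog_graph(hits, e_max=1e-5)
        assert g.number_of_edges() == 0


class TestMCL:
    def test_singleton(self):
        g = nx.Graph()
        g.add_node(("A", "a"))
        fams = mcl(g)
        assert len(fams) == 1 and len(fams[0]) == 1

    def test_two_cliques_split(self):
        g = nx.Graph()
        grp1 = [("g", c) for c in "abc"]
        grp2 = [("g", c) for c in "def"]
        for grp in (grp1, grp2):
            for i in range(3):
                for j in range(i + 1, 3):
                    g.add_edge(grp[i], grp[j], weight=30.0)
        g.add_edge(grp1[2], grp2[0], weight=0.5)
        fams = mcl(g, inflation=2.0)
        assert sorted(sorted(f.members) for f in fams) == [sorted(grp1), sorted(grp2)]

    def test_complete_graph_single_cluster(self):
        g = nx.Graph()
        nodes = [("g", c) for c in "abcde"]
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                g.add_edge(u, v, weight=1.0)
        assert len(mcl(g)) == 1

    def test_partition_property_and_oracle_agreement(self):
        rng = np.random.default_rng(7)
        for _ in range(8):
            n = int(rng.integers(5, 14))
            nodes = [("g", f"n{i}") for i in range(n)]
            edges = []
            g = nx.Graph()
            g.add_nodes_from(nodes)
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.35:
                        w = float(rng.integers(1, 60))
                        edges.append((nodes[i], nodes[j], w))
                        g.add_edge(nodes[i], nodes[j], weight=w)
            fams = mcl(g)
            all_members = [m for f in fams for m in f.members]
            assert sorted(all_members) == sorted(nodes)  # partition
            assert sorted(sorted(f.members) for f in fams) == sorted(
                sorted(c) for c in mcl_dense_oracle(nodes, edges)
            )

    def test_invariant_under_node_relabelling(self):
        rng = np.random.default_rng(11)
        nodes = [("g", f"n{i}") for i in range(10)]
        edges = [
            (nodes[i], nodes[j], float(rng.integers(1, 40)))
            for i in range(10)
            for j in range(i + 1, 10)
            if rng.random() < 0.4
        ]
        base = None
        for perm_seed in range(5):
            prm = np.random.default_rng(perm_seed).permutation(len(nodes))
            g = nx.Graph()
            for k in prm:
                g.add_node(nodes[k])
            for u, v, w in edges:
                g.add_edge(u, v, weight=w)
            res = sorted(sorted(f.members) for f in mcl(g))
            if base is None:
                base = res
            assert res == base

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            mcl(nx.Graph())


class TestOrthologFamilies:
    def prots(self):
        return [
            Proteome("A", [("a1", "MKVL"), ("a2", "MKVL")]),
            Proteome("B", [("b1", "MKVL")]),
        ]

    def test_single_rbh_pair(self):
        prots = [Proteome("A", [("a1", "MKVL")]), Proteome("B", [("b1", "MKVL")])]
        hits = [hit("A", "a1", "B", "b1", 1e-40), hit("B", "b1", "A", "a1", 1e-40)]
        fams = ortholog_families(hits, prots)
        assert {frozenset(f.members) for f in fams} == {
            frozenset({("A", "a1"), ("B", "b1")})
        }

    def test_inparalog_joins_family(self):
        # a1-a2 within-genome E much better than their best between-genome E
        hits = [
            hit("A", "a1", "B", "b1", 1e-40, 400),
            hit("B", "b1", "A", "a1", 1e-40, 400),
            hit("A", "a2", "B", "b1", 1e-35, 350),
            hit("B", "b1", "A", "a2", 1e-35, 350),
            hit("A", "a1", "A", "a2", 1e-80, 500),
            hit("A", "a2", "A", "a1", 1e-80, 500),
        ]
        fams = ortholog_families(hits, self.prots())
        members = {frozenset(f.members) for f in fams}
        assert frozenset({("A", "a1"), ("A", "a2"), ("B", "b1")}) in members

    def test_asymmetric_best_hits_no_rbh(self):
        # a1's best is b1, but b1's best is a2 -> no a1-b1 edge
        hits = [
            hit("A", "a1", "B", "b1", 1e-40, 400),
            hit("B", "b1", "A", "a2", 1e-50, 450),
            hit("B", "b1", "A", "a1", 1e-40, 400),
            hit("A", "a2", "B", "b1", 1e-50, 450),
        ]
        fams = ortholog_families(hits, self.prots())
        members = {frozenset(f.members) for f in fams}
        assert frozenset({("A", "a2"), ("B", "b1")}) in members
        assert not any(
            ("A", "a1") in m and ("B", "b1") in m for m in members
        )

    def test_distant_inparalog_pair_excluded(self):
        # within-genome E is worse than both genes' best between-genome E
        hits = [
            hit("A", "a1", "B", "b1", 1e-40),
            hit("B", "b1", "A", "a1", 1e-40),
            hit("A", "a1", "A", "a2", 1e-10),
            hit("A", "a2", "A", "a1", 1e-10),
            hit("A", "a2", "B", "b1", 1e-30),
            hit("B", "b1", "A", "a2", 1e-30),
        ]
        fams = ortholog_families(hits, self.prots())
        members = {frozenset(f.members) for f in fams}
        assert frozenset({("A", "a1"), ("A", "a2"), ("B", "b1")}) not in members


class TestRemoveInparalogs:
    def family(self):
        from guildphylo.clustering import GeneFamily

        return [
            GeneFamily("O1", "ortholog", frozenset({("A", "a1"), ("A", "a2"), ("B", "b1")}))
        ]

    def test_best_connected_member_kept(self):
        hits = [hit("A", "a1", "B", "b1", 1e-40, 500), hit("A", "a2", "B", "b1", 1e-38, 450)]
        out = remove_inparalogs(self.family(), hits)
        assert out[0].members == frozenset({("A", "a1"), ("B", "b1")})

    def test_tie_breaks_lexicographically(self):
        hits = [hit("A", "a1", "B", "b1", 1e-40, 500), hit("A", "a2", "B", "b1", 1e-40, 500)]
        out = remove_inparalogs(self.family(), hits)
        assert out[0].members == frozenset({("A", "a1"), ("B", "b1")})

    def test_single_copy_family_unchanged(self):
        from guildphylo.clustering import GeneFamily

        fam = [GeneFamily("O1", "ortholog", frozenset({("A", "a1"), ("B", "b1")}))]
        assert remove_inparalogs(fam, [])[0].members == fam[0].members

    def test_drop_multicopy_alternative(self):
        out = remove_inparalogs(self.family(), [], drop_multicopy_families=True)
        assert out == []

    def test_at_most_one_member_per_genome(self, small_dataset):
        _cfg, prots, _truth, hits = small_dataset
        fams = remove_inparalogs(ortholog_families(hits, prots), hits)
        for f in fams:
            genomes = [g for g, _ in f.members]
            assert len(genomes) == len(set(genomes))


def test_exact_family_recovery_without_duplication(small_dataset):
    """With dup_prob=0 clustering must reproduce the planted family table."""
    import logging

    from guildphylo import all_vs_all
    from guildphylo.synthetic_genomes import (
        evolve_sequences,
        simulate_families,
        simulate_species_tree,
    )

    from guildphylo.synthetic_genomes import TABLE_K, TABLE_R, GuildProfile

    no_marker = {
        "K": GuildProfile(categories=dict(TABLE_K)),
        "r": GuildProfile(categories=dict(TABLE_R)),
    }
    tree = simulate_species_tree(6, 81, 0.025)
    truth = simulate_families(tree, None, n_core=8, n_accessory=4, dup_prob=0.0,
                              n_biased=0, seed=82, guild_profiles=no_marker)
    prots = evolve_sequences(truth, 60, 83)
    hits = all_vs_all(prots)
    fams = remove_inparalogs(ortholog_families(hits, prots), hits)
    got = {frozenset(f.members) for f in fams}
    want = {frozenset(m) for m in truth.member_table().values()}
    assert got == want
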