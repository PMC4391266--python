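"""Distances, NJ, parsimony, likelihood, bootstrap, RF and support dots."""

import math

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from guildphylo.matrices import CharacterMatrix
from guildphylo.trees import (
    DistanceModel,
    SubstitutionModel,
    Tree,
    annotate_support,
    bootstrap,
    correct_distance,
    dot_category,
    encode_matrix,
    fitch_score,
    log_likelihood,
    neighbor_joining,
    nj_tree,
    parsimony_score,
    parsimony_search,
    pairwise_distances,
    random_topology,
    rf_distance,
    supports_for_tree,
)
from guildphylo.trees.likelihood import ml_search, optimize_branch_lengths
from guildphylo.trees.nj import path_metric
from oracles import likelihood_enumeration, parsimony_exhaustive


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

class TestDistances:
    def test_zero_p_gives_zero_for_all_models(self):
        for kind in ("p", "felsenstein_nt", "pam_aa"):
            assert correct_distance(0.0, DistanceModel(kind=kind)) == 0.0

    def test_felsenstein_closed_form(self):
        d = correct_distance(0.3, DistanceModel(kind="felsenstein_nt", B=0.75))
        assert d == pytest.approx(-0.75 * math.log(0.6), rel=1e-12)
        assert d == pytest.approx(0.3831, abs=1e-4)

    def test_pam_closed_form(self):
        d = correct_distance(0.1, DistanceModel(kind="pam_aa"))
        assert d == pytest.approx(-math.log(1 - 0.1 - 0.2 * 0.01), rel=1e-12)
        assert d == pytest.approx(0.1076, abs=1e-4)

    def test_saturation_ceiling(self):
        model = DistanceModel(kind="pam_aa", d_max=5.0)
        assert correct_distance(0.99, model) == 5.0

    def test_pairwise_over_comparable_columns_only(self):
        m = CharacterMatrix(
            taxa=["a", "b"], rows=["AAC?", "A?CC"], alphabet="protein"
        )
        taxa, D = pairwise_distances(m, DistanceModel(kind="p"))
        assert D[0, 1] == 0.0  # columns 0 and 2 comparable, both equal

    def test_no_comparable_columns_is_error(self):
        m = CharacterMatrix(taxa=["a", "b"], rows=["A?", "?A"], alphabet="protein")
        with pytest.raises(ValueError, match="a.*b"):
            pairwise_distances(m, DistanceModel(kind="p"))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        true = Tree.from_newick("((A:1,B:2):1,(C:3,D:4):2);")
        names, D = path_metric(true)
        nj = neighbor_joining(names, D)
        assert rf_distance(nj, true) == 0
        _n2, D2 = path_metric(nj)
        assert np.max(np.abs(D - D2)) < 1e-9

    def test_random_additive_matrices_inverted(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(4, 10))
            tree = random_topology([f"t{i}" for i in range(n)], rng)
            for node in tree.postorder():
                if node.parent is not None:
                    node.length = float(rng.uniform(0.1, 2.0))
            names, D = path_metric(tree)
            nj = neighbor_joining(names, D)
            _n2, D2 = path_metric(nj)
            assert np.max(np.abs(D - D2)) < 1e-9
            assert rf_distance(nj, tree) == 0

    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        t = neighbor_joining(["a", "b", "c"], D)
        lengths = {n.name: n.length for n in t.leaves()}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_tie_determinism(self):
        D = np.ones((4, 4)) - np.eye(4)  # fully tied ultrametric
        t1 = neighbor_joining(list("abcd"), D)
        t2 = neighbor_joining(list("abcd"), D)
        assert t1.to_newick() == t2.to_newick()

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            neighbor_joining(["a", "b"], D)


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------

class TestParsimony:
    def test_simple_columns(self):
        t = Tree.from_newick("((A,B),(C,D));")
        m1 = CharacterMatrix(taxa=list("ABCD"), rows=["0", "0", "1", "1"], alphabet="binary")
        m2 = CharacterMatrix(taxa=list("ABCD"), rows=["0", "1", "0", "1"], alphabet="binary")
        assert parsimony_score(t, m1) == 1
        assert parsimony_score(t, m2) == 2

    def test_missing_is_fully_ambiguous(self):
        t = Tree.from_newick("((A,B),(C,D));")
        m = CharacterMatrix(taxa=list("ABCD"), rows=["A", "?", "C", "?"], alphabet="protein")
        assert parsimony_score(t, m) == 1

    def test_matches_exhaustive_enumeration(self):
        """Fitch equals the brute-force internal-labelling minimum."""
        rng = np.random.default_rng(23)
        for _ in range(15):
            n = int(rng.integers(4, 8))
            taxa = [f"t{i}" for i in range(n)]
            tree = random_topology(taxa, rng)
            width = int(rng.integers(1, 6))
            rows = ["".join(rng.choice(["0", "1"], width)) for _ in taxa]
            m = CharacterMatrix(taxa=taxa, rows=rows, alphabet="binary")
            got = parsimony_score(tree, m)
            rooted = tree.rooted_at_edge()
            want = sum(
                parsimony_exhaustive(
                    rooted, {t: int(r[c]) for t, r in zip(taxa, rows)}, 2
                )
                for c in range(width)
            )
            assert got == want

    def test_search_never_worse_than_start(self):
        rng = np.random.default_rng(29)
        taxa = [f"t{i}" for i in range(8)]
        rows = ["".join(rng.choice(["0", "1"], 30)) for _ in taxa]
        m = CharacterMatrix(taxa=taxa, rows=rows, alphabet="binary")
        start = random_topology(taxa, rng)
        start_score = parsimony_score(start, m)
        _tree, score = parsimony_search(m, start=start, seed=1, restarts=2)
        assert score <= start_score

    def test_weighted_score_equals_expanded_matrix(self):
        taxa = list("ABCDE")
        rows = ["001", "011", "101", "110", "010"]
        m = CharacterMatrix(taxa=taxa, rows=rows, alphabet="binary")
        t = nj_tree(m, DistanceModel(kind="p"))
        masks = encode_matrix(m)
        w = np.array([2.0, 0.0, 3.0])
        weighted = fitch_score(t, masks, w)
        expanded = CharacterMatrix(
            taxa=taxa, rows=[r[0] * 2 + r[2] * 3 for r in rows], alphabet="binary"
        )
        assert weighted == parsimony_score(t, expanded)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

class TestLikelihood:
    def test_two_leaves_zero_branch_identical_state(self):
        m = CharacterMatrix(taxa=["A", "B"], rows=["1", "1"], alphabet="binary")
        t = Tree.from_newick("(A:0,B:0);")
        assert log_likelihood(t, m) == pytest.approx(math.log(0.5), abs=1e-12)

    def test_matches_state_enumeration(self):
        """Pruning equals the brute-force sum over internal assignments."""
        rng = np.random.default_rng(31)
        for n in (4, 5, 6):
            taxa = [f"t{i}" for i in range(n)]
            tree = random_topology(taxa, rng)
            for node in tree.postorder():
                if node.parent is not None:
                    node.length = float(rng.uniform(0.05, 1.0))
            rows = ["".join(rng.choice(["0", "1", "?"], 4, p=[0.45, 0.45, 0.1])) for _ in taxa]
            want = likelihood_enumeration(tree, dict(zip(taxa, rows)))
            got = log_likelihood(tree, _ambiguous_binary_matrix(taxa, rows))
            assert got == pytest.approx(want, abs=1e-8)

    def test_root_placement_invariance(self):
        rng = np.random.default_rng(37)
        taxa = [f"t{i}" for i in range(6)]
        tree = random_topology(taxa, rng)
        for node in tree.postorder():
            if node.parent is not None:
                node.length = float(rng.uniform(0.05, 0.8))
        rows = ["".join(rng.choice(["0", "1"], 6)) for _ in taxa]
        m = _binary_matrix(taxa, rows)
        lls = [
            log_likelihood(tree.rooted_at_edge(leaf), m) for leaf in taxa[:4]
        ]
        assert max(lls) - min(lls) < 1e-8

    def test_rate_branch_scaling_symmetry(self):
        """Halving branch lengths at doubled rate leaves the likelihood fixed."""
        taxa = ["a", "b", "c"]
        rows = ["01", "00", "11"]
        m = _binary_matrix(taxa, rows)
        t1 = Tree.from_newick("(a:0.2,b:0.4,c:0.3);")
        t2 = Tree.from_newick("(a:0.1,b:0.2,c:0.15);")
        # the Mk2 model is rate-normalised, so doubling the rate is the
        # same as doubling every branch length
        ll1 = log_likelihood(t1, m)
        model2 = SubstitutionModel(kind="mk2")
        saved = model2.transition
        model2.transition = lambda t: saved(2.0 * t)
        ll2 = log_likelihood(t2, m, model2)
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_zero_width_rejected(self):
        m = CharacterMatrix(taxa=["a", "b"], rows=["", ""], alphabet="binary")
        t = Tree.from_newick("(a:0.1,b:0.1);")
        with pytest.raises(ValueError):
            log_likelihood(t, m)

    def test_branch_optimisation_improves_likelihood(self):
        rng = np.random.default_rng(41)
        taxa = [f"t{i}" for i in range(5)]
        rows = ["".join(rng.choice(["0", "1"], 40)) for _ in taxa]
        m = _binary_matrix(taxa, rows)
        t = nj_tree(m, DistanceModel(kind="p"))
        before = log_likelihood(t, m)
        _t2, after = optimize_branch_lengths(t, m)
        assert after >= before - 1e-9

    def test_ml_search_recovers_clean_split(self):
        taxa = list("ABCD")
        rows = ["0" * 20, "0" * 20, "1" * 20, "1" * 20]
        m = _binary_matrix(taxa, rows)
        tree, _ll = ml_search(m)
        assert {"C", "D"} in [set(b) for b in tree.bipartitions()] or \
               {"A", "B"} in [set(b) for b in tree.bipartitions()]

    def test_lg_model_loads_and_is_reversible(self):
        model = SubstitutionModel(kind="lg")
        P = model.transition(0.5)
        assert P.shape == (20, 20)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        # detailed balance: pi_i P_ij == pi_j P_ji
        pi = model.freqs
        assert np.allclose(pi[:, None] * P, (pi[:, None] * P).T, atol=1e-10)


def _binary_matrix(taxa, rows):
    return CharacterMatrix(taxa=list(taxa), rows=list(rows), alphabet="binary")


class _ambiguous_binary_matrix:
    """Binary data with '?' sites (stricter than CharacterMatrix allows)."""

    alphabet = "binary"

    def __init__(self, taxa, rows):
        self.taxa = list(taxa)
        self.rows = list(rows)
        self.width = len(rows[0])


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

class TestBootstrap:
    def test_perfect_signal_full_support(self):
        taxa = list("ABCD")
        rows = ["0" * 30, "0" * 30, "1" * 30, "1" * 30]
        m = _binary_matrix(taxa, rows)
        table = bootstrap(m, method="nj", n_reps=100, seed=0, model=DistanceModel(kind="p"))
        split = frozenset({"C", "D"})
        assert table[split] == 100.0

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(43)
        taxa = [f"t{i}" for i in range(6)]
        rows = ["".join(rng.choice(["0", "1"], 40)) for _ in taxa]
        m = _binary_matrix(taxa, rows)
        t1 = bootstrap(m, "nj", n_reps=50, seed=7, model=DistanceModel(kind="p"))
        t2 = bootstrap(m, "nj", n_reps=50, seed=7, model=DistanceModel(kind="p"))
        assert t1 == t2

    def test_conflicting_signal_near_fifty(self):
        """50/50 conflicting columns -> support near 50% (binomial noise)."""
        taxa = list("ABCD")
        rows = ["0" * 100 + "0" * 100,
                "0" * 100 + "1" * 100,
                "1" * 100 + "0" * 100,
                "1" * 100 + "1" * 100]
        m = _binary_matrix(taxa, rows)
        table = bootstrap(m, "mp", n_reps=400, seed=1, model=DistanceModel(kind="p"))
        s1 = table.get(frozenset({"C", "D"}), 0.0)
        s2 = table.get(frozenset({"B", "D"}), 0.0)
        se = 100 * math.sqrt(0.25 / 400)
        # the two conflicting resolutions should split the replicates
        assert abs(s1 - 50.0) <= 4 * se + 10 or abs(s2 - 50.0) <= 4 * se + 10

    def test_mp_bootstrap_runs_and_supports_clean_split(self):
        taxa = list("ABCDE")
        rows = ["00000", "00000", "11100", "11111", "11111"]
        m = _binary_matrix(taxa, rows)
        table = bootstrap(m, "mp", n_reps=50, seed=2, model=DistanceModel(kind="p"))
        assert table  # produced some splits with support


# ---------------------------------------------------------------------------
# RF distance
# ---------------------------------------------------------------------------

class TestRFDistance:
    def test_identical_zero(self):
        t = Tree.from_newick("((A,B),(C,D),E);")
        assert rf_distance(t, t.copy()) == 0

    def test_symmetry_and_leafset_check(self):
        a = Tree.from_newick("((A,B),(C,D),E);")
        b = Tree.from_newick("((A,C),(B,D),E);")
        assert rf_distance(a, b) == rf_distance(b, a)
        c = Tree.from_newick("((A,B),C);")
        with pytest.raises(ValueError):
            rf_distance(a, c)

    def test_matches_dendropy_enumeration(self):
        rng = np.random.default_rng(47)
        taxa = [f"t{i}" for i in range(8)]
        tns = dendropy.TaxonNamespace()
        for _ in range(10):
            a = random_topology(taxa, rng)
            b = random_topology(taxa, rng)
            got = rf_distance(a, b)
            da = dendropy.Tree.get(data=a.to_newick(), schema="newick",
                                   taxon_namespace=tns, preserve_underscores=True)
            db = dendropy.Tree.get(data=b.to_newick(), schema="newick",
                                   taxon_namespace=tns, preserve_underscores=True)
            da.encode_bipartitions()
            db.encode_bipartitions()
            want = treecompare.symmetric_difference(da, db)
            assert got == want


# ---------------------------------------------------------------------------
# composite support annotation
# ---------------------------------------------------------------------------

class TestSupportAnnotation:
    def test_three_method_rules(self):
        assert dot_category([96, 97, 95]) == ("black", [])
        assert dot_category([96, 97, 60]) == ("white", [])
        assert dot_category([80, 74, 60]) == ("hollow", [80])
        assert dot_category([70, 74, 60]) == ("none", [])

    def test_six_method_rules(self):
        assert dot_category([96, 96, 97, 95, 60, 70]) == ("white", [])
        assert dot_category([96] * 6) == ("black", [])
        assert dot_category([96, 96, 96, 60, 60, 80]) == ("hollow", [96, 96, 96, 80])

    def test_four_method_rules(self):
        assert dot_category([95, 95, 95, 95]) == ("black", [])
        assert dot_category([95, 95, 95, 60]) == ("white", [])
        assert dot_category([95, 95, 60, 60]) == ("hollow", [95, 95])

    def test_annotation_requires_every_edge(self):
        ref = Tree.from_newick("((A,B),(C,D),E);")
        full = supports_for_tree(ref, {frozenset({"A", "B"}): 99.0})
        with pytest.raises(ValueError, match="no support value"):
            annotate_support(ref, {"nj": {}})
        st = annotate_support(ref, {"nj": full})
        assert set(st.edges) == ref.bipartitions()

    def test_printable_values_in_method_order(self):
        ref = Tree.from_newick("((A,B),(C,D),E);")
        sup = {
            "m1": supports_for_tree(ref, {b: 80.0 for b in ref.bipartitions()}),
            "m2": supports_for_tree(ref, {b: 60.0 for b in ref.bipartitions()}),
            "m3": supports_for_tree(ref, {b: 90.0 for b in ref.bipartitions()}),
        }
        st = annotate_support(ref, sup)
        for e in st.edges.values():
            assert e.category == "hollow" and e.printable == [80.0, 90.0]
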