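"""Supermatrix, core-genes, content matrices and the information filter."""

import numpy as np
import pytest

from guildphylo import Alignment, build_content_matrix, build_core_matrix, build_supermatrix
from guildphylo.clustering import GeneFamily
from guildphylo.matrices import CharacterMatrix, reduce_matrix


def aln(taxa_seqs):
    return Alignment(rows=list(taxa_seqs))


class TestSupermatrix:
    def setup_method(self):
        self.alns = [
            ("f1", aln([(f"g{i}", "A" * 10) for i in range(5)])),
            ("f2", aln([(f"g{i}", "C" * 20) for i in range(4)])),
            ("f3", aln([(f"g{i}", "D" * 30) for i in range(3)])),
        ]

    def test_min_seqs_rule(self):
        m = build_supermatrix(self.alns, min_seqs=4)
        assert [p[0] for p in m.partitions] == ["f1", "f2"]
        assert m.width == 30
        assert m.taxa == [f"g{i}" for i in range(5)]

    def test_min_seqs_one_includes_all(self):
        m = build_supermatrix(self.alns, min_seqs=1)
        assert m.width == 60 and len(m.partitions) == 3

    def test_missing_taxon_filled_with_question_marks(self):
        m = build_supermatrix(self.alns, min_seqs=4)
        row = m.row("g4")  # only in f1
        assert row[:10] == "A" * 10 and row[10:] == "?" * 20

    def test_duplicate_genome_in_family_is_hard_error(self):
        bad = [("f1", Alignment(rows=[("g1", "AAAA"), ("g1", "CCCC"),
                                       ("g2", "AAAA"), ("g3", "AAAA")]))]
        with pytest.raises(ValueError, match="inparalog"):
            build_supermatrix(bad, min_seqs=4)

    def test_width_equals_sum_and_per_taxon_coverage(self):
        m = build_supermatrix(self.alns, min_seqs=1)
        assert m.width == sum(a.width for _f, a in self.alns)
        for t in m.taxa:
            covered = sum(
                (e - s) for (_p, s, e, _f), (_f2, a) in zip(m.partitions, self.alns)
                if t in a.labels
            )
            assert m.nonmissing_width(t) == covered


class TestCoreMatrix:
    def test_membership_rule(self):
        alns = [
            ("fA", aln([("g1", "AAAA"), ("g2", "AAAA"), ("g3", "AAAA")])),
            ("fB", aln([("g1", "CCCC"), ("g3", "CCCC")])),  # misses g2
        ]
        m = build_core_matrix(alns, ["g1", "g2", "g3"])
        assert [p[0] for p in m.partitions] == ["fA"]
        assert "?" not in "".join(m.rows)

    def test_no_qualifying_family_gives_empty_matrix(self):
        alns = [("fB", aln([("g1", "CC"), ("g3", "CC")]))]
        m = build_core_matrix(alns, ["g1", "g2", "g3"])
        assert m.width == 0

    def test_widths_concatenate(self):
        alns = [
            ("fA", aln([("g1", "A" * 40), ("g2", "A" * 40)])),
            ("fB", aln([("g1", "C" * 60), ("g2", "C" * 60)])),
        ]
        m = build_core_matrix(alns, ["g1", "g2"])
        assert m.width == 100 and len(m.partitions) == 2
        assert "?" not in "".join(m.rows)


class TestContentMatrix:
    def fams(self):
        return [
            GeneFamily("F1", "homolog", frozenset({("g1", "a"), ("g2", "b")})),
            GeneFamily("F2", "homolog", frozenset({("g2", "c"), ("g3", "d")})),
        ]

    def test_presence_absence_rows(self):
        m = build_content_matrix(self.fams(), ["g1", "g2", "g3"])
        assert dict(zip(m.taxa, m.rows)) == {"g1": "10", "g2": "11", "g3": "01"}

    def test_singleton_family_column(self):
        fams = self.fams() + [GeneFamily("F3", "homolog", frozenset({("g1", "x")}))]
        m = build_content_matrix(fams, ["g1", "g2", "g3"])
        assert [r[2] for r in m.rows] == ["1", "0", "0"]

    def test_multicopy_still_presence(self):
        fams = [
            GeneFamily("F1", "homolog", frozenset({("g1", "a"), ("g1", "a2"), ("g2", "b")}))
        ]
        m = build_content_matrix(fams, ["g1", "g2"])
        assert dict(zip(m.taxa, m.rows)) == {"g1": "1", "g2": "1"}

    def test_column_sums_equal_family_coverage(self):
        fams = self.fams()
        m = build_content_matrix(fams, ["g1", "g2", "g3"])
        sums = [sum(int(r[i]) for r in m.rows) for i in range(m.width)]
        coverage = [len(f.genomes()) for f in sorted(fams, key=lambda f: f.family_id)]
        assert sums == coverage


class TestReduceMatrix:
    def quartet_matrix(self):
        """Six taxa; f_good perfectly supports a clean split, f_bad is constant."""
        taxa = [f"t{i}" for i in range(6)]
        good = {t: ("AAAAAAAAAA" if i < 3 else "CCCCCCCCCC") for i, t in enumerate(taxa)}
        bad = {t: "DDDDDDDDDD" for t in taxa}
        rows = [good[t] + bad[t] for t in taxa]
        return CharacterMatrix(
            taxa=taxa, rows=rows, alphabet="protein",
            partitions=[("f_bad_x", 0, 10, "f_bad_x"), ("f_bad", 10, 20, "f_bad")],
        )

    def test_informative_partition_kept_constant_dropped(self):
        taxa = [f"t{i}" for i in range(6)]
        good_rows = ["AAAAAAAAAA" if i < 3 else "CCCCCCCCCC" for i in range(6)]
        const_rows = ["DDDDDDDDDD"] * 6
        m = CharacterMatrix(
            taxa=taxa,
            rows=[g + c for g, c in zip(good_rows, const_rows)],
            alphabet="protein",
            partitions=[("f_good", 0, 10, "f_good"), ("f_const", 10, 20, "f_const")],
        )
        red = reduce_matrix(m, quartets_per_partition=50, min_info=0.25, seed=0)
        assert [p[0] for p in red.partitions] == ["f_good"]

    def test_protection_rule_keeps_sole_coverage(self):
        # t5 has data only in the constant partition: it must be retained
        taxa = [f"t{i}" for i in range(6)]
        rows = []
        for i, t in enumerate(taxa):
            good = ("AAAAAAAAAA" if i < 3 else "CCCCCCCCCC") if i < 5 else "?" * 10
            const = "DDDDDDDDDD"
            rows.append(good + const)
        m = CharacterMatrix(
            taxa=taxa, rows=rows, alphabet="protein",
            partitions=[("f_good", 0, 10, "f_good"), ("f_const", 10, 20, "f_const")],
        )
        red = reduce_matrix(m, quartets_per_partition=50, min_info=0.25, seed=0)
        assert {p[0] for p in red.partitions} == {"f_good", "f_const"}
        for t in taxa:
            assert red.nonmissing_width(t) > 0

    def test_deterministic_given_seed(self):
        m = self.quartet_matrix()
        r1 = reduce_matrix(m, seed=3)
        r2 = reduce_matrix(m, seed=3)
        assert r1.rows == r2.rows and r1.partitions == r2.partitions

    def test_small_partition_scores_zero(self):
        # fewer than 4 taxa with data in a partition -> score 0 -> dropped
        taxa = [f"t{i}" for i in range(6)]
        rows = []
        for i, t in enumerate(taxa):
            good = "AAAAAAAAAA" if i < 3 else "CCCCCCCCCC"
            sparse = "EEEEEEEEEE" if i < 3 else "?" * 10
            rows.append(good + sparse)
        m = CharacterMatrix(
            taxa=taxa, rows=rows, alphabet="protein",
            partitions=[("f_good", 0, 10, "f_good"), ("f_sparse", 10, 20, "f_sparse")],
        )
        red = reduce_matrix(m, seed=0)
        assert [p[0] for p in red.partitions] == ["f_good"]


class TestCharacterMatrixInvariants:
    def test_partitions_must_tile(self):
        with pytest.raises(ValueError):
            CharacterMatrix(
                taxa=["a"], rows=["AAAA"], alphabet="protein",
                partitions=[("p1", 0, 2, "f"), ("p2", 3, 4, "f")],
            )

    def test_binary_alphabet_enforced(self):
        with pytest.raises(ValueError):
            CharacterMatrix(taxa=["a"], rows=["01?"], alphabet="binary")
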