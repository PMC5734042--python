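"""k-mer profiles and distances, neighbor joining, Newick, hit filtering."""

import numpy as np
import pandas as pd
import pytest

from aadscan.phylo import (
    DistanceMatrix,
    HitFilter,
    KmerProfile,
    filter_hits,
    kmer_distance,
    kmer_distance_matrix,
    kmer_profile,
    neighbor_joining,
    read_newick,
    write_newick,
)
from aadscan.seq_core import NucleotideSequence
from conftest import random_dna
from helpers_oracles import random_additive_matrix


class TestKmerProfile:
    def test_too_short_sequence_is_empty(self):
        assert len(kmer_profile("ACGT", k=15)) == 0

    def test_length_equals_k(self):
        prof = kmer_profile("ACGTACGTACGTACG", k=15)
        assert len(prof) == 1

    def test_non_repetitive_count(self, rng):
        s = random_dna(rng, 100)
        prof = kmer_profile(s, k=15)
        assert len(prof) == 86  # L - k + 1 when all 15-mers are distinct

    def test_n_containing_kmers_dropped(self):
        prof = kmer_profile("ACGTN" + "ACGTA" * 3, k=5)
        assert all("N" not in m for m in prof.kmers)

    def test_rejects_k_below_one(self):
        with pytest.raises(ValueError):
            kmer_profile("ACGT", k=0)


class TestKmerDistance:
    def test_identical_sequences(self, rng):
        s = random_dna(rng, 200)
        a, b = kmer_profile(s), kmer_profile(s)
        assert kmer_distance(a, b) == 0.0

    def test_disjoint_sequences(self):
        a = kmer_profile("A" * 40, k=15)
        b = kmer_profile("C" * 40, k=15)
        assert kmer_distance(a, b) == 1.0

    def test_hand_enumerated_fraction(self):
        # |A| = 10, |B| = 20, |A & B| = 5 -> d = 1 - 5/10 = 0.5
        a = KmerProfile("a", 3, frozenset(f"A{i:02d}"[:3] for i in range(10)))
        shared = set(list(a.kmers)[:5])
        extra = {f"B{i:02d}"[:3] for i in range(15)}
        b = KmerProfile("b", 3, frozenset(shared | extra))
        assert len(b) == 20
        assert kmer_distance(a, b) == pytest.approx(0.5)
        assert kmer_distance(b, a) == pytest.approx(0.5)

    def test_jaccard_alternative(self):
        a = KmerProfile("a", 3, frozenset({"AAA", "CCC"}))
        b = KmerProfile("b", 3, frozenset({"AAA", "GGG"}))
        assert kmer_distance(a, b, method="jaccard") == pytest.approx(1 - 1 / 3)

    def test_both_empty_is_an_error(self):
        a = KmerProfile("a", 15, frozenset())
        with pytest.raises(ValueError):
            kmer_distance(a, a)

    def test_symmetry_on_random_pairs(self, rng):
        for _ in range(10):
            a = kmer_profile(random_dna(rng, 120))
            b = kmer_profile(random_dna(rng, 150))
            assert kmer_distance(a, b) == kmer_distance(b, a)
            assert 0.0 <= kmer_distance(a, b) <= 1.0


class TestDistanceMatrix:
    def test_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 0.3], [0.2, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.1, 0.3], [0.3, 0.0]]))

    def test_tsv_round_trip(self, tmp_path, rng):
        seqs = [NucleotideSequence(f"s{i}", random_dna(rng, 120)) for i in range(4)]
        dm = kmer_distance_matrix(seqs, k=15)
        dm.to_tsv(tmp_path / "d.tsv")
        back = DistanceMatrix.from_tsv(tmp_path / "d.tsv")
        assert back.labels == dm.labels
        np.testing.assert_allclose(back.values, dm.values, atol=1e-12)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = neighbor_joining(DistanceMatrix(("a", "b", "c"), d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_two_taxa(self):
        tree = neighbor_joining(DistanceMatrix(("a", "b"), np.array([[0, 0.4], [0.4, 0]])))
        assert {t.name for t in tree.tips()} == {"a", "b"}
        assert sum(t.length for t in tree.tips()) == pytest.approx(0.4)

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 7, 8])
    def test_recovers_additive_matrices_exactly(self, n_leaves):
        # path-length oracle: distances measured on a random tree must be
        # reproduced patristically by the NJ reconstruction
        r = np.random.default_rng(n_leaves * 7 + 1)
        for _ in range(4):
            labels, mat = random_additive_matrix(r, n_leaves)
            tree = neighbor_joining(DistanceMatrix(tuple(labels), mat))
            got = tree.tip_tip_distances(endpoints=labels)
            want = DistanceMatrix(tuple(labels), mat).to_skbio().filter(labels)
            np.testing.assert_allclose(
                got.data, want.data, rtol=1e-9, atol=1e-9
            )

    def test_agrees_with_independent_nj_topology(self):
        from skbio.tree import nj as skbio_nj

        r = np.random.default_rng(42)
        for _ in range(5):
            labels, mat = random_additive_matrix(r, 6)
            dm = DistanceMatrix(tuple(labels), mat)
            ours = neighbor_joining(dm)
            theirs = skbio_nj(dm.to_skbio())
            assert ours.compare_rfd(theirs) == 0.0

    def test_identical_rows_join_first_with_zero_pendants(self):
        d = np.array(
            [
                [0.0, 0.0, 0.8, 0.9],
                [0.0, 0.0, 0.8, 0.9],
                [0.8, 0.8, 0.0, 0.5],
                [0.9, 0.9, 0.5, 0.0],
            ]
        )
        tree = neighbor_joining(DistanceMatrix(("a", "b", "c", "d"), d))
        a = [t for t in tree.tips() if t.name == "a"][0]
        b = [t for t in tree.tips() if t.name == "b"][0]
        assert a.parent is b.parent  # joined first
        assert a.length == 0.0 and b.length == 0.0

    def test_leaf_set_matches_matrix(self, rng):
        seqs = [NucleotideSequence(f"s{i}", random_dna(rng, 150)) for i in range(6)]
        dm = kmer_distance_matrix(seqs)
        tree = neighbor_joining(dm)
        assert {t.name for t in tree.tips()} == set(dm.labels)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(
                DistanceMatrix(("a", "b"), np.array([[0.0, 0.1], [0.2, 0.0]]))
            )


class TestHitFilter:
    def make_table(self):
        return pd.DataFrame(
            [
                # species, score, length, rank
                ("sp1", 100.0, 400, 1),
                ("sp1", 90.0, 300, 2),
                ("sp2", 59.0, 400, 1),   # score below 60: dropped
                ("sp2", 80.0, 150, 2),   # length not strictly > 150: dropped
                ("sp3", 61.0, 151, 2),
                ("sp3", 200.0, 100, 1),  # top-ranked but too short
            ],
            columns=["species", "score", "length", "rank"],
        )

    def test_toy_table_by_hand(self):
        out = filter_hits(self.make_table())
        # sp1 keeps its rank-1 hit; sp2 loses both; sp3 keeps the rank-2 hit
        assert set(out["species"]) == {"sp1", "sp3"}
        assert out.set_index("species").loc["sp1", "rank"] == 1
        assert out.set_index("species").loc["sp3", "rank"] == 2

    def test_score_59_dropped(self):
        t = pd.DataFrame(
            [("x", 59.0, 500, 1)], columns=["species", "score", "length", "rank"]
        )
        assert filter_hits(t).empty

    def test_length_150_dropped_strict(self):
        t = pd.DataFrame(
            [("x", 99.0, 150, 1)], columns=["species", "score", "length", "rank"]
        )
        assert filter_hits(t).empty

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            filter_hits(pd.DataFrame({"species": ["x"]}))

    def test_one_per_species_off_keeps_all_passing(self):
        out = filter_hits(self.make_table(), HitFilter(one_per_species=False))
        assert len(out) == 3


class TestNewick:
    def test_two_leaf_form(self):
        tree = neighbor_joining(
            DistanceMatrix(("A", "B"), np.array([[0, 0.6], [0.6, 0]]))
        )
        nwk = write_newick(tree)
        assert nwk.startswith("(") and nwk.endswith(";")
        assert "A:0.3" in nwk and "B:0.3" in nwk

    def test_round_trip_twenty_random_trees(self):
        r = np.random.default_rng(5)
        for i in range(20):
            from helpers_oracles import random_additive_matrix

            labels, mat = random_additive_matrix(r, int(r.integers(4, 9)))
            tree = neighbor_joining(DistanceMatrix(tuple(labels), mat))
            back = read_newick(write_newick(tree))
            assert back.compare_rfd(tree) == 0.0
            got = {t.name: t.length for t in back.tips()}
            want = {t.name: t.length for t in tree.tips()}
            for name in want:
                assert got[name] == pytest.approx(want[name], abs=1e-6)

    def test_unlabeled_internal_nodes_tolerated(self):
        tree = read_newick("((A:1,B:2):0.5,C:3);")
        assert {t.name for t in tree.tips()} == {"A", "B", "C"}

    def test_malformed_string_rejected(self):
        with pytest.raises(ValueError):
            read_newick("((A:1,B:2;")
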