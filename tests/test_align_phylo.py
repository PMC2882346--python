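import random

import numpy as np
import pytest

from parablade.align_phylo import (AlignmentParams, DistanceMatrix,
                                   DomainPartition, build_distance_matrix,
                                   domain_identity_matrix, nj_tree,
                                   pairwise_align, percent_identity,
                                   progressive_msa, _parse_newick)
from parablade.seqio import ProteinSequence

from _oracles import enumerate_alignment_optimum, random_additive_tree


class TestPairwiseAlign:
    def test_identical_sequences_score_is_diagonal_sum(self, blosum62):
        aln, score = pairwise_align("ACD", "ACD")
        assert score == 19  # 4 + 9 + 6
        assert aln.rows == [("seq1", "ACD"), ("seq2", "ACD")]

    def test_empty_vs_sequence_costs_one_gap_run(self):
        aln, score = pairwise_align("", "ACD")
        assert score == -(10 + 2 * 0.5)
        assert aln.rows[0][1] == "---"

    @pytest.mark.parametrize("s1,s2", [("ACD", "AD"), ("WKY", "WY"),
                                       ("AAA", "A"), ("KDEL", "KEL")])
    def test_matches_exhaustive_enumeration(self, blosum62, s1, s2):
        _, score = pairwise_align(s1, s2)
        expected = enumerate_alignment_optimum(s1, s2, blosum62.score, 10, 0.5)
        assert score == pytest.approx(expected)

    def test_random_pairs_match_enumeration(self, blosum62):
        rng = random.Random(42)
        letters = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(60):
            s1 = "".join(rng.choice(letters) for _ in range(rng.randint(1, 5)))
            s2 = "".join(rng.choice(letters) for _ in range(rng.randint(1, 5)))
            _, score = pairwise_align(s1, s2)
            expected = enumerate_alignment_optimum(s1, s2, blosum62.score, 10, 0.5)
            assert score == pytest.approx(expected), (s1, s2)

    def test_alignment_rows_ungap_to_inputs(self):
        aln, _ = pairwise_align("ACDEFG", "ACFG")
        assert aln.rows[0][1].replace("-", "") == "ACDEFG"
        assert aln.rows[1][1].replace("-", "") == "ACFG"

    def test_gap_params_validated(self):
        with pytest.raises(ValueError):
            AlignmentParams(gap_open=0.1, gap_extend=0.5)


class TestPercentIdentity:
    @pytest.mark.parametrize("r1,r2,expected", [
        ("ACDK", "ACDK", 100.0),
        ("AAAA", "VVVV", 0.0),
        ("ACFD", "ACED", 75.0),
        ("AC--", "ACDE", 100.0),  # terminal gaps excluded from denominator
    ])
    def test_values(self, r1, r2, expected):
        assert percent_identity(r1, r2) == pytest.approx(expected)

    def test_no_comparable_columns_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert percent_identity("A-", "-A") == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            percent_identity("AC", "ACD")


class TestDomainIdentityMatrix:
    def _partition(self, length, split):
        return DomainPartition([("N", 1, split), ("C", split + 1, length)])

    def test_identical_sequences_all_domains_100(self):
        seqs = [ProteinSequence("a", "ACDKWE"), ProteinSequence("b", "ACDKWE")]
        parts = {"a": self._partition(6, 3), "b": self._partition(6, 3)}
        dim = domain_identity_matrix(seqs, parts)
        for dom in ("N", "C"):
            assert dim.get("a", "b", dom) == 100.0

    def test_hand_computed_cells(self):
        # gap-free alignable domains: N identity 2/3, C identity 1/3
        seqs = [ProteinSequence("a", "ACDKWE"), ProteinSequence("b", "ACWKYD")]
        parts = {"a": self._partition(6, 3), "b": self._partition(6, 3)}
        dim = domain_identity_matrix(seqs, parts)
        assert dim.get("a", "b", "N") == pytest.approx(100 * 2 / 3)
        assert dim.get("a", "b", "C") == pytest.approx(100 * 1 / 3)

    def test_symmetry_and_bounds(self):
        rng = random.Random(7)
        letters = "ACDEFGHIKLMNPQRSTVWY"
        seqs = [ProteinSequence(f"s{i}",
                                "".join(rng.choice(letters) for _ in range(12)))
                for i in range(3)]
        parts = {s.id: self._partition(12, 5) for s in seqs}
        dim = domain_identity_matrix(seqs, parts)
        for p1 in dim.proteins:
            for p2 in dim.proteins:
                for dom in dim.domains:
                    v = dim.get(p1, p2, dom)
                    assert 0 <= v <= 100
                    assert v == dim.get(p2, p1, dom)
                    if p1 == p2:
                        assert v == 100.0

    def test_missing_partition_is_error(self):
        seqs = [ProteinSequence("a", "ACD"), ProteinSequence("b", "ACD")]
        with pytest.raises(KeyError):
            domain_identity_matrix(seqs, {"a": self._partition(3, 1)})


class TestDistanceMatrix:
    def test_identity_transform(self):
        seqs = [ProteinSequence("a", "AAAA"), ProteinSequence("b", "AAAA"),
                ProteinSequence("c", "VVVV")]
        dm = build_distance_matrix(seqs)
        assert dm.get("a", "b") == 0.0
        assert dm.get("a", "c") == 1.0

    def test_quarter_distance(self):
        seqs = [ProteinSequence("a", "ACFD"), ProteinSequence("b", "ACED"),
                ProteinSequence("c", "WWWW")]
        dm = build_distance_matrix(seqs)
        assert dm.get("a", "b") == pytest.approx(0.25)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            build_distance_matrix([ProteinSequence("a", "ACD"),
                                   ProteinSequence("b", "ACD")])


def _pendant_lengths(newick):
    root = _parse_newick(newick)
    return {leaf.name: leaf.length for leaf in root.leaves()}


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = nj_tree(dm)
        assert _pendant_lengths(tree.newick()) == {"a": 1.0, "b": 1.0, "c": 3.0}

    def test_four_taxon_additive_recovery(self):
        d = np.array([[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], float)
        tree = nj_tree(DistanceMatrix(list("ABCD"), d))
        import dendropy
        tns = dendropy.TaxonNamespace()
        got = dendropy.Tree.get(data=tree.newick(), schema="newick",
                                taxon_namespace=tns)
        want = dendropy.Tree.get(data="((A:1,B:1):2,(C:1,D:1):0);",
                                 schema="newick", taxon_namespace=tns)
        got.encode_bipartitions()
        want.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(got, want) == 0
        # pendant branch lengths recover the generating distances exactly
        assert _pendant_lengths(tree.newick()) == {"A": 1.0, "B": 1.0,
                                                   "C": 1.0, "D": 1.0}

    def test_random_additive_trees_recovered(self):
        import dendropy
        from dendropy.calculate import treecompare
        rng = random.Random(11)
        for trial in range(30):
            n = rng.randint(4, 8)
            true_newick, taxa, dist = random_additive_tree(n, rng)
            tree = nj_tree(DistanceMatrix(taxa, np.array(dist)))
            tns = dendropy.TaxonNamespace()
            got = dendropy.Tree.get(data=tree.newick(), schema="newick",
                                    taxon_namespace=tns)
            want = dendropy.Tree.get(data=true_newick, schema="newick",
                                     taxon_namespace=tns)
            got.encode_bipartitions()
            want.encode_bipartitions()
            assert treecompare.symmetric_difference(got, want) == 0, trial

    def test_outgroup_rooting(self):
        dm = DistanceMatrix(["a", "b", "out"],
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = nj_tree(dm, outgroup="out")
        assert tree.root.children[0].name == "out" or \
            tree.root.children[1].name == "out"
        assert len(tree.root.children) == 2

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestProgressiveMSA:
    def test_identical_sequences_no_gaps(self):
        seqs = [ProteinSequence(f"s{i}", "ACDKWE") for i in range(3)]
        msa = progressive_msa(seqs)
        assert all("-" not in row for _, row in msa.rows)

    def test_two_sequences_equal_pairwise(self):
        s = [ProteinSequence("a", "ACDEFG"), ProteinSequence("b", "ACFG")]
        msa = progressive_msa(s)
        pair, _ = pairwise_align(s[0], s[1])
        assert msa.rows == pair.rows

    def test_induced_pair_matches_pairwise(self):
        seqs = [ProteinSequence("a", "ACDEFG"), ProteinSequence("b", "ACFG"),
                ProteinSequence("c", "ACDEFG")]
        msa = progressive_msa(seqs)
        pair, _ = pairwise_align(seqs[0], seqs[1])
        # project the MSA onto rows a and b, dropping all-gap columns
        ra, rb = msa.row("a"), msa.row("b")
        proj = [(x, y) for x, y in zip(ra, rb) if not (x == "-" and y == "-")]
        want = list(zip(pair.rows[0][1], pair.rows[1][1]))
        assert proj == want

    def test_input_order_invariance_up_to_reordering(self):
        seqs = [ProteinSequence("a", "ACDEFGHIK"), ProteinSequence("b", "ACDFGHIK"),
                ProteinSequence("c", "ACDEFGHIW"), ProteinSequence("d", "CDEFGHIK")]
        msa1 = progressive_msa(seqs)
        msa2 = progressive_msa(list(reversed(seqs)))
        assert dict(msa1.rows) == dict(msa2.rows)

    def test_rows_ungap_to_inputs(self):
        seqs = [ProteinSequence("a", "ACDEFG"), ProteinSequence("b", "ACFG"),
                ProteinSequence("c", "ADEFG")]
        msa = progressive_msa(seqs)
        for s in seqs:
            assert msa.ungapped(s.id) == s.residues
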