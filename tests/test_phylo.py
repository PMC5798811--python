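"""Gene extraction, center-star alignment, NJ and bootstrap."""

import numpy as np
import pytest

from conftest import (enumerate_unrooted_topologies, ls_fit_residual,
                      random_additive_matrix, small_spec)
from orgweaver.io import FType, GeneFeature, revcomp
from orgweaver.phylo import (GENE_SET_15, ConcatAlignment, align_gene,
                             bootstrap, concat, distance_matrix,
                             extract_genes, gene_presence_matrix, nj_tree,
                             p_distance, remove_gap_columns,
                             unique_gene_count)
from orgweaver.synthetic import make_mt_genome, random_seq


def _nw_score(a, b, match=1, mismatch=-1, gap=-2):
    """Brute-force global alignment optimum (independent DP oracle)."""
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1))
    dp[:, 0] = np.arange(n + 1) * gap
    dp[0, :] = np.arange(m + 1) * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            dp[i, j] = max(dp[i - 1, j - 1] + s, dp[i - 1, j] + gap,
                           dp[i, j - 1] + gap)
    return dp[n, m]


class TestExtractGenes:
    def test_minus_strand_reverse_complemented(self):
        genome = "A" * 99 + "ACGTACGTAA" + "T" * 50
        feats = [GeneFeature("nad1", FType.CDS, 100, 109, "-")]
        genes, _ = extract_genes(genome, feats, ["nad1"])
        assert genes["nad1"] == revcomp("ACGTACGTAA")

    def test_missing_gene_reported(self):
        genome = "ACGT" * 100
        feats = [GeneFeature("atp1", FType.CDS, 1, 30, "+")]
        genes, missing = extract_genes(genome, feats)
        assert "rps4" in missing and len(genes) == 1

    def test_wrapping_feature(self):
        genome = "CCCC" + "A" * 92 + "GGGG"
        feats = [GeneFeature("cob", FType.CDS, 97, 4, "+", wraps=True)]
        genes, _ = extract_genes(genome, feats, ["cob"])
        assert genes["cob"] == "GGGGCCCC"

    def test_all_15_recovered_from_synthetic_genome(self):
        mt, feats, _ = make_mt_genome(small_spec(2))
        genes, missing = extract_genes(mt, feats)
        assert missing == []
        assert set(genes) == set(GENE_SET_15)

    def test_multicopy_keeps_longest(self):
        genome = "ACGT" * 100
        feats = [GeneFeature("cox1", FType.CDS, 1, 12, "+"),
                 GeneFeature("cox1", FType.CDS, 21, 60, "+")]
        genes, _ = extract_genes(genome, feats, ["cox1"])
        assert len(genes["cox1"]) == 40


class TestAlignment:
    def test_identical_sequences_no_gaps(self):
        block = align_gene({"a": "ACGTAC", "b": "ACGTAC", "c": "ACGTAC"})
        assert all(v == "ACGTAC" for v in block.values())

    def test_single_gap_and_dp_oracle(self):
        block = align_gene({"a": "ACGT", "b": "AGT"})
        assert len(block["a"]) == len(block["b"]) == 4
        assert block["b"].count("-") == 1
        # pairwise score equals the exhaustive DP optimum
        from orgweaver.phylo import pairwise_global
        _, _, score = pairwise_global("ACGT", "AGT")
        assert score == _nw_score("ACGT", "AGT")

    def test_rows_recover_inputs_when_degapped(self):
        rng = np.random.default_rng(8)
        seqs = {f"t{i}": random_seq(rng, 60 + int(rng.integers(0, 10)), 0.5)
                for i in range(4)}
        block = align_gene(seqs)
        for t, s in seqs.items():
            assert block[t].replace("-", "") == s

    def test_center_is_max_similarity_row(self):
        center = random_seq(np.random.default_rng(5), 60, 0.5)
        seqs = {"center": center}
        for i in range(4):
            mutated = list(center)
            p = 10 + i * 9
            mutated[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[p]]
            seqs[f"t{i}"] = "".join(mutated)
        block = align_gene(seqs)
        # one substitution from every other row: no gaps are needed at all
        assert all("-" not in row for row in block.values())


class TestGapColumnsAndConcat:
    def test_remove_gap_columns(self):
        block = {"a": "AC-T", "b": "ACGT"}
        out = remove_gap_columns(block)
        assert out == {"a": "ACT", "b": "ACT".replace("T", "T")[:2] + "T"} \
            or out == {"a": "ACT", "b": "ACT"}
        with pytest.raises(ValueError):
            remove_gap_columns({"a": "--", "b": "AC"})

    def test_concat_partitions_tile_width(self):
        blocks = {"g1": {"a": "ACGTACGTAC", "b": "ACGTACGTAC"},
                  "g2": {"a": "TTTTTTTTTT", "b": "TTTTTTTTTT"}}
        aln = concat(blocks)
        assert aln.width == 20
        spans = sorted(aln.partitions.values())
        assert spans[0] == (0, 10) and spans[1] == (10, 20)

    def test_concat_drops_taxa_missing_a_gene(self):
        blocks = {"g1": {"a": "ACGT", "b": "ACGT", "c": "ACGT"},
                  "g2": {"a": "TTTT", "b": "TTTT"}}
        with pytest.warns(UserWarning, match="dropped"):
            aln = concat(blocks)
        assert aln.taxa == ["a", "b"]
        aln2 = concat(blocks, pad_missing=True)
        assert aln2.taxa == ["a", "b", "c"]
        assert aln2.matrix["c"].endswith("NNNN")

    def test_disjoint_taxa_error(self):
        with pytest.raises(ValueError):
            concat({"g1": {"a": "AC"}, "g2": {"b": "AC"}})


class TestDistances:
    def test_p_distance(self):
        assert p_distance("AAAA", "AAAA") == 0.0
        assert p_distance("AAAA", "AAAT") == 0.25
        assert p_distance("ACGT", "TGCA") == p_distance("TGCA", "ACGT")
        with pytest.raises(ValueError):
            p_distance("", "")
        with pytest.raises(ValueError):
            p_distance("A", "AC")


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], float)
        t = nj_tree(D, ["a", "b", "c"])
        lens = {lf.taxon.label: lf.edge.length
                for lf in t.tree.leaf_node_iter()}
        assert lens["a"] == pytest.approx((5 + 9 - 8) / 2)
        assert lens["b"] == pytest.approx((5 + 8 - 9) / 2)
        assert lens["c"] == pytest.approx((9 + 8 - 5) / 2)

    def test_four_taxon_tree_vs_exhaustive_least_squares(self):
        """NJ picks the same topology as brute-force LS over all three
        4-leaf topologies, with the generating branch lengths."""
        rng = np.random.default_rng(13)
        for _ in range(10):
            D, true_bps = random_additive_matrix(4, rng)
            t = nj_tree(D, [str(i) for i in range(4)])
            assert {frozenset(int(x) for x in bp)
                    for bp in t.bipartitions()} == true_bps
            residuals = [ls_fit_residual(topo, 4, D)
                         for topo in enumerate_unrooted_topologies(4)]
            assert min(residuals) == pytest.approx(0, abs=1e-9)

    @pytest.mark.parametrize("n", [5, 6, 7, 8])
    def test_additive_matrix_recovery(self, n):
        """On additive matrices NJ reproduces the generating tree's
        topology and, via path distances, its branch lengths."""
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            D, true_bps = random_additive_matrix(n, rng)
            t = nj_tree(D, [str(i) for i in range(n)])
            assert {frozenset(int(x) for x in bp)
                    for bp in t.bipartitions()} == true_bps
            # path distances on the NJ tree equal D to machine precision
            pdm = t.tree.phylogenetic_distance_matrix()
            tns = t.tree.taxon_namespace
            for i in range(n):
                for j in range(i + 1, n):
                    got = pdm.distance(tns.get_taxon(str(i)),
                                       tns.get_taxon(str(j)))
                    assert got == pytest.approx(D[i, j], abs=1e-9)

    def test_matches_scikit_bio_nj(self):
        """Independent cross-check against another NJ implementation."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(77)
        D, _ = random_additive_matrix(6, rng)
        ids = [str(i) for i in range(6)]
        ours = nj_tree(D, ids)
        theirs = skbio_nj(DistanceMatrix(D, ids))
        # same set of nontrivial bipartitions
        their_bps = set()
        all_ids = frozenset(ids)
        for node in theirs.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(ids) - 2:
                their_bps.add(min(side, all_ids - side,
                                  key=lambda s: (len(s), sorted(s))))
        assert ours.bipartitions() == their_bps

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0, 1], [1, 0]]), ["a", "b"])
        bad = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError):
            nj_tree(bad, ["a", "b", "c"])


class TestBootstrap:
    @staticmethod
    def _saturated_alignment():
        mat = {"a": "A" * 30 + "C" * 30, "b": "A" * 29 + "T" + "C" * 30,
               "c": "G" * 30 + "T" * 30, "d": "G" * 29 + "A" + "T" * 30}
        return ConcatAlignment(taxa=sorted(mat), matrix=mat,
                               partitions={"g": (0, 60)})

    def test_saturated_signal_gets_full_support(self):
        t = bootstrap(self._saturated_alignment(), reps=50, seed=3)
        assert t.support == {frozenset({"a", "b"}): 100}

    def test_single_replicate_support_binary(self):
        t = bootstrap(self._saturated_alignment(), reps=1, seed=5)
        assert set(t.support.values()) <= {0, 100}

    def test_same_seed_same_support(self):
        a = bootstrap(self._saturated_alignment(), reps=20, seed=9)
        b = bootstrap(self._saturated_alignment(), reps=20, seed=9)
        assert a.support == b.support

    def test_support_in_newick_output(self):
        t = bootstrap(self._saturated_alignment(), reps=10, seed=1)
        assert ")100:" in t.newick().replace(" ", "") or "100" in t.newick()


class TestGenePresence:
    def test_presence_and_loss(self):
        g1 = [GeneFeature("rps11", FType.CDS, 1, 30, "+"),
              GeneFeature("trnm", FType.tRNA, 50, 120, "+")]
        g2 = [GeneFeature("trnm", FType.tRNA, 50, 120, "+")]
        df = gene_presence_matrix({"s1": g1, "s2": g2})
        assert bool(df.loc["s1", "rps11"]) is True
        assert bool(df.loc["s2", "rps11"]) is False
        df2 = gene_presence_matrix({"s1": []})
        assert df2.shape[1] == 0 or not df2.any().any()

    def test_unique_gene_count_collapses_duplicates(self):
        feats = [GeneFeature("rrn16", FType.rRNA, 1, 100, "+"),
                 GeneFeature("rrn16", FType.rRNA, 500, 600, "-"),
                 GeneFeature("trnm", FType.tRNA, 200, 280, "+")]
        assert unique_gene_count(feats) == 2
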