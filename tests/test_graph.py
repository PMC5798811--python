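"""Contig-graph construction, pruning, multiplicity and traversal."""

import pytest

from conftest import (enumerate_closed_walks, same_circular_sequence,
                      small_spec)
from orgweaver.binning import Bin, BinAssignment, bin_contigs
from orgweaver.graph import (Orientation, OrientedContig, OrganellePath,
                             build_graph, estimate_multiplicity,
                             path_to_sequence, prune_false_links,
                             reference_guided_order, traverse)
from orgweaver.io import ContigEdge, ContigRecord, End, revcomp
from orgweaver.synthetic import (fragment_to_contigs, make_cp_genome,
                                 make_mt_genome)


def _contig(cid, depth, length=1000, seq=None):
    return ContigRecord(cid, f"c{cid}", length if seq is None else len(seq),
                        depth, sequence=seq)


def _assign(contigs, bins):
    return [BinAssignment(c.contig_id, bins[c.contig_id], c.depth)
            for c in contigs]


class TestBuildGraph:
    def test_bin_restriction(self):
        contigs = [_contig("1", 70), _contig("2", 72), _contig("3", 68),
                   _contig("4", 2)]
        edges = [ContigEdge("1", End.THREE, "2", End.FIVE, 30),
                 ContigEdge("2", End.THREE, "3", End.FIVE, 30),
                 ContigEdge("3", End.THREE, "4", End.FIVE, 5)]
        bins = {"1": Bin.MT, "2": Bin.MT, "3": Bin.MT, "4": Bin.NUCLEAR}
        g = build_graph(contigs, edges, Bin.MT, _assign(contigs, bins))
        assert sorted(g.contigs) == ["1", "2", "3"]
        assert len(g.edges) == 2

    def test_cp_like_contig_retained_in_mt_graph(self):
        """A chloroplast-depth contig inside a mitochondrial chain is kept
        (cp->mt transferred DNA) but labeled CP_LIKE and never seeded."""
        contigs = [_contig("1", 70), _contig("2", 130), _contig("3", 72),
                   _contig("4", 68)]
        edges = [ContigEdge("1", End.THREE, "2", End.FIVE, 30),
                 ContigEdge("2", End.THREE, "3", End.FIVE, 30),
                 ContigEdge("3", End.THREE, "4", End.FIVE, 30)]
        bins = {"1": Bin.MT, "2": Bin.CP, "3": Bin.MT, "4": Bin.MT}
        g = build_graph(contigs, edges, Bin.MT, _assign(contigs, bins))
        assert sorted(g.contigs) == ["1", "2", "3", "4"]
        assert g.labels["2"] == "CP_LIKE"
        g2 = build_graph(contigs, edges, Bin.MT, _assign(contigs, bins),
                         allow_cp_like_in_mt=False)
        assert "2" not in g2.contigs

    def test_empty_bin_errors(self):
        contigs = [_contig("1", 2)]
        with pytest.raises(ValueError, match="no candidate contigs"):
            build_graph(contigs, [], Bin.CP,
                        _assign(contigs, {"1": Bin.NUCLEAR}))


class TestPruneAndMultiplicity:
    def test_depth_ratio_pruning(self):
        contigs = [_contig("1", 70), _contig("2", 500)]
        edges = [ContigEdge("1", End.THREE, "2", End.FIVE, 30)]
        bins = {"1": Bin.MT, "2": Bin.CP}
        g = build_graph(contigs, edges, Bin.MT, _assign(contigs, bins))
        g2 = prune_false_links(g, depth_ratio_max=3.0)
        assert g2.edges == []
        assert sorted(g2.contigs) == ["1", "2"]  # nodes untouched

    def test_multiplicity_explains_depth_ratio(self):
        """60x joined to 120x survives when the 120x contig is a collapsed
        two-copy repeat (adjusted ratio 60/60 = 1)."""
        contigs = [_contig("1", 60), _contig("2", 120), _contig("3", 58),
                   _contig("4", 62)]
        edges = [ContigEdge("1", End.THREE, "2", End.FIVE, 30)]
        bins = {c.contig_id: Bin.MT for c in contigs}
        bins["2"] = Bin.MT
        g = build_graph(contigs, edges, Bin.MT, _assign(contigs, bins))
        mult = estimate_multiplicity(g)
        assert mult["2"].copy_number == 2
        g2 = prune_false_links(g, depth_ratio_max=3.0, multiplicities=mult)
        assert len(g2.edges) == 1

    def test_min_edge_depth(self):
        contigs = [_contig("1", 70), _contig("2", 71)]
        edges = [ContigEdge("1", End.THREE, "2", End.FIVE, 1)]
        bins = {"1": Bin.MT, "2": Bin.MT}
        g = build_graph(contigs, edges, Bin.MT, _assign(contigs, bins))
        assert prune_false_links(g, min_edge_depth=2).edges == []

    def test_multiplicity_median_baseline(self):
        """depths {70, 72, 68, 140} -> baseline 71, copies {1,1,1,2}."""
        contigs = [_contig("1", 70), _contig("2", 72), _contig("3", 68),
                   _contig("4", 140)]
        bins = {c.contig_id: Bin.MT for c in contigs}
        g = build_graph(contigs, [], Bin.MT, _assign(contigs, bins))
        mult = estimate_multiplicity(g)
        assert mult["1"].baseline_depth == 71
        assert [mult[c].copy_number for c in "1234"] == [1, 1, 1, 2]

    def test_multiplicity_degenerate_cases(self):
        contigs = [_contig("1", 70)]
        g = build_graph(contigs, [], Bin.MT,
                        _assign(contigs, {"1": Bin.MT}))
        assert estimate_multiplicity(g)["1"].copy_number == 1


class TestTraverse:
    def test_self_edge_single_contig_circle(self):
        contigs = [_contig("1", 70, seq="ACGT")]
        edges = [ContigEdge("1", End.THREE, "1", End.FIVE, 10)]
        g = build_graph(contigs, edges, Bin.MT,
                        _assign(contigs, {"1": Bin.MT}))
        res = traverse(g)
        assert len(res.paths) == 1
        p = res.paths[0]
        assert p.circular
        assert p.steps == [OrientedContig("1", Orientation.FWD)]
        assert path_to_sequence(p, g.contigs) == "ACGT"

    def test_four_contig_cycle_with_flip(self):
        """Cycle where one contig's stored strand is reversed: polarity
        3'-3' / 5'-5' junctions force a REV step; verified against the
        exhaustive closed-walk enumeration."""
        contigs = [_contig(c, 70, seq=s) for c, s in
                   [("1", "ACGTACGTAA"), ("2", "GGGTTTACGC"),
                    ("3", "TTCAGGACGT"), ("4", "CATCATCCCC")]]
        # genome order 1 fwd, 2 rev, 3 fwd, 4 fwd
        edges = [ContigEdge("1", End.THREE, "2", End.THREE, 30),
                 ContigEdge("2", End.FIVE, "3", End.FIVE, 31),
                 ContigEdge("3", End.THREE, "4", End.FIVE, 29),
                 ContigEdge("4", End.THREE, "1", End.FIVE, 32)]
        bins = {c.contig_id: Bin.MT for c in contigs}
        g = build_graph(contigs, edges, Bin.MT, _assign(contigs, bins))
        res = traverse(g)
        assert len(res.paths) == 1 and res.paths[0].circular
        oris = {s.contig_id: s.orientation for s in res.paths[0].steps}
        assert oris["2"] is Orientation.REV
        assert {c for c, o in oris.items() if o is Orientation.FWD} \
            == {"1", "3", "4"}
        # oracle: the traversal is one of the enumerated closed walks and
        # achieves the maximal edge-depth sum
        walks = enumerate_closed_walks(
            contigs, edges, {c.contig_id: 1 for c in contigs}, "1")
        assert walks
        best = max(w[0] for w in walks)
        assert sorted(s.contig_id for s in res.paths[0].steps) \
            in [sorted(c for c, _ in w[1]) for w in walks]
        assert best == sum(e.edge_depth for e in edges)

    def test_figure_eight_repeat_resolved(self):
        """A two-copy repeat bridging two loops is walked twice, producing
        a single master circle."""
        contigs = [_contig("A", 70, seq="A" * 50 + "CGT" * 10),
                   _contig("R", 140, seq="CCGGAATTCC" * 6),
                   _contig("B", 72, seq="T" * 40 + "GCA" * 10)]
        edges = [ContigEdge("A", End.THREE, "R", End.FIVE, 30),
                 ContigEdge("R", End.THREE, "B", End.FIVE, 31),
                 ContigEdge("B", End.THREE, "R", End.FIVE, 29),
                 ContigEdge("R", End.THREE, "A", End.FIVE, 28)]
        extra = [_contig("x", 70), _contig("y", 71)]  # stabilize the median
        allc = contigs + extra
        bins = {c.contig_id: Bin.MT for c in allc}
        g = build_graph(allc, edges, Bin.MT, _assign(allc, bins))
        mult = estimate_multiplicity(g)
        assert mult["R"].copy_number == 2
        res = traverse(g, mult)
        master = res.paths[0]
        assert master.circular
        visits = [s.contig_id for s in master.steps]
        assert visits.count("R") == 2
        assert set(visits) == {"A", "R", "B"}
        # matches the exhaustive oracle's depth-maximal closed walk
        walks = enumerate_closed_walks(
            allc, edges, {c.contig_id: mult[c.contig_id].copy_number
                          for c in allc}, "A")
        assert max(w[0] for w in walks) == sum(e.edge_depth for e in edges)
        assert len(master.steps) == 4  # A, R, B, R

    def test_breakpoint_gives_linear_path(self):
        contigs = [_contig("1", 70), _contig("2", 71), _contig("3", 69)]
        edges = [ContigEdge("1", End.THREE, "2", End.FIVE, 30),
                 ContigEdge("2", End.THREE, "3", End.FIVE, 30)]
        bins = {c.contig_id: Bin.MT for c in contigs}
        g = build_graph(contigs, edges, Bin.MT, _assign(contigs, bins))
        res = traverse(g)
        assert len(res.paths) == 1
        assert not res.paths[0].circular
        assert [s.contig_id for s in res.paths[0].steps] == ["1", "2", "3"]

    def test_determinism(self):
        spec = small_spec(9)
        mt, _, _ = make_mt_genome(spec)
        contigs, edges, _ = fragment_to_contigs({"MT": mt}, spec)
        assigns = bin_contigs(contigs)
        g = build_graph(contigs, edges, Bin.MT, assigns)
        r1 = traverse(g)
        r2 = traverse(g)
        assert [(s.contig_id, s.orientation) for p in r1.paths
                for s in p.steps] == [(s.contig_id, s.orientation)
                                      for p in r2.paths for s in p.steps]

    def test_conservation_of_contigs(self):
        """Every bin contig appears in the union of paths + unused report,
        never more often than its copy number."""
        spec = small_spec(11)
        mt, _, _ = make_mt_genome(spec)
        contigs, edges, _ = fragment_to_contigs({"MT": mt}, spec)
        assigns = bin_contigs(contigs)
        g = build_graph(contigs, edges, Bin.MT, assigns)
        mult = estimate_multiplicity(g)
        res = traverse(g, mult)
        from collections import Counter
        used = Counter(s.contig_id for p in res.paths for s in p.steps)
        for cid in g.order:
            assert used[cid] <= mult[cid].copy_number
            assert used[cid] > 0 or cid in res.unused


class TestPathToSequence:
    def test_revcomp_step(self):
        contigs = {"1": _contig("1", 70, seq="ACGT"),
                   "2": _contig("2", 70, seq="AAAC")}
        p = OrganellePath(steps=[OrientedContig("1", Orientation.FWD),
                                 OrientedContig("2", Orientation.REV)])
        assert path_to_sequence(p, contigs) == "ACGT" + "GTTT"

    def test_gap_markers_emit_n_runs(self):
        contigs = {"1": _contig("1", 70, seq="ACGT"),
                   "2": _contig("2", 70, seq="TTTT")}
        p = OrganellePath(steps=[OrientedContig("1", Orientation.FWD),
                                 OrientedContig("2", Orientation.FWD)],
                          gaps=[0])
        assert path_to_sequence(p, contigs, gap_n=5) == "ACGT" + "N" * 5 + "TTTT"

    def test_missing_sequence_names_contig(self):
        contigs = {"1": _contig("1", 70)}
        p = OrganellePath(steps=[OrientedContig("1", Orientation.FWD)])
        with pytest.raises(ValueError, match="1"):
            path_to_sequence(p, contigs)


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(1, 6))
    def test_genome_recovered_up_to_rotation_and_strand(self, seed):
        spec = small_spec(seed)
        cp, _, _ = make_cp_genome(spec)
        mt, _, _ = make_mt_genome(spec)
        contigs, edges, _ = fragment_to_contigs({"CP": cp, "MT": mt}, spec)
        assigns = bin_contigs(contigs)
        for bin_, genome in ((Bin.CP, cp), (Bin.MT, mt)):
            g = build_graph(contigs, edges, bin_, assigns)
            mult = estimate_multiplicity(g)
            g = prune_false_links(g, multiplicities=mult)
            res = traverse(g, mult)
            assert len(res.paths) == 1 and res.paths[0].circular
            seq = path_to_sequence(res.paths[0], g.contigs)
            assert same_circular_sequence(seq, genome)


class TestReferenceGuidedOrder:
    def test_exact_tiling_recovers_reference(self):
        spec = small_spec(4)
        cp, _, _ = make_cp_genome(spec)
        contigs, _, truth = fragment_to_contigs({"CP": cp}, spec)
        path, unanchored = reference_guided_order(contigs, cp)
        assert unanchored == []
        assert path.gaps == []
        # stitched sequence reproduces the reference as a circle
        by_id = {c.contig_id: c for c in contigs}
        seq = path_to_sequence(path, by_id)
        assert same_circular_sequence(seq, cp)

    def test_reverse_complemented_contig_flagged_rev(self):
        ref = "".join("ACGTTGCA"[i % 8] for i in range(3000))
        import numpy as np

        from orgweaver.synthetic import random_seq
        rng = np.random.default_rng(5)
        ref = random_seq(rng, 3000, 0.545)
        contigs = [_contig("1", 120, seq=ref[:1500]),
                   _contig("2", 120, seq=revcomp(ref[1500:]))]
        path, _ = reference_guided_order(contigs, ref, min_anchor=200)
        oris = {s.contig_id: s.orientation for s in path.steps}
        assert oris["1"] is Orientation.FWD
        assert oris["2"] is Orientation.REV

    def test_no_anchor_errors(self):
        contigs = [_contig("1", 120, seq="A" * 600)]
        with pytest.raises(ValueError, match="anchor"):
            reference_guided_order(contigs, "CGCGTATA" * 200)
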