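"""End-polarity contig graph and the organelle path traversal.

Nodes are contigs; an edge joins a specific end (5' or 3') of one contig to
a specific end of another, and carries the number of reads spanning the
junction. A traversal walks oriented contigs: a forward contig is entered at
its 5' end and exited at its 3' end, a reversed contig the other way round.

The assembly procedure is: restrict the graph to one depth bin (keeping
chloroplast-depth contigs that touch mitochondrial paths, since cp->mt DNA
transfer makes them genuine mitochondrial sequence), drop edges that are
weakly supported or join contigs of incompatible depth, estimate per-contig
copy number from depth, and then extend greedily from a seed contig in both
directions, resolving forks by edge depth, until the walk closes into a
circle or breaks. Every step is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from statistics import median
from typing import Sequence

from .binning import Bin, BinAssignment
from .io import ContigEdge, ContigRecord, End, revcomp


class Orientation(str, Enum):
    FWD = "FWD"
    REV = "REV"


@dataclass(frozen=True)
class OrientedContig:
    contig_id: str
    orientation: Orientation

    @property
    def entry_end(self) -> End:
        """End through which the walk enters this contig."""
        return End.FIVE if self.orientation is Orientation.FWD else End.THREE

    @property
    def exit_end(self) -> End:
        return End.THREE if self.orientation is Orientation.FWD else End.FIVE


@dataclass
class OrganellePath:
    """An ordered, oriented contig walk; ``gaps`` lists junction indices
    (between steps[i] and steps[i+1]) not supported by a graph edge."""

    steps: list[OrientedContig]
    circular: bool = False
    gaps: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class MultiplicityEstimate:
    contig_id: str
    copy_number: int
    baseline_depth: float


@dataclass
class ContigGraph:
    """Bin-restricted view of the contig graph.

    ``labels`` maps node id to "CP", "MT", "NUCLEAR" or "CP_LIKE" (a
    chloroplast-depth contig retained inside the mitochondrial graph).
    ``order`` preserves input file order for traversal seeding.
    """

    contigs: dict[str, ContigRecord]
    edges: list[ContigEdge]
    labels: dict[str, str]
    order: list[str]
    bin: Bin

    def adjacency(self) -> dict[tuple[str, End], list[int]]:
        adj: dict[tuple[str, End], list[int]] = {}
        for i, e in enumerate(self.edges):
            adj.setdefault((e.left_id, e.left_end), []).append(i)
            if (e.right_id, e.right_end) != (e.left_id, e.left_end):
                adj.setdefault((e.right_id, e.right_end), []).append(i)
        return adj


def build_graph(contigs: Sequence[ContigRecord], edges: Sequence[ContigEdge],
                bin: Bin, assignments: Sequence[BinAssignment],
                allow_cp_like_in_mt: bool = True) -> ContigGraph:
    """Restrict the full contig graph to one organelle bin.

    For the mitochondrial bin, chloroplast-binned contigs adjacent to at
    least one mitochondrial contig are retained as ``CP_LIKE`` nodes (they
    are frequently real mitochondrial sequence of chloroplast origin) but
    are never used as traversal seeds.
    """
    by_id = {c.contig_id: c for c in contigs}
    bins = {a.contig_id: a.bin for a in assignments}
    missing = set(by_id) - set(bins)
    if missing:
        raise ValueError(f"assignments missing contigs: {sorted(missing)[:5]}")
    keep = [c.contig_id for c in contigs if bins[c.contig_id] is bin]
    labels = {cid: bin.value for cid in keep}
    if bin is Bin.MT and allow_cp_like_in_mt:
        kept = set(keep)
        for e in edges:
            for cid, other in ((e.left_id, e.right_id), (e.right_id, e.left_id)):
                if cid not in kept and bins.get(cid) is Bin.CP and other in kept \
                        and bins[other] is Bin.MT:
                    keep.append(cid)
                    kept.add(cid)
                    labels[cid] = "CP_LIKE"
        # restore file order for the appended cp-like nodes
        keep = [c.contig_id for c in contigs if c.contig_id in kept]
    if not keep:
        raise ValueError(f"no candidate contigs in bin {bin.value}")
    kept_set = set(keep)
    sub_edges = [e for e in edges
                 if e.left_id in kept_set and e.right_id in kept_set]
    return ContigGraph(contigs={cid: by_id[cid] for cid in keep},
                       edges=sub_edges, labels=labels, order=keep, bin=bin)


def estimate_multiplicity(graph: ContigGraph,
                          assignments: Sequence[BinAssignment] | None = None,
                          ) -> dict[str, MultiplicityEstimate]:
    """Copy number per contig: depth / median depth of the bin's own nodes,
    rounded half-up, floored at 1. Collapsed repeats show up as copy >= 2."""
    core = [graph.contigs[cid].depth for cid in graph.order
            if graph.labels[cid] == graph.bin.value]
    baseline = median(core) if core else median(
        c.depth for c in graph.contigs.values())
    out = {}
    for cid in graph.order:
        depth = graph.contigs[cid].depth
        copy = max(1, int(depth / baseline + 0.5)) if baseline > 0 else 1
        out[cid] = MultiplicityEstimate(cid, copy, baseline)
    return out


def prune_false_links(graph: ContigGraph, depth_ratio_max: float = 3.0,
                      min_edge_depth: int = 2,
                      multiplicities: dict[str, MultiplicityEstimate] | None = None,
                      max_rescue_copies: int = 2) -> ContigGraph:
    """Drop weakly supported edges and depth-incompatible junctions.

    An edge is a false link when its endpoints' depths differ by more than
    ``depth_ratio_max``, or when fewer than ``min_edge_depth`` reads span
    it. A collapsed repeat legitimately carries a multiple of the baseline
    depth, so a contig with copy number up to ``max_rescue_copies`` is
    compared at depth/copy; higher copy estimates are treated as evidence
    of a different genome (nuclear repeat, chloroplast), not a collapsed
    organellar repeat, and get no rescue. Nodes are never removed here.
    """
    if multiplicities is None:
        multiplicities = estimate_multiplicity(graph)

    def adjusted(cid: str) -> float:
        copy = multiplicities[cid].copy_number
        depth = graph.contigs[cid].depth
        return depth / copy if 1 < copy <= max_rescue_copies else depth

    kept = []
    for e in graph.edges:
        if e.edge_depth < min_edge_depth:
            continue
        lo, hi = sorted((adjusted(e.left_id), adjusted(e.right_id)))
        if lo > 0 and hi / lo > depth_ratio_max:
            continue
        kept.append(e)
    return replace(graph, edges=kept)


@dataclass
class TraversalResult:
    paths: list[OrganellePath]
    unused: list[str]          # contigs with remaining unused copies
    copies_used: dict[str, int]


def _enter_orientation(entry_end: End) -> Orientation:
    return Orientation.FWD if entry_end is End.FIVE else Orientation.REV


def traverse(graph: ContigGraph,
             multiplicities: dict[str, MultiplicityEstimate] | None = None,
             seed_policy: str = "file_order") -> TraversalResult:
    """Greedy bidirectional walk from successive seed contigs.

    The first bin contig in file order (or the longest, per ``seed_policy``)
    seeds a path in forward orientation. The path extends from both ends: at
    each tip, edges leaving the tip's open end are candidates, ranked by
    (edge depth, partner length, then lexicographically smallest partner
    id). Extension to an unvisited contig takes precedence; when none
    exists, an edge back into the path's opposite open end closes it into a
    circle; failing that, a contig with spare copies (a collapsed repeat)
    may be revisited — a revisit is only ever taken when the path would
    otherwise break, so depth-inflated repeats cannot be walked forever. A
    tip with no candidates is a breakpoint. New seeds are drawn from the
    remaining unvisited bin contigs until none remain. cp-like nodes are
    walked but never seeded.
    """
    if multiplicities is None:
        multiplicities = estimate_multiplicity(graph)
    adj = graph.adjacency()
    copies_used = {cid: 0 for cid in graph.order}
    edge_used = [False] * len(graph.edges)

    seed_order = list(graph.order)
    if seed_policy == "longest":
        seed_order.sort(key=lambda cid: (-graph.contigs[cid].length, cid))
    elif seed_policy != "file_order":
        raise ValueError(f"unknown seed_policy {seed_policy!r}")
    seeds = [cid for cid in seed_order if graph.labels[cid] != "CP_LIKE"]

    def partner(edge: ContigEdge, cid: str, end: End) -> tuple[str, End]:
        if (edge.left_id, edge.left_end) == (cid, end):
            return edge.right_id, edge.right_end
        return edge.left_id, edge.left_end

    def rank_key(cid: str, end: End):
        def key(i: int):
            pid, _ = partner(graph.edges[i], cid, end)
            return (-graph.edges[i].edge_depth, -graph.contigs[pid].length, pid)
        return key

    has_repeats = any(m.copy_number > 1 for m in multiplicities.values())

    paths: list[OrganellePath] = []
    for seed in seeds:
        if copies_used[seed] > 0:
            continue
        # a graph with collapsed repeats admits several edge-consistent
        # closures (recombination isomers); emit the master circle — the
        # depth-maximal closed walk — found by bounded exhaustive search
        if has_repeats and len(graph.edges) <= 64:
            walk = _best_closed_walk(graph, adj, multiplicities, seed,
                                     copies_used, edge_used, partner,
                                     rank_key)
            if walk is not None:
                paths.append(OrganellePath(steps=walk, circular=True))
                continue
        steps = [OrientedContig(seed, Orientation.FWD)]
        copies_used[seed] += 1
        circular = False

        def extend(rightwards: bool) -> bool:
            """Grow one tip until closure or breakpoint; True if closed."""
            nonlocal steps
            while True:
                if rightwards:
                    cid, end = steps[-1].contig_id, steps[-1].exit_end
                    goal = (steps[0].contig_id, steps[0].entry_end)
                else:
                    cid, end = steps[0].contig_id, steps[0].entry_end
                    goal = (steps[-1].contig_id, steps[-1].exit_end)
                cands = [i for i in adj.get((cid, end), []) if not edge_used[i]]
                fresh, revisit, close = [], [], None
                for i in cands:
                    pid, pend = partner(graph.edges[i], cid, end)
                    if (pid, pend) == goal and close is None:
                        close = i
                    if copies_used[pid] == 0:
                        fresh.append(i)
                    elif copies_used[pid] < multiplicities[pid].copy_number:
                        revisit.append(i)
                if fresh:
                    best = min(fresh, key=rank_key(cid, end))
                elif close is not None:
                    edge_used[close] = True
                    return True
                elif revisit:
                    best = min(revisit, key=rank_key(cid, end))
                else:
                    return False
                pid, pend = partner(graph.edges[best], cid, end)
                edge_used[best] = True
                copies_used[pid] += 1
                if rightwards:
                    steps.append(OrientedContig(pid, _enter_orientation(pend)))
                else:
                    # partner exits through pend into our left tip
                    ori = Orientation.FWD if pend is End.THREE else Orientation.REV
                    steps.insert(0, OrientedContig(pid, ori))

        circular = extend(rightwards=True)
        if not circular:
            circular = extend(rightwards=False)
        paths.append(OrganellePath(steps=steps, circular=circular))

    unused = [cid for cid in graph.order
              if copies_used[cid] < multiplicities[cid].copy_number]
    return TraversalResult(paths=paths, unused=unused, copies_used=copies_used)


def _best_closed_walk(graph, adj, multiplicities, seed, copies_used,
                      edge_used, partner, rank_key,
                      max_states: int = 50_000):
    """Depth-maximal closed walk from ``seed`` (forward) respecting contig
    copy numbers, by depth-first search over fork choices.

    Mutates ``copies_used``/``edge_used`` with the chosen walk and returns
    its steps, or None when no closed walk exists (or the state budget is
    exhausted with nothing found). Deterministic: candidates are explored
    in the greedy ranking order, and ties in total edge depth keep the
    first walk found.
    """
    seed_entry = End.FIVE
    best: tuple[int, list[OrientedContig], list[int]] | None = None
    states = 0

    local_copies = dict(copies_used)
    local_copies[seed] += 1
    used: list[int] = []

    def dfs(steps: list[OrientedContig], depth_sum: int) -> None:
        nonlocal best, states
        states += 1
        if states > max_states:
            return
        tip = steps[-1]
        cands = sorted((i for i in adj.get((tip.contig_id, tip.exit_end), [])
                        if not edge_used[i] and i not in used_set),
                       key=rank_key(tip.contig_id, tip.exit_end))
        for i in cands:
            pid, pend = partner(graph.edges[i], tip.contig_id, tip.exit_end)
            if pid == seed and pend == seed_entry:
                score = depth_sum + graph.edges[i].edge_depth
                if best is None or score > best[0]:
                    best = (score, list(steps), used + [i])
                continue
            if local_copies[pid] >= multiplicities[pid].copy_number:
                continue
            local_copies[pid] += 1
            used.append(i)
            used_set.add(i)
            steps.append(OrientedContig(pid, _enter_orientation(pend)))
            dfs(steps, depth_sum + graph.edges[i].edge_depth)
            steps.pop()
            used_set.discard(i)
            used.pop()
            local_copies[pid] -= 1

    used_set: set[int] = set()
    dfs([OrientedContig(seed, Orientation.FWD)], 0)
    if best is None:
        return None
    _, steps, walk_edges = best
    for i in walk_edges:
        edge_used[i] = True
    for s in steps:
        copies_used[s.contig_id] += 1
    return steps


def path_to_sequence(path: OrganellePath, contigs: dict[str, ContigRecord],
                     junction_overlap_trim: int = 0, gap_n: int = 100) -> str:
    """Concatenate a path's oriented contig sequences into one nucleotide
    string, with a run of ``gap_n`` Ns at each flagged gap junction."""
    pieces: list[str] = []
    gapset = set(path.gaps)
    for i, step in enumerate(path.steps):
        rec = contigs.get(step.contig_id)
        if rec is None or rec.sequence is None:
            raise ValueError(f"contig {step.contig_id} has no sequence")
        seq = rec.sequence if step.orientation is Orientation.FWD \
            else revcomp(rec.sequence)
        if junction_overlap_trim and i > 0:
            seq = seq[junction_overlap_trim:]
        pieces.append(seq)
        if i in gapset and i < len(path.steps) - 1:
            pieces.append("N" * gap_n)
    return "".join(pieces)


def reference_guided_order(contigs: Sequence[ContigRecord], reference: str,
                           min_anchor: int = 500, k: int = 21,
                           ) -> tuple[OrganellePath, list[str]]:
    """Order and orient contigs along a homologous reference genome.

    Chloroplast genomes are conserved enough that a related species' genome
    fixes contig order. Each contig is anchored by unique shared k-mers; the
    anchored span's midpoint orders the contigs, the majority match strand
    orients them, and junctions where consecutive anchors leave uncovered
    reference sequence are flagged as gaps. Contigs anchoring less than
    ``min_anchor`` bp (or, for short contigs, less than half their length)
    are reported separately.
    """
    if not reference:
        raise ValueError("reference must be nonempty")
    ref_kmers: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(reference) - k + 1):
        km = reference[i:i + k]
        if km in ref_kmers:
            dup.add(km)
        else:
            ref_kmers[km] = i
    for km in dup:
        ref_kmers.pop(km, None)

    anchored = []  # (midpoint, start, end, contig_id, orientation)
    unanchored: list[str] = []
    for c in contigs:
        if c.sequence is None:
            raise ValueError(f"contig {c.contig_id} has no sequence")
        best = None
        L = len(reference)
        for ori, seq in ((Orientation.FWD, c.sequence),
                         (Orientation.REV, revcomp(c.sequence))):
            hits = [ref_kmers[seq[i:i + k]]
                    for i in range(len(seq) - k + 1)
                    if seq[i:i + k] in ref_kmers]
            if not hits:
                continue
            if max(hits) - min(hits) > 2 * len(seq):
                # contig wraps the circular origin: unwrap the tail hits
                hits = [h - L if h > L // 2 else h for h in hits]
            span = (min(hits), max(hits) + k)
            if best is None or len(hits) > best[0]:
                best = (len(hits), span, ori)
        need = min(min_anchor, max(k, len(c.sequence) // 2))
        if best is None or best[1][1] - best[1][0] < need:
            unanchored.append(c.contig_id)
            continue
        _, (s, e), ori = best
        anchored.append(((s + e) / 2, s, e, c.contig_id, ori))
    if not anchored:
        raise ValueError("no contig anchors to the reference")
    anchored.sort(key=lambda t: (t[0], t[3]))
    steps = [OrientedContig(cid, ori) for _, _, _, cid, ori in anchored]
    gaps = [i for i in range(len(anchored) - 1)
            if anchored[i + 1][1] > anchored[i][2]]
    return OrganellePath(steps=steps, circular=False, gaps=gaps), unanchored
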