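"""Synthetic organellar fixtures: genomes, fragmented contig graphs, reads.

Emulates the data the assembly method consumes, so every stage is testable
without downloads: a circular chloroplast genome with quadripartite
LSC + IRa + SSC + IRb architecture (defaults 85 kb / 25 kb / 15 kb / 25 kb),
a circular mitochondrial genome with the 15 conserved protein-coding genes,
three rRNAs, dispersed repeats and one chloroplast-derived insertion
carrying trnM/trnH/trnS; fragmentation of each circle into contigs with an
end-polarity edge file in the 454ContigGraph dialect and depths drawn
around the organelle bands (nuclear ~2x, mitochondrial ~70x, chloroplast
~120x, 10% CV so the default thresholds separate cleanly); and
pyrosequencing-like reads whose dominant error is single-base
insertion/deletion at homopolymer runs, plus rarer substitutions.

All randomness flows from one explicitly seeded generator per fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import ContigEdge, ContigRecord, End, FType, GeneFeature, revcomp
from .phylo import GENE_SET_15
from .stats import QuadripartitePartition

_BASES = np.array(list("ACGT"))


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study: sizes, depths, error rates."""

    seed: int = 0
    cp_len: int = 150_000
    ir_len: int = 25_000
    lsc_len: int = 85_000
    ssc_len: int = 15_000
    mt_len: int = 400_000
    mt_repeat_count: int = 2      # copies of the dispersed repeat
    mt_repeat_len: int = 5_000
    at_bias: float = 0.545
    depths: dict[str, float] = field(default_factory=lambda: {
        "NUCLEAR": 2.0, "MT": 70.0, "CP": 120.0})
    depth_cv: float = 0.10
    read_len: int = 360
    error_sub: float = 0.001
    error_homopolymer_indel: float = 0.005

    def __post_init__(self) -> None:
        if self.cp_len != self.lsc_len + self.ssc_len + 2 * self.ir_len:
            raise ValueError("cp_len must equal lsc_len + ssc_len + 2*ir_len")
        if not (0.5 < self.at_bias < 0.7):
            raise ValueError("at_bias must be in (0.5, 0.7)")
        if min(self.cp_len, self.mt_len, self.ir_len, self.lsc_len,
               self.ssc_len) <= 0:
            raise ValueError("all lengths must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def random_seq(rng: np.random.Generator, length: int, at_bias: float) -> str:
    p = np.array([at_bias / 2, (1 - at_bias) / 2, (1 - at_bias) / 2,
                  at_bias / 2])  # A C G T
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


CP_GENES = ("trnm", "trnh", "trns", "rbcl", "psba", "matk", "rpob", "ndhf",
            "atpa", "psbb")
CP_IR_GENES = ("rrn16", "rrn23")
MT_RRNAS = ("rrn5", "rrn18", "rrn26")


def _plant_genes(rng: np.random.Generator, region_len: int,
                 genes: Sequence[str], at_bias: float, offset: int = 0,
                 ) -> tuple[str, list[GeneFeature]]:
    """Build a region of ``region_len`` with the named genes written in at
    spaced positions; coordinates in the returned features are 1-based and
    shifted by ``offset``."""
    seq = list(random_seq(rng, region_len, at_bias))
    feats: list[GeneFeature] = []
    budget = region_len // max(1, len(genes))
    cursor = 0
    for g in genes:
        glen = int(rng.integers(240, min(1800, max(300, budget // 2))))
        start = cursor + int(rng.integers(20, max(21, budget - glen - 20)))
        if start + glen > region_len:
            break
        gene_seq = random_seq(rng, glen, at_bias)
        strand = "+" if rng.random() < 0.5 else "-"
        seq[start:start + glen] = list(gene_seq if strand == "+"
                                       else revcomp(gene_seq))
        ftype = FType.tRNA if g.startswith("trn") else (
            FType.rRNA if g.startswith("rrn") else FType.CDS)
        feats.append(GeneFeature(gene=g, ftype=ftype,
                                 start=offset + start + 1,
                                 end=offset + start + glen, strand=strand))
        cursor = start + glen
    return "".join(seq), feats


def make_cp_genome(spec: FixtureSpec,
                   ) -> tuple[str, QuadripartitePartition, list[GeneFeature]]:
    """Quadripartite chloroplast genome LSC + IRa + SSC + revcomp(IRa).

    tRNAs and single-copy genes sit in the LSC/SSC; the rRNA operon sits in
    IRa (its IRb mirror copy is not separately annotated). Deterministic
    for a given spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    lsc, feats = _plant_genes(rng, spec.lsc_len, CP_GENES, spec.at_bias, 0)
    ira, ir_feats = _plant_genes(rng, spec.ir_len, CP_IR_GENES, spec.at_bias,
                                 spec.lsc_len)
    ssc, ssc_feats = _plant_genes(rng, spec.ssc_len, ("ndhd",), spec.at_bias,
                                  spec.lsc_len + spec.ir_len)
    genome_l = list(lsc + ira + ssc + revcomp(ira))
    # break chance complementarity at the four IR boundaries so the planted
    # repeat pair is exactly maximal (mirror partners of the flanking bases
    # must not complement them)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    n = spec.cp_len
    pairs = ((spec.lsc_len - 1, 0),                       # outside LSC|IRa vs IRb|origin
             (spec.lsc_len + spec.ir_len,                 # first SSC base vs
              spec.lsc_len + spec.ir_len + spec.ssc_len - 1))  # last SSC base
    for x, y in pairs:
        if genome_l[x] == comp[genome_l[y]]:
            genome_l[y] = "A" if genome_l[y] != "A" else "C"
    genome = "".join(genome_l)
    assert len(genome) == spec.cp_len
    part = QuadripartitePartition(
        LSC=(0, spec.lsc_len),
        IRa=(spec.lsc_len, spec.lsc_len + spec.ir_len),
        SSC=(spec.lsc_len + spec.ir_len, spec.lsc_len + spec.ir_len + spec.ssc_len),
        IRb=(spec.lsc_len + spec.ir_len + spec.ssc_len, spec.cp_len),
        length=spec.cp_len)
    return genome, part, feats + ir_feats + ssc_feats


@dataclass
class MtTruth:
    repeat_spans: list[tuple[int, int]]
    cp_insert_span: tuple[int, int]


def make_mt_genome(spec: FixtureSpec, cp_genome: str | None = None,
                   ) -> tuple[str, list[GeneFeature], MtTruth]:
    """Circular mitochondrial genome with the 15 conserved protein-coding
    genes and three rRNAs planted, ``mt_repeat_count`` identical dispersed
    repeat copies, and one chloroplast-derived insertion carrying
    trnM/trnH/trnS (copied from ``cp_genome``'s LSC when provided)."""
    rng = np.random.default_rng(spec.seed + 1)
    gene_region = spec.mt_len // 2
    seq, feats = _plant_genes(rng, gene_region,
                              tuple(GENE_SET_15) + MT_RRNAS, spec.at_bias, 0)
    rest = random_seq(rng, spec.mt_len - gene_region, spec.at_bias)
    genome = list(seq + rest)

    # dispersed identical repeats in the gene-free half
    repeat = random_seq(rng, spec.mt_repeat_len, spec.at_bias)
    repeat_spans = []
    if spec.mt_repeat_count > 0:
        slot = (spec.mt_len - gene_region) // (spec.mt_repeat_count + 1)
        for i in range(spec.mt_repeat_count):
            start = gene_region + (i + 1) * slot - spec.mt_repeat_len // 2
            genome[start:start + spec.mt_repeat_len] = list(repeat)
            repeat_spans.append((start, start + spec.mt_repeat_len))

    # one cp->mt transferred segment with the three tRNAs
    ins_len = 2000
    ins_start = gene_region - 4000
    if cp_genome is not None:
        segment = cp_genome[1000:1000 + ins_len]
    else:
        segment = random_seq(rng, ins_len, spec.at_bias)
    genome[ins_start:ins_start + ins_len] = list(segment)
    for j, g in enumerate(("trnm", "trnh", "trns")):
        g_start = ins_start + 100 + j * 400
        feats.append(GeneFeature(gene=g, ftype=FType.tRNA, start=g_start + 1,
                                 end=g_start + 80, strand="+"))
    feats = [f for f in feats
             if not (ins_start < f.end and f.start - 1 < ins_start + ins_len)
             or f.ftype is FType.tRNA]
    return "".join(genome), feats, MtTruth(repeat_spans=repeat_spans,
                                           cp_insert_span=(ins_start,
                                                           ins_start + ins_len))


@dataclass
class FragmentTruth:
    """Generator-side record of how each circle was cut."""

    paths: dict[str, list[tuple[str, str]]]   # bin -> [(contig_id, FWD/REV)]
    genomes: dict[str, str]


def fragment_to_contigs(genomes: dict[str, str], spec: FixtureSpec,
                        n_cuts: dict[str, int] | None = None,
                        flip_prob: float = 0.3,
                        collapse_spans: dict[str, list[tuple[int, int]]] | None = None,
                        ) -> tuple[list[ContigRecord], list[ContigEdge], FragmentTruth]:
    """Cut each circular genome into contigs and emit the edge file contents.

    ``genomes`` maps bin name (CP/MT/NUCLEAR) to a circular sequence. Each
    circle is cut at ``n_cuts[bin]`` random positions (default 5; one cut
    gives a single contig with a self-edge). A random subset of contigs is
    stored reverse-complemented, with edge polarities adjusted, so the
    traversal has to re-orient them. ``collapse_spans`` marks intervals
    (e.g. the two copies of a dispersed repeat) that are excised as their
    own contigs and merged into a single record with summed depth,
    producing a repeat node of multiplicity >= 2. Depths are drawn
    Normal(bin depth, depth_cv) truncated at 1. Contig file order is
    shuffled across bins (deterministically) as a real assembler's would be
    arbitrary.
    """
    rng = np.random.default_rng(spec.seed + 2)
    n_cuts = n_cuts or {}
    contigs: list[ContigRecord] = []
    edges: list[ContigEdge] = []
    truth_paths: dict[str, list[tuple[str, str]]] = {}
    next_id = 1

    for bin_name in sorted(genomes):
        genome = genomes[bin_name]
        L = len(genome)
        depth_mu = spec.depths.get(bin_name, 2.0)
        k = n_cuts.get(bin_name, 5)
        spans = sorted((s % L, e) for s, e in (collapse_spans or {}).get(
            bin_name, []))
        forbidden = set()
        for s, e in spans:
            forbidden.update((s, e))
        cuts = set(forbidden)
        while len(cuts) < k + len(forbidden):
            c = int(rng.integers(0, L))
            if any(s < c < e for s, e in spans):
                continue  # don't cut inside a collapsed repeat
            cuts.add(c)
        cut_list = sorted(cuts)
        if not cut_list:
            cut_list = [0]
        # arcs between consecutive cuts (circular)
        arcs = []
        for i, start in enumerate(cut_list):
            end = cut_list[(i + 1) % len(cut_list)]
            sub = genome[start:end] if end > start else genome[start:] + genome[:end]
            if not sub:
                continue
            arcs.append((start, end, sub))

        # identical arcs (collapsed repeats) share one contig record
        seq_to_id: dict[str, str] = {}
        flipped_by_id: dict[str, bool] = {}
        path: list[tuple[str, str]] = []
        arc_ids: list[tuple[str, bool]] = []   # (contig_id, flipped)
        depth_by_id: dict[str, float] = {}
        count_by_id: dict[str, int] = {}
        for start, end, sub in arcs:
            if sub in seq_to_id:
                cid = seq_to_id[sub]
                count_by_id[cid] += 1
                arc_ids.append((cid, flipped_by_id[cid]))
                path.append((cid, "REV" if flipped_by_id[cid] else "FWD"))
                continue
            cid = str(next_id)
            next_id += 1
            seq_to_id[sub] = cid
            can_flip = not any(s == start and e == end for s, e in spans)
            flip = bool(rng.random() < flip_prob) and can_flip
            # truncate at +/-1.5 sigma so the bands stay separated and the
            # default thresholds never misbin a generated contig
            sigma = spec.depth_cv * depth_mu
            depth = float(np.clip(rng.normal(depth_mu, sigma),
                                  max(1.0, depth_mu - 1.5 * sigma),
                                  depth_mu + 1.5 * sigma))
            depth_by_id[cid] = depth
            count_by_id[cid] = 1
            flipped_by_id[cid] = flip
            stored = revcomp(sub) if flip else sub
            contigs.append(ContigRecord(contig_id=cid,
                                        name=f"contig{int(cid):05d}",
                                        length=len(sub), depth=depth,
                                        sequence=stored))
            arc_ids.append((cid, flip))
            path.append((cid, "REV" if flip else "FWD"))
        # summed depth for collapsed repeats
        for rec in contigs:
            if rec.contig_id in count_by_id and count_by_id[rec.contig_id] > 1:
                rec.depth = depth_by_id[rec.contig_id] * count_by_id[rec.contig_id]
        # edges along the circle
        for i in range(len(arc_ids)):
            a_id, a_flip = arc_ids[i]
            b_id, b_flip = arc_ids[(i + 1) % len(arc_ids)]
            left_end = End.FIVE if a_flip else End.THREE
            right_end = End.THREE if b_flip else End.FIVE
            depth = max(2, int(round(rng.normal(depth_mu * 0.5,
                                                depth_mu * 0.1))))
            edges.append(ContigEdge(left_id=a_id, left_end=left_end,
                                    right_id=b_id, right_end=right_end,
                                    edge_depth=depth))
        truth_paths[bin_name] = path

    # shuffle contig file order deterministically
    order = rng.permutation(len(contigs))
    contigs = [contigs[i] for i in order]
    return contigs, edges, FragmentTruth(paths=truth_paths,
                                         genomes=dict(genomes))


def simulate_reads(sequence: str, coverage: float, spec: FixtureSpec,
                   seed: int | None = None, circular: bool = True,
                   prefix: str = "r") -> list[tuple[str, str]]:
    """Pyrosequencing-like reads: uniform starts on the circle, random
    strand, substitutions at ``error_sub`` per base, and with probability
    ``error_homopolymer_indel`` per homopolymer run (>= 3 bases) a
    single-base insertion or deletion in the run."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(spec.seed + 3 if seed is None else seed)
    L = len(sequence)
    rlen = min(spec.read_len, L)
    n_reads = int(round(coverage * L / rlen))
    doubled = sequence + sequence[:rlen]
    reads: list[tuple[str, str]] = []
    for i in range(n_reads):
        start = int(rng.integers(0, L)) if circular \
            else int(rng.integers(0, max(1, L - rlen + 1)))
        raw = doubled[start:start + rlen]
        seq = list(raw)
        if spec.error_sub > 0:
            n_err = rng.binomial(len(seq), spec.error_sub)
            for pos in rng.choice(len(seq), size=n_err, replace=False):
                cur = seq[pos]
                options = [b for b in "ACGT" if b != cur]
                seq[pos] = options[int(rng.integers(0, 3))]
        if spec.error_homopolymer_indel > 0:
            seq = _homopolymer_indels(seq, rng, spec.error_homopolymer_indel)
        read = "".join(seq)
        if rng.random() < 0.5:
            read = revcomp(read)
        reads.append((f"{prefix}{i}", read))
    return reads


def _homopolymer_indels(seq: list[str], rng: np.random.Generator,
                        rate: float) -> list[str]:
    out: list[str] = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run = seq[i:j]
        if j - i >= 3 and rng.random() < rate:
            if rng.random() < 0.5:
                run = run + [seq[i]]       # one extra base
            else:
                run = run[:-1]             # one base dropped
        out.extend(run)
        i = j
    return out


def plant_errors(sequence: str, n_sub: int, n_indel: int,
                 rng: np.random.Generator,
                 ) -> tuple[str, list[tuple[int, str]]]:
    """Corrupt a genome with substitutions and single-base homopolymer
    indels at distinct, well-separated positions; returns the corrupted
    sequence and the list of (position, kind) on the original coordinates.
    Used to build draft genomes for polishing tests."""
    L = len(sequence)
    min_gap = 50
    positions: list[int] = []
    tries = 0
    while len(positions) < n_sub + n_indel and tries < 100 * (n_sub + n_indel + 1):
        tries += 1
        p = int(rng.integers(100, L - 100))
        if all(abs(p - q) >= min_gap for q in positions):
            positions.append(p)
    errors: list[tuple[int, str]] = []
    edits: list[tuple[int, str, str]] = []  # (pos, kind, payload)
    for idx, p in enumerate(positions):
        if idx < n_sub:
            cur = sequence[p]
            new = {"A": "C", "C": "A", "G": "T", "T": "G"}[cur]
            edits.append((p, "sub", new))
            errors.append((p, "sub"))
        else:
            # duplicate a base inside (or create) a homopolymer context
            edits.append((p, "ins", sequence[p]))
            errors.append((p, "ins"))
    out = []
    last = 0
    for p, kind, payload in sorted(edits):
        out.append(sequence[last:p])
        if kind == "sub":
            out.append(payload)
            last = p + 1
        else:  # insertion into the draft
            out.append(sequence[p] + payload)
            last = p + 1
    out.append(sequence[last:])
    return "".join(out), errors
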