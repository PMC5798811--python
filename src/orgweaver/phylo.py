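"""Mitochondrial 15-gene phylogeny and gene-content comparison.

The comparative analysis concatenates fifteen conserved mitochondrial
protein-coding genes (atp1, atp9, ccmB, cob, cox1, cox3, nad1, nad3, nad4,
nad4L, nad6, nad7, nad9, rps3, rps4), aligns each gene across taxa,
removes every alignment column containing a gap, and builds a
neighbor-joining tree on p-distances with nonparametric bootstrap support
(column resampling with replacement). Alignment is center-star progressive:
each sequence is aligned globally to the most central sequence and the
pairwise alignments are merged under the once-a-gap-always-a-gap rule —
adequate for genes this conserved, and fully deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
from Bio import Align

from .io import GeneFeature, revcomp

logger = logging.getLogger("orgweaver")

GENE_SET_15 = ("atp1", "atp9", "ccmb", "cob", "cox1", "cox3", "nad1", "nad3",
               "nad4", "nad4l", "nad6", "nad7", "nad9", "rps3", "rps4")

GAP = "-"


@dataclass
class ConcatAlignment:
    """Gap-free concatenated alignment with per-gene column partitions."""

    taxa: list[str]
    matrix: dict[str, str]
    partitions: dict[str, tuple[int, int]]

    @property
    def width(self) -> int:
        return len(next(iter(self.matrix.values()))) if self.matrix else 0


def extract_genes(genome: str, features: Sequence[GeneFeature],
                  wanted: Sequence[str] = GENE_SET_15,
                  ) -> tuple[dict[str, str], list[str]]:
    """Pull gene sequences out of a genome by annotated coordinates.

    Minus-strand genes are reverse-complemented; for multi-copy genes the
    longest copy is kept (with a warning); the second return value lists
    wanted genes absent from the annotation.
    """
    wanted_lc = [w.lower() for w in wanted]
    out: dict[str, str] = {}
    for f in features:
        if f.gene not in wanted_lc:
            continue
        if f.wraps:
            sub = genome[f.start - 1:] + genome[:f.end]
        else:
            sub = genome[f.start - 1:f.end]
        if f.strand == "-":
            sub = revcomp(sub)
        if f.gene in out:
            logger.warning("gene %s has multiple copies; keeping the longest",
                           f.gene)
            if len(sub) <= len(out[f.gene]):
                continue
        out[f.gene] = sub
    missing = [w for w in wanted_lc if w not in out]
    return out, missing


def _make_aligner(match: float = 1.0, mismatch: float = -1.0,
                  gap: float = -2.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def pairwise_global(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
                    gap: float = -2.0) -> tuple[str, str, float]:
    """Optimal global alignment of two sequences (linear gap cost);
    returns the two gapped rows and the score."""
    aligner = _make_aligner(match, mismatch, gap)
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1]), aln.score


def align_gene(orthologs: dict[str, str], match: float = 1.0,
               mismatch: float = -1.0, gap: float = -2.0) -> dict[str, str]:
    """Center-star multiple alignment of one gene across taxa.

    The center is the sequence maximizing its summed pairwise global
    alignment score to all others (ties to the lexicographically first
    taxon); every other sequence's pairwise alignment to the center is
    merged into a single MSA, inserting center gaps into all rows already
    merged. Removing gaps from any output row recovers its input.
    """
    taxa = sorted(orthologs)
    if len(taxa) < 2:
        warnings.warn("align_gene: fewer than 2 taxa; passthrough")
        return dict(orthologs)
    aligner = _make_aligner(match, mismatch, gap)
    score_sum = {t: 0.0 for t in taxa}
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            s = aligner.score(orthologs[t1], orthologs[t2])
            score_sum[t1] += s
            score_sum[t2] += s
    center = sorted(taxa, key=lambda t: (-score_sum[t], t))[0]

    master = orthologs[center]          # center row with accumulated gaps
    rows: dict[str, str] = {center: master}
    for t in taxa:
        if t == center:
            continue
        c_row, t_row, _ = pairwise_global(master.replace(GAP, ""),
                                          orthologs[t], match, mismatch, gap)
        # re-insert the master's existing gap columns into this pairwise
        # alignment, then any new center gaps into all previous rows
        merged_c, merged_t = [], []
        mi = ci = 0
        while mi < len(master) or ci < len(c_row):
            if mi < len(master) and master[mi] == GAP:
                merged_c.append(GAP)
                merged_t.append(GAP)
                mi += 1
            elif ci < len(c_row) and c_row[ci] == GAP:
                merged_c.append(GAP)
                merged_t.append(t_row[ci])
                # a brand-new gap in the center: widen all previous rows
                for key in rows:
                    rows[key] = rows[key][:len(merged_c) - 1] + GAP \
                        + rows[key][len(merged_c) - 1:]
                ci += 1
            else:
                merged_c.append(master[mi])
                merged_t.append(t_row[ci])
                mi += 1
                ci += 1
        master = "".join(merged_c)
        rows[center] = master
        rows[t] = "".join(merged_t)
    width = len(master)
    assert all(len(r) == width for r in rows.values())
    return {t: rows[t] for t in taxa}


def remove_gap_columns(block: dict[str, str]) -> dict[str, str]:
    """Drop every column containing at least one gap character."""
    taxa = sorted(block)
    rows = [block[t] for t in taxa]
    keep = [i for i in range(len(rows[0]))
            if all(r[i] != GAP for r in rows)]
    if not keep:
        raise ValueError("no columns remain after gap removal")
    return {t: "".join(block[t][i] for i in keep) for t in taxa}


def concat(blocks: dict[str, dict[str, str]],
           pad_missing: bool = False) -> ConcatAlignment:
    """Concatenate per-gene gap-free blocks into one supermatrix.

    Taxa missing a gene are dropped (with a warning) unless ``pad_missing``,
    which fills the gene's span with Ns for those taxa. Partitions record
    each gene's half-open column interval.
    """
    gene_order = sorted(blocks)
    if pad_missing:
        taxa = sorted({t for b in blocks.values() for t in b})
    else:
        taxa_sets = [set(b) for b in blocks.values()]
        shared = set.intersection(*taxa_sets) if taxa_sets else set()
        dropped = sorted(set.union(*taxa_sets) - shared) if taxa_sets else []
        if dropped:
            warnings.warn(f"taxa missing >=1 gene dropped: {dropped}")
        if not shared:
            raise ValueError("no taxon is present in every gene block")
        taxa = sorted(shared)
    matrix = {t: [] for t in taxa}
    partitions: dict[str, tuple[int, int]] = {}
    col = 0
    for gene in gene_order:
        block = blocks[gene]
        width = len(next(iter(block.values())))
        for t in taxa:
            matrix[t].append(block.get(t, "N" * width))
        partitions[gene] = (col, col + width)
        col += width
    return ConcatAlignment(taxa=taxa,
                           matrix={t: "".join(v) for t, v in matrix.items()},
                           partitions=partitions)


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites between two equal-length rows."""
    if len(a) != len(b):
        raise ValueError("rows must have equal length")
    if not a:
        raise ValueError("zero-length rows")
    return sum(1 for x, y in zip(a, b) if x != y) / len(a)


def jc_distance(a: str, b: str) -> float:
    """Jukes-Cantor corrected distance."""
    p = p_distance(a, b)
    if p >= 0.75:
        raise ValueError("p-distance too large for JC correction")
    return -0.75 * np.log(1 - 4 * p / 3)


def distance_matrix(aln: ConcatAlignment, model: str = "p") -> np.ndarray:
    f = p_distance if model == "p" else jc_distance
    n = len(aln.taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = f(aln.matrix[aln.taxa[i]],
                                  aln.matrix[aln.taxa[j]])
    return D


@dataclass
class PhyloTree:
    """Unrooted tree with branch lengths and optional bootstrap support.

    ``tree`` is a dendropy Tree; ``support`` maps an internal bipartition
    (frozenset of the smaller side's taxon labels) to percent support.
    ``negative_clamped`` flags agglomeration steps that produced a negative
    branch length (clamped to 0).
    """

    tree: dendropy.Tree
    taxa: list[str]
    support: dict[frozenset, int] = field(default_factory=dict)
    negative_clamped: bool = False

    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    def bipartitions(self) -> set[frozenset]:
        """Nontrivial bipartitions as frozensets of the smaller/canonical
        side's leaf labels."""
        out = set()
        all_taxa = frozenset(self.taxa)
        for edge in self.tree.preorder_edge_iter():
            node = edge.head_node
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if len(side) <= 1 or len(side) >= len(all_taxa) - 1:
                continue
            other = all_taxa - side
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out


def nj_tree(D: np.ndarray, taxa: Sequence[str]) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Exact on additive distance matrices: recovers the generating topology
    and branch lengths to machine precision. Negative branch lengths are
    clamped to zero and flagged.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) \
            or not np.allclose(np.diag(D), 0):
        raise ValueError("D must be square symmetric with a zero diagonal")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if len(taxa) != n:
        raise ValueError("taxa/matrix size mismatch")

    tns = dendropy.TaxonNamespace([str(t) for t in taxa])
    nodes = [dendropy.Node(taxon=tns.get_taxon(str(t))) for t in taxa]
    active = list(range(n))
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n)}
    clamped = False
    next_nodes = list(nodes)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * dist[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * dist[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = dist[i, j] - li
        if li < 0 or lj < 0:
            clamped = True
            li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(next_nodes[i])
        parent.add_child(next_nodes[j])
        next_nodes[i].edge.length = li
        next_nodes[j].edge.length = lj
        k = len(next_nodes)
        next_nodes.append(parent)
        for x in active:
            if x in (i, j):
                continue
            d = 0.5 * (dist[i, x] + dist[j, x] - dist[i, j])
            dist[k, x] = dist[x, k] = d
        dist[k, k] = 0.0
        active = [x for x in active if x not in (i, j)] + [k]

    # join the last three nodes at an unrooted trifurcation
    i, j, k = active
    li = 0.5 * (dist[i, j] + dist[i, k] - dist[j, k])
    lj = 0.5 * (dist[i, j] + dist[j, k] - dist[i, k])
    lk = 0.5 * (dist[i, k] + dist[j, k] - dist[i, j])
    lens = [li, lj, lk]
    if any(x < 0 for x in lens):
        clamped = True
        lens = [max(x, 0.0) for x in lens]
    root = dendropy.Node()
    for idx, ln in zip((i, j, k), lens):
        root.add_child(next_nodes[idx])
        next_nodes[idx].edge.length = ln
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree=tree, taxa=[str(t) for t in taxa],
                     negative_clamped=clamped)


def bootstrap(aln: ConcatAlignment, reps: int = 100, seed: int = 0,
              model: str = "p") -> PhyloTree:
    """NJ tree with bootstrap support from column resampling.

    Support for each internal bipartition of the tree built on the original
    alignment is the percentage of replicate trees (columns resampled with
    replacement, same width) containing that bipartition. Deterministic for
    a given seed; taxa are canonically sorted, so input order is irrelevant.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    base = nj_tree(distance_matrix(aln, model), aln.taxa)
    target = base.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    width = aln.width
    rows = {t: np.frombuffer(aln.matrix[t].encode(), dtype="S1")
            for t in aln.taxa}
    for _ in range(reps):
        cols = rng.integers(0, width, size=width)
        resampled = ConcatAlignment(
            taxa=aln.taxa,
            matrix={t: rows[t][cols].tobytes().decode() for t in aln.taxa},
            partitions={"all": (0, width)})
        rep_tree = nj_tree(distance_matrix(resampled, model), aln.taxa)
        rep_bps = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    base.support = {bp: round(100 * c / reps) for bp, c in counts.items()}
    # annotate internal nodes with support for Newick output
    all_taxa = frozenset(base.taxa)
    for node in base.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = min(side, all_taxa - side, key=lambda s: (len(s), sorted(s)))
        if key in base.support:
            node.label = str(base.support[key])
    return base


def gene_presence_matrix(genomes: dict[str, Sequence[GeneFeature]],
                         genes: Sequence[str] | None = None):
    """taxon x gene presence/absence table (pandas DataFrame of bools).

    With ``genes=None`` the union of all annotated gene names is used, so
    tRNA/rRNA content (trnM, rrn5, ...) is comparable across taxa too.
    """
    import pandas as pd

    if genes is None:
        genes = sorted({f.gene for feats in genomes.values() for f in feats})
    else:
        genes = [g.lower() for g in genes]
    rows = {}
    for taxon, feats in sorted(genomes.items()):
        present = {f.gene for f in feats}
        rows[taxon] = {g: g in present for g in genes}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(genes))


def unique_gene_count(features: Sequence[GeneFeature]) -> int:
    """Number of distinct gene names in an annotation (a duplicated IR gene
    or a multi-exon gene counts once)."""
    return len({f.gene for f in features})
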