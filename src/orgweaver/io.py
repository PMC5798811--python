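"""Readers and writers for the formats the pipeline touches.

Covers FASTA/FASTQ, the Newbler ``454ContigGraph.txt`` dialect (a contig
statistics section followed by ``C`` edge lines), plain tab-separated edge
lists, GenBank feature tables (gene name / type / coordinates / strand only),
simple 5-column gene tables, and DOT export of the contig graph.

Coordinate conventions: gene features are 1-based inclusive externally (the
GenBank convention); everything internal to the package is 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger("orgweaver")

IUPAC_NUC = set("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


class End(str, Enum):
    """Which end of a contig an edge attaches to."""

    FIVE = "5'"
    THREE = "3'"

    def other(self) -> "End":
        return End.THREE if self is End.FIVE else End.FIVE


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


class ReferenceError_(ValueError):
    """Raised when an edge references an undeclared contig."""


@dataclass
class ContigRecord:
    """One contig: id, name, length (bp), mean read depth, optional sequence."""

    contig_id: str
    name: str
    length: int
    depth: float
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"contig {self.contig_id}: length must be >= 1")
        if self.depth < 0 or self.depth != self.depth:
            raise ValueError(f"contig {self.contig_id}: depth must be finite and >= 0")
        if self.sequence is not None:
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"contig {self.contig_id}: sequence length "
                    f"{len(self.sequence)} != declared length {self.length}"
                )
            bad = set(self.sequence.upper()) - set("ACGTN")
            if bad:
                raise ValueError(
                    f"contig {self.contig_id}: non-ACGTN symbol(s) {sorted(bad)}"
                )


@dataclass(frozen=True)
class ContigEdge:
    """A read-supported junction between two contig ends.

    ``edge_depth`` is the number of reads spanning the junction.
    """

    left_id: str
    left_end: End
    right_id: str
    right_end: End
    edge_depth: int

    def __post_init__(self) -> None:
        if self.edge_depth < 1:
            raise ValueError("edge_depth must be >= 1")


class FType(str, Enum):
    CDS = "CDS"
    tRNA = "tRNA"
    rRNA = "rRNA"


@dataclass
class GeneFeature:
    """A gene feature with 1-based inclusive coordinates.

    ``wraps`` flags features crossing the circular origin (end < start).
    """

    gene: str
    ftype: FType
    start: int
    end: int
    strand: str
    wraps: bool = False

    def __post_init__(self) -> None:
        self.gene = self.gene.lower()
        if self.start < 1:
            raise ValueError(f"feature {self.gene}: start must be >= 1")
        if self.end < self.start and not self.wraps:
            raise ValueError(
                f"feature {self.gene}: end < start on a non-wrapping feature"
            )
        if self.strand not in "+-":
            raise ValueError(f"feature {self.gene}: strand must be '+' or '-'")


def _strip_commas(token: str) -> str:
    # Printed tables use thousands separators ("349,730"); accept and strip.
    return token.replace(",", "")


def read_contig_graph(path: str | Path) -> tuple[list[ContigRecord], list[ContigEdge]]:
    """Parse a ``454ContigGraph.txt``-dialect file.

    Section 1 lines: ``index  name  length  depth`` (whitespace-separated,
    thousands separators tolerated). Section 2 lines start with ``C``:
    ``C  left_id  5'|3'  right_id  5'|3'  edge_depth``. Unknown sections are
    skipped with a warning. Contig order is preserved as file order because
    traversal seeding starts from the first row.
    """
    path = Path(path)
    contigs: list[ContigRecord] = []
    edges: list[ContigEdge] = []
    known: set[str] = set()
    with open(path) as fh:
        lines = fh.readlines()
    if not any(line.strip() for line in lines):
        raise ParseError(f"{path}: empty contig-graph file")
    for lineno, raw in enumerate(lines, 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split()
        if parts[0] == "C":
            if len(parts) != 6:
                raise ParseError(f"{path}:{lineno}: malformed edge line: {line!r}")
            try:
                edge = ContigEdge(
                    left_id=parts[1],
                    left_end=_parse_end(parts[2], path, lineno),
                    right_id=parts[3],
                    right_end=_parse_end(parts[4], path, lineno),
                    edge_depth=int(_strip_commas(parts[5])),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            for cid in (edge.left_id, edge.right_id):
                if cid not in known:
                    raise ReferenceError_(
                        f"{path}:{lineno}: edge references unknown contig {cid!r}"
                    )
            edges.append(edge)
        elif parts[0].isdigit() or (len(parts) == 4 and _is_number(parts[3])):
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: malformed contig line: {line!r}")
            try:
                rec = ContigRecord(
                    contig_id=parts[0],
                    name=parts[1],
                    length=int(_strip_commas(parts[2])),
                    depth=float(_strip_commas(parts[3])),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            contigs.append(rec)
            known.add(rec.contig_id)
        else:
            logger.warning("%s:%d: skipping unrecognized section line: %r",
                           path, lineno, line)
    return contigs, edges


def _parse_end(token: str, path: Path, lineno: int) -> End:
    token = token.replace("′", "'")  # prime character as printed
    if token in ("5'", "5"):
        return End.FIVE
    if token in ("3'", "3"):
        return End.THREE
    raise ParseError(f"{path}:{lineno}: bad end polarity {token!r}")


def _is_number(token: str) -> bool:
    try:
        float(_strip_commas(token))
        return True
    except ValueError:
        return False


def write_contig_graph(contigs: Sequence[ContigRecord],
                       edges: Sequence[ContigEdge],
                       path: str | Path) -> None:
    """Write contigs + edges back out in the same dialect (round-trip safe)."""
    with open(path, "w") as fh:
        for c in contigs:
            depth = f"{c.depth:g}"
            fh.write(f"{c.contig_id}\t{c.name}\t{c.length}\t{depth}\n")
        for e in edges:
            fh.write(f"C\t{e.left_id}\t{e.left_end.value}\t{e.right_id}\t"
                     f"{e.right_end.value}\t{e.edge_depth}\n")


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as a list of (id, sequence).

    Duplicate ids and non-IUPAC symbols are errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC_NUC
        if bad:
            raise ParseError(
                f"{path}: record {rec.id!r} has non-IUPAC symbol(s) {sorted(bad)}"
            )
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTQ as (id, sequence); qualities are parsed but discarded."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def read_reads(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ, sniffing the format from the first character."""
    with open(path) as fh:
        first = fh.read(1)
    return read_fastq(path) if first == "@" else read_fasta(path)


# -------------------------------------------------------------- gene features

_FTYPE_KEYS = {"CDS": FType.CDS, "tRNA": FType.tRNA, "rRNA": FType.rRNA}


def read_gene_features(path: str | Path, dialect: str = "table") -> list[GeneFeature]:
    """Read gene features from a GenBank flat file or a 5-column TSV.

    The TSV columns are gene, type, start, end, strand (1-based inclusive).
    Gene names are lower-cased so that e.g. ``NAD1`` matches ``nad1``.
    Unknown feature keys are skipped with a warning, never an error.
    """
    if dialect == "table":
        return _read_gene_table(Path(path))
    if dialect == "genbank":
        return _read_genbank_features(Path(path))
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_gene_table(path: Path) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"\t|\s{2,}", line)
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns: {line!r}")
            gene, ftype, start, end, strand = parts[:5]
            if ftype not in _FTYPE_KEYS:
                logger.warning("%s:%d: skipping unknown feature key %r",
                               path, lineno, ftype)
                continue
            start_i, end_i = int(start), int(end)
            feats.append(GeneFeature(gene=gene, ftype=_FTYPE_KEYS[ftype],
                                     start=start_i, end=end_i, strand=strand,
                                     wraps=end_i < start_i))
    return feats


def _read_genbank_features(path: Path) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        length = len(rec.seq) if rec.seq is not None else None
        for feat in rec.features:
            if feat.type not in _FTYPE_KEYS:
                if feat.type not in ("source", "gene", "misc_feature", "exon",
                                     "intron", "repeat_region"):
                    logger.warning("%s: skipping unknown feature key %r",
                                   path, feat.type)
                continue
            qual = feat.qualifiers
            name = (qual.get("gene") or qual.get("product") or ["?"])[0]
            start = int(feat.location.start) + 1  # to 1-based inclusive
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            wraps = False
            # CompoundLocation crossing the origin: end of record then start
            parts = getattr(feat.location, "parts", [feat.location])
            if length and len(parts) > 1 and int(parts[0].end) == length:
                start = int(parts[0].start) + 1
                end = int(parts[-1].end)
                wraps = True
            feats.append(GeneFeature(gene=name, ftype=_FTYPE_KEYS[feat.type],
                                     start=start, end=end, strand=strand,
                                     wraps=wraps))
    return feats


def write_gene_table(features: Sequence[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene\ttype\tstart\tend\tstrand\n")
        for f in features:
            fh.write(f"{f.gene}\t{f.ftype.value}\t{f.start}\t{f.end}\t{f.strand}\n")


# ------------------------------------------------------------------------ DOT

_BIN_COLORS = {"CP": "#2ca02c", "MT": "#1f77b4", "NUCLEAR": "#bbbbbb",
               "CP_LIKE": "#98df8a"}


def write_dot(contigs: Sequence[ContigRecord], edges: Sequence[ContigEdge],
              bins: dict[str, str], path: str | Path) -> None:
    """Export the contig graph as DOT: nodes labeled id/length/depth and
    colored by bin, undirected edges labeled with end polarities and depth."""
    with open(path, "w") as fh:
        fh.write("graph contigs {\n  node [style=filled];\n")
        for c in contigs:
            bin_name = bins.get(c.contig_id, "NUCLEAR")
            color = _BIN_COLORS.get(bin_name, "#ffffff")
            fh.write(
                f'  "{c.contig_id}" [label="{c.contig_id}\\n{c.length} bp\\n'
                f'{c.depth:g}x" fillcolor="{color}"];\n'
            )
        for e in edges:
            fh.write(
                f'  "{e.left_id}" -- "{e.right_id}" '
                f'[label="{e.left_end.value}-{e.right_end.value} d={e.edge_depth}"];\n'
            )
        fh.write("}\n")
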