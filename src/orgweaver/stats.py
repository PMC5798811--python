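"""Comparative genome statistics.

Base composition and GC content (organellar genomes of seed plants lean
A+T-rich), windowed GC for circular map tracks, assembly metrics (N50 and
fraction of a reference covered by contig anchors), and detection of the
chloroplast quadripartite architecture: a large single-copy region (LSC), a
small single-copy region (SSC), and two inverted repeats (IRa/IRb, exact
reverse complements of one another, typically 20-28 kb) separating them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .io import ContigRecord, revcomp

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class BaseComposition:
    fractions: dict[str, float]   # of counted (non-N) bases
    n_count: int
    length: int

    def percent(self, base: str) -> float:
        """Percentage rounded half-up to 2 decimals, as printed in genome
        reports."""
        return float(Decimal(self.fractions[base] * 100)
                     .quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))

    @property
    def gc(self) -> float:
        return self.fractions["G"] + self.fractions["C"]

    @property
    def at(self) -> float:
        return self.fractions["A"] + self.fractions["T"]


@dataclass
class QuadripartitePartition:
    """0-based half-open intervals on the circle; intervals may wrap
    (start > end means crossing the origin)."""

    LSC: tuple[int, int]
    IRa: tuple[int, int]
    SSC: tuple[int, int]
    IRb: tuple[int, int]
    length: int

    def segment(self, seq: str, which: str) -> str:
        s, e = getattr(self, which)
        return seq[s:e] if s <= e else seq[s:] + seq[:e]

    def seg_len(self, which: str) -> int:
        s, e = getattr(self, which)
        return e - s if s <= e else self.length - s + e


def base_composition(seq: str) -> BaseComposition:
    """Counts of A/T/C/G as fractions of non-N bases."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    counts = {b: 0 for b in "ATCG"}
    n = 0
    for ch in seq:
        if ch in counts:
            counts[ch] += 1
        elif ch == "N":
            n += 1
        else:
            raise ValueError(f"non-IUPAC/non-ACGTN symbol {ch!r}")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence contains no A/C/G/T")
    return BaseComposition(fractions={b: c / total for b, c in counts.items()},
                           n_count=n, length=len(seq))


def gc_windows(seq: str, window: int = 500, step: int = 200,
               circular: bool = True) -> pd.DataFrame:
    """Sliding-window GC fraction (columns: start, gc). Windows wrap on
    circular sequences; on linear ones the last windows are truncated."""
    if window <= 0:
        raise ValueError("window must be positive")
    if window > len(seq):
        raise ValueError("window exceeds sequence length")
    seq = seq.upper()
    rows = []
    n = len(seq)
    for start in range(0, n, step):
        if circular:
            win = seq[start:start + window]
            if len(win) < window:
                win += seq[:window - len(win)]
        else:
            win = seq[start:start + window]
        counted = sum(1 for c in win if c in "ACGT")
        gc = sum(1 for c in win if c in "GC") / counted if counted else 0.0
        rows.append({"start": start, "gc": gc})
    return pd.DataFrame(rows)


def n50(lengths: Sequence[int]) -> int:
    """Smallest length in the minimal set of longest contigs holding at
    least half the total assembled bases."""
    if not lengths:
        raise ValueError("need at least one contig")
    total = sum(lengths)
    acc = 0
    for ln in sorted(lengths, reverse=True):
        acc += ln
        if acc * 2 >= total:
            return ln
    return min(lengths)  # unreachable


def assembly_metrics(contigs: Sequence[ContigRecord],
                     reference: str | None = None, k: int = 21,
                     ) -> tuple[int, float | None]:
    """(N50, fraction of reference covered by contig anchors).

    Coverage marks every reference position under the k-mer-anchored span
    of some contig (either strand); None when no reference is given.
    """
    value = n50([c.length for c in contigs])
    if reference is None:
        return value, None
    ref_kmers: dict[str, list[int]] = {}
    for i in range(len(reference) - k + 1):
        ref_kmers.setdefault(reference[i:i + k], []).append(i)
    covered = [False] * len(reference)
    for c in contigs:
        if c.sequence is None:
            continue
        for seq in (c.sequence, revcomp(c.sequence)):
            hits = []
            for i in range(len(seq) - k + 1):
                pos = ref_kmers.get(seq[i:i + k])
                if pos and len(pos) == 1:
                    hits.append(pos[0])
            if hits:
                for p in range(min(hits), min(max(hits) + k, len(reference))):
                    covered[p] = True
    return value, sum(covered) / len(reference)


def find_quadripartite(seq: str, min_ir: int = 10000, k: int = 25,
                       ) -> QuadripartitePartition | None:
    """Locate the longest inverted-repeat pair >= ``min_ir`` and partition
    the circle into LSC + IRa + SSC + IRb.

    Shared k-mers between the sequence and its reverse complement seed
    candidate repeat diagonals; the best seed is extended exactly (the IRs
    of a chloroplast genome are typically identical copies). The longer
    single-copy segment is labeled LSC. Returns None when no inverted
    repeat reaches ``min_ir``.
    """
    n = len(seq)
    if n < 2 * min_ir:
        return None
    seq = seq.upper()
    rc = revcomp(seq)

    pos_by_kmer: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        pos_by_kmer.setdefault(seq[i:i + k], []).append(i)

    # Pairing scheme: positions x (in one repeat copy) and y (in the other)
    # are mirrored partners when x + y == S for a constant S, with
    # seq[x] == comp(seq[y]). Every k-mer seed shared between seq and its
    # reverse complement fixes one S, so seeds of the same repeat pair
    # collapse onto one anti-diagonal.
    diag_hits: dict[int, list[int]] = {}
    stride = max(1, k // 2)
    for i in range(0, n - k + 1, stride):
        word = rc[i:i + k]
        # rc position i corresponds to seq interval [n-i-k, n-i)
        q = n - i - k
        for p in pos_by_kmer.get(word, ()):
            if p == q:
                continue  # a palindrome matching itself
            s_const = (p + q + k - 1) % (2 * n)
            diag_hits.setdefault(s_const % n, []).append(p)

    def comp_at(x: int, s_const: int) -> bool:
        return seq[x % n] == _COMP.get(seq[(s_const - x) % n], "?")

    best: tuple[int, int, int] | None = None  # (length, x_min mod n, S)
    for diag in sorted(diag_hits, key=lambda d: (-len(diag_hits[d]), d))[:10]:
        hits = sorted(diag_hits[diag])
        for p in hits[:: max(1, len(hits) // 10)]:
            # unwrap: partner block sits to the right of p (possibly past n)
            s_const = diag if diag - p - k + 1 > p else diag + n
            x_min = x_max = p
            while 2 * (x_max + 1) < s_const and comp_at(x_max + 1, s_const):
                x_max += 1
            while 2 * (x_min - 1) > s_const - 2 * n and comp_at(x_min - 1, s_const):
                x_min -= 1
            length = x_max - x_min + 1
            if length >= min_ir and (best is None or length > best[0]):
                best = (length, x_min % n, s_const)
    if best is None:
        return None
    ir_len, a, s_const = best
    b = (s_const - (a + ir_len - 1)) % n  # start of the mirrored copy
    ira = (a % n, (a + ir_len) % n or n)
    irb = (b % n, (b + ir_len) % n or n)
    # single-copy segments between the repeats
    seg1 = ((a + ir_len) % n, b % n)                  # between IRa end, IRb start
    seg2 = ((b + ir_len) % n, a % n)                  # wraps through origin
    def _slen(s, e):
        return e - s if s <= e else n - s + e
    # canonical circle order is LSC -> IRa -> SSC -> IRb: IRa is the
    # repeat copy immediately following the large single-copy region
    if _slen(*seg1) >= _slen(*seg2):
        lsc, ssc = seg1, seg2
        ira, irb = irb, ira
    else:
        lsc, ssc = seg2, seg1
    part = QuadripartitePartition(LSC=lsc, IRa=ira, SSC=ssc, IRb=irb, length=n)
    # exactness invariant
    if part.segment(seq, "IRb") != revcomp(part.segment(seq, "IRa")):
        return None
    return part
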