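"""Draft correction with accurate short reads.

Pyrosequencing drafts carry homopolymer-associated insertion/deletion errors
as their dominant error class, plus occasional substitutions. Accurate short
reads (e.g. Illumina) are mapped to the draft by exact-seed-and-verify —
the verification allows a small number of edits (default 2), covering both
substitutions and single-base indels — then a per-column pileup is built
and every column where a qualified majority disagrees with the draft is
corrected. Quality scores are not used: the consensus is a plain majority
vote, and ambiguous columns are left unchanged, never N-masked.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import edlib

from .io import revcomp


@dataclass
class ReadPlacement:
    """One read placed on the (possibly circular) draft.

    ``ref_span`` is 0-based half-open on the unrolled draft and may extend
    past ``len(draft)`` for reads wrapping the circular origin (positions
    are taken modulo the draft length downstream). ``indels`` holds
    (ref position, "I"/"D", base) events of the read relative to the draft.
    """

    read_id: str
    ref_span: tuple[int, int]
    strand: str
    mismatches: int
    indels: list[tuple[int, str, str]] = field(default_factory=list)
    aligned_read: str = ""
    cigar: str = ""


@dataclass
class CorrectionReport:
    n_substitutions: int = 0
    n_insertions: int = 0
    n_deletions: int = 0
    positions: list[tuple[int, str, str, str]] = field(default_factory=list)
    # (ref_pos, kind, draft_base, new_base)

    @property
    def total(self) -> int:
        return self.n_substitutions + self.n_insertions + self.n_deletions


_CIG = re.compile(r"(\d+)([=XIDM])")


def map_reads(reads: Sequence[tuple[str, str]], draft: str, circular: bool = False,
              seed_len: int = 31, max_mismatch: int = 2) -> list[ReadPlacement]:
    """Place each read at its best location on the draft.

    Candidate locations come from exact seed k-mers taken at several
    offsets along the read (so one sequencing error cannot kill every
    seed); each candidate is verified by edit-distance alignment against
    the local draft window, accepting at most ``max_mismatch`` edits
    (substitutions or indels combined). Multi-mapping reads go to the
    lowest-edit site; exact ties are dropped. Circular drafts are unrolled
    by appending the first (max read length - 1) bases so origin-spanning
    reads place once.
    """
    if not reads:
        return []
    max_rlen = max(len(s) for _, s in reads)
    ref = draft + draft[:max_rlen - 1] if circular else draft
    L = len(draft)
    index: dict[str, list[int]] = {}
    for i in range(len(ref) - seed_len + 1):
        index.setdefault(ref[i:i + seed_len], []).append(i)

    placements: list[ReadPlacement] = []
    for rid, seq in reads:
        if len(seq) < seed_len:
            continue
        best: tuple[int, int, str, dict] | None = None  # (edits, pos, strand, aln)
        tied = False
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            offsets = {0, (len(s) - seed_len) // 2, len(s) - seed_len}
            cand_pos: set[int] = set()
            for off in offsets:
                for p in index.get(s[off:off + seed_len], ()):
                    cand_pos.add(p - off)
            for pos in sorted(cand_pos):
                lo = max(0, pos - max_mismatch)
                hi = min(len(ref), pos + len(s) + max_mismatch)
                res = edlib.align(s, ref[lo:hi], mode="HW", task="path",
                                  k=max_mismatch)
                if res["editDistance"] < 0:
                    continue
                start = lo + res["locations"][0][0]
                if circular and start >= L:
                    continue  # same placement exists un-wrapped
                key = (res["editDistance"], start, strand)
                if best is None or key[0] < best[0]:
                    best = (res["editDistance"], start, strand,
                            {"res": res, "lo": lo, "s": s})
                    tied = False
                elif key[0] == best[0] and (start, strand) != (best[1], best[2]):
                    tied = True
        if best is None or tied:
            continue
        edits, start, strand, info = best
        res, s = info["res"], info["s"]
        loc = res["locations"][0]
        end = info["lo"] + loc[1] + 1
        mism, indels = _parse_cigar(res["cigar"], start, s, ref)
        placements.append(ReadPlacement(read_id=rid, ref_span=(start, end),
                                        strand=strand, mismatches=mism,
                                        indels=indels, aligned_read=s,
                                        cigar=res["cigar"]))
    return placements


def _parse_cigar(cigar: str, ref_start: int, read: str, ref: str,
                 ) -> tuple[int, list[tuple[int, str, str]]]:
    """Count substitutions and collect indel events from an edlib CIGAR
    (read vs draft; 'I' = base present in read but not draft)."""
    rpos, qpos = ref_start, 0
    mism = 0
    indels: list[tuple[int, str, str]] = []
    for n_s, op in _CIG.findall(cigar):
        n = int(n_s)
        if op in "=M":
            if op == "M":
                mism += sum(1 for a, b in zip(read[qpos:qpos + n],
                                              ref[rpos:rpos + n]) if a != b)
            rpos += n
            qpos += n
        elif op == "X":
            mism += n
            rpos += n
            qpos += n
        elif op == "I":  # extra base(s) in read -> missing from draft
            for j in range(n):
                indels.append((rpos, "I", read[qpos + j]))
            qpos += n
        elif op == "D":  # draft base(s) unsupported by read
            for j in range(n):
                indels.append((rpos + j, "D", ref[rpos + j]))
            rpos += n
    return mism, indels


DEL = "-"


def consensus_correct(draft: str, placements: Sequence[ReadPlacement],
                      min_depth: int = 3, min_fraction: float = 0.6,
                      circular: bool = False,
                      ) -> tuple[str, CorrectionReport]:
    """Majority-vote correction of the draft from a read pileup.

    Per column: if coverage >= ``min_depth`` and the plurality call (a base,
    or the deletion mark) differs from the draft with a vote fraction >=
    ``min_fraction``, the draft is corrected. Insertions relative to the
    draft are handled the same way on inter-column junctions. Positions on
    circular drafts wrap modulo the draft length.
    """
    L = len(draft)
    counts: list[dict[str, int]] = [dict() for _ in range(L)]
    ins_counts: list[dict[str, int]] = [dict() for _ in range(L)]
    ins_depth = [0] * L

    for pl in placements:
        rpos, qpos = pl.ref_span[0], 0
        read = pl.aligned_read
        votes: dict[int, str] = {}      # unrolled ref pos -> base or DEL
        ins: dict[int, str] = {}        # unrolled junction -> inserted seq
        for n_s, op in _CIG.findall(pl.cigar):
            n = int(n_s)
            if op in "=MX":
                for j in range(n):
                    votes[rpos + j] = read[qpos + j]
                rpos += n
                qpos += n
            elif op == "I":
                key = read[qpos:qpos + n]
                # left-align within a homopolymer so votes from reads at
                # different offsets land on the same junction
                junction = rpos
                while junction > 0 and draft[(junction - 1) % L] == key[0]:
                    junction -= 1
                ins[junction] = key
                qpos += n
            elif op == "D":
                for j in range(n):
                    votes[rpos + j] = DEL
                rpos += n
        # left-normalize single-base deletions inside homopolymer runs by
        # swapping the DEL vote with the match vote at the run start, so
        # every spanning read deletes the same column
        for p, v in list(votes.items()):
            if v is not DEL:
                continue
            r0 = p
            while r0 > 0 and draft[(r0 - 1) % L] == draft[p % L] \
                    and votes.get(r0 - 1) == draft[p % L]:
                r0 -= 1
            if r0 != p:
                votes[p] = draft[p % L]
                votes[r0] = DEL
        for p, b in votes.items():
            col = counts[p % L]
            col[b] = col.get(b, 0) + 1
        for p, key in ins.items():
            j = p % L
            ins_counts[j][key] = ins_counts[j].get(key, 0) + 1
        # every read spanning a junction (whether or not it has an
        # insertion there) votes on that junction's insertion state
        for p in range(pl.ref_span[0] + 1, pl.ref_span[1]):
            ins_depth[p % L] += 1

    report = CorrectionReport()
    out: list[str] = []
    for i in range(L):
        # insertion junction before column i
        idepth = ins_depth[i]
        if ins_counts[i] and idepth >= min_depth:
            key, votes = max(sorted(ins_counts[i].items()), key=lambda kv: kv[1])
            if votes / idepth >= min_fraction:
                out.append(key)
                report.n_insertions += len(key)
                report.positions.append((i, "ins", "", key))
        col = counts[i]
        depth = sum(col.values())
        base = draft[i]
        if depth >= min_depth:
            top, votes = max(sorted(col.items()), key=lambda kv: kv[1])
            if top != base and votes / depth >= min_fraction:
                if top == DEL:
                    report.n_deletions += 1
                    report.positions.append((i, "del", base, ""))
                    continue  # drop this draft base
                report.n_substitutions += 1
                report.positions.append((i, "sub", base, top))
                base = top
        out.append(base)
    return "".join(out), report


def polish(draft: str, reads: Sequence[tuple[str, str]], circular: bool = False,
           seed_len: int = 31, max_mismatch: int = 2, min_depth: int = 3,
           min_fraction: float = 0.6) -> tuple[str, CorrectionReport]:
    """One map + consensus round. Iterating to a fixed point converges in
    one extra round on clean data (the second round makes no changes)."""
    placements = map_reads(reads, draft, circular=circular, seed_len=seed_len,
                           max_mismatch=max_mismatch)
    return consensus_correct(draft, placements, min_depth=min_depth,
                             min_fraction=min_fraction, circular=circular)
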