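"""Shared fixtures and independent oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from orgweaver.io import End, revcomp
from orgweaver.synthetic import FixtureSpec


def small_spec(seed: int, **overrides) -> FixtureSpec:
    """A desk-scale fixture spec (30 kb cp / 40 kb mt) for fast tests."""
    defaults = dict(seed=seed, cp_len=30_000, ir_len=6_000, lsc_len=14_000,
                    ssc_len=4_000, mt_len=40_000, mt_repeat_len=1_500)
    defaults.update(overrides)
    return FixtureSpec(**defaults)


def same_circular_sequence(a: str, b: str) -> bool:
    """Equality of circular sequences up to rotation and strand."""
    if len(a) != len(b):
        return False
    return a in b + b or revcomp(a) in b + b


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------- SW oracle

def smith_waterman(a: str, b: str, match: int = 1, mismatch: int = -2,
                   gap_open: int = -3, gap_extend: int = -1) -> int:
    """Brute-force affine-gap local alignment score (Gotoh three-state DP).

    ``gap_open`` is the score of the first gap base, ``gap_extend`` of each
    further base, matching the convention of the implementation under test.
    """
    n, m = len(a), len(b)
    NEG = -10 ** 9
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)   # gap in a
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)   # gap in b
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            if H[i, j] > best:
                best = int(H[i, j])
    return best


# ------------------------------------------------- closed-walk oracle

def enumerate_closed_walks(contigs, edges, multiplicities, seed_id):
    """All edge-consistent closed walks from ``seed_id`` (forward), each
    edge used at most once and each contig at most its copy number.

    Returns a list of (edge_depth_sum, [(contig_id, orientation), ...]).
    Purely recursive enumeration, independent of the traversal code.
    """
    adj: dict[tuple[str, End], list[int]] = {}
    for i, e in enumerate(edges):
        adj.setdefault((e.left_id, e.left_end), []).append(i)
        if (e.right_id, e.right_end) != (e.left_id, e.left_end):
            adj.setdefault((e.right_id, e.right_end), []).append(i)

    def other(eidx, cid, end):
        e = edges[eidx]
        if (e.left_id, e.left_end) == (cid, end):
            return e.right_id, e.right_end
        return e.left_id, e.left_end

    results = []
    copy = {cid: 0 for cid in multiplicities}
    copy[seed_id] = 1

    def walk(cur_id, cur_exit, steps, used, depth_sum):
        for i in adj.get((cur_id, cur_exit), []):
            if i in used:
                continue
            pid, pend = other(i, cur_id, cur_exit)
            if pid == seed_id and pend == End.FIVE:
                results.append((depth_sum + edges[i].edge_depth, list(steps)))
                continue
            if copy.get(pid, 0) >= multiplicities[pid]:
                continue
            copy[pid] += 1
            used.add(i)
            ori = "FWD" if pend is End.FIVE else "REV"
            steps.append((pid, ori))
            nxt_exit = End.THREE if ori == "FWD" else End.FIVE
            walk(pid, nxt_exit, steps, used, depth_sum + edges[i].edge_depth)
            steps.pop()
            used.discard(i)
            copy[pid] -= 1

    walk(seed_id, End.THREE, [(seed_id, "FWD")], set(), 0)
    return results


# ------------------------------------------------- NJ least-squares oracle

def enumerate_unrooted_topologies(n: int):
    """All unrooted binary topologies on leaves 0..n-1, as edge lists over
    node ids (leaves 0..n-1, internal nodes n, n+1, ...)."""
    assert n >= 3
    base = [(0, n), (1, n), (2, n)]
    topologies = [(base, n + 1)]
    for leaf in range(3, n):
        new = []
        for edges_, next_id in topologies:
            for k in range(len(edges_)):
                u, v = edges_[k]
                mid = next_id
                grown = edges_[:k] + edges_[k + 1:] + [
                    (u, mid), (v, mid), (leaf, mid)]
                new.append((grown, next_id + 1))
        topologies = new
    return [t[0] for t in topologies]


def ls_fit_residual(edges_, n, D):
    """Least-squares branch lengths for one topology; returns residual."""
    paths = {}
    adjacency: dict[int, list[tuple[int, int]]] = {}
    for ei, (u, v) in enumerate(edges_):
        adjacency.setdefault(u, []).append((v, ei))
        adjacency.setdefault(v, []).append((u, ei))

    def path_edges(a, b):
        stack = [(a, -1, [])]
        while stack:
            node, prev, acc = stack.pop()
            if node == b:
                return acc
            for nxt, ei in adjacency[node]:
                if nxt != prev:
                    stack.append((nxt, node, acc + [ei]))
        raise AssertionError("disconnected topology")

    rows, y = [], []
    for i in range(n):
        for j in range(i + 1, n):
            row = np.zeros(len(edges_))
            for ei in path_edges(i, j):
                row[ei] = 1.0
            rows.append(row)
            y.append(D[i, j])
    A = np.array(rows)
    sol, *_ = np.linalg.lstsq(A, np.array(y), rcond=None)
    return float(np.linalg.norm(A @ sol - np.array(y)))


def random_additive_matrix(n: int, rng: np.random.Generator):
    """Random unrooted binary tree with positive branch lengths and its
    additive leaf distance matrix; returns (D, bipartitions)."""
    edges_ = [(0, n), (1, n), (2, n)]
    next_id = n + 1
    for leaf in range(3, n):
        k = int(rng.integers(0, len(edges_)))
        u, v = edges_.pop(k)
        mid = next_id
        next_id += 1
        edges_ += [(u, mid), (v, mid), (leaf, mid)]
    lengths = {e: float(rng.uniform(0.05, 1.0)) for e in edges_}
    adjacency: dict[int, list[tuple[int, float]]] = {}
    for (u, v), ln in lengths.items():
        adjacency.setdefault(u, []).append((v, ln))
        adjacency.setdefault(v, []).append((u, ln))
    D = np.zeros((n, n))
    for i in range(n):
        dist = {i: 0.0}
        stack = [(i, -1)]
        while stack:
            node, prev = stack.pop()
            for nxt, ln in adjacency[node]:
                if nxt != prev:
                    dist[nxt] = dist[node] + ln
                    stack.append((nxt, node))
        for j in range(n):
            D[i, j] = dist[j]
    D = (D + D.T) / 2  # exact symmetry despite fp accumulation order
    # nontrivial bipartitions: leaf sets on one side of each edge
    bps = set()
    for (u, v) in edges_:
        side = set()
        stack = [u]
        seen = {u}
        while stack:
            node = stack.pop()
            if node < n:
                side.add(node)
            for nxt, _ in adjacency[node]:
                if nxt not in seen and not ((node, nxt) == (u, v)
                                            or (nxt, node) == (u, v)):
                    seen.add(nxt)
                    stack.append(nxt)
        if 2 <= len(side) <= n - 2:
            other = frozenset(range(n)) - frozenset(side)
            bps.add(min(frozenset(side), other,
                        key=lambda s: (len(s), sorted(s))))
    return D, bps
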