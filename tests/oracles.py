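"""Independent reference implementations used only to check the package.

These deliberately avoid the production code paths: window minima by direct
scan, chain scores by exhaustive subset search, interval queries by linear
scan, and alignment scores by memoized recursion over the scoring
definition (plus Biopython as a third-party cross-check in the tests).
"""
from __future__ import annotations

from functools import lru_cache
from typing import List, Sequence, Tuple

import numpy as np


def brute_minimizer_positions(seq: str, k: int, w: int) -> List[int]:
    """Positions of all per-window minimum-hash k-mers, by direct scan."""
    from wgalign.seeding import canonical_kmer

    nk = len(seq) - k + 1
    if nk <= 0:
        return []
    hashes = []
    for p in range(nk):
        ck = canonical_kmer(seq[p : p + k])
        hashes.append(None if ck is None else ck[0])
    emit = set()
    windows = (
        [range(j, j + w) for j in range(nk - w + 1)]
        if nk >= w
        else [range(nk)]
    )
    for win in windows:
        vals = [(hashes[q], q) for q in win if hashes[q] is not None]
        if not vals:
            continue
        lo = min(v for v, _ in vals)
        emit.update(q for v, q in vals if v == lo)
    return sorted(emit)


def brute_best_chain_score(
    anchors, params, strand: int
) -> float:
    """Exhaustive best chain score over all feasible anchor subsequences.

    Anchors are dicts/records with qpos/tpos/span, already sorted by
    (tpos, qpos); any feasible chain is a subsequence of that order because
    tpos must strictly increase. DFS over extensions.
    """
    import math

    n = len(anchors)

    def feasible_cost(j, i):
        dt = int(anchors[i]["tpos"]) - int(anchors[j]["tpos"])
        if strand == 0:
            dq = int(anchors[i]["qpos"]) - int(anchors[j]["qpos"])
        else:
            dq = int(anchors[j]["qpos"]) - int(anchors[i]["qpos"])
        if dt <= 0 or dq <= 0 or dq > params.max_gap or dt > params.max_gap:
            return None
        g = abs(dq - dt)
        if g > params.max_skew_bandwidth:
            return None
        span = int(anchors[i]["span"])
        gain = min(dq, dt, span)
        cost = params.gap_open_scale * span * g + 0.5 * math.log2(g + 1)
        return gain - cost

    best = 0.0
    stack = [(i, float(anchors[i]["span"])) for i in range(n)]
    while stack:
        i, score = stack.pop()
        best = max(best, score)
        for nxt in range(i + 1, n):
            delta = feasible_cost(i, nxt)
            if delta is not None:
                stack.append((nxt, score + delta))
    return best


def linear_scan_overlaps(
    intervals: Sequence[Tuple[int, int]], s: int, e: int
) -> List[int]:
    """Indices of stored half-open intervals with positive overlap vs [s, e)."""
    return [
        i for i, (a, b) in enumerate(intervals) if min(b, e) - max(a, s) > 0
    ]


def exhaustive_align_score(a: str, b: str, params) -> float:
    """Optimal global affine-gap score by memoized recursion over
    (position in a, position in b, preceding operation) — the exhaustive
    maximum over all alignments, formulated directly from the scoring rules.
    """
    match, mismatch = params.match, params.mismatch
    o, e = params.gap_open, params.gap_extend
    la, lb = len(a), len(b)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, last: str) -> float:
        if i == la and j == lb:
            return 0.0
        best = -np.inf
        if i < la and j < lb:
            s = match if a[i] == b[j] else -mismatch
            best = max(best, s + rec(i + 1, j + 1, "M"))
        if i < la:
            gap = e if last == "I" else o + e
            best = max(best, -gap + rec(i + 1, j, "I"))
        if j < lb:
            gap = e if last == "D" else o + e
            best = max(best, -gap + rec(i, j + 1, "D"))
        return best

    result = rec(0, 0, "")
    rec.cache_clear()
    return result


def cigar_score(a: str, b: str, cigar, params) -> float:
    """Score an alignment CIGAR directly from the scoring definition."""
    i = j = 0
    score = 0.0
    for op, length in cigar:
        if op == "M":
            for _ in range(length):
                score += params.match if a[i] == b[j] else -params.mismatch
                i += 1
                j += 1
        elif op == "I":
            score -= params.gap_open + params.gap_extend * length
            i += length
        elif op == "D":
            score -= params.gap_open + params.gap_extend * length
            j += length
    assert i == len(a) and j == len(b), "CIGAR does not consume both sequences"
    return score
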