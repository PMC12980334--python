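"""Anchor chaining: partition by (reference sequence, strand), then DP.

Anchors from a query against two different reference sequences — or the two
orientations of one sequence — can never belong to the same chain, so the
sorted anchor array is split into at most 2T contiguous partitions and each
partition is chained independently. Partitioning is what makes the chaining
stage parallel without changing its output: chain_all(workers=n) is
structurally identical to chain_all(workers=1) and to an unpartitioned
sequential pass (chain_reference).

The per-partition kernel scores anchor i as

    f(i) = max( span_i,  max_{j in lookback window, feasible}
                f(j) + min(dq, dt, span_i) - cost(j, i) )

with cost = gap_open_scale * span_i * g + 0.5 * log2(g + 1), g = |dq - dt|.
Feasibility requires 0 < dq, dt <= max_gap and g <= max_skew_bandwidth.
Predecessor ties go to the largest j (closest predecessor); chains are
extracted best-first with anchors used at most once.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import List, NamedTuple, Optional, Sequence

import numpy as np

from ._pool import run_pool
from .errors import PreconditionError
from .seeding import ANCHOR_DTYPE

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda fn: fn

#: returned by gap_cost for anchor pairs that cannot be chained
INFEASIBLE = math.inf


class ChainFlag(IntEnum):
    UNSET = 0
    PRIMARY = 1
    SECONDARY = 2


class Anchor(NamedTuple):
    qpos: int
    seqid: int
    tpos: int
    strand: int
    span: int


@dataclass(frozen=True)
class ChainParams:
    max_gap: int = 5000
    max_skew_bandwidth: int = 500
    min_chain_score: float = 40.0
    min_anchors: int = 3
    gap_open_scale: float = 0.01
    lookback: int = 50

    def __post_init__(self):
        for name in (
            "max_gap",
            "max_skew_bandwidth",
            "min_chain_score",
            "min_anchors",
            "gap_open_scale",
            "lookback",
        ):
            if getattr(self, name) <= 0:
                raise PreconditionError(f"{name} must be positive")


@dataclass
class Partition:
    seqid: int
    strand: int
    anchors: np.ndarray  # contiguous slice of the sorted anchor array


@dataclass
class Chain:
    anchors: np.ndarray  # ANCHOR_DTYPE members, increasing tpos
    score: float
    seqid: int
    strand: int
    qs: int
    qe: int
    ts: int
    te: int
    n_anchors: int
    flag: ChainFlag = ChainFlag.UNSET

    def __eq__(self, other):
        if not isinstance(other, Chain):
            return NotImplemented
        return (
            self.score == other.score
            and self.seqid == other.seqid
            and self.strand == other.strand
            and (self.qs, self.qe, self.ts, self.te) == (other.qs, other.qe, other.ts, other.te)
            and self.n_anchors == other.n_anchors
            and self.flag == other.flag
            and np.array_equal(self.anchors, other.anchors)
        )


def _check_sorted(anchors: np.ndarray) -> None:
    if anchors.shape[0] < 2:
        return
    a, b = anchors[:-1], anchors[1:]
    lt = (
        (a["seqid"] < b["seqid"])
        | ((a["seqid"] == b["seqid"]) & (a["strand"] < b["strand"]))
        | (
            (a["seqid"] == b["seqid"])
            & (a["strand"] == b["strand"])
            & (a["tpos"] < b["tpos"])
        )
        | (
            (a["seqid"] == b["seqid"])
            & (a["strand"] == b["strand"])
            & (a["tpos"] == b["tpos"])
            & (a["qpos"] <= b["qpos"])
        )
    )
    if not lt.all():
        raise PreconditionError(
            "anchors are not sorted by (seqid, strand, tpos, qpos)"
        )


def partition_anchors(anchors: np.ndarray, T: int) -> List[Partition]:
    """Split the sorted anchor array into per-(seqid, strand) slices.

    At most 2*T non-empty partitions exist; their concatenation in
    (seqid, strand) order is the input array.
    """
    _check_sorted(anchors)
    if anchors.shape[0] == 0:
        return []
    group = anchors["seqid"].astype(np.int64) * 2 + anchors["strand"]
    cuts = np.nonzero(np.diff(group))[0] + 1
    starts = np.concatenate(([0], cuts))
    stops = np.concatenate((cuts, [anchors.shape[0]]))
    return [
        Partition(
            seqid=int(anchors["seqid"][s]),
            strand=int(anchors["strand"][s]),
            anchors=anchors[s:t],
        )
        for s, t in zip(starts, stops)
    ]


def gap_cost(prev, cur, params: ChainParams) -> float:
    """Gap penalty between consecutive anchors, or INFEASIBLE.

    dq is measured in the direction of the chain (reversed on strand 1).
    The span factor uses the current (later) anchor's span.
    """
    dt = int(cur.tpos) - int(prev.tpos)
    if int(cur.strand) == 0:
        dq = int(cur.qpos) - int(prev.qpos)
    else:
        dq = int(prev.qpos) - int(cur.qpos)
    if dt <= 0 or dq <= 0 or dq > params.max_gap or dt > params.max_gap:
        return INFEASIBLE
    g = abs(dq - dt)
    if g > params.max_skew_bandwidth:
        return INFEASIBLE
    return params.gap_open_scale * int(cur.span) * g + 0.5 * math.log2(g + 1)


def anchor_at(anchors: np.ndarray, i: int) -> Anchor:
    row = anchors[i]
    return Anchor(
        qpos=int(row["qpos"]),
        seqid=int(row["seqid"]),
        tpos=int(row["tpos"]),
        strand=int(row["strand"]),
        span=int(row["span"]),
    )


@njit(cache=False)
def _dp_kernel(qpos, tpos, span, strand, max_gap, bw, lookback, gap_scale):
    n = tpos.shape[0]
    f = np.empty(n, np.float64)
    pred = np.full(n, -1, np.int64)
    for i in range(n):
        best = float(span[i])
        bp = -1
        lo = i - lookback
        if lo < 0:
            lo = 0
        for j in range(i - 1, lo - 1, -1):
            dt = tpos[i] - tpos[j]
            if dt <= 0 or dt > max_gap:
                continue
            if strand == 0:
                dq = qpos[i] - qpos[j]
            else:
                dq = qpos[j] - qpos[i]
            if dq <= 0 or dq > max_gap:
                continue
            g = dq - dt
            if g < 0:
                g = -g
            if g > bw:
                continue
            gain = dq if dq < dt else dt
            if span[i] < gain:
                gain = span[i]
            cost = gap_scale * span[i] * g + 0.5 * np.log2(g + 1.0)
            sc = f[j] + gain - cost
            if sc > best:  # strict: ties keep the largest (first-seen) j
                best = sc
                bp = j
        f[i] = best
        pred[i] = bp
    return f, pred


def _extract_chains(
    anchors: np.ndarray, f: np.ndarray, pred: np.ndarray, params: ChainParams
) -> List[Chain]:
    """Best-first backtracking; each anchor joins at most one chain."""
    n = anchors.shape[0]
    used = np.zeros(n, dtype=bool)
    order = np.argsort(-f, kind="stable")  # ties -> smallest index first
    chains: List[Chain] = []
    for i in order:
        if used[i]:
            continue
        members = []
        j = int(i)
        while j >= 0 and not used[j]:
            members.append(j)
            used[j] = True
            j = int(pred[j])
        members.reverse()
        score = float(f[i])
        if score < params.min_chain_score or len(members) < params.min_anchors:
            continue
        sub = anchors[np.asarray(members, dtype=np.int64)]
        qlo = int(sub["qpos"].min())
        qhi = int((sub["qpos"] + sub["span"]).max())
        chains.append(
            Chain(
                anchors=sub,
                score=score,
                seqid=int(sub["seqid"][0]),
                strand=int(sub["strand"][0]),
                qs=qlo,
                qe=qhi,
                ts=int(sub["tpos"][0]),
                te=int(sub["tpos"][-1] + sub["span"][-1]),
                n_anchors=len(members),
            )
        )
    return chains


def chain_partition(p: Partition, params: ChainParams) -> List[Chain]:
    """Chain one (seqid, strand) partition; anchors sorted by (tpos, qpos)."""
    a = p.anchors
    if a.shape[0] == 0:
        return []
    f, pred = _dp_kernel(
        a["qpos"].astype(np.int64),
        a["tpos"].astype(np.int64),
        a["span"].astype(np.int64),
        p.strand,
        params.max_gap,
        params.max_skew_bandwidth,
        params.lookback,
        params.gap_open_scale,
    )
    return _extract_chains(a, f, pred, params)


def _chain_order_key(c: Chain):
    return (-c.score, c.qs, c.seqid, c.ts, c.strand)


def sort_chains(chains: List[Chain]) -> List[Chain]:
    """Descending score; ties by ascending (qs, seqid, ts, strand)."""
    return sorted(chains, key=_chain_order_key)


def chain_all(
    anchors: np.ndarray, T: int, params: ChainParams, workers: int = 1
) -> List[Chain]:
    """Chain every partition (dispatched largest-first to the worker pool)
    and merge into one globally score-sorted chain list.

    The result is identical for every workers value.
    """
    parts = partition_anchors(anchors, T)
    results = run_pool(
        parts,
        lambda p: chain_partition(p, params),
        workers=workers,
        size=lambda p: p.anchors.shape[0],
    )
    merged: List[Chain] = []
    for chains in results:
        merged.extend(chains)
    return sort_chains(merged)


def chain_reference(
    anchors: np.ndarray, T: int, params: ChainParams
) -> List[Chain]:
    """Unpartitioned sequential chaining over the whole sorted anchor array.

    Pure-Python reference: one DP pass with cross-(seqid, strand) pairs
    forbidden; the lookback window counts same-partition candidates (the
    sorted array keeps partitions contiguous, so this matches the
    per-partition window). Used to validate chain_all.
    """
    _check_sorted(anchors)
    n = anchors.shape[0]
    f = [0.0] * n
    pred = [-1] * n
    seqid = anchors["seqid"]
    strand = anchors["strand"]
    for i in range(n):
        ai = anchor_at(anchors, i)
        best, bp = float(ai.span), -1
        examined = 0
        j = i - 1
        while j >= 0 and examined < params.lookback:
            if seqid[j] != seqid[i] or strand[j] != strand[i]:
                break  # partitions are contiguous: nothing chainable further back
            cost = gap_cost(anchor_at(anchors, j), ai, params)
            if cost != INFEASIBLE:
                gain = _ref_gain(anchor_at(anchors, j), ai)
                sc = f[j] + gain - cost
                if sc > best:
                    best, bp = sc, j
            examined += 1
            j -= 1
        f[i], pred[i] = best, bp
    chains = _extract_chains(
        anchors, np.asarray(f, dtype=np.float64), np.asarray(pred, np.int64), params
    )
    return sort_chains(chains)


def _ref_gain(prev: Anchor, cur: Anchor) -> int:
    dt = cur.tpos - prev.tpos
    dq = cur.qpos - prev.qpos if cur.strand == 0 else prev.qpos - cur.qpos
    return min(dq, dt, cur.span)
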