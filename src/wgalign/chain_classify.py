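"""Primary/secondary chain marking by query-interval overlap fraction.

Two chains compete when their query intervals overlap by more than the mask
level (default 0.5, strictly greater) of the shorter interval. Walking the
score-sorted chain list, the first chain is primary; each later chain is
secondary if it overlaps a previously accepted primary above the threshold,
else it becomes primary itself.

Two implementations of the same decision rule are provided: a quadratic
baseline that scans the primary set linearly per chain, and an accelerated
version that keeps primary intervals in an interval tree so only actual
overlaps are tested. They are exactly equivalent on every input; the
quadratic form is the oracle in the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree as _ITree

from .chaining import Chain, ChainFlag
from .errors import PreconditionError


@dataclass(frozen=True)
class IntervalRecord:
    s: int
    e: int
    payload: int  # chain index

    def __post_init__(self):
        if self.s >= self.e:
            raise PreconditionError(f"interval [{self.s}, {self.e}) is empty")


class IntervalTree:
    """Half-open interval store with insert and overlap (stabbing) queries.

    Backed by a balanced interval tree; query(s, e) returns exactly the
    stored records with positive overlap length against [s, e). Result order
    is unspecified.
    """

    def __init__(self):
        self._tree = _ITree()

    def __len__(self) -> int:
        return len(self._tree)

    def insert(self, rec: IntervalRecord) -> None:
        self._tree.addi(rec.s, rec.e, rec)

    def query(self, s: int, e: int) -> List[IntervalRecord]:
        if s >= e:
            raise PreconditionError(f"query interval [{s}, {e}) is empty")
        return [iv.data for iv in self._tree.overlap(s, e)]


def it_insert(tree: IntervalTree, rec: IntervalRecord) -> None:
    tree.insert(rec)


def it_query(tree: IntervalTree, s: int, e: int) -> List[IntervalRecord]:
    return tree.query(s, e)


def overlap_fraction(c1, c2) -> float:
    """Overlap length of the two query intervals over the shorter length.

    Accepts any objects with qs/qe attributes (chains) or s/e attributes.
    """
    s1, e1 = _interval(c1)
    s2, e2 = _interval(c2)
    ov = max(0, min(e1, e2) - max(s1, s2))
    return ov / min(e1 - s1, e2 - s2)


def _interval(c):
    if hasattr(c, "qs"):
        return c.qs, c.qe
    return c.s, c.e


def _check_score_sorted(chains: Sequence[Chain]) -> None:
    for prev, cur in zip(chains, chains[1:]):
        if cur.score > prev.score:
            raise PreconditionError("chains are not sorted by descending score")


def mark_primary_quadratic(
    chains: Sequence[Chain],
    mask_level: float = 0.5,
    stats: Optional[Dict[str, int]] = None,
) -> List[ChainFlag]:
    """Baseline marking: linear scan of the primary set per chain (O(n^2))."""
    _check_score_sorted(chains)
    flags: List[ChainFlag] = []
    qs: List[int] = []
    qe: List[int] = []
    comparisons = 0
    for c in chains:
        secondary = False
        if qs:
            comparisons += len(qs)
            s = np.asarray(qs)
            e = np.asarray(qe)
            ov = np.minimum(e, c.qe) - np.maximum(s, c.qs)
            np.maximum(ov, 0, out=ov)
            frac = ov / np.minimum(e - s, c.qe - c.qs)
            secondary = bool((frac > mask_level).any())
        if secondary:
            flags.append(ChainFlag.SECONDARY)
        else:
            flags.append(ChainFlag.PRIMARY)
            qs.append(c.qs)
            qe.append(c.qe)
    if stats is not None:
        stats["comparisons"] = stats.get("comparisons", 0) + comparisons
    return flags


def mark_primary_fast(
    chains: Sequence[Chain],
    mask_level: float = 0.5,
    stats: Optional[Dict[str, int]] = None,
) -> List[ChainFlag]:
    """Interval-tree marking; flags are identical to the quadratic baseline.

    Only primaries whose interval actually overlaps the candidate are
    retrieved, so each step costs O(log |Q| + k) instead of O(|Q|).
    """
    _check_score_sorted(chains)
    tree = IntervalTree()
    flags: List[ChainFlag] = []
    comparisons = 0
    for idx, c in enumerate(chains):
        secondary = False
        if len(tree):
            hits = tree.query(c.qs, c.qe) if c.qe > c.qs else []
            comparisons += len(hits)
            for rec in hits:
                ov = min(rec.e, c.qe) - max(rec.s, c.qs)
                if ov / min(rec.e - rec.s, c.qe - c.qs) > mask_level:
                    secondary = True
                    break
        if secondary:
            flags.append(ChainFlag.SECONDARY)
        else:
            flags.append(ChainFlag.PRIMARY)
            tree.insert(IntervalRecord(c.qs, c.qe, idx))
    if stats is not None:
        stats["comparisons"] = stats.get("comparisons", 0) + comparisons
    return flags
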