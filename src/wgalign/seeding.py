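"""Minimizer seeding: reference index construction and anchor collection.

A minimizer is the k-mer of minimal hash within each window of w consecutive
k-mer start positions (closed-window scheme, all tied positions emitted).
K-mers are canonicalized: forward and reverse-complement encodings are both
hashed with an invertible 64-bit mixer and the smaller hash wins, so a query
k-mer matches reference occurrences on either strand through a single key.
"""
from __future__ import annotations

import heapq
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence

import numpy as np

from ._util import encode, mix64, revcomp
from .errors import InvalidInputError
from .genome_io import SequenceRecord

#: one emitted minimizer (seqid is filled in by build_index)
MINIMIZER_DTYPE = np.dtype(
    [("key", np.uint64), ("tpos", np.int64), ("strand", np.uint8)]
)

#: one exact k-mer match between query and reference
ANCHOR_DTYPE = np.dtype(
    [
        ("seqid", np.int32),
        ("strand", np.uint8),
        ("tpos", np.int64),
        ("qpos", np.int64),
        ("span", np.int32),
    ]
)

#: posting-list entry in the index table
POSTING_DTYPE = np.dtype(
    [("seqid", np.int32), ("tpos", np.int64), ("strand", np.uint8)]
)

_SENTINEL = np.uint64(0xFFFFFFFFFFFFFFFF)  # marks k-mers containing N


@dataclass(frozen=True)
class IndexParams:
    k: int = 15
    w: int = 10
    max_occ: int = 100

    def __post_init__(self):
        if not (1 <= self.k <= 28):
            raise InvalidInputError(f"k must be in [1, 28], got {self.k}")
        if self.w < 1:
            raise InvalidInputError(f"w must be >= 1, got {self.w}")
        if self.max_occ < 1:
            raise InvalidInputError(f"max_occ must be >= 1, got {self.max_occ}")


@dataclass
class MinimizerIndex:
    params: IndexParams
    seqs: List[SequenceRecord]
    table: Dict[int, np.ndarray]  # key -> postings sorted by (seqid, tpos)
    T: int = field(default=0)

    def __post_init__(self):
        if not self.T:
            self.T = len(self.seqs)


def _kmer_hashes(codes: np.ndarray, k: int):
    """Per-position canonical k-mer hash, strand, validity (vectorized).

    Returns (hash, strand, valid) arrays of length len(codes) - k + 1. The
    hash of invalid (N-containing) positions is the sentinel max-uint64.
    """
    n = codes.shape[0]
    nk = n - k + 1
    if nk <= 0:
        return (
            np.empty(0, np.uint64),
            np.empty(0, np.uint8),
            np.empty(0, bool),
        )
    isn = (codes == 4).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(isn)))
    valid = (cs[k:] - cs[:-k]) == 0

    c64 = np.where(codes == 4, 0, codes).astype(np.uint64)
    fwd = np.zeros(nk, dtype=np.uint64)
    rc = np.zeros(nk, dtype=np.uint64)
    three = np.uint64(3)
    with np.errstate(over="ignore"):
        for j in range(k):
            fwd = (fwd << np.uint64(2)) | c64[j : j + nk]
            # reverse complement accumulates in the opposite direction
            rc |= (three - c64[j : j + nk]) << np.uint64(2 * j)
    hf = mix64(fwd)
    hr = mix64(rc)
    strand = (hr < hf).astype(np.uint8)  # palindrome tie -> strand 0
    h = np.minimum(hf, hr)
    h[~valid] = _SENTINEL
    return h, strand, valid


def canonical_kmer(seq_window: str, k: Optional[int] = None):
    """Canonical hash of one k-mer window, or None if it contains N.

    Returns (key, strand); strand is 1 when the reverse complement hashed
    smaller, 0 otherwise (ties, i.e. palindromes, count as forward).
    """
    if k is not None and len(seq_window) != k:
        raise InvalidInputError(
            f"window length {len(seq_window)} != k={k}"
        )
    codes = encode(seq_window)
    h, strand, valid = _kmer_hashes(codes, len(seq_window))
    if h.shape[0] == 0 or not valid[0]:
        return None
    return int(h[0]), int(strand[0])


def minimizers(seq: str, params: IndexParams) -> np.ndarray:
    """All window minimizers of ``seq`` as a MINIMIZER_DTYPE array by tpos.

    Every window of ``w`` consecutive k-mer positions contributes its minimal
    valid hash; all tied positions are emitted; duplicates across overlapping
    windows collapse. Sequences shorter than k+w-1 use a single window over
    whatever full k-mers exist.
    """
    k, w = params.k, params.w
    codes = encode(seq)
    h, strand, valid = _kmer_hashes(codes, k)
    nk = h.shape[0]
    if nk == 0:
        return np.empty(0, MINIMIZER_DTYPE)
    nwin = nk - w + 1
    if nwin < 1:
        if not valid.any():
            return np.empty(0, MINIMIZER_DTYPE)
        m0 = h[valid].min()
        emit = valid & (h == m0)
    else:
        from numpy.lib.stride_tricks import sliding_window_view

        m = sliding_window_view(h, w).min(axis=1)  # window minima
        # position p is emitted iff some window j in [p-w+1, p] has m[j]==h[p];
        # since m[j] <= h[p] for windows containing p, that is max(m[j])==h[p].
        pad = np.zeros(w - 1, dtype=np.uint64)
        padded = np.concatenate([pad, m, pad])
        big = sliding_window_view(padded, w).max(axis=1)
        emit = valid & (big == h)
    pos = np.nonzero(emit)[0]
    out = np.empty(pos.shape[0], MINIMIZER_DTYPE)
    out["key"] = h[pos]
    out["tpos"] = pos
    out["strand"] = strand[pos]
    return out


def build_index(ref: Sequence[SequenceRecord], params: IndexParams) -> MinimizerIndex:
    """Index all reference minimizers, dropping keys occurring > max_occ times."""
    if not ref or all(r.length == 0 for r in ref):
        raise InvalidInputError("reference genome is empty")
    keys_parts, postings_parts = [], []
    for seqid, rec in enumerate(ref):
        mins = minimizers(rec.seq, params)
        posting = np.empty(mins.shape[0], POSTING_DTYPE)
        posting["seqid"] = seqid
        posting["tpos"] = mins["tpos"]
        posting["strand"] = mins["strand"]
        keys_parts.append(mins["key"])
        postings_parts.append(posting)
    keys = np.concatenate(keys_parts)
    postings = np.concatenate(postings_parts)
    table: Dict[int, np.ndarray] = {}
    if keys.shape[0]:
        order = np.argsort(keys, kind="stable")  # stable: (seqid, tpos) preserved
        keys = keys[order]
        postings = postings[order]
        uniq, starts, counts = np.unique(keys, return_index=True, return_counts=True)
        for key, start, count in zip(uniq.tolist(), starts.tolist(), counts.tolist()):
            if count <= params.max_occ:
                table[key] = postings[start : start + count]
    return MinimizerIndex(params=params, seqs=list(ref), table=table, T=len(ref))


def collect_anchors(
    query: SequenceRecord, index: MinimizerIndex, workers: int = 1
) -> np.ndarray:
    """All exact k-mer matches of the query against the index.

    One anchor per (query minimizer, posting) pair; anchor strand is the XOR
    of the two canonical strands. Output is stably sorted by
    (seqid, strand, tpos, qpos) so partitions are contiguous runs.
    """
    params = index.params
    qmins = minimizers(query.seq, params)
    hit_parts = []
    table = index.table
    for key, qpos, qstrand in zip(
        qmins["key"].tolist(), qmins["tpos"].tolist(), qmins["strand"].tolist()
    ):
        posting = table.get(key)
        if posting is None:
            continue
        block = np.empty(posting.shape[0], ANCHOR_DTYPE)
        block["seqid"] = posting["seqid"]
        block["strand"] = posting["strand"] ^ np.uint8(qstrand)
        block["tpos"] = posting["tpos"]
        block["qpos"] = qpos
        block["span"] = params.k
        hit_parts.append(block)
    if not hit_parts:
        return np.empty(0, ANCHOR_DTYPE)
    anchors = np.concatenate(hit_parts)
    return sort_anchors(anchors, workers=workers)


def anchor_sort_key(anchors: np.ndarray) -> Callable[[int], tuple]:
    seqid, strand = anchors["seqid"], anchors["strand"]
    tpos, qpos = anchors["tpos"], anchors["qpos"]
    return lambda i: (seqid[i], strand[i], tpos[i], qpos[i])


def sort_anchors(anchors: np.ndarray, workers: int = 1) -> np.ndarray:
    order = stable_parallel_sort(
        range(anchors.shape[0]), key=anchor_sort_key(anchors), workers=workers
    )
    return anchors[np.asarray(order, dtype=np.int64)]


def stable_parallel_sort(
    items: Iterable, key: Optional[Callable] = None, workers: int = 1
) -> list:
    """Chunked sort + k-way stable merge; equals sequential stable sort.

    Elements with equal keys keep their input order for every workers value
    (chunks are contiguous and heapq.merge breaks ties by chunk index).
    """
    items = list(items)
    if workers <= 1 or len(items) < 2 * workers:
        return sorted(items, key=key)
    bounds = np.linspace(0, len(items), workers + 1).astype(int)
    chunks = [items[bounds[i] : bounds[i + 1]] for i in range(workers)]
    with ThreadPoolExecutor(max_workers=workers) as pool:
        sorted_chunks = list(pool.map(lambda c: sorted(c, key=key), chunks))
    if key is None:
        return list(heapq.merge(*sorted_chunks))
    return list(heapq.merge(*sorted_chunks, key=key))
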