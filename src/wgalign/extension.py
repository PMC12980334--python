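"""Base-to-base extension: affine-gap global alignment between anchors.

Each chain becomes one PAF record. Anchors contribute exact k-long match
runs; the gaps between consecutive anchors are filled with a Gotoh
three-state global alignment (match/insertion/deletion states, gap cost
gap_open + gap_extend * length). The alignment spans exactly the chain's
anchor extents — no soft end extension.

The traceback is deterministic: on score ties the diagonal move is preferred
over a deletion, and a deletion over an insertion. With integer-valued
scoring parameters (the defaults) all DP cell values are exact in float64,
so tie decisions are reproducible bit-for-bit.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from ._util import encode, revcomp
from .chaining import Chain, ChainFlag
from .errors import BandExceededError, InternalConsistencyError, PreconditionError
from .genome_io import PafRecord, SequenceRecord

Cigar = List[Tuple[str, int]]

_NEG = -1.0e30


@dataclass(frozen=True)
class AlignParams:
    match: float = 2.0
    mismatch: float = 4.0  # applied as -mismatch
    gap_open: float = 4.0
    gap_extend: float = 2.0
    band: int = 500

    def __post_init__(self):
        if min(self.match, self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise PreconditionError("scoring parameters must be non-negative")
        if self.band < 1:
            raise PreconditionError("band must be >= 1")


def cigar_to_str(cigar: Cigar) -> str:
    return "".join(f"{length}{op}" for op, length in cigar)


def merge_cigar(ops: Cigar) -> Cigar:
    """Collapse adjacent runs with the same operator, dropping empty runs."""
    out: Cigar = []
    for op, length in ops:
        if length <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + length)
        else:
            out.append((op, length))
    return out


def cigar_spans(cigar: Cigar) -> Tuple[int, int]:
    """(query columns, target columns) consumed by a CIGAR."""
    q = sum(l for op, l in cigar if op in "MI")
    t = sum(l for op, l in cigar if op in "MD")
    return q, t


def affine_align(a: str, b: str, params: AlignParams = AlignParams()):
    """Optimal global alignment of a (query) vs b (target).

    Returns (score, cigar) with CIGAR ops M (column consuming both),
    I (consuming a only) and D (consuming b only). Gap of length L costs
    gap_open + gap_extend * L. Cells with |i - j| > band are excluded;
    inputs whose length difference exceeds the band raise BandExceededError.
    """
    m, n = len(a), len(b)
    if abs(m - n) > params.band:
        raise BandExceededError(
            f"length difference {abs(m - n)} exceeds band {params.band}"
        )
    if m == 0 and n == 0:
        return 0.0, []
    if m == 0:
        return -(params.gap_open + params.gap_extend * n), [("D", n)]
    if n == 0:
        return -(params.gap_open + params.gap_extend * m), [("I", m)]

    o, e = params.gap_open, params.gap_extend
    band = params.band
    ac = encode(a).astype(np.int16)
    bc = encode(b).astype(np.int16)

    M = np.full((m + 1, n + 1), _NEG)
    I = np.full((m + 1, n + 1), _NEG)
    D = np.full((m + 1, n + 1), _NEG)
    # backpointers: for M the predecessor state (0=M,1=D,2=I); for I whether
    # the gap extends (vs opens); for D the source column of the gap run.
    msrc = np.zeros((m + 1, n + 1), dtype=np.int8)
    iext = np.zeros((m + 1, n + 1), dtype=bool)
    dsrc = np.zeros((m + 1, n + 1), dtype=np.int32)

    M[0, 0] = 0.0
    js = np.arange(1, n + 1)
    D[0, 1:] = -(o + e * js)
    dsrc[0, 1:] = 0
    cols = np.arange(n + 1)

    for i in range(1, m + 1):
        subst = np.where(
            (ac[i - 1] == bc) & (ac[i - 1] != 4), params.match, -params.mismatch
        )
        prevM, prevI, prevD = M[i - 1], I[i - 1], D[i - 1]
        # diagonal: best predecessor state with priority M > D > I
        diag = np.maximum(prevM, np.maximum(prevD, prevI))
        src = np.where(prevM >= diag, 0, np.where(prevD >= diag, 1, 2))
        M[i, 1:] = diag[:-1] + subst
        msrc[i, 1:] = src[:-1]
        # vertical gap (I, consumes a): open from best of row i-1 or extend
        best_prev = np.maximum(diag, _NEG)
        open_v = best_prev - (o + e)
        ext_v = prevI - e
        # prefer extending an open gap on ties (keeps runs maximal)
        iext[i] = ext_v >= open_v
        I[i] = np.where(iext[i], ext_v, open_v)
        # horizontal gap (D, consumes b): D[i,j] = max_{k<j} maxMI[i,k]-o-e*(j-k)
        mi = np.maximum(M[i], I[i])
        c = mi[:-1] + e * cols[:-1]
        run = np.maximum.accumulate(c)
        marker = np.where(
            np.concatenate(([True], c[1:] > run[:-1])), cols[:-1], -1
        )
        dsrc[i, 1:] = np.maximum.accumulate(marker)
        D[i, 1:] = run - o - e * cols[1:]
        # band: mask cells with |i - j| > band
        off = np.abs(i - cols) > band
        if off.any():
            M[i, off] = _NEG
            I[i, off] = _NEG
            D[i, off] = _NEG

    sM, sD, sI = M[m, n], D[m, n], I[m, n]
    score = max(sM, sD, sI)
    if score <= _NEG / 2:
        raise BandExceededError("no alignment within the DP band")
    # start state priority: diagonal > deletion > insertion
    state = 0 if sM >= score else (1 if sD >= score else 2)

    ops: Cigar = []
    i, j = m, n
    while i > 0 or j > 0:
        if state == 0:  # M column
            ops.append(("M", 1))
            state = int(msrc[i, j])
            i, j = i - 1, j - 1
        elif state == 1:  # D run back to its source column
            k = int(dsrc[i, j])
            ops.append(("D", j - k))
            j = k
            if i == 0 and j == 0:
                break
            # gap opened from max(M, I) at (i, k): prefer M
            state = 0 if M[i, j] >= I[i, j] else 2
        else:  # I column
            ops.append(("I", 1))
            state = 2 if iext[i, j] else None
            i = i - 1
            if state is None:
                # opened from the best state of row i (now i after decrement)
                diag_here = max(M[i, j], D[i, j], I[i, j])
                state = 0 if M[i, j] >= diag_here else (1 if D[i, j] >= diag_here else 2)
    ops.reverse()
    return float(score), merge_cigar(ops)


def compute_mapq(primary_score: float, best_secondary_score: Optional[float]) -> int:
    """Mapping quality: 60 when unchallenged, scaled down linearly by the
    best competing secondary score, clamped to [0, 60]."""
    if best_secondary_score is None:
        return 60
    ratio = best_secondary_score / primary_score if primary_score > 0 else 1.0
    return max(0, min(60, int(math.floor(60.0 * (1.0 - ratio) + 0.5))))


def _trim_anchors(chain_anchors: np.ndarray, qpos: np.ndarray):
    """Effective (qstart, tstart, mlen) per anchor after overlap trimming.

    ``qpos`` is already in chain orientation (ascending). When consecutive
    anchors overlap on query or target (offset < span) the later anchor's
    match run is shortened from the left by the larger overlap; anchors
    trimmed to nothing are dropped.
    """
    tpos = chain_anchors["tpos"].astype(np.int64)
    span = chain_anchors["span"].astype(np.int64)
    rows = []
    prev_qe = prev_te = None
    for i in range(chain_anchors.shape[0]):
        q, t, s = int(qpos[i]), int(tpos[i]), int(span[i])
        trim = 0
        if prev_qe is not None:
            trim = max(prev_qe - q, prev_te - t, 0)
        if trim >= s:
            continue  # fully contained in the previous anchor's run
        rows.append((q + trim, t + trim, s - trim))
        prev_qe, prev_te = q + s, t + s
    return rows


def extend_chain(
    chain: Chain,
    query: SequenceRecord,
    ref: SequenceRecord,
    params: AlignParams = AlignParams(),
) -> PafRecord:
    """Fill the chain's inter-anchor gaps and emit one PAF record.

    For strand-1 chains the query is reverse-complemented once and anchor
    coordinates are mapped so the chain is co-linear; the record's query
    interval is reported in the original orientation with strand '-'. The
    CIGAR reads along the query in its aligned orientation.
    """
    qlen = query.length
    if chain.strand == 1:
        qseq = revcomp(query.seq)
        qpos = qlen - chain.anchors["qpos"].astype(np.int64) - chain.anchors["span"]
    else:
        qseq = query.seq
        qpos = chain.anchors["qpos"].astype(np.int64)

    rows = _trim_anchors(chain.anchors, qpos)
    if not rows:
        raise InternalConsistencyError("chain has no anchors after trimming")

    qcodes = encode(qseq)
    tcodes = encode(ref.seq)

    ops: Cigar = []
    nmatch = 0
    score_gap_pairs: List[Tuple[str, str]] = []
    prev_qe = prev_te = None
    for qstart, tstart, mlen in rows:
        if prev_qe is not None:
            qgap = qstart - prev_qe
            tgap = tstart - prev_te
            if qgap < 0 or tgap < 0:
                raise InternalConsistencyError(
                    "negative inter-anchor gap after trimming"
                )
            if qgap or tgap:
                if abs(qgap - tgap) > params.band:
                    # bounded fallback: two pure gap runs
                    ops.append(("D", tgap))
                    ops.append(("I", qgap))
                else:
                    qseg = qseq[prev_qe:qstart]
                    tseg = ref.seq[prev_te:tstart]
                    _, cig = affine_align(qseg, tseg, params)
                    qi, ti = prev_qe, prev_te
                    for op, length in cig:
                        if op == "M":
                            nmatch += int(
                                np.count_nonzero(
                                    qcodes[qi : qi + length]
                                    == tcodes[ti : ti + length]
                                )
                            )
                            qi += length
                            ti += length
                        elif op == "I":
                            qi += length
                        else:
                            ti += length
                    ops.extend(cig)
        # anchor match run: must be exact by construction
        agree = int(
            np.count_nonzero(
                qcodes[qstart : qstart + mlen] == tcodes[tstart : tstart + mlen]
            )
        )
        if agree != mlen:
            raise InternalConsistencyError(
                f"anchor at q={qstart} t={tstart} does not match the sequences"
            )
        nmatch += mlen
        ops.append(("M", mlen))
        prev_qe, prev_te = qstart + mlen, tstart + mlen

    cigar = merge_cigar(ops)
    q_cols, t_cols = cigar_spans(cigar)
    alnlen = sum(l for _, l in cigar)

    q0, t0 = rows[0][0], rows[0][1]
    qe_aln, te_aln = q0 + q_cols, t0 + t_cols
    if chain.strand == 1:
        qstart_f, qend_f = qlen - qe_aln, qlen - q0
    else:
        qstart_f, qend_f = q0, qe_aln

    flag_char = "S" if chain.flag == ChainFlag.SECONDARY else "P"
    rec = PafRecord(
        qname=query.name,
        qlen=qlen,
        qstart=qstart_f,
        qend=qend_f,
        strand="-" if chain.strand == 1 else "+",
        tname=ref.name,
        tlen=ref.length,
        tstart=t0,
        tend=te_aln,
        nmatch=nmatch,
        alnlen=alnlen,
        mapq=60,
        tags=[
            ("tp", "A", flag_char),
            ("cm", "i", chain.n_anchors),
            ("s1", "i", int(math.floor(chain.score))),
            ("cg", "Z", cigar_to_str(cigar)),
        ],
    )
    rec.validate()
    return rec
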