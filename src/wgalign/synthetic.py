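"""Synthetic reference/query genome pairs with exact truth records.

Structural events (inversions, duplications, translocations) are applied
first at fixed, non-overlapping footprints; point mutations (SNPs, short
indels) are then scattered outside those footprints. Because edits never
cascade, both reference and query coordinates of every event are exact and
are emitted as truth records plus a BED serialization (reference
coordinates, 0-based half-open).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from ._util import revcomp
from .errors import InvalidSpecError
from .genome_io import SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class MutationSpec:
    snp_rate: float = 0.0
    indel_rate: float = 0.0
    indel_max: int = 10
    inversions: Tuple[Tuple[int, int, int], ...] = ()  # (seqid, start, length)
    duplications: Tuple[Tuple[int, int, int, int], ...] = ()  # (+ insert_at)
    translocations: Tuple[Tuple[int, int, int, int, int], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.snp_rate <= 1.0 and 0.0 <= self.indel_rate <= 1.0):
            raise InvalidSpecError("mutation rates must be in [0, 1]")
        if self.indel_max < 1:
            raise InvalidSpecError("indel_max must be >= 1")


@dataclass
class TruthEvent:
    kind: str  # SNP | INS | DEL | INV | DUP | TRA
    ref_seqid: int
    ref_start: int
    ref_end: int
    query_seqid: int
    query_start: int
    query_end: int
    detail: str = ""


def random_genome(
    n_seqs: int, lengths: Sequence[int], seed: int
) -> List[SequenceRecord]:
    """I.i.d. uniform A/C/G/T sequences named chr1..chrN, reproducible from seed."""
    if len(lengths) != n_seqs:
        raise InvalidSpecError(
            f"n_seqs={n_seqs} but {len(lengths)} lengths given"
        )
    if any(l <= 0 for l in lengths):
        raise InvalidSpecError("sequence lengths must be positive")
    rng = np.random.default_rng(seed)
    records = []
    for i, length in enumerate(lengths):
        codes = rng.integers(0, 4, size=length)
        seq = _BASES[codes].tobytes().decode("ascii")
        records.append(SequenceRecord(name=f"chr{i + 1}", seq=seq))
    return records


# Internal edit representation: (ref_pos, ref_consumed, kind, payload)
# sorted by ref_pos; insertions consume 0 reference bases.


def _structural_edits(ref, spec):
    """Per-sequence edit lists and footprints for the structural events."""
    edits: Dict[int, List] = {i: [] for i in range(len(ref))}
    footprints: Dict[int, List[Tuple[int, int]]] = {i: [] for i in range(len(ref))}

    def claim(seqid, start, end):
        if seqid < 0 or seqid >= len(ref):
            raise InvalidSpecError(f"seqid {seqid} out of range")
        if not (0 <= start < end <= ref[seqid].length):
            raise InvalidSpecError(
                f"interval [{start}, {end}) out of bounds for {ref[seqid].name}"
            )
        for s, e in footprints[seqid]:
            if max(s, start) < min(e, end):
                raise InvalidSpecError(
                    f"overlapping events on {ref[seqid].name}: "
                    f"[{start}, {end}) vs [{s}, {e})"
                )
        footprints[seqid].append((start, end))

    def claim_point(seqid, insert_at):
        if not (0 <= insert_at <= ref[seqid].length):
            raise InvalidSpecError(
                f"insert_at {insert_at} out of bounds for {ref[seqid].name}"
            )
        if insert_at < ref[seqid].length:
            claim(seqid, insert_at, insert_at + 1)

    for seqid, start, length in spec.inversions:
        claim(seqid, start, start + length)
        edits[seqid].append((start, length, "INV", None))
    for seqid, start, length, insert_at in spec.duplications:
        claim(seqid, start, start + length)
        claim_point(seqid, insert_at)
        content = ref[seqid].seq[start : start + length]
        edits[seqid].append(
            (insert_at, 0, "DUP", (content, seqid, start, start + length))
        )
    for src, start, length, dst, insert_at in spec.translocations:
        claim(src, start, start + length)
        claim_point(dst, insert_at)
        content = ref[src].seq[start : start + length]
        edits[src].append((start, length, "TRA_CUT", (src, start, start + length)))
        edits[dst].append(
            (insert_at, 0, "TRA_INS", (content, src, start, start + length))
        )
    return edits, footprints


def _point_edits(ref, spec, footprints, rng):
    """SNP and indel edits outside structural footprints, per sequence."""
    edits: Dict[int, List] = {i: [] for i in range(len(ref))}
    for seqid, rec in enumerate(ref):
        n = rec.length
        blocked = np.zeros(n, dtype=bool)
        for s, e in footprints[seqid]:
            blocked[s:e] = True
        snp_pos = np.nonzero((rng.random(n) < spec.snp_rate) & ~blocked)[0]
        indel_pos = np.nonzero((rng.random(n) < spec.indel_rate) & ~blocked)[0]
        taken = set(snp_pos.tolist())
        for p in snp_pos.tolist():
            old = rec.seq[p]
            choices = [b for b in "ACGT" if b != old] or ["N"]
            alt = choices[int(rng.integers(0, len(choices)))]
            edits[seqid].append((p, 1, "SNP", alt))
        for p in indel_pos.tolist():
            length = int(rng.integers(1, spec.indel_max + 1))
            if rng.random() < 0.5:  # insertion before p
                if p in taken:
                    continue
                ins = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
                edits[seqid].append((p, 0, "INS", ins))
                taken.add(p)
            else:  # deletion of [p, p+length)
                end = min(p + length, n)
                span = range(p, end)
                if any(q in taken for q in span) or blocked[p:end].any():
                    continue
                edits[seqid].append((p, end - p, "DEL", None))
                taken.update(span)
    return edits


_KIND_ORDER = {"SNP": 0, "INS": 1, "DEL": 2, "INV": 3, "DUP": 4, "TRA_CUT": 5, "TRA_INS": 6}


def mutate(
    ref: Sequence[SequenceRecord], spec: MutationSpec
) -> Tuple[List[SequenceRecord], List[TruthEvent], str]:
    """Apply the spec to the reference; return (query, truth, BED text)."""
    rng = np.random.default_rng(spec.seed)
    struct, footprints = _structural_edits(list(ref), spec)
    points = _point_edits(list(ref), spec, footprints, rng)

    query: List[SequenceRecord] = []
    truth: List[TruthEvent] = []
    for seqid, rec in enumerate(ref):
        edits = sorted(
            struct[seqid] + points[seqid],
            key=lambda t: (t[0], _KIND_ORDER[t[2]]),
        )
        out: List[str] = []
        cursor = 0
        qpos = 0
        for pos, consumed, kind, payload in edits:
            if pos < cursor:
                raise InvalidSpecError(
                    f"overlapping edits on {rec.name} near position {pos}"
                )
            keep = rec.seq[cursor:pos]
            out.append(keep)
            qpos += len(keep)
            if kind == "SNP":
                out.append(payload)
                truth.append(
                    TruthEvent("SNP", seqid, pos, pos + 1, seqid, qpos, qpos + 1,
                               f"{rec.seq[pos]}>{payload}")
                )
                qpos += 1
            elif kind == "INS":
                out.append(payload)
                truth.append(
                    TruthEvent("INS", seqid, pos, pos, seqid, qpos,
                               qpos + len(payload), payload)
                )
                qpos += len(payload)
            elif kind == "DEL":
                truth.append(
                    TruthEvent("DEL", seqid, pos, pos + consumed, seqid, qpos, qpos)
                )
            elif kind == "INV":
                out.append(revcomp(rec.seq[pos : pos + consumed]))
                truth.append(
                    TruthEvent("INV", seqid, pos, pos + consumed, seqid, qpos,
                               qpos + consumed)
                )
                qpos += consumed
            elif kind == "DUP":
                content, sq, ss, se = payload
                out.append(content)
                truth.append(
                    TruthEvent("DUP", sq, ss, se, seqid, qpos, qpos + len(content),
                               f"insert_at={pos}")
                )
                qpos += len(content)
            elif kind == "TRA_CUT":
                sq, ss, se = payload
                # query coordinates recorded by the paired TRA_INS edit
            elif kind == "TRA_INS":
                content, sq, ss, se = payload
                out.append(content)
                truth.append(
                    TruthEvent("TRA", sq, ss, se, seqid, qpos, qpos + len(content),
                               f"dst={rec.name}:{pos}")
                )
                qpos += len(content)
            cursor = pos + consumed
        out.append(rec.seq[cursor:])
        query.append(SequenceRecord(name=rec.name, seq="".join(out)))

    bed_lines = [
        f"{ref[ev.ref_seqid].name}\t{ev.ref_start}\t{ev.ref_end}\t{ev.kind}\n"
        for ev in truth
    ]
    return query, truth, "".join(bed_lines)
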