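"""FASTA input and PAF output.

Coordinates are 0-based half-open everywhere in the package, matching the PAF
convention; no conversion happens at any boundary.
"""
from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, List, Sequence, Tuple, Union

from .errors import InternalConsistencyError, MalformedInputError

PathOrStream = Union[str, Path, IO]

# Uppercase and collapse anything outside {A,C,G,T,N} to N in one pass.
_CLEAN = {}
for _i in range(256):
    _ch = chr(_i).upper()
    _CLEAN[_i] = _ch if _ch in "ACGTN" else "N"
_CLEAN_TABLE = str.maketrans({k: v for k, v in _CLEAN.items() if chr(k) != v})


@dataclass
class SequenceRecord:
    """One FASTA sequence: name is the first whitespace-delimited header token."""

    name: str
    seq: str
    length: int = field(default=-1)

    def __post_init__(self):
        if self.length < 0:
            self.length = len(self.seq)


@dataclass
class PafRecord:
    """One PAF alignment row: 12 mandatory columns plus typed tags."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    alnlen: int
    mapq: int
    tags: List[Tuple[str, str, object]] = field(default_factory=list)

    def validate(self) -> None:
        ok = (
            0 <= self.qstart < self.qend <= self.qlen
            and 0 <= self.tstart < self.tend <= self.tlen
            and self.nmatch <= self.alnlen
            and self.strand in "+-"
            and 0 <= self.mapq <= 255
        )
        if not ok:
            raise InternalConsistencyError(
                f"invalid PAF record for query {self.qname!r} vs {self.tname!r}: "
                f"q[{self.qstart},{self.qend})/{self.qlen} "
                f"t[{self.tstart},{self.tend})/{self.tlen} "
                f"nmatch={self.nmatch} alnlen={self.alnlen} mapq={self.mapq}"
            )


def _open_text(source: PathOrStream) -> IO:
    if isinstance(source, (str, Path)):
        with open(source, "rb") as probe:
            magic = probe.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(source, "rt")
        return open(source, "rt")
    if isinstance(source, io.TextIOBase):
        return source
    # binary stream: sniff for gzip
    data = source.read()
    if isinstance(data, str):
        return io.StringIO(data)
    if data[:2] == b"\x1f\x8b":
        data = gzip.decompress(data)
    return io.StringIO(data.decode("ascii"))


def read_fasta(source: PathOrStream) -> List[SequenceRecord]:
    """Read a (possibly gzip-compressed) multi-FASTA file.

    Lowercase bases are uppercased; characters outside {A,C,G,T,N} become N;
    wrapped sequence lines are concatenated. Raises MalformedInputError (with a
    line number) on an empty file, text before the first header, or a record
    with an empty sequence.
    """
    handle = _open_text(source)
    close = handle is not source
    try:
        records: List[SequenceRecord] = []
        name = None
        header_line = 0
        parts: List[str] = []
        saw_any = False

        def flush():
            if name is None:
                return
            seq = "".join(parts)
            if not seq:
                raise MalformedInputError(
                    f"record {name!r} (header at line {header_line}) has an empty sequence"
                )
            records.append(SequenceRecord(name=name, seq=seq))

        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            saw_any = True
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise MalformedInputError(f"empty FASTA header at line {lineno}")
                header_line = lineno
                parts = []
            else:
                if name is None:
                    raise MalformedInputError(
                        f"sequence text before first '>' header at line {lineno}"
                    )
                parts.append(line.translate(_CLEAN_TABLE).upper())
        if not saw_any:
            raise MalformedInputError("empty FASTA input (line 1)")
        flush()
        return records
    finally:
        if close:
            handle.close()


def _format_tag_value(typ: str, value) -> str:
    if typ == "i":
        return str(int(value))
    if typ == "f":
        return str(float(value))
    return str(value)


def write_paf(records: Iterable[PafRecord], sink: PathOrStream) -> None:
    """Serialize records as PAF, one tab-separated line each, in input order."""
    text = paf_text(records)
    if isinstance(sink, (str, Path)):
        with open(sink, "w") as fh:
            fh.write(text)
    else:
        sink.write(text)


def paf_text(records: Iterable[PafRecord]) -> str:
    lines = []
    for rec in records:
        rec.validate()
        cols = [
            rec.qname,
            str(rec.qlen),
            str(rec.qstart),
            str(rec.qend),
            rec.strand,
            rec.tname,
            str(rec.tlen),
            str(rec.tstart),
            str(rec.tend),
            str(rec.nmatch),
            str(rec.alnlen),
            str(rec.mapq),
        ]
        for tag, typ, value in rec.tags:
            cols.append(f"{tag}:{typ}:{_format_tag_value(typ, value)}")
        lines.append("\t".join(cols) + "\n")
    return "".join(lines)


def parse_paf(source: PathOrStream) -> List[PafRecord]:
    """Parse PAF text; inverse of write_paf on its image.

    Unknown tags are preserved verbatim (typed by their TYPE letter).
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source.read()
    records = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise MalformedInputError(
                f"PAF line {lineno}: expected >=12 columns, got {len(cols)}"
            )
        try:
            rec = PafRecord(
                qname=cols[0],
                qlen=int(cols[1]),
                qstart=int(cols[2]),
                qend=int(cols[3]),
                strand=cols[4],
                tname=cols[5],
                tlen=int(cols[6]),
                tstart=int(cols[7]),
                tend=int(cols[8]),
                nmatch=int(cols[9]),
                alnlen=int(cols[10]),
                mapq=int(cols[11]),
            )
        except ValueError as exc:
            raise MalformedInputError(f"PAF line {lineno}: {exc}") from exc
        for col in cols[12:]:
            parts = col.split(":", 2)
            if len(parts) != 3:
                raise MalformedInputError(
                    f"PAF line {lineno}: malformed tag {col!r}"
                )
            tag, typ, raw = parts
            value: object = raw
            if typ == "i":
                value = int(raw)
            elif typ == "f":
                value = float(raw)
            rec.tags.append((tag, typ, value))
        records.append(rec)
    return records
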