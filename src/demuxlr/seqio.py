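"""Streaming FASTA/FASTQ readers and writers.

Input may be a path, ``"-"`` (standard input) or an open binary handle;
gzip is detected from the magic bytes and the record format from the first
character (``>`` FASTA, ``@`` FASTQ), so pipelines never need to declare
either.  Parsing is done with Biopython's low-level iterators
(`SimpleFastaParser`, `FastqGeneralIterator`) which stream record by record
and keep quality strings verbatim — output is therefore a bit-exact
round trip for unwrapped records.
"""

from __future__ import annotations

import gzip
import io
import sys
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

GZIP_MAGIC = b"\x1f\x8b"


@dataclass
class Read:
    """One sequencing record; ``id`` is the first whitespace token."""

    id: str
    sequence: str
    description: str = ""
    qualities: Optional[str] = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )


class MalformedRecordError(ValueError):
    pass


def _split_title(title: str):
    parts = title.split(None, 1)
    return parts[0] if parts else "", parts[1] if len(parts) > 1 else ""


def _binary_source(source) -> io.BufferedReader:
    if source == "-" or source is None:
        raw = sys.stdin.buffer
    elif hasattr(source, "read"):
        raw = source
    else:
        raw = open(source, "rb")
    if not isinstance(raw, io.BufferedReader):
        try:
            raw = io.BufferedReader(raw)
        except (TypeError, AttributeError):
            pass
    return raw


def open_reads(source) -> Iterator[Read]:
    """Stream reads from a FASTA/FASTQ file, gzipped or not, or stdin.

    Sequences are uppercased on ingest; record order is preserved; an empty
    input yields an empty stream.  Malformed records raise
    :class:`MalformedRecordError` carrying the record index.
    """
    buf = _binary_source(source)
    head = buf.peek(2)[:2] if hasattr(buf, "peek") else b""
    if head == GZIP_MAGIC:
        buf = io.BufferedReader(gzip.GzipFile(fileobj=buf))
    first = buf.peek(1)[:1] if hasattr(buf, "peek") else b""
    text = io.TextIOWrapper(buf, encoding="ascii")
    if not first:
        return
    if first == b">":
        parser = SimpleFastaParser(text)
        fastq = False
    elif first == b"@":
        parser = FastqGeneralIterator(text)
        fastq = True
    else:
        raise MalformedRecordError(
            f"cannot determine format from first byte {first!r} (expected '>' or '@')"
        )
    index = 0
    while True:
        try:
            item = next(parser, None)
        except ValueError as exc:
            raise MalformedRecordError(f"malformed record at index {index}: {exc}") from exc
        if item is None:
            return
        try:
            if fastq:
                title, seq, qual = item
                rid, desc = _split_title(title)
                yield Read(id=rid, sequence=seq.upper(), description=desc, qualities=qual)
            else:
                title, seq = item
                rid, desc = _split_title(title)
                yield Read(id=rid, sequence=seq.upper(), description=desc)
        except ValueError as exc:
            raise MalformedRecordError(f"malformed record at index {index}: {exc}") from exc
        index += 1


def _as_read(record) -> Read:
    if isinstance(record, Read):
        return record
    # DemuxRecord duck-typing: build the conventional output name
    return Read(
        id=record.output_id(),
        sequence=record.trimmed_sequence,
        description=record.source_read_id,
        qualities=record.trimmed_qualities,
    )


def _open_sink(sink):
    if sink == "-" or sink is None:
        return sys.stdout, False
    if hasattr(sink, "write"):
        return sink, False
    if str(sink).endswith(".gz"):
        return gzip.open(sink, "wt"), True
    return open(sink, "w"), True


def write_reads(records: Iterable, sink, fmt: str = "fastq") -> int:
    """Write reads (or demux records) as unwrapped FASTA or FASTQ.

    FASTQ output fabricates ``'I'`` qualities when a record has none.
    Returns the number of records written.
    """
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    out, close = _open_sink(sink)
    n = 0
    try:
        for record in records:
            read = _as_read(record)
            header = f"{read.id} {read.description}".rstrip()
            if fmt == "fasta":
                out.write(f">{header}\n{read.sequence}\n")
            else:
                qual = read.qualities or "I" * len(read.sequence)
                out.write(f"@{header}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    finally:
        out.flush()
        if close:
            out.close()
    return n


ASSIGNMENT_HEADER = (
    "#read_id\tsub_read_index\tbarcode\tdistance\tumi\tstrand\tstatus\tflank_edit_distance"
)


def write_assignments(records: Iterable, sink) -> int:
    """Write the per-record assignment table as TSV with a '#' header."""
    out, close = _open_sink(sink)
    n = 0
    try:
        out.write(ASSIGNMENT_HEADER + "\n")
        for rec in records:
            a = rec.assignment
            row = (
                rec.source_read_id,
                str(rec.sub_read_index),
                a.barcode or "-",
                "-" if a.distance is None else str(a.distance),
                a.umi or "-",
                rec.strand,
                a.status.value,
                "-" if a.flank_distance is None else str(a.flank_distance),
            )
            out.write("\t".join(row) + "\n")
            n += 1
    finally:
        out.flush()
        if close:
            out.close()
    return n
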