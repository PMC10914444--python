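"""Declarative read-structure description and window extraction.

A read structure is an ordered list of segments: fixed-sequence flanks
(primer, polyT, any anchor sequence) and variable segments (one barcode,
one UMI) known only by length.  The default models a 10x Genomics 3' v3
library read as seen by long-read sequencing: 22 nt of read-1 primer,
a 16 nt cell barcode, a 12 nt UMI, then 9 nt of polyT.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .align import WILDCARD, InfixHit, align_prefix_ends, encode


class StructureError(ValueError):
    """Raised for read structures that violate an invariant."""


class SegmentKind(enum.Enum):
    FLANK = "flank"
    BARCODE = "barcode"
    UMI = "umi"


@dataclass(frozen=True)
class Segment:
    kind: SegmentKind
    sequence: Optional[str] = None
    length: Optional[int] = None
    name: str = ""

    def __post_init__(self):
        if self.kind is SegmentKind.FLANK:
            if not self.sequence:
                raise StructureError("FLANK segment requires a non-empty sequence")
            if self.length is not None:
                raise StructureError("FLANK segment must not carry a length")
            seq = self.sequence.upper()
            encode(seq)  # validates the alphabet
            if WILDCARD in seq or "X" in seq:
                raise StructureError("FLANK sequence may not contain '?' or 'X'")
            object.__setattr__(self, "sequence", seq)
        else:
            if self.sequence is not None:
                raise StructureError(f"{self.kind.name} segment must not carry a sequence")
            if self.length is None or self.length < 1:
                raise StructureError(f"{self.kind.name} segment requires length >= 1")

    @property
    def n_bases(self) -> int:
        return len(self.sequence) if self.sequence is not None else int(self.length)


def flank(sequence: str, name: str = "flank") -> Segment:
    return Segment(SegmentKind.FLANK, sequence=sequence, name=name)


def barcode(length: int, name: str = "barcode") -> Segment:
    return Segment(SegmentKind.BARCODE, length=length, name=name)


def umi(length: int, name: str = "umi") -> Segment:
    return Segment(SegmentKind.UMI, length=length, name=name)


# Published standard sequences for the default structure: the 3' end of the
# 10x read-1 primer (22 nt) and a 9 nt polyT stretch.  Fully overridable.
DEFAULT_PRIMER = "CTACACGACGCTCTTCCGATCT"
DEFAULT_POLYT = "TTTTTTTTT"


@dataclass(frozen=True)
class ReadStructure:
    """Ordered segments plus the search/assignment tolerances.

    ``flank_max_d`` bounds the edit distance of the full wildcard pattern
    against the read (default 8), ``barcode_max_d`` bounds barcode
    error-correction (default 2), and ``window_pad`` widens the extracted
    variable region by a few bases on each side (default 5) so that flank
    alignment slippage cannot push the true barcode out of the window.
    """

    segments: tuple
    flank_max_d: int = 8
    barcode_max_d: int = 2
    window_pad: int = 5

    def __post_init__(self):
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if not any(s.kind is SegmentKind.FLANK for s in segs):
            raise StructureError("structure requires at least one FLANK segment")
        for kind in (SegmentKind.BARCODE, SegmentKind.UMI):
            if sum(1 for s in segs if s.kind is kind) > 1:
                raise StructureError(f"at most one {kind.name} segment is allowed")
        if self.flank_max_d < 0 or self.barcode_max_d < 0 or self.window_pad < 0:
            raise StructureError("tolerances and padding must be >= 0")

    def _segment(self, kind: SegmentKind) -> Optional[Segment]:
        for s in self.segments:
            if s.kind is kind:
                return s
        return None

    @property
    def barcode_segment(self) -> Optional[Segment]:
        return self._segment(SegmentKind.BARCODE)

    @property
    def umi_segment(self) -> Optional[Segment]:
        return self._segment(SegmentKind.UMI)

    @property
    def has_variable(self) -> bool:
        return any(s.kind is not SegmentKind.FLANK for s in self.segments)

    def _span(self, kind: SegmentKind):
        pos = 0
        for s in self.segments:
            if s.kind is kind:
                return pos, pos + s.n_bases
            pos += s.n_bases
        return None

    @property
    def variable_span(self):
        """Pattern-coordinate interval covering all variable segments."""
        pos, lo, hi = 0, None, None
        for s in self.segments:
            if s.kind is not SegmentKind.FLANK:
                lo = pos if lo is None else lo
                hi = pos + s.n_bases
            pos += s.n_bases
        return None if lo is None else (lo, hi)

    @property
    def barcode_span(self):
        return self._span(SegmentKind.BARCODE)

    @property
    def umi_after_barcode(self) -> bool:
        """True when the UMI segment follows the barcode segment."""
        kinds = [s.kind for s in self.segments]
        return kinds.index(SegmentKind.UMI) > kinds.index(SegmentKind.BARCODE)


def default_structure(
    primer: str = DEFAULT_PRIMER,
    polyt: str = DEFAULT_POLYT,
    barcode_length: int = 16,
    umi_length: int = 12,
    **tolerances,
) -> ReadStructure:
    """The standard 10x 3' v3 layout: primer, barcode, UMI, polyT."""
    return ReadStructure(
        segments=(
            flank(primer, "primer"),
            barcode(barcode_length),
            umi(umi_length),
            flank(polyt, "polyT"),
        ),
        **tolerances,
    )


def build_pattern(structure: ReadStructure) -> str:
    """Concatenate segment contributions into the search pattern.

    Flanks contribute their literal sequence, variable segments a run of
    ``?`` wildcards of their length, in structure order.
    """
    parts = []
    for s in structure.segments:
        if s.kind is SegmentKind.FLANK:
            parts.append(s.sequence)
        else:
            parts.append(WILDCARD * s.length)
    return "".join(parts)


@dataclass(frozen=True)
class ExtractionWindow:
    """The variable region of a hit, padded, in strand-normalised coordinates."""

    window: str
    read_interval: tuple
    strand: str
    variable_interval: tuple = field(default=(0, 0))


def locate_span(text: str, hit: InfixHit, structure: ReadStructure, span) -> tuple:
    """Map a pattern-coordinate span to text coordinates through traceback.

    Globally aligns the pattern to the matched substring and reads off the
    text offsets at which the span's pattern prefix boundaries land.
    """
    ends = align_prefix_ends(build_pattern(structure), text[hit.start : hit.end])
    lo, hi = span
    return hit.start + int(ends[lo]), hit.start + int(ends[hi])


def extract_window(read, hit: InfixHit, structure: ReadStructure) -> ExtractionWindow:
    """Extract the barcode+UMI window (± ``window_pad``) from a flank hit.

    ``read`` may be a sequence string or anything with a ``sequence``
    attribute; it must be the same (possibly reverse-complemented, possibly
    masked) text that produced ``hit``.  The window is clipped to the read
    bounds; the variable-region interval itself is recorded alongside.
    """
    text = read if isinstance(read, str) else read.sequence
    span = structure.variable_span
    if span is None:
        raise StructureError(
            "structure has no variable segment; search-only mode bypasses extraction"
        )
    a, b = locate_span(text, hit, structure, span)
    ws = max(0, a - structure.window_pad)
    we = min(len(text), b + structure.window_pad)
    return ExtractionWindow(
        window=text[ws:we],
        read_interval=(ws, we),
        strand=hit.strand,
        variable_interval=(a, b),
    )
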