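"""Per-read demultiplexing engine.

For each read the engine (i) locates the flank pattern by semi-global
search, (ii) extracts the padded barcode+UMI window, (iii) error-corrects
the barcode against the whitelist, (iv) masks the matched interval with the
sentinel and repeats — catching chimeric reads carrying several barcode
structures — and (v) runs the identical loop on the reverse complement of
the still-masked read.  Found structures are then used to split and trim
the read into per-molecule records.

Barcode assignment follows a unique-minimum rule: each whitelist barcode is
scored by its semi-global edit distance against the window (both window
ends free); the single barcode attaining the minimum is reported if that
minimum is within ``barcode_max_d``, ties are AMBIGUOUS, and a minimum
above the threshold is NO_BARCODE.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional

import numpy as np

from .align import SENTINEL, _SUB, InfixHit, encode, infix_search, reverse_complement
from .structure import (
    ExtractionWindow,
    ReadStructure,
    build_pattern,
    extract_window,
)


class AssignmentStatus(enum.Enum):
    ASSIGNED = "assigned"
    AMBIGUOUS = "ambiguous"
    NO_FLANK = "no_flank"
    NO_BARCODE = "no_barcode"


@dataclass(frozen=True)
class BarcodeAssignment:
    status: AssignmentStatus
    barcode: Optional[str] = None
    distance: Optional[int] = None
    umi: Optional[str] = None
    umi_truncated: bool = False
    window: Optional[ExtractionWindow] = None
    flank_distance: Optional[int] = None
    barcode_interval: Optional[tuple] = None


@dataclass
class DemuxRecord:
    """One demultiplexed (sub-)read.

    ``sub_read_index`` is greater than zero only for chimera-split outputs.
    ``trimmed_sequence`` is strand-normalised: it reads 5'→3' downstream of
    the barcode structure.
    """

    source_read_id: str
    sub_read_index: int
    assignment: BarcodeAssignment
    trimmed_sequence: str
    trimmed_qualities: Optional[str]
    strand: str
    structure_interval: Optional[tuple] = None  # original-read coordinates

    @property
    def status(self) -> AssignmentStatus:
        return self.assignment.status

    def output_id(self) -> str:
        bc = self.assignment.barcode or "-"
        u = self.assignment.umi or "-"
        return f"{bc}_{u}#{self.source_read_id}_{self.sub_read_index}"


@dataclass(frozen=True)
class DemuxParams:
    split_chimeras: bool = True
    max_rounds: int = 10  # cap on mask-iterate rounds per strand


class BarcodeIndex:
    """An immutable, order-independent whitelist with pre-encoded barcodes."""

    def __init__(self, barcodes: Iterable[str]):
        uniq = sorted({str(b).strip().upper() for b in barcodes if str(b).strip()})
        if not uniq:
            raise ValueError(
                "whitelist is empty; run barcode discovery instead of demultiplexing"
            )
        lengths = {len(b) for b in uniq}
        if len(lengths) != 1:
            raise ValueError(f"whitelist barcodes have mixed lengths: {sorted(lengths)}")
        self.barcodes: List[str] = uniq
        self.length: int = lengths.pop()
        self.matrix = np.stack([encode(b) for b in uniq])
        # per-position substitution-cost rows, indexed later by window codes
        self._cost = _SUB[self.matrix]  # (k, length, |alphabet|)

    def __len__(self) -> int:
        return len(self.barcodes)

    def __contains__(self, b: str) -> bool:
        return b in set(self.barcodes)


def as_index(whitelist) -> BarcodeIndex:
    return whitelist if isinstance(whitelist, BarcodeIndex) else BarcodeIndex(whitelist)


def mask_interval(seq: str, interval) -> str:
    """Overwrite ``seq[interval]`` with the sentinel; length is preserved."""
    s, e = interval
    if not (0 <= s <= e <= len(seq)):
        raise ValueError(f"interval {interval} out of bounds for length {len(seq)}")
    return seq[:s] + SENTINEL * (e - s) + seq[e:]


def _semi_global_distances(index: BarcodeIndex, window: str) -> np.ndarray:
    """Semi-global distance of every whitelist barcode against the window.

    Vectorised across the whole whitelist: the DP iterates over barcode
    positions (rows), carrying a (k, |window|+1) state; the in-row
    dependency along the window axis is resolved with the prefix-min trick.
    """
    ct = encode(window)
    k, lb = index.matrix.shape
    n = len(ct)
    if n == 0:
        return np.full(k, lb, dtype=np.int64)
    ar = np.arange(n + 1, dtype=np.int64)
    prev = np.zeros((k, n + 1), dtype=np.int64)  # row 0: window start is free
    cand = np.empty((k, n + 1), dtype=np.int64)
    for i in range(lb):
        cand[:, 0] = i + 1
        np.minimum(prev[:, :-1] + index._cost[:, i, :][:, ct],
                   prev[:, 1:] + 1, out=cand[:, 1:])
        prev = np.minimum.accumulate(cand - ar, axis=1) + ar
    return prev.min(axis=1)  # window end is free too


def assign_barcode(window, whitelist, barcode_max_d: int) -> BarcodeAssignment:
    """Error-correct one extracted window against the whitelist.

    Returns ASSIGNED with the unique nearest barcode when its distance is
    within ``barcode_max_d``; AMBIGUOUS when two or more barcodes tie at the
    minimum; NO_BARCODE otherwise.
    """
    index = as_index(whitelist)
    win = window.window if isinstance(window, ExtractionWindow) else str(window)
    dists = _semi_global_distances(index, win)
    d = int(dists.min())
    ew = window if isinstance(window, ExtractionWindow) else None
    if d > barcode_max_d:
        return BarcodeAssignment(status=AssignmentStatus.NO_BARCODE, distance=d, window=ew)
    winners = np.nonzero(dists == d)[0]
    if len(winners) > 1:
        return BarcodeAssignment(status=AssignmentStatus.AMBIGUOUS, distance=d, window=ew)
    bc = index.barcodes[int(winners[0])]
    # locate the barcode inside the window for UMI extraction
    hit = infix_search(bc, win, max_d=d)
    interval = None
    if hit is not None and ew is not None:
        off = ew.read_interval[0]
        interval = (off + hit.start, off + hit.end)
    return BarcodeAssignment(
        status=AssignmentStatus.ASSIGNED,
        barcode=bc,
        distance=d,
        window=ew,
        barcode_interval=interval,
    )


def extract_umi(norm_seq: str, assignment: BarcodeAssignment, structure: ReadStructure):
    """UMI bases adjacent to the located barcode, on the normalised strand.

    The UMI follows the barcode when the structure orders it after the
    barcode, and precedes it otherwise.  A shorter-than-expected tail yields
    a truncated UMI plus a flag, never an error.
    """
    useg = structure.umi_segment
    if useg is None or assignment.barcode_interval is None:
        return None, False
    bs, be = assignment.barcode_interval
    ulen = useg.length
    if structure.umi_after_barcode:
        u = norm_seq[be : be + ulen]
    else:
        u = norm_seq[max(0, bs - ulen) : bs]
    return u, len(u) < ulen


@dataclass
class _Locus:
    hit: InfixHit  # frame coordinates
    strand: str
    frame_text: str  # text state (with earlier masks) when found
    orig_interval: tuple  # original-read coordinates
    assignment: BarcodeAssignment = field(
        default_factory=lambda: BarcodeAssignment(status=AssignmentStatus.NO_FLANK)
    )


def iter_structure_loci(seq: str, structure: ReadStructure, max_rounds: int = 10):
    """Scan both strands with iterative masking; yield loci as found.

    The forward strand is scanned repeatedly, masking each hit (flanks plus
    variable region) with the sentinel, until no further hit exists or the
    round cap is reached.  The reverse complement of the masked read is then
    scanned the same way, so forward hits can never be re-found on the
    reverse strand.  Every locus is yielded — callers decide what to do with
    hits whose barcode cannot be assigned.
    """
    pattern = build_pattern(structure)
    loci: List[_Locus] = []
    text = seq
    n = len(seq)
    for _ in range(max_rounds):
        hit = infix_search(pattern, text, structure.flank_max_d)
        if hit is None:
            break
        loci.append(
            _Locus(hit=hit, strand="+", frame_text=text, orig_interval=(hit.start, hit.end))
        )
        text = mask_interval(text, (hit.start, hit.end))
    rc_text = reverse_complement(text)
    for _ in range(max_rounds):
        hit = infix_search(pattern, rc_text, structure.flank_max_d)
        if hit is None:
            break
        hit = replace(hit, strand="-")
        loci.append(
            _Locus(
                hit=hit,
                strand="-",
                frame_text=rc_text,
                orig_interval=(n - hit.end, n - hit.start),
            )
        )
        rc_text = mask_interval(rc_text, (hit.start, hit.end))
    return loci


def _assign_locus(locus: _Locus, structure: ReadStructure, index, barcode_max_d: int):
    if not structure.has_variable or index is None:
        return
    win = extract_window(locus.frame_text, locus.hit, structure)
    asn = assign_barcode(win, index, barcode_max_d)
    asn = replace(asn, flank_distance=locus.hit.distance)
    if asn.status is AssignmentStatus.ASSIGNED:
        u, trunc = extract_umi(locus.frame_text, asn, structure)
        asn = replace(asn, umi=u, umi_truncated=trunc)
    locus.assignment = asn


def split_and_trim(read, records: List[DemuxRecord], structure: ReadStructure):
    """Fill in trimmed sequences/qualities for position-ordered records.

    Each record's insert runs from the end of its own structure to the start
    of the nearest downstream structure (or the read end), evaluated in that
    record's strand frame so the insert always reads 5'→3' downstream of the
    barcode.  Failure records pass the full read through untrimmed.
    """
    seq = read.sequence
    qual = read.qualities
    n = len(seq)
    intervals = [r.structure_interval for r in records if r.structure_interval]
    for rec in records:
        if rec.structure_interval is None:  # failure record: pass through
            rec.trimmed_sequence = seq
            rec.trimmed_qualities = qual
            continue
        if rec.strand == "+":
            frame_ivs = intervals
            own_end = rec.structure_interval[1]
        else:
            frame_ivs = [(n - e, n - s) for (s, e) in intervals]
            own_end = n - rec.structure_interval[0]
        nxt = min((s for (s, _e) in frame_ivs if s >= own_end), default=None)
        stop = n if nxt is None else nxt
        if rec.strand == "+":
            rec.trimmed_sequence = seq[own_end:stop]
            rec.trimmed_qualities = None if qual is None else qual[own_end:stop]
        else:
            rec.trimmed_sequence = reverse_complement(seq)[own_end:stop]
            rec.trimmed_qualities = None if qual is None else qual[::-1][own_end:stop]
    return records


def demultiplex_read(
    read,
    structure: ReadStructure,
    whitelist=None,
    params: DemuxParams = DemuxParams(),
) -> List[DemuxRecord]:
    """Demultiplex one read; returns records ordered by original position.

    One record per assigned structure locus (chimeric reads give several);
    when no locus can be assigned a single failure record carries the most
    informative status (NO_FLANK when the pattern was never found).
    """
    seq = read.sequence.upper()
    index = as_index(whitelist) if whitelist is not None else None
    if structure.has_variable and structure.barcode_segment is not None and index is None:
        raise ValueError("a whitelist is required to assign barcodes")

    max_rounds = params.max_rounds if params.split_chimeras else 1
    loci = iter_structure_loci(seq, structure, max_rounds=max_rounds)
    for locus in loci:
        _assign_locus(locus, structure, index, structure.barcode_max_d)

    loci.sort(key=lambda l: l.orig_interval)
    assigned = [l for l in loci if l.assignment.status is AssignmentStatus.ASSIGNED]
    if not params.split_chimeras and assigned:
        assigned = assigned[:1]

    records: List[DemuxRecord] = []
    if assigned:
        for i, locus in enumerate(assigned):
            records.append(
                DemuxRecord(
                    source_read_id=read.id,
                    sub_read_index=i,
                    assignment=locus.assignment,
                    trimmed_sequence="",
                    trimmed_qualities=None,
                    strand=locus.strand,
                    structure_interval=locus.orig_interval,
                )
            )
    else:
        asn = loci[0].assignment if loci else BarcodeAssignment(status=AssignmentStatus.NO_FLANK)
        records.append(
            DemuxRecord(
                source_read_id=read.id,
                sub_read_index=0,
                assignment=asn,
                trimmed_sequence="",
                trimmed_qualities=None,
                strand=loci[0].strand if loci else "+",
                structure_interval=None,
            )
        )
    return split_and_trim(read, records, structure)
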