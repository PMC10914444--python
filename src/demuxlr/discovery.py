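"""De novo barcode discovery and knee-plot filtering.

When no whitelist exists, the barcode-length stretch immediately following
the left flank of every structure hit is tallied as a putative barcode.
Real cell barcodes then separate from ambient/error barcodes on the
rank–frequency ("knee") plot: sorting barcodes by read count and plotting
log10(count) against log10(rank) shows a sharp drop — the knee — at the
boundary.  The filter approximates the derivative of that curve with a
rolling window and takes the most negative value inside a search range as
the inflection point; every barcode ranked at or above it is kept.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd

from .demux import iter_structure_loci
from .structure import ReadStructure, StructureError, locate_span


@dataclass
class BarcodeFrequencyTable:
    counts: dict
    total_reads: int = 0

    def sorted_items(self) -> List[tuple]:
        """(barcode, count) sorted by descending count, ties lexicographic."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_frame(self) -> pd.DataFrame:
        items = self.sorted_items()
        return pd.DataFrame(items, columns=["barcode", "count"])

    def write_tsv(self, sink) -> None:
        self.to_frame().to_csv(sink, sep="\t", header=False, index=False)

    @classmethod
    def read_tsv(cls, source) -> "BarcodeFrequencyTable":
        df = pd.read_csv(
            source, sep="\t", comment="#", header=None, names=["barcode", "count"]
        )
        counts = dict(zip(df["barcode"].astype(str), df["count"].astype(int)))
        return cls(counts=counts, total_reads=int(df["count"].sum()))


@dataclass
class KneeResult:
    inflection_rank: int
    count_at_inflection: int
    kept: List[str]
    derivative_series: np.ndarray
    search_range: tuple
    window: int
    low_confidence: bool = False


def count_putative_barcodes(
    reads: Iterable, structure: ReadStructure, max_rounds: int = 10
) -> BarcodeFrequencyTable:
    """Tally the sequence following the left flank across all reads.

    Both strands are scanned with the same mask-and-iterate loop as
    demultiplexing, so chimeric reads contribute one putative barcode per
    embedded structure.  Substrings containing ``N`` (or mask sentinel) or
    truncated below the barcode length are skipped.
    """
    bseg = structure.barcode_segment
    if bseg is None:
        raise StructureError("discovery requires a structure with a BARCODE segment")
    span = structure.barcode_span
    blen = bseg.length
    counts: Counter = Counter()
    total = 0
    for read in reads:
        total += 1
        seq = read.sequence.upper()
        for locus in iter_structure_loci(seq, structure, max_rounds=max_rounds):
            start, _end = locate_span(locus.frame_text, locus.hit, structure, span)
            putative = locus.frame_text[start : start + blen]
            if len(putative) < blen or any(c not in "ACGT" for c in putative):
                continue
            counts[putative] += 1
    return BarcodeFrequencyTable(counts=dict(counts), total_reads=total)


def rolling_derivative(sorted_counts, window: int) -> np.ndarray:
    """Rolling-window slope of the knee curve in log10–log10 space.

    With 1-based ranks, ``slope[i] = (log10 c[i+w] - log10 c[i]) /
    (log10 (i+w) - log10 i)`` for ``i = 1 .. N-w``.  Counts must be sorted
    descending, so every slope is <= 0.
    """
    counts = np.asarray(sorted_counts, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(counts) <= window:
        raise ValueError(
            f"need more than window={window} entries, got {len(counts)}"
        )
    logc = np.log10(counts)
    logr = np.log10(np.arange(1, len(counts) + 1, dtype=float))
    return (logc[window:] - logc[:-window]) / (logr[window:] - logr[:-window])


def find_inflection(slopes, search_range) -> int:
    """1-based rank minimising the slope within ``search_range`` (inclusive).

    Ties resolve to the smallest rank.
    """
    slopes = np.asarray(slopes, dtype=float)
    lo, hi = search_range
    lo = max(1, int(lo))
    hi = min(len(slopes), int(hi))
    if hi < lo:
        raise ValueError(f"empty inflection search range [{lo}, {hi}]")
    return lo + int(np.argmin(slopes[lo - 1 : hi]))


def knee_filter(
    table: BarcodeFrequencyTable,
    window: int = 20,
    search_range: Optional[tuple] = None,
    whitelist: Optional[Iterable[str]] = None,
    min_search_count: int = 5,
    plot_path: Optional[str] = None,
) -> KneeResult:
    """Call true barcodes from the rank–frequency knee.

    A whitelist, when given, restricts the table *before* the knee is
    computed (non-whitelist counts are discarded).  The default search
    range skips the first 9 ranks (super-loaded droplet artifacts) and
    stops at the last rank whose count is at least ``min_search_count``:
    among trailing barcodes seen only a handful of times the integer count
    plateaus (…2,2,1,1,1) make a per-rank log derivative arbitrarily steep,
    which would otherwise always win over the real knee.  Pass an explicit
    ``search_range`` to override both ends.
    """
    items = table.sorted_items()
    if whitelist is not None:
        allowed = {str(b).strip().upper() for b in whitelist}
        items = [(b, c) for (b, c) in items if b in allowed]
    n = len(items)
    if n < window + 1:
        raise ValueError(
            f"only {n} barcodes after restriction; need > window={window} "
            "(try a smaller window)"
        )
    barcodes = [b for b, _ in items]
    counts = np.array([c for _, c in items], dtype=float)
    slopes = rolling_derivative(counts, window)
    if search_range is None:
        hi = int(np.nonzero(counts >= min_search_count)[0].max() + 1) if (
            counts >= min_search_count
        ).any() else n - window
        hi = max(1, min(hi, n - window))
        # skip the first 9 ranks (super-loaded droplets) when there is room
        search_range = (min(10, hi), hi)
    rank = find_inflection(slopes, search_range)
    slope_at = slopes[rank - 1]
    median_mag = float(np.median(np.abs(slopes)))
    low_conf = bool(abs(slope_at) < 2.0 * median_mag)
    result = KneeResult(
        inflection_rank=rank,
        count_at_inflection=int(counts[rank - 1]),
        kept=barcodes[:rank],
        derivative_series=slopes,
        search_range=tuple(search_range),
        window=window,
        low_confidence=low_conf,
    )
    if plot_path is not None:
        plot_knee(counts, result, plot_path)
    return result


def plot_knee(sorted_counts, result: KneeResult, path) -> None:
    """Diagnostic log–log rank/count curve with the inflection marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = np.asarray(sorted_counts, dtype=float)
    ranks = np.arange(1, len(counts) + 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ranks, counts, lw=1.2, color="steelblue")
    ax.axvline(result.inflection_rank, color="firebrick", ls="--", lw=1,
               label=f"inflection rank {result.inflection_rank}")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("barcode rank")
    ax.set_ylabel("read count")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
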