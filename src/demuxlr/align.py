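"""Alignment primitives for error-tolerant sequence search.

This module implements the two Levenshtein-distance computations the whole
tool is built on:

* :func:`levenshtein` / :func:`bounded_levenshtein` — global edit distance
  between two sequences, used for barcode error correction and whitelist
  spacing checks.

* :func:`infix_search` — semi-global ("infix") search of a pattern inside a
  longer text, where both ends of the matched substring are free.  Patterns
  may carry ``?`` wildcards which match any real base at zero cost; this is
  how the unknown barcode+UMI stretch between two known flanking sequences
  is expressed.

Cost model (a true edit distance; all indels cost 1):

* ``?`` (pattern wildcard) substitutes against ``A/C/G/T/N`` — and itself —
  at cost 0.
* ``N`` in a read matches only ``N`` and ``?``; against a concrete base it
  costs 1.  This is deliberately conservative so that N-runs cannot fake a
  flank match.
* ``X`` is the mask sentinel written over already-found structure during
  chimera iteration.  It mismatches *everything, including itself*, so a
  masked region can never be matched again.

The dynamic programming is vectorised with numpy row-by-row; the recurrence
``D[i][j] = min(D[i-1][j-1]+cost, D[i-1][j]+1, D[i][j-1]+1)`` has a
left-to-right dependency within a row which is resolved with the standard
prefix-minimum trick: ``cur = min.accumulate(cand - j) + j``.  When the
optional ``edlib`` accelerator is importable, :func:`infix_search` first
asks it (k-bounded, with wildcard equivalences) whether any hit exists at
all, which makes rejecting structure-free sequence cheap; the coordinates
and tie-breaking of an actual hit are always produced by the in-package DP.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

try:  # optional accelerator; never required for correctness
    import edlib as _edlib
except ImportError:  # pragma: no cover - present in the supported environment
    _edlib = None

WILDCARD = "?"
SENTINEL = "X"
ALPHABET = "ACGTN?X"

_A, _C, _G, _T, _N, _Q, _X = range(7)

# substitution cost matrix over the 7-letter working alphabet (0 = free)
_SUB = np.ones((7, 7), dtype=np.int32)
for _i in (_A, _C, _G, _T, _N, _Q):
    _SUB[_i, _i] = 0
for _i in (_A, _C, _G, _T, _N):
    _SUB[_Q, _i] = 0
    _SUB[_i, _Q] = 0
# note: _SUB[_X, _X] stays 1 — the sentinel mismatches itself

_ENCODE = np.full(256, -1, dtype=np.int16)
for _i, _ch in enumerate(ALPHABET):
    _ENCODE[ord(_ch)] = _i
    _ENCODE[ord(_ch.lower())] = _i

_WILDCARD_EQUALITIES = [(WILDCARD, b) for b in "ACGTN"]


class _Exceeded:
    """Singleton returned by bounded_levenshtein when the bound is passed."""

    __slots__ = ()

    def __repr__(self) -> str:
        return "EXCEEDED"


EXCEEDED = _Exceeded()


@dataclass(frozen=True)
class InfixHit:
    """A located occurrence of a pattern inside a read.

    ``start``/``end`` are 0-based half-open offsets into the searched text,
    ``distance`` the edit distance of the pattern against ``text[start:end]``.
    """

    start: int
    end: int
    distance: int
    strand: str = "+"


def encode(seq: str) -> np.ndarray:
    """Encode a sequence into integer codes over the working alphabet.

    Raises ``ValueError`` naming the offending character and position for
    anything outside ``A/C/G/T/N/?/X`` (case-insensitive).
    """
    try:
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    except UnicodeEncodeError as exc:
        raise ValueError(f"non-ASCII character in sequence: {exc}") from exc
    codes = _ENCODE[raw]
    if codes.size and codes.min() < 0:
        pos = int(np.argmax(codes < 0))
        raise ValueError(f"invalid character {seq[pos]!r} at position {pos}")
    return codes.astype(np.int64)


def _nw_last_row(cp: np.ndarray, ct: np.ndarray) -> np.ndarray:
    """Last row of the global (Needleman–Wunsch, unit cost) DP matrix."""
    n = len(ct)
    ar = np.arange(n + 1, dtype=np.int64)
    prev = ar.copy()
    if len(cp) == 0:
        return prev
    costs = _SUB[cp][:, ct] if n else None
    cand = np.empty(n + 1, dtype=np.int64)
    for i in range(len(cp)):
        cand[0] = i + 1
        if n:
            np.minimum(prev[:-1] + costs[i], prev[1:] + 1, out=cand[1:])
        prev = np.minimum.accumulate(cand - ar) + ar
    return prev


def _hw_last_row(cp: np.ndarray, ct: np.ndarray) -> np.ndarray:
    """Last row of the semi-global DP: pattern global, text ends free."""
    n = len(ct)
    ar = np.arange(n + 1, dtype=np.int64)
    prev = np.zeros(n + 1, dtype=np.int64)
    costs = _SUB[cp][:, ct] if n else None
    cand = np.empty(n + 1, dtype=np.int64)
    for i in range(len(cp)):
        cand[0] = i + 1
        if n:
            np.minimum(prev[:-1] + costs[i], prev[1:] + 1, out=cand[1:])
        prev = np.minimum.accumulate(cand - ar) + ar
    return prev


def _nw_matrix(cp: np.ndarray, ct: np.ndarray) -> np.ndarray:
    """Full global DP matrix, kept for traceback."""
    m, n = len(cp), len(ct)
    ar = np.arange(n + 1, dtype=np.int64)
    mat = np.empty((m + 1, n + 1), dtype=np.int64)
    mat[0] = ar
    costs = _SUB[cp][:, ct] if n else None
    cand = np.empty(n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        cand[0] = i
        if n:
            np.minimum(mat[i - 1, :-1] + costs[i - 1], mat[i - 1, 1:] + 1, out=cand[1:])
        mat[i] = np.minimum.accumulate(cand - ar) + ar
    return mat


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance between two sequences.

    Symmetric; zero iff the sequences are equal and sentinel-free.  The mask
    sentinel mismatches everything including itself, so e.g.
    ``levenshtein("X", "X") == 1``.
    """
    ca, cb = encode(a), encode(b)
    return int(_nw_last_row(ca, cb)[-1])


def bounded_levenshtein(a: str, b: str, max_d: int):
    """Edit distance if it is ``<= max_d``, else the ``EXCEEDED`` sentinel.

    A banded computation is used: rows whose minimum already exceeds the
    bound abort early.  Results agree with :func:`levenshtein` whenever the
    distance is within the bound.
    """
    if max_d < 0:
        raise ValueError("max_d must be >= 0")
    ca, cb = encode(a), encode(b)
    if abs(len(ca) - len(cb)) > max_d:
        return EXCEEDED
    n = len(cb)
    ar = np.arange(n + 1, dtype=np.int64)
    prev = ar.copy()
    costs = _SUB[ca][:, cb] if n else None
    cand = np.empty(n + 1, dtype=np.int64)
    for i in range(len(ca)):
        cand[0] = i + 1
        if n:
            np.minimum(prev[:-1] + costs[i], prev[1:] + 1, out=cand[1:])
        prev = np.minimum.accumulate(cand - ar) + ar
        if prev.min() > max_d:
            return EXCEEDED
    d = int(prev[-1])
    return d if d <= max_d else EXCEEDED


def _edlib_prefilter(pattern: str, text: str, max_d: int):
    """Ask edlib whether any hit <= max_d exists; None means 'unknown'."""
    if _edlib is None or not text:
        return None
    res = _edlib.align(
        pattern.upper(),
        text.upper(),
        mode="HW",
        task="distance",
        k=max_d,
        additionalEqualities=_WILDCARD_EQUALITIES,
    )
    return res["editDistance"] != -1


def infix_search(pattern: str, text: str, max_d: int, strand: str = "+"):
    """Best semi-global match of ``pattern`` inside ``text``.

    Returns the :class:`InfixHit` minimising the edit distance over all
    substrings of ``text`` (both substring ends free), or ``None`` when no
    substring achieves distance ``<= max_d``.  Ties are broken
    deterministically: smallest start, then smallest end (leftmost-shortest),
    mirroring scan order so that iterated masking is reproducible.
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    if max_d < 0:
        raise ValueError("max_d must be >= 0")
    cp = encode(pattern)
    ct = encode(text)
    m, n = len(cp), len(ct)
    if m - n > max_d:
        return None
    if _edlib_prefilter(pattern, text, max_d) is False:
        return None

    fwd = _hw_last_row(cp, ct)
    d = int(fwd.min())
    if d > max_d:
        return None
    # smallest start achieving the optimum: run the DP on the reversed pair;
    # its last row indexes substring *starts* (from the right).
    rev = _hw_last_row(cp[::-1], ct[::-1])
    start = n - int(np.nonzero(rev == d)[0].max())
    # smallest end for that start: global DP of the pattern against the
    # suffix; the optimal end cannot lie beyond start + m + d.
    cap = min(n, start + m + d)
    last = _nw_last_row(cp, ct[start:cap])
    end = start + int(np.nonzero(last == d)[0].min())
    return InfixHit(start=start, end=end, distance=d, strand=strand)


def align_prefix_ends(pattern: str, text: str) -> np.ndarray:
    """Text offsets consumed by each pattern prefix in one optimal alignment.

    Globally aligns ``pattern`` to ``text`` and returns an array ``ends`` of
    length ``len(pattern) + 1`` where ``ends[i]`` is the text offset reached
    after aligning ``pattern[:i]``.  Traceback ties are resolved with a fixed
    preference (match/substitute, then pattern-gap, then text-gap) so the
    mapping is deterministic.  This is what delimits the wildcard (barcode +
    UMI) region inside an inexact flank hit.
    """
    cp, ct = encode(pattern), encode(text)
    m, n = len(cp), len(ct)
    mat = _nw_matrix(cp, ct)
    ends = np.empty(m + 1, dtype=np.int64)
    i, j = m, n
    ends[m] = n
    while i > 0:
        if j > 0 and mat[i, j] == mat[i - 1, j - 1] + _SUB[cp[i - 1], ct[j - 1]]:
            i -= 1
            j -= 1
            ends[i] = j
        elif mat[i, j] == mat[i - 1, j] + 1:
            i -= 1
            ends[i] = j
        else:
            j -= 1
    return ends


_COMPLEMENT = str.maketrans("ACGTNX?acgtnx", "TGCANX?tgcanx")
_VALID_RC = re.compile(r"[^ACGTNXacgtnx?]")


def reverse_complement(seq: str) -> str:
    """Reverse complement over ``A/C/G/T/N`` plus the mask sentinel.

    ``N`` and ``X`` self-complement; anything else raises ``ValueError``
    naming the character and its position.
    """
    bad = _VALID_RC.search(seq)
    if bad is not None:
        raise ValueError(
            f"cannot reverse-complement character {bad.group()!r} "
            f"at position {bad.start()}"
        )
    return seq.translate(_COMPLEMENT)[::-1]
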