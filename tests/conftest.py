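import itertools
import random
from functools import lru_cache

import pytest
from hypothesis import settings

from demuxlr import default_structure

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

# ---------------------------------------------------------------------------
# Independent oracles, deliberately naive: the textbook edit-distance
# recurrence (memoised) with the same character-cost rules the package
# defines, and a brute-force infix search built on top of it.  These never
# touch the package's DP code paths.
# ---------------------------------------------------------------------------

_REAL = set("ACGTN")


def _sub_cost(p: str, t: str) -> int:
    if p == "?" or t == "?":
        other = t if p == "?" else p
        return 0 if (other in _REAL or other == "?") else 1
    if p == "X" or t == "X":
        return 1  # the mask sentinel mismatches everything, itself included
    return 0 if p == t else 1


def oracle_levenshtein(a: str, b: str) -> int:
    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            rec(i - 1, j - 1) + _sub_cost(a[i - 1], b[j - 1]),
            rec(i - 1, j) + 1,
            rec(i, j - 1) + 1,
        )

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * (len(a) + len(b)) + 100))
    try:
        return rec(len(a), len(b))
    finally:
        sys.setrecursionlimit(old)


def oracle_infix(pattern: str, text: str, max_d: int):
    """Brute-force best infix hit: for every start, a prefix DP over the
    suffix gives the distance to every end at once.  Tie-break: smallest
    distance, then smallest start, then smallest end."""
    m, n = len(pattern), len(text)
    best = None  # (distance, start, end)
    for s in range(n + 1):
        suffix = text[s:]
        prev = list(range(len(suffix) + 1))
        rows = [prev[:]]
        for i in range(1, m + 1):
            cur = [i]
            for j in range(1, len(suffix) + 1):
                cur.append(
                    min(
                        prev[j - 1] + _sub_cost(pattern[i - 1], suffix[j - 1]),
                        prev[j] + 1,
                        cur[j - 1] + 1,
                    )
                )
            prev = cur
        for j, dist in enumerate(prev):
            cand = (dist, s, s + j)
            if best is None or cand < best:
                best = cand
    if best is None or best[0] > max_d:
        return None
    return best


def random_seq(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


def all_strings(alphabet: str, max_len: int):
    for ln in range(max_len + 1):
        for tup in itertools.product(alphabet, repeat=ln):
            yield "".join(tup)


@pytest.fixture(scope="session")
def structure():
    return default_structure()
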