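"""Independent brute-force oracles used only by the test suite.

Each oracle favours obviousness over speed and shares no code with the
implementation it checks.
"""

from __future__ import annotations

import math
from functools import lru_cache
from itertools import combinations


def oracle_trim_point(quals: list[int], threshold: int) -> int:
    """Best 3' trim point by direct enumeration of every suffix sum.

    Returns the retained length: the index minimizing sum(q_j - threshold
    for j >= i) when that minimum is negative (ties to the largest index),
    else the full length.
    """
    L = len(quals)
    sums = [sum(q - threshold for q in quals[i:]) for i in range(L + 1)]
    best = min(sums)
    if best >= 0:
        return L
    return max(i for i, s in enumerate(sums) if s == best)


def oracle_glocal_score(read: str, ref: str, match=5, mismatch=-4, gap_open=10, gap_ext=1) -> int:
    """Exhaustive affine glocal score by top-down recursion over all paths.

    Global in the read, free reference flanks; a gap of length L costs
    gap_open + L * gap_ext.  Only usable on tiny sequences.
    """
    m, n = len(read), len(ref)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str) -> float:
        if i == m:
            return 0.0  # free reference suffix
        best = -math.inf
        if j < n:
            s = match if read[i] == ref[j] else mismatch
            best = max(best, rec(i + 1, j + 1, "M") + s)
            if state != "S":  # internal ref-consuming gap (not before the read starts)
                cost = gap_ext if state == "X" else gap_open + gap_ext
                best = max(best, rec(i, j + 1, "X") - cost)
        cost = gap_ext if state == "Y" else gap_open + gap_ext
        best = max(best, rec(i + 1, j, "Y") - cost)
        return best

    return int(max(rec(0, s, "S") for s in range(n + 1)))


def oracle_frame_category(net_indel: int, n_events: int) -> str:
    """The reading-frame trichotomy applied to known planted edits."""
    if n_events == 0:
        return "WT"
    return "IN_FRAME" if net_indel % 3 == 0 else "FRAMESHIFT"


def oracle_mw_exact_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by explicit assignment enumeration."""
    a = list(map(float, a))
    b = list(map(float, b))

    def u_min(x, y):
        ua = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
        return min(ua, len(x) * len(y) - ua)

    obs = u_min(a, b)
    pooled = a + b
    n, na = len(pooled), len(a)
    hits = total = 0
    for pick in combinations(range(n), na):
        pick_set = set(pick)
        ga = [pooled[i] for i in pick]
        gb = [pooled[i] for i in range(n) if i not in pick_set]
        hits += u_min(ga, gb) <= obs + 1e-12
        total += 1
    return hits / total


def oracle_protospacer_sites(reference: str, spacer: str) -> list[tuple[str, int]]:
    """All spacer+NGG occurrences by per-position substring checks."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[c] for c in reversed(spacer))
    out = []
    k = len(spacer)
    for i in range(len(reference) - k + 1):
        if reference[i : i + k] == spacer and i + k + 3 <= len(reference):
            pam = reference[i + k : i + k + 3]
            if pam[1:] == "GG":
                out.append(("+", i))
        if reference[i : i + k] == rc and i >= 3:
            pam_rc = "".join(comp[c] for c in reversed(reference[i - 3 : i]))
            if pam_rc[1:] == "GG":
                out.append(("-", i))
    return out
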