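"""Read filtering: 3' quality trimming, length filter, pair merging.

Trimming follows the BWA-style suffix-sum rule used by cutadapt's ``-q``
option: with per-base deficits ``d_j = q_j - threshold``, the suffix
starting at the index minimizing the suffix sum is removed when that
minimum is negative.  Pipelines screening CRISPR amplicons typically run
this at Q20 and then drop reads shorter than 100 nt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .refdata import revcomp

__all__ = ["TrimPolicy", "quality_trim_3prime", "length_filter", "merge_pairs", "trim_pair"]


@dataclass(frozen=True)
class TrimPolicy:
    quality_threshold: int = 20
    min_length: int = 100
    phred_offset: int = 33

    def __post_init__(self) -> None:
        if self.quality_threshold < 0:
            raise ValueError("quality_threshold must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


def quality_trim_3prime(seq: str, qual: str, policy: TrimPolicy | None = None) -> tuple[str, str]:
    """Trim the 3' end by the suffix-sum (BWA / cutadapt ``-q``) rule.

    Among the trim points minimizing the suffix sum, the rightmost one is
    taken, i.e. ties are broken toward the longest retained read.  Returns
    the (possibly empty) trimmed sequence and quality strings.
    """
    policy = policy or TrimPolicy()
    if len(seq) != len(qual):
        raise ValueError(f"sequence/quality length mismatch ({len(seq)} vs {len(qual)})")
    if not seq:
        return seq, qual
    q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64)
    d = q - policy.phred_offset - policy.quality_threshold
    # suffix[i] = sum(d[i:]) for i in 0..L (suffix[L] = 0)
    suffix = np.zeros(len(seq) + 1, dtype=np.int64)
    suffix[:-1] = d[::-1].cumsum()[::-1]
    if suffix.min() >= 0:
        return seq, qual
    cut = len(suffix) - 1 - int(np.argmin(suffix[::-1]))  # rightmost minimizer
    return seq[:cut], qual[:cut]


def length_filter(seq: str, policy: TrimPolicy | None = None) -> bool:
    """Keep the read iff it is at least ``min_length`` nt long."""
    policy = policy or TrimPolicy()
    return len(seq) >= policy.min_length


def trim_pair(
    r1: tuple[str, str], r2: tuple[str, str], policy: TrimPolicy | None = None
) -> tuple[tuple[str, str], tuple[str, str]] | None:
    """Trim both mates; return None when either fails the length filter."""
    policy = policy or TrimPolicy()
    t1 = quality_trim_3prime(*r1, policy)
    t2 = quality_trim_3prime(*r2, policy)
    if not (length_filter(t1[0], policy) and length_filter(t2[0], policy)):
        return None
    return t1, t2


@njit(nogil=True)
def _best_overlap(s1, s2, max_mismatch_frac, min_overlap):  # pragma: no cover - numba
    """Best ungapped suffix(s1)/prefix(s2) overlap by matches - mismatches."""
    n1 = s1.shape[0]
    n2 = s2.shape[0]
    best_ov = -1
    best_score = -1
    best_mm = 0
    hi = n1 if n1 < n2 else n2
    for ov in range(min_overlap, hi + 1):
        allowed = int(max_mismatch_frac * ov)
        mm = 0
        off = n1 - ov
        ok = True
        for k in range(ov):
            if s1[off + k] != s2[k]:
                mm += 1
                if mm > allowed:
                    ok = False
                    break
        if ok:
            score = ov - 2 * mm
            if score > best_score:
                best_score = score
                best_ov = ov
                best_mm = mm
    return best_ov, best_mm


def merge_pairs(
    r1: tuple[str, str],
    r2: tuple[str, str],
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> tuple[str, str] | None:
    """Merge a read pair through its best ungapped 3' overlap.

    ``r2`` is reverse-complemented (qualities reversed) and laid over the
    end of ``r1``.  Among overlaps of length >= ``min_overlap`` with a
    mismatch fraction <= ``max_mismatch_frac``, the one maximizing
    matches - mismatches wins.  Consensus: agreeing positions keep the
    higher of the two qualities; disagreements take the higher-quality
    base (ties favour r1).  Returns None when no acceptable overlap
    exists; callers then fall back to the unmerged pair.
    """
    s1, q1 = r1
    s2 = revcomp(r2[0])
    q2 = r2[1][::-1]
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not s1 or not s2:
        return None
    a1 = np.frombuffer(s1.encode("ascii"), dtype=np.uint8)
    a2 = np.frombuffer(s2.encode("ascii"), dtype=np.uint8)
    ov, _ = _best_overlap(a1, a2, float(max_mismatch_frac), int(min_overlap))
    if ov < 0:
        return None
    b1 = a1[len(a1) - ov :]
    b2 = a2[:ov]
    p1 = np.frombuffer(q1[len(q1) - ov :].encode("ascii"), dtype=np.uint8)
    p2 = np.frombuffer(q2[:ov].encode("ascii"), dtype=np.uint8)
    take2 = p2 > p1
    cons = np.where(take2, b2, b1)
    consq = np.where(b1 == b2, np.maximum(p1, p2), np.where(take2, p2, p1))
    seq = s1[: len(s1) - ov] + cons.tobytes().decode("ascii") + s2[ov:]
    qual = q1[: len(q1) - ov] + consq.tobytes().decode("ascii") + q2[ov:]
    return seq, qual
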