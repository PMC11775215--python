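"""Glocal pairwise alignment with affine gaps.

The aligner is global in the read and free at the reference flanks
("glocal"), which is the natural shape for an amplicon read that may start
or end inside the reference but must be explained end to end.  Scoring is
affine: a gap of length L costs ``gap_open + L * gap_extend``.

Determinism contract: ties in the dynamic program are broken with a fixed
state priority (diagonal > deletion-from-reference > insertion), and
internal indels are left-normalized within homopolymer runs after the
backtrace, so co-optimal alignments always yield the same reported ops.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from numba import njit

from .refdata import ReferenceAmplicon

__all__ = ["Scoring", "AlnOp", "Alignment", "align_glocal", "DIAG", "DEL", "INS"]

DIAG = "diag"  # read base aligned to reference base (match or mismatch)
DEL = "del"  # reference bases absent from the read
INS = "ins"  # read bases absent from the reference

_NEG = np.int32(-(10**8))

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Scoring:
    """Affine-gap scoring parameters (EMBOSS-style gap cost open + L*extend)."""

    match: int = 5
    mismatch: int = -4
    gap_open: int = 10
    gap_extend: int = 1

    def max_attainable(self, read_len: int) -> int:
        return self.match * read_len


@dataclass(frozen=True)
class AlnOp:
    """One run-length-encoded alignment operation.

    ``ref_pos``/``read_pos`` are the 0-based start coordinates of the run;
    for an insertion ``ref_pos`` is the reference *gap* index, for a
    deletion ``read_pos`` is the read gap index.
    """

    kind: str  # DIAG | DEL | INS
    ref_pos: int
    read_pos: int
    length: int


@dataclass(frozen=True)
class Alignment:
    """A glocal alignment of ``read`` against ``ref``.

    ``ref_start``/``ref_end`` delimit the consumed reference interval; the
    flanks outside it are free end-gaps.  ``mismatch_ref_pos`` holds the
    reference coordinates of substituted columns.
    """

    read: str
    ref: str
    score: int
    ref_start: int
    ref_end: int
    ops: tuple[AlnOp, ...]
    mismatch_ref_pos: tuple[int, ...]

    @property
    def indel_ops(self) -> tuple[AlnOp, ...]:
        return tuple(op for op in self.ops if op.kind != DIAG)

    def consumed(self) -> tuple[int, int]:
        """(reference nt consumed, read nt consumed) — for consistency checks."""
        ref_nt = sum(op.length for op in self.ops if op.kind in (DIAG, DEL))
        read_nt = sum(op.length for op in self.ops if op.kind in (DIAG, INS))
        return ref_nt, read_nt


@njit(nogil=True)
def _glocal_dp(read, ref, match, mismatch, gap_open, gap_ext, diag_off, halfband):  # pragma: no cover - numba
    m = read.shape[0]
    n = ref.shape[0]
    M = np.full((m + 1, n + 1), _NEG, np.int32)
    X = np.full((m + 1, n + 1), _NEG, np.int32)
    Y = np.full((m + 1, n + 1), _NEG, np.int32)
    pM = np.zeros((m + 1, n + 1), np.uint8)
    pX = np.zeros((m + 1, n + 1), np.uint8)
    pY = np.zeros((m + 1, n + 1), np.uint8)
    for j in range(n + 1):
        M[0, j] = 0  # free reference prefix
    for i in range(1, m + 1):
        a = M[i - 1, 0] - gap_open - gap_ext
        b = Y[i - 1, 0] - gap_ext
        if a >= b:
            Y[i, 0] = a
            pY[i, 0] = 0
        else:
            Y[i, 0] = b
            pY[i, 0] = 2
    for i in range(1, m + 1):
        if halfband > 0:
            c = i + diag_off
            jlo = c - halfband
            if jlo < 1:
                jlo = 1
            jhi = c + halfband
            if jhi > n:
                jhi = n
        else:
            jlo = 1
            jhi = n
        ri = read[i - 1]
        for j in range(jlo, jhi + 1):
            # diagonal state (priority on ties: M > X > Y)
            best = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 2
            s = match if ri == ref[j - 1] else mismatch
            M[i, j] = best + s
            pM[i, j] = p
            # deletion-from-reference state (consumes ref only)
            best = M[i, j - 1] - gap_open - gap_ext
            p = 0
            v = X[i, j - 1] - gap_ext
            if v > best:
                best = v
                p = 1
            v = Y[i, j - 1] - gap_open - gap_ext
            if v > best:
                best = v
                p = 2
            X[i, j] = best
            pX[i, j] = p
            # insertion state (consumes read only)
            best = M[i - 1, j] - gap_open - gap_ext
            p = 0
            v = X[i - 1, j] - gap_open - gap_ext
            if v > best:
                best = v
                p = 1
            v = Y[i - 1, j] - gap_ext
            if v > best:
                best = v
                p = 2
            Y[i, j] = best
            pY[i, j] = p
    # free reference suffix: best over the last row (ending in a
    # ref-consuming gap would always be dominated by the free suffix)
    best = _NEG
    end_j = 0
    end_state = np.uint8(0)
    for j in range(n + 1):
        if M[m, j] > best:
            best = M[m, j]
            end_j = j
            end_state = np.uint8(0)
        if Y[m, j] > best:
            best = Y[m, j]
            end_j = j
            end_state = np.uint8(2)
    # backtrace with run-length encoding (built in reverse)
    cap = m + n + 2
    k_kind = np.empty(cap, np.uint8)
    k_ref = np.empty(cap, np.int32)
    k_read = np.empty(cap, np.int32)
    k_len = np.empty(cap, np.int32)
    mism = np.empty(m + 1, np.int32)
    nm = 0
    nops = 0
    cur = np.uint8(255)
    i = m
    j = end_j
    st = end_state
    while i > 0:
        if st == 0:
            if read[i - 1] != ref[j - 1]:
                mism[nm] = j - 1
                nm += 1
            nxt = pM[i, j]
            kind = np.uint8(0)
            i -= 1
            j -= 1
        elif st == 1:
            nxt = pX[i, j]
            kind = np.uint8(1)
            j -= 1
        else:
            nxt = pY[i, j]
            kind = np.uint8(2)
            i -= 1
        if kind == cur:
            k_len[nops - 1] += 1
            k_ref[nops - 1] = j
            k_read[nops - 1] = i
        else:
            k_kind[nops] = kind
            k_len[nops] = 1
            k_ref[nops] = j
            k_read[nops] = i
            nops += 1
            cur = kind
        st = nxt
    return best, j, end_j, k_kind[:nops], k_ref[:nops], k_read[:nops], k_len[:nops], mism[:nm]


_KIND_NAMES = (DIAG, DEL, INS)


def _left_normalize(ops: list[AlnOp], read: str, ref: str) -> list[AlnOp]:
    """Shift internal indels as far left as homopolymer context allows.

    A shift by one is legal when the aligned column immediately left of the
    indel is a match and rotating the indel one position left reproduces
    the same two sequences; the flanking diagonal runs are re-sized
    accordingly so the op list still reconstructs both sequences exactly.
    """
    ops = list(ops)
    i = 1
    while i < len(ops):
        op = ops[i]
        if op.kind == DIAG or ops[i - 1].kind != DIAG:
            i += 1
            continue
        prev = ops[i - 1]
        p, r, L = op.ref_pos, op.read_pos, op.length
        shift = 0
        while shift < prev.length:
            left_ref = ref[p - 1]
            left_read = read[r - 1]
            if left_read != left_ref:  # column to the left is not a match
                break
            tail = ref[p + L - 1] if op.kind == DEL else read[r + L - 1]
            if tail != left_ref:  # rotation would change a sequence
                break
            p -= 1
            r -= 1
            shift += 1
        if shift == 0:
            i += 1
            continue
        ops[i] = AlnOp(op.kind, p, r, L)
        ops[i - 1] = AlnOp(DIAG, prev.ref_pos, prev.read_pos, prev.length - shift)
        # grow (or create) the trailing diagonal run displaced by the shift
        nref = p + (L if op.kind == DEL else 0)
        nread = r + (L if op.kind == INS else 0)
        if i + 1 < len(ops) and ops[i + 1].kind == DIAG:
            nxt = ops[i + 1]
            ops[i + 1] = AlnOp(DIAG, nref, nread, nxt.length + shift)
        else:
            ops.insert(i + 1, AlnOp(DIAG, nref, nread, shift))
        if ops[i - 1].length == 0:
            del ops[i - 1]
        else:
            i += 1
    return ops


def align_glocal(
    read: str,
    amp: ReferenceAmplicon | str,
    scoring: Scoring | None = None,
    band: int | None = None,
    band_offset: int = 0,
) -> Alignment:
    """Optimal glocal affine-gap alignment of *read* against an amplicon.

    Parameters
    ----------
    read, amp
        Non-empty DNA strings (an :class:`ReferenceAmplicon` is accepted
        for ``amp``).
    band
        Optional half-width of a diagonal band around ``i + band_offset``;
        ``None`` computes the full matrix.  The band is an acceleration for
        reads whose edit distance to the reference is known to be small
        (e.g. from a preceding edlib screen); callers must choose it wide
        enough to contain the optimum.
    """
    ref = amp.sequence if isinstance(amp, ReferenceAmplicon) else amp
    if not read or not ref:
        raise ValueError("read and reference must be non-empty")
    sc = scoring or Scoring()
    score, ref_start, ref_end, kk, kr, kd, kl, mism = _glocal_dp(
        _encode(read),
        _encode(ref),
        np.int32(sc.match),
        np.int32(sc.mismatch),
        np.int32(sc.gap_open),
        np.int32(sc.gap_extend),
        np.int32(band_offset),
        np.int32(band if band is not None else 0),
    )
    ops = [
        AlnOp(_KIND_NAMES[kk[t]], int(kr[t]), int(kd[t]), int(kl[t]))
        for t in range(len(kk) - 1, -1, -1)
    ]
    ops = _left_normalize(ops, read, ref)
    return Alignment(
        read=read,
        ref=ref,
        score=int(score),
        ref_start=int(ref_start),
        ref_end=int(ref_end),
        ops=tuple(ops),
        mismatch_ref_pos=tuple(sorted(int(x) for x in mism)),
    )
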