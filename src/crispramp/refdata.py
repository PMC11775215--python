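"""Reference amplicons, Cas9 target sites and quantification windows.

Coordinate convention: everything is 0-based, half-open.  A cut position
(``cut_pos``) names the *gap* before the indexed base, so an amplicon cut
at ``cut_pos=67`` is severed between bases 66 and 67.  Cas9 with an NGG
PAM produces a blunt cut 3 nt 5' of the PAM on the protospacer strand;
that rule is applied identically on both strands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = [
    "TargetSite",
    "ReferenceAmplicon",
    "QuantWindow",
    "TargetNotFoundError",
    "AmbiguousTargetError",
    "revcomp",
    "locate_protospacer",
    "make_quant_window",
    "load_references",
    "write_references",
    "SPACER_IGM_1",
    "SPACER_IGM_2",
]

#: Spacer sequences of the two candidate guides targeting the mu-1 exon of
#: both IgM heavy-chain loci (A and B) in Atlantic salmon.  Only one of the
#: two produced efficient mutagenesis in vivo, so the pipeline always takes
#: the spacer as an input instead of hard-coding either.
SPACER_IGM_1 = "GCGCAATGTGGCTCCGGGAC"
SPACER_IGM_2 = "CTGGCTTCACGCCTGCCTCC"

#: Blunt Cas9 cut distance from the PAM-proximal protospacer end.
CUT_OFFSET_FROM_PAM = 3

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class TargetNotFoundError(ValueError):
    """The spacer (with an adjacent NGG PAM) occurs on neither strand."""


class AmbiguousTargetError(ValueError):
    """The spacer+PAM occurs more than once; the caller must disambiguate."""


@dataclass(frozen=True)
class TargetSite:
    """A protospacer/PAM occurrence on a reference amplicon.

    ``protospacer_span`` and ``pam_span`` are intervals on the *reference*
    (plus-strand) coordinates regardless of ``strand``; ``cut_pos`` is the
    reference gap index of the blunt cut, 3 nt from the PAM on the
    protospacer strand.
    """

    spacer: str
    strand: str  # "+" or "-"
    protospacer_span: tuple[int, int]
    pam_span: tuple[int, int]
    cut_pos: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        s, e = self.protospacer_span
        if e - s != len(self.spacer):
            raise ValueError("protospacer span length must equal spacer length")
        ps, pe = self.pam_span
        if pe - ps != 3:
            raise ValueError("PAM span must be 3 nt")
        # blunt cut 3 nt from the PAM-proximal end, on the protospacer strand
        expected = (e - CUT_OFFSET_FROM_PAM) if self.strand == "+" else (s + CUT_OFFSET_FROM_PAM)
        if self.cut_pos != expected:
            raise ValueError(
                f"cut_pos {self.cut_pos} is not {CUT_OFFSET_FROM_PAM} nt from the PAM "
                f"(expected {expected})"
            )


@dataclass(frozen=True)
class ReferenceAmplicon:
    """A locus-specific reference amplicon with annotated target site.

    The primer spans mark the PCR primers at the two ends of the amplicon;
    the quantifiable region is the inter-primer interval.
    """

    locus_id: str
    sequence: str
    primer_fwd_span: tuple[int, int]
    primer_rev_span: tuple[int, int]
    target_site: TargetSite

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set("ACGT"):
            raise ValueError(f"{self.locus_id}: sequence must be non-empty uppercase ACGT")
        n = len(self.sequence)
        for name, (s, e) in (
            ("primer_fwd_span", self.primer_fwd_span),
            ("primer_rev_span", self.primer_rev_span),
        ):
            if not (0 <= s < e <= n):
                raise ValueError(f"{self.locus_id}: {name} {s, e} outside [0, {n})")
        if self.primer_fwd_span[1] > self.primer_rev_span[0]:
            raise ValueError(f"{self.locus_id}: primer spans overlap or are out of order")
        cut = self.target_site.cut_pos
        if not (self.primer_fwd_span[1] <= cut <= self.primer_rev_span[0]):
            raise ValueError(f"{self.locus_id}: cut position {cut} overlaps a primer span")

    @property
    def inter_primer_span(self) -> tuple[int, int]:
        return (self.primer_fwd_span[1], self.primer_rev_span[0])

    @property
    def cut_pos(self) -> int:
        return self.target_site.cut_pos

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass(frozen=True)
class QuantWindow:
    """Reference interval within which indels are counted towards the verdict."""

    span: tuple[int, int]
    mode: str  # "full_amplicon" | "cut_centered"

    def __post_init__(self) -> None:
        s, e = self.span
        if e <= s:
            raise ValueError(f"empty quantification window {self.span}")

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]


def _iter_sites(reference: str, spacer: str) -> Iterable[TargetSite]:
    """Yield every spacer+NGG occurrence on either strand of *reference*."""
    k = len(spacer)
    # plus strand: spacer followed immediately by NGG
    start = reference.find(spacer)
    while start != -1:
        pam_s = start + k
        if pam_s + 3 <= len(reference) and reference[pam_s + 1 : pam_s + 3] == "GG":
            yield TargetSite(
                spacer=spacer,
                strand="+",
                protospacer_span=(start, start + k),
                pam_span=(pam_s, pam_s + 3),
                cut_pos=start + k - CUT_OFFSET_FROM_PAM,
            )
        start = reference.find(spacer, start + 1)
    # minus strand: reverse complement of the spacer, preceded by CCN
    rc = revcomp(spacer)
    start = reference.find(rc)
    while start != -1:
        if start >= 3 and reference[start - 3 : start - 1] == "CC":
            yield TargetSite(
                spacer=spacer,
                strand="-",
                protospacer_span=(start, start + k),
                pam_span=(start - 3, start),
                cut_pos=start + CUT_OFFSET_FROM_PAM,
            )
        start = reference.find(rc, start + 1)


def locate_protospacer(reference: str, spacer: str) -> TargetSite:
    """Locate the unique spacer+NGG occurrence on either strand.

    Parameters
    ----------
    reference
        Uppercase DNA string, at least 23 nt (20-nt protospacer + NGG).
    spacer
        Exact 20-mer over ACGT, written 5'->3' as on the guide RNA.

    Raises
    ------
    TargetNotFoundError
        If no occurrence exists on either strand.
    AmbiguousTargetError
        If more than one occurrence exists.
    """
    if len(spacer) != 20 or set(spacer) - set("ACGT"):
        raise ValueError("spacer must be an exact 20-mer over ACGT")
    if len(reference) < 23:
        raise ValueError("reference must be at least 23 nt")
    sites = list(_iter_sites(reference, spacer))
    if not sites:
        raise TargetNotFoundError(f"target not found: spacer {spacer} has no NGG-adjacent hit")
    if len(sites) > 1:
        where = ", ".join(f"{s.strand}{s.protospacer_span[0]}" for s in sites)
        raise AmbiguousTargetError(f"ambiguous target: {len(sites)} hits ({where})")
    return sites[0]


def make_quant_window(
    amp: ReferenceAmplicon, mode: str = "full_amplicon", halfwidth: int = 30
) -> QuantWindow:
    """Build the quantification window for an amplicon.

    ``full_amplicon`` uses the whole inter-primer region; ``cut_centered``
    uses ``[cut_pos - halfwidth, cut_pos + halfwidth)`` clipped to the
    inter-primer region.  The cut position always lies in the window.
    """
    lo, hi = amp.inter_primer_span
    if mode == "full_amplicon":
        span = (lo, hi)
    elif mode == "cut_centered":
        if halfwidth < 1:
            raise ValueError("halfwidth must be >= 1 for cut_centered mode")
        cut = amp.cut_pos
        span = (max(lo, cut - halfwidth), min(hi, cut + halfwidth))
    else:
        raise ValueError(f"unknown window mode {mode!r}")
    if span[1] <= span[0]:
        raise ValueError(f"quantification window is empty after clipping: {span}")
    return QuantWindow(span=span, mode=mode)


def write_references(amps: Iterable[ReferenceAmplicon], fasta_path, sites_path) -> None:
    """Write amplicons as FASTA plus a JSON sidecar (spacer + primer spans)."""
    amps = list(amps)
    with open(fasta_path, "w") as fh:
        for amp in amps:
            fh.write(f">{amp.locus_id}\n")
            for i in range(0, len(amp.sequence), 70):
                fh.write(amp.sequence[i : i + 70] + "\n")
    sidecar = {
        amp.locus_id: {
            "spacer": amp.target_site.spacer,
            "primer_fwd_span": list(amp.primer_fwd_span),
            "primer_rev_span": list(amp.primer_rev_span),
        }
        for amp in amps
    }
    Path(sites_path).write_text(json.dumps(sidecar, indent=2) + "\n")


def load_references(fasta_path, sites_path) -> list[ReferenceAmplicon]:
    """Load amplicons from FASTA + JSON sidecar, re-locating each target site."""
    from Bio import SeqIO

    sidecar = json.loads(Path(sites_path).read_text())
    amps = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        locus = rec.id
        if locus not in sidecar:
            raise KeyError(f"locus {locus!r} present in FASTA but missing from {sites_path}")
        meta = sidecar[locus]
        seq = str(rec.seq).upper()
        site = locate_protospacer(seq, meta["spacer"])
        amps.append(
            ReferenceAmplicon(
                locus_id=locus,
                sequence=seq,
                primer_fwd_span=tuple(meta["primer_fwd_span"]),
                primer_rev_span=tuple(meta["primer_rev_span"]),
                target_site=site,
            )
        )
    if not amps:
        raise ValueError(f"no records in {fasta_path}")
    return amps
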