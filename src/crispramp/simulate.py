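"""Synthetic mosaic-crispant amplicon data with ground truth.

An F0 crispant is genetically mosaic: each tissue is a mixture of cell
populations carrying different Cas9-induced alleles at the target locus.
The generator models that mixture explicitly — an individual owns a pool
of edited alleles per locus, each tissue draws its own Dirichlet weights
over that shared pool (so tissues of one fish can disagree, as fin and
leukocytes do in real crispants), and paired-end reads are then sampled
from the per-tissue allele spectrum with substitution errors and
MiSeq-like quality strings.  Every emitted read is counted in a truth
table, so downstream classification can be validated by parameter
recovery rather than by eyeballing.

The two bundled reference amplicons are *synthetic stand-ins* for the
duplicated salmon IgM heavy-chain loci (A/B): near-identical 380-nt
sequences that both embed the printed IgM-1 spacer + NGG target site and
differ at eight flanking positions, mimicking the locus-discriminating
variation a real duplicated genome provides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .refdata import SPACER_IGM_1, ReferenceAmplicon, locate_protospacer

__all__ = [
    "IndelOp",
    "EditAllele",
    "WT_ALLELE",
    "AlleleSpectrum",
    "SimConfig",
    "ReadPair",
    "SimulatedSample",
    "sample_allele_pool",
    "sample_allele_spectrum",
    "apply_allele",
    "simulate_reads",
    "simulate_sample",
    "simulate_dataset",
    "build_default_references",
    "simulate_ct_table",
    "WT",
    "IN_FRAME",
    "FRAMESHIFT",
]

WT = "WT"
IN_FRAME = "IN_FRAME"
FRAMESHIFT = "FRAMESHIFT"

_BASES = "ACGT"
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class IndelOp:
    """A single indel on reference coordinates.

    For an insertion ``ref_pos`` is the gap index where ``inserted_seq``
    enters; for a deletion ``[ref_pos, ref_pos + length)`` is removed.
    """

    ref_pos: int
    kind: str  # "ins" | "del"
    length: int
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("ins", "del"):
            raise ValueError(f"kind must be 'ins' or 'del', got {self.kind!r}")
        if self.length < 1:
            raise ValueError("indel length must be >= 1")
        if self.kind == "ins" and len(self.inserted_seq) != self.length:
            raise ValueError("inserted_seq length must equal op length")
        if self.kind == "del" and self.inserted_seq:
            raise ValueError("deletions carry no inserted_seq")


@dataclass(frozen=True)
class EditAllele:
    """An edited allele: a set of indel ops relative to the reference."""

    ops: tuple[IndelOp, ...] = ()
    label: str = ""

    @property
    def net_len(self) -> int:
        return sum(op.length if op.kind == "ins" else -op.length for op in self.ops)

    @property
    def is_wt(self) -> bool:
        return not self.ops

    @property
    def category(self) -> str:
        if self.is_wt:
            return WT
        return IN_FRAME if self.net_len % 3 == 0 else FRAMESHIFT


WT_ALLELE = EditAllele(ops=(), label="WT")


@dataclass(frozen=True)
class AlleleSpectrum:
    """Per (individual, tissue, locus) allele fractions; fractions sum to 1."""

    alleles: tuple[tuple[EditAllele, float], ...]

    def __post_init__(self) -> None:
        fracs = [f for _, f in self.alleles]
        if not fracs or min(fracs) < 0:
            raise ValueError("allele fractions must be non-negative and non-empty")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"allele fractions sum to {sum(fracs)}, not 1")

    @property
    def wt_fraction(self) -> float:
        return sum(f for a, f in self.alleles if a.is_wt)

    def category_fractions(self) -> dict[str, float]:
        out = {WT: 0.0, IN_FRAME: 0.0, FRAMESHIFT: 0.0}
        for a, f in self.alleles:
            out[a.category] += f
        return out


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Defaults emulate the sequencing design of a salmonid F0 knockout
    screen: 20 crispants, MiSeq 2x300 bp amplicon reads at 10,000 pairs
    per sample, an expected edited cell fraction of 0.975, and short
    cut-site indels (geometric sizes, deletions dominating insertions).
    """

    seed: int
    n_individuals: int = 20
    tissues: tuple[str, ...] = ("fin",)
    read_depth: int = 10_000
    read_length: int = 300
    editing_rate: float = 0.975
    dirichlet_concentration: float = 1.0
    wt_concentration: float = 20.0
    mean_edited_alleles: float = 4.0
    p_ins: float = 0.3
    ins_geom_p: float = 0.5
    ins_cap: int = 10
    del_geom_p: float = 0.25
    del_cap: int = 30
    error_rate: float = 0.003
    body_quality: int = 35
    tail_length: int = 30
    tail_min_quality: int = 10
    quality_jitter: int = 2

    def __post_init__(self) -> None:
        for name in ("editing_rate", "p_ins", "ins_geom_p", "del_geom_p", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(frozen=True)
class ReadPair:
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str
    allele_index: int


@dataclass(frozen=True)
class SimulatedSample:
    individual: str
    tissue: str
    locus: str
    spectrum: AlleleSpectrum
    pairs: tuple[ReadPair, ...]
    truth: dict


def _sample_indel(amp: ReferenceAmplicon, cfg: SimConfig, rng: np.random.Generator) -> IndelOp:
    """One cut-site-anchored indel: insertions at the cut, deletions spanning it."""
    cut = amp.cut_pos
    lo, hi = amp.inter_primer_span
    if rng.random() < cfg.p_ins:
        length = min(int(rng.geometric(cfg.ins_geom_p)), cfg.ins_cap)
        ins = "".join(_BASES[b] for b in rng.integers(0, 4, size=length))
        return IndelOp(ref_pos=cut, kind="ins", length=length, inserted_seq=ins)
    length = min(int(rng.geometric(cfg.del_geom_p)), cfg.del_cap)
    start = cut - (length + 1) // 2
    start = max(lo, min(start, hi - length))
    return IndelOp(ref_pos=start, kind="del", length=length)


def sample_allele_pool(
    amp: ReferenceAmplicon, cfg: SimConfig, rng: np.random.Generator, k: int | None = None
) -> tuple[EditAllele, ...]:
    """Draw an individual's pool of distinct edited alleles at one locus."""
    if k is None:
        k = 1 + int(rng.poisson(max(cfg.mean_edited_alleles - 1.0, 0.0)))
    pool: list[EditAllele] = []
    seen = set()
    tries = 0
    while len(pool) < k and tries < 50 * k:
        tries += 1
        op = _sample_indel(amp, cfg, rng)
        if op in seen:
            continue
        seen.add(op)
        pool.append(EditAllele(ops=(op,), label=f"allele_{len(pool) + 1}"))
    return tuple(pool)


def sample_allele_spectrum(
    amp: ReferenceAmplicon,
    cfg: SimConfig,
    rng: np.random.Generator,
    pool: Sequence[EditAllele] | None = None,
) -> AlleleSpectrum:
    """Draw one mosaic allele spectrum.

    The wild-type fraction is Beta-distributed with mean
    ``1 - editing_rate`` (concentration ``wt_concentration``); the edited
    remainder is split over the allele pool with Dirichlet weights.
    """
    if cfg.editing_rate <= 0.0 or (pool is not None and len(pool) == 0):
        return AlleleSpectrum(alleles=((WT_ALLELE, 1.0),))
    if pool is None:
        pool = sample_allele_pool(amp, cfg, rng)
    if not pool:
        return AlleleSpectrum(alleles=((WT_ALLELE, 1.0),))
    if cfg.editing_rate >= 1.0:
        wt_frac = 0.0
    else:
        c = cfg.wt_concentration
        wt_frac = float(rng.beta(c * (1.0 - cfg.editing_rate), c * cfg.editing_rate))
    weights = rng.dirichlet([cfg.dirichlet_concentration] * len(pool)) * (1.0 - wt_frac)
    alleles = [(WT_ALLELE, wt_frac)] + [(a, float(w)) for a, w in zip(pool, weights)]
    total = sum(f for _, f in alleles)
    alleles = [(a, f / total) for a, f in alleles]
    return AlleleSpectrum(alleles=tuple(alleles))


def apply_allele(amp: ReferenceAmplicon | str, allele: EditAllele) -> str:
    """Splice an allele's indels into the reference sequence."""
    ref = amp.sequence if isinstance(amp, ReferenceAmplicon) else amp
    parts = []
    cursor = 0
    last_start = -1
    for op in allele.ops:
        start = op.ref_pos
        if start < cursor or start <= last_start:
            raise ValueError("allele ops overlap or are unsorted")
        last_start = start
        parts.append(ref[cursor:start])
        if op.kind == "ins":
            parts.append(op.inserted_seq)
            cursor = start
        else:
            if start + op.length > len(ref):
                raise ValueError("deletion runs off the reference")
            cursor = start + op.length
        prev_end = cursor
    parts.append(ref[cursor:])
    return "".join(parts)


def _quality_template(length: int, cfg: SimConfig) -> np.ndarray:
    """High-quality body with a linearly decaying 3' tail."""
    q = np.full(length, cfg.body_quality, dtype=np.int64)
    tail = min(cfg.tail_length, length)
    if tail > 0:
        ramp = np.linspace(cfg.body_quality, cfg.tail_min_quality, tail + 1)[1:]
        q[length - tail :] = np.round(ramp).astype(np.int64)
    return q


def _emit_group(
    seq: str, n: int, cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[str], list[str], list[str], list[str]]:
    """Vectorized read-pair emission for *n* pairs from one allele sequence."""
    codes = np.array([_CODE[b] for b in seq], dtype=np.uint8)
    rc_codes = (3 - codes)[::-1].copy()
    rl = min(cfg.read_length, len(seq))
    out: list[list[str]] = []
    for template in (codes[:rl], rc_codes[:rl]):
        mat = np.tile(template, (n, 1))
        if cfg.error_rate > 0:
            err = rng.random((n, rl)) < cfg.error_rate
            shift = rng.integers(1, 4, size=(n, rl), dtype=np.uint8)
            mat = np.where(err, (mat + shift) % 4, mat)
        qt = _quality_template(rl, cfg)
        if cfg.quality_jitter > 0:
            qmat = qt + rng.integers(-cfg.quality_jitter, cfg.quality_jitter + 1, size=(n, rl))
        else:
            qmat = np.tile(qt, (n, 1))
        qmat = np.clip(qmat, 2, 40) + 33
        seqs = _DECODE[mat]
        out.append([row.tobytes().decode("ascii") for row in seqs])
        out.append([row.tobytes().decode("ascii") for row in qmat.astype(np.uint8)])
    return out[0], out[1], out[2], out[3]


def simulate_reads(
    amp: ReferenceAmplicon,
    spectrum: AlleleSpectrum,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[tuple[ReadPair, ...], dict]:
    """Sample paired-end reads from an allele spectrum.

    R1 runs from the 5' end of the (edited) amplicon, R2 is the reverse
    complement from the 3' end; substitution errors are injected per base
    at ``error_rate``.  The returned truth dict counts what was actually
    emitted, not just the expected fractions.
    """
    alleles = [a for a, _ in spectrum.alleles]
    fracs = np.array([f for _, f in spectrum.alleles], dtype=float)
    fracs = fracs / fracs.sum()
    n = cfg.read_depth
    idx = rng.choice(len(alleles), size=n, p=fracs)
    seqs = [apply_allele(amp, a) for a in alleles]
    r1s: list[str | None] = [None] * n
    r1q: list[str | None] = [None] * n
    r2s: list[str | None] = [None] * n
    r2q: list[str | None] = [None] * n
    for k in range(len(alleles)):
        rows = np.nonzero(idx == k)[0]
        if rows.size == 0:
            continue
        g1, gq1, g2, gq2 = _emit_group(seqs[k], rows.size, cfg, rng)
        for t, row in enumerate(rows):
            r1s[row] = g1[t]
            r1q[row] = gq1[t]
            r2s[row] = g2[t]
            r2q[row] = gq2[t]
    pairs = tuple(
        ReadPair(r1s[i], r1q[i], r2s[i], r2q[i], int(idx[i])) for i in range(n)
    )
    cats = np.array([{WT: 0, IN_FRAME: 1, FRAMESHIFT: 2}[a.category] for a in alleles])
    counts = np.bincount(cats[idx], minlength=3)
    expected = spectrum.category_fractions()
    truth = {
        "n_pairs": int(n),
        "n_wt": int(counts[0]),
        "n_inframe": int(counts[1]),
        "n_frameshift": int(counts[2]),
        "frac_wt": counts[0] / n,
        "frac_inframe": counts[1] / n,
        "frac_frameshift": counts[2] / n,
        "expected_wt": expected[WT],
        "expected_inframe": expected[IN_FRAME],
        "expected_frameshift": expected[FRAMESHIFT],
    }
    return pairs, truth


def simulate_sample(
    amp: ReferenceAmplicon,
    cfg: SimConfig,
    rng: np.random.Generator,
    individual: str,
    tissue: str,
    pool: Sequence[EditAllele] | None = None,
) -> SimulatedSample:
    spectrum = sample_allele_spectrum(amp, cfg, rng, pool=pool)
    pairs, truth = simulate_reads(amp, spectrum, cfg, rng)
    truth = {"individual": individual, "tissue": tissue, "locus": amp.locus_id, **truth}
    return SimulatedSample(
        individual=individual,
        tissue=tissue,
        locus=amp.locus_id,
        spectrum=spectrum,
        pairs=pairs,
        truth=truth,
    )


def simulate_dataset(
    amps: Sequence[ReferenceAmplicon], cfg: SimConfig
) -> Iterator[SimulatedSample]:
    """Yield one sample per (individual, tissue, locus), deterministically.

    Each individual holds one edited-allele pool per locus, shared by all
    of its tissues; tissues re-draw mixture weights over that pool, which
    is what makes fin and leukocyte spectra of the same fish diverge.
    """
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_individuals)
    for i in range(cfg.n_individuals):
        individual = f"IgM_{i + 1:02d}"
        rng = np.random.default_rng(children[i])
        for amp in amps:
            pool = sample_allele_pool(amp, cfg, rng)
            for tissue in cfg.tissues:
                yield simulate_sample(amp, cfg, rng, individual, tissue, pool=pool)


# ---------------------------------------------------------------------------
# Synthetic reference amplicons (stand-ins for the duplicated IgM loci)
# ---------------------------------------------------------------------------

_REF_SEED = 202_501
_AMPLICON_LEN = 380
_PRIMER_LEN = 25
_PROTOSPACER_START = 170
#: flanking positions where the synthetic A and B loci differ
_LOCUS_DIFF_POSITIONS = (40, 70, 100, 130, 240, 270, 300, 330)


def build_default_references() -> list[ReferenceAmplicon]:
    """Two synthetic near-identical amplicons carrying the IgM-1 target site.

    These are synthetic stand-ins (the real locus sequences are genome
    accessions, not printed data): 380 nt, primers in the outer 25 nt,
    the 20-nt IgM-1 spacer + TGG PAM embedded mid-amplicon, and eight
    locus-discriminating substitutions in the flanks of locus B.
    """
    rng = np.random.default_rng(_REF_SEED)
    seq = list("".join(_BASES[b] for b in rng.integers(0, 4, size=_AMPLICON_LEN)))
    s = _PROTOSPACER_START
    seq[s : s + 20] = SPACER_IGM_1
    seq[s + 20 : s + 23] = "TGG"
    seq_a = "".join(seq)
    seq_b = list(seq_a)
    for pos in _LOCUS_DIFF_POSITIONS:
        seq_b[pos] = _BASES[(_CODE[seq_b[pos]] + 1) % 4]
    amps = []
    for locus, sequence in (("IgM_A", seq_a), ("IgM_B", "".join(seq_b))):
        site = locate_protospacer(sequence, SPACER_IGM_1)  # raises if not unique
        amps.append(
            ReferenceAmplicon(
                locus_id=locus,
                sequence=sequence,
                primer_fwd_span=(0, _PRIMER_LEN),
                primer_rev_span=(_AMPLICON_LEN - _PRIMER_LEN, _AMPLICON_LEN),
                target_site=site,
            )
        )
    return amps


# ---------------------------------------------------------------------------
# Toy planted-indel cases for desk-scale classifier validation
# ---------------------------------------------------------------------------

#: Aperiodic flanking anchors for toy references.  Like primer regions on a
#: real amplicon, they pin the alignment at both ends: neither anchor admits
#: a self-match under shifts of 1-4 nt, so a planted interior indel cannot
#: slide into the free reference end-gaps and change its apparent length.
TOY_ANCHOR_5 = "ATCGGT"
TOY_ANCHOR_3 = "ACCTGA"


def sample_toy_indel_case(rng: np.random.Generator) -> tuple[str, str, EditAllele, tuple[int, int]]:
    """One toy case: (reference <= 30 nt, read, planted allele, window span).

    The reference is anchor + random core + anchor; 0-2 indels of 1-4 nt
    are planted in the core interior, and the quantification window is the
    inter-anchor span.  The planted net indel length determines the
    expected reading-frame category.
    """
    core_len = int(rng.integers(16, 19))
    core = "".join(_BASES[b] for b in rng.integers(0, 4, size=core_len))
    ref = TOY_ANCHOR_5 + core + TOY_ANCHOR_3
    n_events = int(rng.integers(0, 3))

    def _indel(pos: int) -> IndelOp:
        length = int(rng.integers(1, 5))
        if rng.random() < 0.5:
            return IndelOp(pos, "del", length)
        ins = "".join(_BASES[b] for b in rng.integers(0, 4, size=length))
        return IndelOp(pos, "ins", length, ins)

    ops: list[IndelOp] = []
    if n_events >= 1:
        ops.append(_indel(int(rng.integers(8, 11))))
    if n_events == 2:
        p1 = ops[0].ref_pos
        ops.append(_indel(int(rng.integers(p1 + 7, len(ref) - 10))))
    allele = EditAllele(ops=tuple(ops))
    read = apply_allele(ref, allele)
    # the anchors prevent indels from escaping into the free reference
    # end-gaps, so the whole reference is a safe quantification window
    window = (0, len(ref))
    return ref, read, allele, window


# ---------------------------------------------------------------------------
# Synthetic qPCR Ct tables
# ---------------------------------------------------------------------------

#: True ΔΔCt shifts (cycles, positive = lower expression in crispants) used
#: by the synthetic Ct generator; chosen to emulate the qualitative pattern
#: of a membrane-IgM knockdown with an IgT compensatory rise.
DEFAULT_CT_SHIFTS = {
    ("mIgM", "head_kidney"): 3.0,
    ("mIgM", "spleen"): 3.0,
    ("sIgM", "head_kidney"): -0.7,
    ("sIgM", "spleen"): 0.0,
    ("IgT", "head_kidney"): -1.0,
    ("IgT", "spleen"): -1.2,
}


def simulate_ct_table(
    seed: int,
    n_crispant: int = 20,
    n_control: int = 10,
    tissues: tuple[str, ...] = ("head_kidney", "spleen"),
    genes: tuple[str, ...] = ("mIgM", "sIgM", "IgT"),
    reference_gene: str = "Ef1a",
    shifts: dict | None = None,
    biological_sd: float = 0.4,
    replicate_sd: float = 0.15,
) -> pd.DataFrame:
    """Synthetic duplicate-Ct table emulating a crispant-vs-control qPCR run.

    Returns a long-format frame with columns sample_id, group, tissue,
    gene, ct_rep1, ct_rep2.  ``shifts`` maps (gene, tissue) to the true
    ΔΔCt of the crispant group (controls sit at 0 by construction).
    """
    rng = np.random.default_rng(seed)
    shifts = DEFAULT_CT_SHIFTS if shifts is None else shifts
    groups = (
        [("crispant", f"IgM_{i + 1:02d}") for i in range(n_crispant)]
        + [("control_wt", f"WT_{i + 1:02d}") for i in range(n_control)]
        + [("control_albino", f"Alb_{i + 1:02d}") for i in range(n_control)]
    )
    base_ct = {g: 24.0 + 1.5 * k for k, g in enumerate(genes)}
    rows = []
    for tissue in tissues:
        for group, sample in groups:
            ct_ref = rng.normal(18.0, 0.3)
            for gene in genes:
                dct = rng.normal(base_ct[gene] - 18.0, biological_sd)
                if group == "crispant":
                    dct += shifts.get((gene, tissue), 0.0)
                ct_goi = ct_ref + dct
                rows.append(
                    {
                        "sample_id": sample,
                        "group": group,
                        "tissue": tissue,
                        "gene": gene,
                        "ct_rep1": round(ct_goi + rng.normal(0, replicate_sd), 3),
                        "ct_rep2": round(ct_goi + rng.normal(0, replicate_sd), 3),
                    }
                )
            rows.append(
                {
                    "sample_id": sample,
                    "group": group,
                    "tissue": tissue,
                    "gene": reference_gene,
                    "ct_rep1": round(ct_ref + rng.normal(0, replicate_sd), 3),
                    "ct_rep2": round(ct_ref + rng.normal(0, replicate_sd), 3),
                }
            )
    return pd.DataFrame(rows)
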