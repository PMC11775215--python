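# Methods

`crispramp` quantifies CRISPR/Cas9 editing outcomes from deep amplicon
sequencing of mosaic F0 animals ("crispants") and computes
efficiency-corrected relative gene expression from qPCR Ct tables. This
note documents the models, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## Reference model and coordinates

All coordinates are 0-based, half-open. A cut position names the gap
*before* the indexed base, which makes indel placement unambiguous. A
`ReferenceAmplicon` is a locus-specific PCR product with annotated primer
spans; the quantifiable region is the inter-primer interval. The Cas9
target site is located by searching both strands for the exact 20-nt
spacer adjacent to an NGG PAM (`CCN` upstream of the reverse-complement
occurrence on the minus strand). The blunt cut is placed 3 nt 5' of the
PAM on the protospacer strand. Zero hits and multiple hits are errors;
the caller must disambiguate multi-hit references. Because guide
efficiency in vivo is unpredictable and typically only one of several
candidate guides produces usable mutagenesis, the spacer is always an
input, never hard-coded; both candidate spacers for the salmon IgM mu-1
exon are shipped as constants.

The duplicated salmon genome carries two near-identical IgM heavy-chain
loci (A and B). Reads are demultiplexed by alignment: a read is assigned
to the reference with the best glocal edit-distance-derived score,
provided it reaches half the maximum attainable score and strictly beats
the runner-up; ties and sub-floor reads are UNASSIGNED and excluded from
all denominators. The bundled pair of reference amplicons is a
**synthetic stand-in** for the real loci (whose sequences are genome
accessions, not printed data): 380 nt, 25-nt primer spans, the real
IgM-1 spacer + TGG PAM embedded mid-amplicon, and eight discriminating
substitutions placed in the flanks of locus B, away from the
quantification window, mirroring how locus-specific variation sits
outside the cut region in the real duplicated loci.

## Read filtering

Trimming reproduces the BWA-style suffix-sum rule implemented by
cutadapt's `-q`: with deficits `d_j = q_j - Q`, remove the suffix
starting at the index that minimizes the suffix sum when that minimum is
negative, ties broken toward the longest retained read. Defaults are
Q20 and a 100-nt minimum length (reads shorter than 100 nt are
discarded; exactly 100 is kept), Phred+33. A pair is dropped when either
mate fails the length filter.

Pair merging (the original analysis does not state how pairs were
handled, so this is a config switch, `pairing: merge | r1_only`, default
merge): the best ungapped overlap of R1 with the reverse complement of
R2 of length >= 20 and mismatch fraction <= 0.1, scored by
matches − mismatches. Consensus takes the higher-quality base at
disagreements (ties favour R1) and the higher quality at agreements.
Unmergeable pairs fall back to R1 alone. With 2x300 reads on a ~380-nt
amplicon, merged reads span the full amplicon, so every read covers the
quantification window and the two mates error-correct each other over
most of its length.

## Alignment

Each retained read is aligned to its assigned reference by affine-gap
dynamic programming, global in the read with free end-gaps on the
reference ("glocal") — the well-posed pairwise core of read-to-reference
mapping. Scores: match +5, mismatch −4, gap open −10, gap extend −1; a
gap of length L costs 10 + L (EMBOSS convention). Determinism: ties in
the DP are resolved with a fixed state priority (diagonal >
deletion-from-reference > insertion), and after backtrace internal
indels are left-normalized — shifted left one base at a time while the
column to the left is a match and the rotation reproduces both sequences
— giving VCF-like leftmost placement inside homopolymer runs. The kernel
is numba-compiled; the pipeline bands it around the diagonal suggested
by a preceding edlib glocal screen (half-width `2d + 16` for edit
distance `d`), which provably contains the edit-distance path and, in
all tested conditions, the affine optimum; `band=None` computes the full
matrix and is what the oracle tests exercise.

## Classification

Indel events whose reference footprint intersects the quantification
window are collected; `net = Σ insertions − Σ deletions` over those
events. At least one event and `net % 3 != 0` → FRAMESHIFT; at least one
event and `net % 3 == 0` → IN_FRAME; no events and at most `max_subs`
in-window substitutions (default 0, i.e. strict perfect match) → WT.
Event-free reads with excess substitutions have no home in the strict
trichotomy; the default policy counts them as IN_FRAME (mutated,
frame-preserving), with `wt` and `separate` available. Reads whose
alignment does not span the window are UNASSIGNED.

Two window modes exist. `full_amplicon` (the inter-primer region) is the
most literal reading of whole-read categorization and is the library
default. `cut_centered` (± 30 nt around the cut) is the mode used by the
recovery study and the bundled pipeline configuration: substitution
sequencing errors are Poisson over the window, so with strict
perfect-match WT a ~330-nt window at error rate 0.003 relabels the
majority of true-WT reads as mutated (an effect of the classification
convention, not an implementation artifact — the error-robustness test
measures it and confirms the analytic rate 1 − (1 − e)^w), whereas a
60-nt cut-centred window keeps that leak near 0.4 percentage points
while still containing every Cas9-induced indel, which the simulator
anchors at the cut. Per-sample fractions are over classified reads only;
cohort statistics are unweighted means across individuals, so deep and
shallow samples count equally.

## Synthetic mosaic crispants

The generator models an F0 crispant as a mixture of cell populations.
Per individual and locus, a pool of K distinct edited alleles is drawn
(K = 1 + Poisson(3)); each tissue then draws its own spectrum over the
shared pool, which is what makes fin and leukocyte spectra of one fish
diverge while remaining related. The wild-type fraction is
Beta-distributed with mean `1 − editing_rate` (concentration 20); the
edited remainder is split by a symmetric Dirichlet (concentration 1).
Indels are single events anchored at the cut: insertions at the cut gap,
deletions centred on it; sizes are geometric (deletions p = 0.25 capped
at 30 nt, insertions p = 0.5 capped at 10 nt, P(ins) = 0.3), matching
the qualitative dominance of short deletions at Cas9 cuts. Under these
defaults the edited-allele frameshift probability is 0.787.

Reads: R1 from the 5' end of the edited amplicon, R2 the reverse
complement from the 3' end, 300 nt each; substitution errors are
injected per base at a configured uniform rate (0.003 in the recovery
study); qualities follow a Q35 body with a linear 30-nt 3' decay to Q10
plus ±2 jitter, so the trimmer has realistic work. The truth table
counts the categories of the reads actually emitted (not just their
expectations), and with a fixed seed the output is byte-identical across
runs (gzip members are written with mtime 0).

What passing recovery tests show: the trimming → merging → demultiplex →
alignment → classification chain is unbiased to within ±0.01 per
category under MiSeq-like error and realistic mosaic spectra at 10,000
pairs/sample. What they do not show: robustness to PCR chimeras, indel
sequencing errors, adapter read-through, large structural variants, or
real locus sequence context — none of which the generator models.

The qPCR side has its own synthetic generator: duplicate-Ct tables for
crispant/wild-type-control/albino-control groups in head kidney and
spleen, with configurable true ΔΔCt shifts (defaults emulate a
membrane-IgM knockdown of ~3 cycles with an IgT rise), between-sample
SD 0.4 cycles and replicate SD 0.15 cycles.

## qPCR analysis

Technical replicates are averaged (SD > 0.5 cycles flagged). Per sample,
ΔCt = Ct_goi − Ct_ref; the calibrator per gene and tissue is the mean
ΔCt of the pooled control samples (both control groups together); ΔΔCt =
ΔCt − calibrator. Two fold-change modes are implemented because the
efficiency-corrected literature mixes them: `single_efficiency`
(default) computes `FC = E_goi^(−ΔΔCt)` — it follows the stated
ΔCt/calibrator/ΔΔCt steps literally while using the measured per-gene
efficiency — and `pfaffl_full` computes the ratio form
`E_goi^(ΔCt_goi,cal−sample) / E_ref^(ΔCt_ref,cal−sample)` with
calibrator Cts equal to mean control Cts. The modes coincide exactly
when E_goi = E_ref, and the calibrator definition forces the geometric
mean of control fold changes to 1 in the default mode; both identities
are asserted in tests. Efficiencies are inputs (fold per cycle,
validated to (1, 2.2]); the measured values for the salmon Ef1a, sIgM,
mIgM and IgT assays in head kidney/spleen ship as defaults.

Group comparisons use the Mann–Whitney U test (U reported as
min(U_a, U_b), two-sided p, no multiplicity adjustment, controls
pooled). For tie-free pooled samples of at most 16 observations the p is
the exact permutation probability P(min(U_a, U_b) ≤ observed), computed
from the exact null distribution of U via the classical count recurrence
f(m, n, u) = f(m−1, n, u−n) + f(m, n−1, u); otherwise a normal
approximation with tie correction and a two-sided continuity correction
(|U − μ| reduced by ½ and clamped at zero, so identical groups give
p = 1 exactly). The exact path is cross-checked in tests against both
brute-force assignment enumeration and an independent library
implementation.

## Numerical and degenerate-input choices

- Empty reads, empty groups, all-NaN replicates, missing reference-gene
  rows and missing efficiencies are errors that name the offending
  sample or file; corrupt FASTQ records name the file.
- `editing_rate = 0` short-circuits to a pure-WT spectrum;
  `editing_rate = 1` removes the WT allele entirely.
- Allele fractions must sum to 1 within 1e-9; category fractions sum to
  1 by construction over classified reads.
- Per-sample classification results are memoized by read sequence;
  error-free reads collapse onto their source alleles, which removes
  roughly half the alignment work at 0.3% error.
- Fixed internal seed (202501) for the synthetic reference pair; all
  study randomness flows from the user seed through
  `numpy.random.SeedSequence.spawn`, one child per individual.

## Problem sizes

The recovery study runs 20 individuals × 2 loci × 10,000 read pairs
(400,000 pairs end to end, a few minutes on one core); oracle batteries
use 1,000 random reads (trimming), 200 anchored toy references
(classification), and 500 random small-sample cases (Mann–Whitney). Toy
classifier references are ≤ 30 nt with aperiodic 6-nt anchor flanks;
the anchors pin the glocal alignment so that a planted interior indel
cannot partially escape into the free reference end-gaps (without them,
a homopolymer run touching a reference end occasionally lets an optimal
alignment absorb one gap base into the free flank and change the
apparent net indel length — a boundary effect of glocal alignment, not
of the classifier).

## Known limitations

- The strict perfect-match WT convention makes the WT fraction an
  underestimate in the presence of any substitution noise when wide
  windows are used; use `cut_centered` or `max_subs > 0` when that bias
  matters.
- Demultiplexing assumes locus-discriminating positions outside the
  edited region; alleles deleting those positions could in principle be
  misassigned (not possible with the bundled references, whose
  discriminating sites sit outside the maximal deletion span).
- The banded alignment is a heuristic acceleration; pathological reads
  whose affine optimum deviates from the edlib path by more than the
  band could be misscored. No such case has been observed; full-matrix
  alignment is available everywhere.
- Fold-change analysis treats efficiencies as known constants;
  uncertainty in E is not propagated.
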