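"""Pipeline orchestration: simulate → trim/merge → classify → qPCR.

File-based entry points (used by the CLI) plus in-memory study runners
used for parameter-recovery validation.  Every output table starts with a
comment line carrying the package version, the seed and a config hash, so
a result file can always be traced back to the run that made it.
"""

from __future__ import annotations

import dataclasses
import gzip
import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import __version__
from .align import Scoring
from .classify import (
    ClassifyPolicy,
    LocusSummary,
    SequenceClassifier,
    cohort_means,
    summarize_locus,
)
from .preprocess import TrimPolicy, merge_pairs, trim_pair
from .qpcr import efficiency_table, fold_change, group_comparison
from .refdata import ReferenceAmplicon, load_references, make_quant_window, write_references
from .simulate import SimConfig, SimulatedSample, build_default_references, simulate_dataset

__all__ = [
    "PipelineConfig",
    "analyze_pairs",
    "analyze_sample",
    "run_simulate",
    "run_trim",
    "run_classify",
    "run_qpcr",
    "run_recovery_study",
    "open_maybe_gzip",
    "read_fastq",
    "read_fastq_pairs",
    "write_fastq",
    "write_table",
    "read_table",
]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, serializable to/from YAML."""

    seed: int = 1
    out_dir: str = "crispramp_out"
    references_fasta: str | None = None  # None = bundled synthetic references
    sites_json: str | None = None
    manifest: str | None = None
    ct_table: str | None = None
    efficiency_table: str | None = None
    pairing: str = "merge"  # merge | r1_only
    min_overlap: int = 20
    max_mismatch_frac: float = 0.1
    window_mode: str = "full_amplicon"
    window_halfwidth: int = 30
    qpcr_mode: str = "single_efficiency"
    write_per_read: bool = False
    trim: TrimPolicy = field(default_factory=TrimPolicy)
    scoring: Scoring = field(default_factory=Scoring)
    classify: ClassifyPolicy = field(default_factory=ClassifyPolicy)
    sim: SimConfig | None = None

    def __post_init__(self) -> None:
        if self.pairing not in ("merge", "r1_only"):
            raise ValueError(f"pairing must be 'merge' or 'r1_only', got {self.pairing!r}")
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)

    def to_dict(self) -> dict:
        # JSON round-trip normalizes tuples to lists for stable serialization
        return json.loads(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        for key, sub in (("trim", TrimPolicy), ("scoring", Scoring), ("classify", ClassifyPolicy), ("sim", SimConfig)):
            if key in data and isinstance(data[key], dict):
                kwargs = dict(data[key])
                if "tissues" in kwargs:
                    kwargs["tissues"] = tuple(kwargs["tissues"])
                data[key] = sub(**kwargs)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def load_amplicons(self) -> list[ReferenceAmplicon]:
        if self.references_fasta is None:
            return build_default_references()
        if self.sites_json is None:
            raise ValueError("sites_json is required alongside references_fasta")
        return load_references(self.references_fasta, self.sites_json)

    def windows(self, amps: Sequence[ReferenceAmplicon]):
        return {
            a.locus_id: make_quant_window(a, self.window_mode, self.window_halfwidth)
            for a in amps
        }


# ---------------------------------------------------------------------------
# FASTQ and table I/O
# ---------------------------------------------------------------------------


def open_maybe_gzip(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        if "r" in mode:
            return gzip.open(path, mode)
        # fixed mtime so identical content gives byte-identical files
        raw = gzip.GzipFile(path, mode.replace("t", "") or "wb", mtime=0)
        if "t" in mode:
            import io

            return io.TextIOWrapper(raw)
        return raw
    return open(path, mode)


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    with open_maybe_gzip(path) as fh:
        try:
            yield from FastqGeneralIterator(fh)
        except ValueError as exc:
            raise ValueError(f"corrupt FASTQ record in {path}: {exc}") from exc


def read_fastq_pairs(r1_path, r2_path) -> Iterator[tuple[tuple[str, str], tuple[str, str]]]:
    for (t1, s1, q1), (t2, s2, q2) in zip(read_fastq(r1_path), read_fastq(r2_path), strict=True):
        id1 = re.sub(r"/[12]$", "", t1.split()[0])
        id2 = re.sub(r"/[12]$", "", t2.split()[0])
        if id1 != id2:
            raise ValueError(f"read pairing mismatch: {t1!r} vs {t2!r}")
        yield (s1, q1), (s2, q2)


def write_fastq(path, records: Iterable[tuple[str, str, str]]) -> None:
    with open_maybe_gzip(path, "wt") as fh:
        for title, seq, qual in records:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")


def write_table(df: pd.DataFrame, path, seed: int, config_hash: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# crispramp={__version__} seed={seed} config={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# Core per-sample analysis
# ---------------------------------------------------------------------------


def analyze_pairs(
    pairs: Iterable,
    classifier: SequenceClassifier,
    trim_policy: TrimPolicy,
    pairing: str = "merge",
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
):
    """Trim, (optionally) merge, and classify a stream of read pairs.

    ``pairs`` yields ((r1_seq, r1_qual), (r2_seq, r2_qual)) or objects with
    those four attributes.  Returns (classifications, stats dict).
    """
    stats = {"pairs_in": 0, "discarded_short": 0, "merged": 0, "r1_only": 0}
    out = []
    for item in pairs:
        if isinstance(item, tuple):
            (s1, q1), (s2, q2) = item
        else:
            s1, q1, s2, q2 = item.r1_seq, item.r1_qual, item.r2_seq, item.r2_qual
        stats["pairs_in"] += 1
        trimmed = trim_pair((s1, q1), (s2, q2), trim_policy)
        if trimmed is None:
            stats["discarded_short"] += 1
            continue
        if pairing == "merge":
            merged = merge_pairs(
                trimmed[0], trimmed[1], min_overlap=min_overlap, max_mismatch_frac=max_mismatch_frac
            )
            if merged is not None:
                stats["merged"] += 1
                seq = merged[0]
            else:
                stats["r1_only"] += 1
                seq = trimmed[0][0]
        else:
            stats["r1_only"] += 1
            seq = trimmed[0][0]
        out.append(classifier(seq))
    return out, stats


def analyze_sample(
    sample: SimulatedSample, config: PipelineConfig, classifier: SequenceClassifier
) -> tuple[LocusSummary, dict]:
    cls, stats = analyze_pairs(
        sample.pairs,
        classifier,
        config.trim,
        pairing=config.pairing,
        min_overlap=config.min_overlap,
        max_mismatch_frac=config.max_mismatch_frac,
    )
    summary = summarize_locus(cls, sample.individual, sample.tissue, sample.locus)
    return summary, stats


# ---------------------------------------------------------------------------
# File-based stage runners
# ---------------------------------------------------------------------------


def run_simulate(config: PipelineConfig, out_dir=None) -> pd.DataFrame:
    """Simulate a dataset to disk; returns the manifest frame."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    amps = config.load_amplicons()
    if config.references_fasta is None:
        write_references(amps, out / "references.fasta", out / "sites.json")
    chash = config.config_hash()
    manifest_rows = []
    truth_rows = []
    for sample in simulate_dataset(amps, config.sim):
        stem = f"{sample.individual}_{sample.tissue}_{sample.locus}"
        r1_path = out / f"{stem}_R1.fastq.gz"
        r2_path = out / f"{stem}_R2.fastq.gz"
        tag = f"{sample.individual}:{sample.tissue}:{sample.locus}"
        write_fastq(
            r1_path,
            ((f"{tag}:{i}/1", p.r1_seq, p.r1_qual) for i, p in enumerate(sample.pairs)),
        )
        write_fastq(
            r2_path,
            ((f"{tag}:{i}/2", p.r2_seq, p.r2_qual) for i, p in enumerate(sample.pairs)),
        )
        manifest_rows.append(
            {
                "individual": sample.individual,
                "tissue": sample.tissue,
                "locus": sample.locus,
                "r1": r1_path.name,
                "r2": r2_path.name,
            }
        )
        truth_rows.append(sample.truth)
    manifest = pd.DataFrame(
        manifest_rows, columns=["individual", "tissue", "locus", "r1", "r2"]
    )
    write_table(manifest, out / "manifest.tsv", config.seed, chash)
    truth = pd.DataFrame(truth_rows)
    if not truth.empty:
        write_table(truth, out / "truth.tsv", config.seed, chash)
    config.to_yaml(out / "config.yaml")
    return manifest


def run_trim(
    r1_path, r2_path, out_r1, out_r2, policy: TrimPolicy | None = None
) -> dict:
    """Trim a FASTQ pair to disk, dropping pairs failing the length filter."""
    policy = policy or TrimPolicy()
    stats = {"pairs_in": 0, "pairs_kept": 0, "discarded_short": 0}

    def _records():
        for (t1, s1, q1), (t2, s2, q2) in zip(
            read_fastq(r1_path), read_fastq(r2_path), strict=True
        ):
            stats["pairs_in"] += 1
            trimmed = trim_pair((s1, q1), (s2, q2), policy)
            if trimmed is None:
                stats["discarded_short"] += 1
                continue
            stats["pairs_kept"] += 1
            yield (t1, *trimmed[0]), (t2, *trimmed[1])

    with open_maybe_gzip(out_r1, "wt") as f1, open_maybe_gzip(out_r2, "wt") as f2:
        for (t1, s1, q1), (t2, s2, q2) in _records():
            f1.write(f"@{t1}\n{s1}\n+\n{q1}\n")
            f2.write(f"@{t2}\n{s2}\n+\n{q2}\n")
    return stats


def run_classify(config: PipelineConfig, fastq_dir=None, out_dir=None) -> dict:
    """Classify every sample in the manifest; write summary tables.

    Returns a dict with the per-sample summary frame, the cohort-mean
    frame, and per-sample processing stats.  Raises if any sample yields
    zero classified reads.
    """
    if config.manifest is None:
        raise ValueError("config.manifest is required for run_classify")
    fastq_dir = Path(fastq_dir or Path(config.manifest).parent)
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    amps = config.load_amplicons()
    windows = config.windows(amps)
    chash = config.config_hash()
    manifest = read_table(config.manifest)
    summaries = []
    stats_rows = []
    per_read_rows = []
    for row in manifest.itertuples():
        classifier = SequenceClassifier(amps, windows, config.classify, config.scoring)
        pairs = read_fastq_pairs(fastq_dir / row.r1, fastq_dir / row.r2)
        cls, stats = analyze_pairs(
            pairs,
            classifier,
            config.trim,
            pairing=config.pairing,
            min_overlap=config.min_overlap,
            max_mismatch_frac=config.max_mismatch_frac,
        )
        summary = summarize_locus(cls, row.individual, row.tissue, row.locus)
        summaries.append(summary)
        stats_rows.append({"individual": row.individual, "tissue": row.tissue, "locus": row.locus, **stats})
        if config.write_per_read:
            per_read_rows.extend(
                {
                    "individual": row.individual,
                    "tissue": row.tissue,
                    "locus": row.locus,
                    "read_index": i,
                    "assigned_locus": c.assigned_locus or "",
                    "category": c.category,
                    "net_indel": c.net_indel,
                    "n_indel_events": c.n_indel_events,
                    "n_substitutions": c.n_substitutions,
                }
                for i, c in enumerate(cls)
            )
    per_sample = pd.DataFrame([s.as_dict() for s in summaries])
    cohort = cohort_means(summaries)
    write_table(per_sample, out / "per_sample_summary.tsv", config.seed, chash)
    write_table(cohort, out / "cohort_means.tsv", config.seed, chash)
    write_table(pd.DataFrame(stats_rows), out / "trim_report.tsv", config.seed, chash)
    if config.write_per_read:
        write_table(pd.DataFrame(per_read_rows), out / "per_read.tsv", config.seed, chash)
    return {"per_sample": per_sample, "cohort": cohort, "stats": pd.DataFrame(stats_rows)}


def run_qpcr(config: PipelineConfig, out_dir=None) -> dict:
    """Fold changes and group comparisons from a long-format Ct table."""
    if config.ct_table is None:
        raise ValueError("config.ct_table is required for run_qpcr")
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = read_table(config.ct_table)
    eff = (
        read_table(config.efficiency_table)
        if config.efficiency_table is not None
        else efficiency_table()
    )
    expression = fold_change(records, eff, mode=config.qpcr_mode)
    comparison = group_comparison(expression)
    chash = config.config_hash()
    write_table(expression, out / "expression.tsv", config.seed, chash)
    write_table(comparison, out / "group_comparison.tsv", config.seed, chash)
    return {"expression": expression, "comparison": comparison}


# ---------------------------------------------------------------------------
# In-memory parameter-recovery study
# ---------------------------------------------------------------------------


def run_recovery_study(
    seed: int,
    n_individuals: int = 20,
    read_depth: int = 10_000,
    error_rate: float = 0.003,
    editing_rate: float = 0.975,
    window_mode: str = "cut_centered",
    window_halfwidth: int = 30,
    pairing: str = "merge",
) -> dict:
    """Simulate a crispant cohort and recover its editing statistics.

    One tissue, both duplicated loci, ``read_depth`` pairs per sample.
    Returns per-sample estimates joined to the simulator truth, cohort
    means of both, and the per-category absolute cohort errors — the
    primary end-to-end validation of the whole read-level pipeline.
    """
    amps = build_default_references()
    sim = SimConfig(
        seed=seed,
        n_individuals=n_individuals,
        tissues=("fin",),
        read_depth=read_depth,
        error_rate=error_rate,
        editing_rate=editing_rate,
    )
    config = PipelineConfig(
        seed=seed, sim=sim, window_mode=window_mode, window_halfwidth=window_halfwidth, pairing=pairing
    )
    windows = config.windows(amps)
    summaries = []
    truth_rows = []
    for sample in simulate_dataset(amps, sim):
        classifier = SequenceClassifier(amps, windows, config.classify, config.scoring)
        summary, _ = analyze_sample(sample, config, classifier)
        summaries.append(summary)
        truth_rows.append(sample.truth)
    est = pd.DataFrame([s.as_dict() for s in summaries])
    truth = pd.DataFrame(truth_rows)
    key = ["individual", "tissue", "locus"]
    joined = est.merge(truth, on=key, suffixes=("", "_truth"))
    for cat in ("wt", "inframe", "frameshift"):
        joined[f"abs_err_{cat}"] = (joined[f"f_{cat}"] - joined[f"frac_{cat}"]).abs()
    truth["frac_mutated"] = truth["frac_inframe"] + truth["frac_frameshift"]
    est_cohort = (
        est.groupby("locus")[["f_wt", "f_inframe", "f_frameshift", "f_mutated"]]
        .mean()
        .rename(columns=lambda c: c.replace("f_", ""))
    )
    truth_cohort = (
        truth.groupby("locus")[["frac_wt", "frac_inframe", "frac_frameshift", "frac_mutated"]]
        .mean()
        .rename(columns=lambda c: c.replace("frac_", ""))
    )
    cohort_abs_err = (est_cohort - truth_cohort).abs()
    return {
        "per_sample": joined,
        "estimate_cohort": est_cohort,
        "truth_cohort": truth_cohort,
        "cohort_abs_err": cohort_abs_err,
        "config": config,
    }
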