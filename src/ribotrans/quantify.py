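"""Alignment quantification: counts, FPKM, translation efficiency, QC.

Reads transcript-space SAM/BAM, keeps primary uniquely-mapped records
(NH tag when present, else a mapping-quality threshold), and produces per
transcript x sample raw counts and FPKM. For RNA-Seq every transcript-mapped
read counts against the full transcript length; for Ribo-Seq a read counts
only if its 5' end lies inside the CDS (half-open), against the CDS length.
FPKM below 1.0 is floored to 1.0 before any log-scale quantity is formed,
and translation efficiency is the log2 ratio of floored Ribo to floored RNA
FPKM.

The FPKM denominator (``mapped_total``) is, for both assays, the number of
unique non-rRNA transcript-mapped reads, so the CDS restriction affects the
Ribo numerator only and denominators stay comparable across assays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .reference import Annotation

__all__ = [
    "AlignedRead",
    "SampleTally",
    "QuantTable",
    "iter_alignments",
    "tally_sample",
    "count_reads",
    "fpkm",
    "floor_fpkm",
    "translation_efficiency",
    "frame_distribution",
    "region_density",
    "replicate_correlation",
    "coverage_filter",
    "quantify_samples",
    "qc_report",
    "condition_log2",
]

DEFAULT_MIN_MAPQ = 10


@dataclass(frozen=True)
class AlignedRead:
    """A read placed on a transcript (0-based 5'-end offset)."""

    transcript_id: str
    start: int
    read_length: int
    is_unique: bool = True


def iter_alignments(
    path: str | Path, min_mapq: int = DEFAULT_MIN_MAPQ
) -> Iterator[AlignedRead]:
    """Yield primary mapped records from a transcript-space SAM/BAM.

    Uniqueness comes from the NH tag when present (NH == 1), otherwise from
    ``mapq >= min_mapq``.
    """
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.has_tag("NH"):
                unique = rec.get_tag("NH") == 1
            else:
                unique = rec.mapping_quality >= min_mapq
            length = rec.infer_query_length() or rec.query_length
            yield AlignedRead(rec.reference_name, rec.reference_start, int(length), unique)


@dataclass
class SampleTally:
    """One-pass per-sample tallies over an alignment stream."""

    all_counts: dict[str, int] = field(default_factory=dict)  # any-region, per transcript
    cds_counts: dict[str, int] = field(default_factory=dict)  # 5' end in CDS
    frame: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=np.int64))
    region_reads: dict[str, int] = field(
        default_factory=lambda: {"utr5": 0, "cds": 0, "utr3": 0}
    )
    mapped_total: int = 0  # unique non-rRNA transcript-mapped reads
    n_records: int = 0
    n_nonunique: int = 0
    n_rrna: int = 0


def _tally_stream(reads, ann, on_missing_reference):
    """Shared tally loop over (transcript_id, start, is_unique) triples."""
    tally = SampleTally()
    missing: set[str] = set()
    spans = {
        tid: (t.cds_start, t.cds_end, t.is_rRNA) for tid, t in ann.transcripts.items()
    }
    frames = [0, 0, 0]
    for tid, s, unique in reads:
        tally.n_records += 1
        span = spans.get(tid)
        if span is None:
            if on_missing_reference == "error":
                raise KeyError(f"SAM reference {tid} absent from annotation")
            missing.add(tid)
            continue
        if not unique:
            tally.n_nonunique += 1
            continue
        if span[2]:
            tally.n_rrna += 1
            tally.all_counts[tid] = tally.all_counts.get(tid, 0) + 1
            continue
        tally.mapped_total += 1
        tally.all_counts[tid] = tally.all_counts.get(tid, 0) + 1
        if s < span[0]:
            tally.region_reads["utr5"] += 1
        elif s < span[1]:
            tally.region_reads["cds"] += 1
            tally.cds_counts[tid] = tally.cds_counts.get(tid, 0) + 1
            frames[(s - span[0]) % 3] += 1
        else:
            tally.region_reads["utr3"] += 1
    tally.frame += np.array(frames, dtype=np.int64)
    if missing:
        warnings.warn(f"{len(missing)} SAM references absent from annotation; skipped")
    return tally


def _sam_triples(path: str | Path, min_mapq: int):
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            try:
                unique = rec.get_tag("NH") == 1
            except KeyError:
                unique = rec.mapping_quality >= min_mapq
            yield rec.reference_name, rec.reference_start, unique


def tally_sample(
    alignments: str | Path | Iterable[AlignedRead],
    ann: Annotation,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    on_missing_reference: str = "error",
) -> SampleTally:
    """Count unique reads per transcript, per CDS, per frame and per region."""
    if isinstance(alignments, (str, Path)):
        reads = _sam_triples(alignments, min_mapq)
    else:
        reads = ((r.transcript_id, r.start, r.is_unique) for r in alignments)
    return _tally_stream(reads, ann, on_missing_reference)


def count_reads(
    alignments: str | Path | Iterable[AlignedRead],
    ann: Annotation,
    assay: str,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    on_missing_reference: str = "error",
) -> tuple[dict[str, int], int]:
    """Per-transcript raw counts plus the FPKM denominator for one sample."""
    if assay not in ("rna", "ribo"):
        raise ValueError(f"assay must be 'rna' or 'ribo', got {assay!r}")
    tally = tally_sample(alignments, ann, min_mapq, on_missing_reference)
    counts = tally.all_counts if assay == "rna" else tally.cds_counts
    counts = {tid: n for tid, n in counts.items() if not ann[tid].is_rRNA}
    return counts, tally.mapped_total


def fpkm(raw_count, feature_length, mapped_total) -> np.ndarray | float:
    """Fragments per kilobase of feature per million mapped reads."""
    if np.any(np.asarray(mapped_total) <= 0):
        raise ValueError("mapped_total must be positive (empty library?)")
    if np.any(np.asarray(feature_length) <= 0):
        raise ValueError("feature_length must be positive")
    return np.asarray(raw_count, dtype=float) / (
        (np.asarray(feature_length, dtype=float) / 1e3)
        * (np.asarray(mapped_total, dtype=float) / 1e6)
    )


def floor_fpkm(value, floor: float = 1.0):
    """Clamp FPKM from below (default 1.0) so log ratios are defined and damped."""
    return np.maximum(value, floor)


def translation_efficiency(ribo_fpkm_floored, rna_fpkm_floored):
    """TE = log2(ribo FPKM) - log2(rna FPKM), both floored at 1.0."""
    return np.log2(ribo_fpkm_floored) - np.log2(rna_fpkm_floored)


def frame_distribution(
    alignments: str | Path | Iterable[AlignedRead] | SampleTally,
    ann: Annotation | None = None,
) -> np.ndarray | None:
    """Fraction of CDS-internal reads whose 5' end falls in frame 0/1/2.

    Returns None (undefined) when the sample has no CDS reads.
    """
    tally = (
        alignments
        if isinstance(alignments, SampleTally)
        else tally_sample(alignments, ann)
    )
    total = int(tally.frame.sum())
    if total == 0:
        return None
    return tally.frame / total


def region_density(
    alignments: str | Path | Iterable[AlignedRead] | SampleTally,
    ann: Annotation,
) -> tuple[dict[str, float], float | None]:
    """Reads per kilobase of aggregate 5'UTR / CDS / 3'UTR, plus 3'UTR depletion.

    Depletion is the 3'UTR density divided by the CDS density; genuine
    ribosome footprints give values near zero.
    """
    tally = (
        alignments
        if isinstance(alignments, SampleTally)
        else tally_sample(alignments, ann)
    )
    lens = {"utr5": 0, "cds": 0, "utr3": 0}
    for t in ann.non_rrna():
        lens["utr5"] += t.utr5_len
        lens["cds"] += t.cds_len
        lens["utr3"] += t.utr3_len
    density = {
        r: (tally.region_reads[r] / (lens[r] / 1e3)) if lens[r] > 0 else float("nan")
        for r in lens
    }
    if lens["utr3"] == 0 or density["cds"] == 0:
        return density, None
    return density, density["utr3"] / density["cds"]


def replicate_correlation(sample_a: np.ndarray, sample_b: np.ndarray) -> float | None:
    """Pearson r between two log2 floored FPKM vectors; None if degenerate."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("replicate vectors must share the transcript universe")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant log2 FPKM vector; correlation undefined")
        return None
    return float(stats.pearsonr(a, b).statistic)


# ---------------------------------------------------------------------------
# tables


@dataclass
class QuantTable:
    """Raw counts and FPKM per transcript x sample, with sample metadata.

    ``counts`` rows are non-rRNA representative transcripts; columns are
    sample ids. RNA columns hold any-region counts, Ribo columns CDS-only
    counts. ``samples`` carries assay/condition/batch/replicate/mapped_total.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    ann: Annotation
    floor: float = 1.0

    def __post_init__(self) -> None:
        self.samples = self.samples.set_index("sample_id", drop=False)
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples sheet lacks metadata for {sorted(missing)}")

    def feature_lengths(self, assay: str) -> pd.Series:
        vals = {
            tid: (self.ann[tid].length if assay == "rna" else self.ann[tid].cds_len)
            for tid in self.counts.index
        }
        return pd.Series(vals, name="feature_length")

    @property
    def fpkm(self) -> pd.DataFrame:
        out = {}
        for sid in self.counts.columns:
            assay = self.samples.at[sid, "assay"]
            total = self.samples.at[sid, "mapped_total"]
            out[sid] = fpkm(self.counts[sid].to_numpy(), self.feature_lengths(assay).to_numpy(), total)
        return pd.DataFrame(out, index=self.counts.index)

    @property
    def fpkm_floored(self) -> pd.DataFrame:
        return floor_fpkm(self.fpkm, self.floor)

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        """Long-format TSV: transcript, sample, assay, condition, count, fpkm."""
        fp = self.fpkm
        fpf = floor_fpkm(fp, self.floor)
        long = []
        for sid in self.counts.columns:
            meta = self.samples.loc[sid]
            long.append(
                pd.DataFrame(
                    {
                        "transcript_id": self.counts.index,
                        "sample_id": sid,
                        "assay": meta["assay"],
                        "condition": meta["condition"],
                        "batch": meta["batch"],
                        "raw_count": self.counts[sid].to_numpy(),
                        "fpkm": fp[sid].to_numpy(),
                        "fpkm_floored": fpf[sid].to_numpy(),
                    }
                )
            )
        df = pd.concat(long, ignore_index=True)
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, sep="\t", index=False)


def quantify_samples(
    sheet: pd.DataFrame,
    ann: Annotation,
    data_dir: str | Path,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    on_missing_reference: str = "error",
) -> tuple[QuantTable, dict[str, SampleTally]]:
    """Tally every sample in the sheet; returns the table and raw tallies."""
    data_dir = Path(data_dir)
    tids = sorted(t.transcript_id for t in ann.non_rrna())
    cols = {}
    tallies = {}
    meta_rows = []
    for _, row in sheet.iterrows():
        sid = row["sample_id"]
        tally = tally_sample(
            data_dir / row["path"], ann, min_mapq, on_missing_reference
        )
        tallies[sid] = tally
        src = tally.all_counts if row["assay"] == "rna" else tally.cds_counts
        cols[sid] = np.array([src.get(tid, 0) for tid in tids], dtype=np.int64)
        meta_rows.append(
            {
                "sample_id": sid,
                "assay": row["assay"],
                "condition": row["condition"],
                "batch": row["batch"],
                "replicate": row.get("replicate", 1),
                "mapped_total": tally.mapped_total,
            }
        )
    counts = pd.DataFrame(cols, index=pd.Index(tids, name="transcript_id"))
    return QuantTable(counts, pd.DataFrame(meta_rows), ann), tallies


def coverage_filter(quant: QuantTable, min_reads: int = 40) -> list[str]:
    """Transcripts with >= ``min_reads`` in both assays in some condition.

    Replicates within an (assay, condition) are summed at the count level;
    retention requires a single condition where both the RNA-Seq and the
    Ribo-Seq pooled counts reach the threshold.
    """
    meta = quant.samples
    pooled: dict[tuple[str, str], np.ndarray] = {}
    for (assay, cond), grp in meta.groupby(["assay", "condition"]):
        pooled[(assay, cond)] = quant.counts[grp["sample_id"]].sum(axis=1).to_numpy()
    conds = sorted({c for (_, c) in pooled})
    keep = np.zeros(len(quant.counts), dtype=bool)
    for c in conds:
        if ("rna", c) in pooled and ("ribo", c) in pooled:
            keep |= (pooled[("rna", c)] >= min_reads) & (pooled[("ribo", c)] >= min_reads)
    return list(quant.counts.index[keep])


def condition_log2(
    quant: QuantTable, assay: str, batch: str | None = None
) -> pd.DataFrame:
    """Condition-level log2 floored FPKM: mean over replicates per condition.

    With ``batch`` given, only samples from that batch contribute (used for
    batch-paired fold changes; conditions absent from the batch are omitted).
    """
    meta = quant.samples
    sel = meta[meta["assay"] == assay]
    if batch is not None:
        sel = sel[sel["batch"] == batch]
    logf = np.log2(quant.fpkm_floored)
    out = {}
    for cond, grp in sel.groupby("condition"):
        out[cond] = logf[grp["sample_id"]].mean(axis=1)
    return pd.DataFrame(out, index=quant.counts.index)


def qc_report(
    quant: QuantTable, tallies: dict[str, SampleTally], ann: Annotation
) -> dict:
    """Ribosome-profiling QC: frame bias, region densities, replicate r."""
    report: dict = {"samples": {}, "replicate_pairs": []}
    for sid, tally in tallies.items():
        meta = quant.samples.loc[sid]
        entry: dict = {
            "assay": meta["assay"],
            "condition": meta["condition"],
            "batch": meta["batch"],
            "mapped_total": int(tally.mapped_total),
            "rrna_reads": int(tally.n_rrna),
            "nonunique_reads": int(tally.n_nonunique),
        }
        if meta["assay"] == "ribo":
            frac = frame_distribution(tally)
            density, depletion = region_density(tally, ann)
            entry["frame_fractions"] = None if frac is None else [float(x) for x in frac]
            entry["region_density"] = {k: float(v) for k, v in density.items()}
            entry["utr3_depletion"] = None if depletion is None else float(depletion)
        report["samples"][sid] = entry
    logf = np.log2(quant.fpkm_floored)
    meta = quant.samples
    for (assay, cond, batch), grp in meta.groupby(["assay", "condition", "batch"]):
        sids = list(grp["sample_id"])
        for i in range(len(sids)):
            for j in range(i + 1, len(sids)):
                r = replicate_correlation(
                    logf[sids[i]].to_numpy(), logf[sids[j]].to_numpy()
                )
                report["replicate_pairs"].append(
                    {
                        "assay": assay,
                        "condition": cond,
                        "batch": batch,
                        "sample_a": sids[i],
                        "sample_b": sids[j],
                        "pearson_r": None if r is None else float(r),
                    }
                )
    return report
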