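"""Synthetic RNA-Seq / Ribo-Seq data with known ground truth.

Emulates the statistical structure the downstream analysis assumes: a
transcriptome of multi-isoform genes with 5'UTR/CDS/3'UTR segmentation,
RNA-Seq reads (50 nt) uniform over transcripts, ribosome footprints
(30-33 nt) concentrated in the CDS with a strong frame-0 bias and near-total
depletion from 3'UTRs, per-condition expression and translation-efficiency
(TE) multipliers arranged in cluster archetypes, batch-specific library
scaling, rRNA contamination, and negative-binomial count noise.

Everything is driven by a single integer seed; the same seed yields
byte-identical FASTA/GTF/SAM/TSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import Annotation, TranscriptModel

__all__ = [
    "Archetype",
    "TruthConfig",
    "default_archetypes",
    "plant_top",
    "generate_transcriptome",
    "generate_reads",
    "simulate",
    "write_fasta",
    "write_gtf",
    "write_gmt",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_PYRIMIDINES = np.frombuffer(b"CT", dtype=np.uint8)


@dataclass
class Archetype:
    """A planted per-condition response pattern.

    ``expr`` and ``te`` are multiplicative factors, one per condition in the
    configured condition order (control first, factor 1.0 by convention).
    """

    expr: tuple[float, ...]
    te: tuple[float, ...]
    fraction: float
    gene_set: str | None = None
    plant_top: bool = False


def default_archetypes() -> dict[str, Archetype]:
    """Response archetypes mirroring the major observed pattern classes.

    Across control (C), quiescence (Q), pre-senescence (preS), senescence (S)
    and transformation (T): RNA induction specific to Q, to S, or to T; RNA
    repression of cell-cycle-like genes in Q/S and of ribosome-biogenesis-like
    genes mostly in Q; TE repression of ribosomal-protein-like genes in Q and
    S (these carry a planted 5'-TOP element); and a TE-induction pattern.
    Fractions sum to 0.30; the remaining 70% of genes are flat.
    """
    return {
        "rna_up_quiescence": Archetype((1, 4, 1, 1, 1), (1, 1, 1, 1, 1), 0.04),
        "rna_up_senescence": Archetype((1, 1, 2.5, 4, 1), (1, 1, 1, 1, 1), 0.04),
        "rna_up_transformed": Archetype((1, 1, 1, 1, 4), (1, 1, 1, 1, 1), 0.03),
        "rna_down_cellcycle": Archetype(
            (1, 0.3, 0.5, 0.25, 1), (1, 1, 1, 1, 1), 0.06, gene_set="cell-cycle-like"
        ),
        "rna_down_ribogenesis": Archetype(
            (1, 0.25, 0.6, 0.4, 1),
            (1, 1, 1, 1, 1),
            0.04,
            gene_set="ribosome-biogenesis-like",
        ),
        "te_down_rp": Archetype(
            (1, 1, 1, 1, 1),
            (1, 0.25, 0.6, 0.35, 1),
            0.05,
            gene_set="ribosomal-protein-like",
            plant_top=True,
        ),
        "te_up": Archetype((1, 1, 1, 1, 1), (1, 2.5, 1, 2, 1), 0.04),
    }


@dataclass
class TruthConfig:
    """Generator configuration; defaults encode the study design emulated.

    ``batches`` maps a batch (sequencer run) label to the list of *test*
    conditions profiled in that run; every batch additionally receives its
    own control samples, since fold changes are computed against the control
    of the same batch.
    """

    n_genes: int = 2000
    conditions: tuple[str, ...] = (
        "control",
        "quiescence",
        "pre_senescence",
        "senescence",
        "transformation",
    )
    batches: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "batch1": ("quiescence", "pre_senescence"),
            "batch2": ("senescence", "transformation"),
        }
    )
    archetypes: dict[str, Archetype] = field(default_factory=default_archetypes)
    replicates: int = 2
    library_size: int = 2_000_000
    frame0_prob: float = 0.85
    utr3_leak: float = 0.01
    utr5_leak: float = 0.04
    footprint_lengths: dict[int, float] = field(
        default_factory=lambda: {30: 0.15, 31: 0.35, 32: 0.35, 33: 0.15}
    )
    rna_read_length: int = 50
    dispersion: float = 0.003
    batch_scale: dict[str, float] = field(
        default_factory=lambda: {"batch1": 1.0, "batch2": 1.3}
    )
    multimap_fraction: float = 0.02
    rrna_fraction: float = 0.05  # ribo libraries only
    n_rrna: int = 5
    abundance_sigma: float = 1.0  # lognormal spread of baseline abundance
    utr5_range: tuple[int, int] = (50, 200)
    cds_codons_range: tuple[int, int] = (100, 500)
    utr3_range: tuple[int, int] = (100, 500)
    top_run_range: tuple[int, int] = (6, 12)
    plant_top_random: bool = False  # plant TOP on random genes instead of archetype
    decoy_fraction: float = 0.2  # genes receiving 1-3 shorter-CDS decoy isoforms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        frac = sum(a.fraction for a in self.archetypes.values())
        if frac > 1 + 1e-9:
            raise ValueError(f"archetype fractions sum to {frac} > 1")
        for name, a in self.archetypes.items():
            if len(a.expr) != len(self.conditions) or len(a.te) != len(self.conditions):
                raise ValueError(f"archetype {name}: multiplier length != n conditions")
            if min(a.expr) <= 0 or min(a.te) <= 0:
                raise ValueError(f"archetype {name}: multipliers must be positive")
        for p in (self.frame0_prob, self.utr3_leak, self.utr5_leak, self.multimap_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for b in self.batches:
            if b not in self.batch_scale:
                self.batch_scale[b] = 1.0

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, default=list)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthConfig":
        with open(path) as fh:
            d = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "archetypes" in d:
            d["archetypes"] = {
                k: Archetype(
                    expr=tuple(v["expr"]),
                    te=tuple(v["te"]),
                    fraction=v["fraction"],
                    gene_set=v.get("gene_set"),
                    plant_top=v.get("plant_top", False),
                )
                for k, v in d["archetypes"].items()
            }
        if "footprint_lengths" in d:
            d["footprint_lengths"] = {int(k): v for k, v in d["footprint_lengths"].items()}
        for key in ("conditions", "utr5_range", "cds_codons_range", "utr3_range", "top_run_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "batches" in d:
            d["batches"] = {k: tuple(v) for k, v in d["batches"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# sequence-level helpers


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def plant_top(sequence: str, run_length: int, rng: np.random.Generator | None = None) -> str:
    """Overwrite the transcript 5' end with a 5'-TOP element.

    Position 0 becomes C and positions 1..run_length-1 pyrimidines (C/T); the
    rest of the sequence is untouched. ``run_length`` must be at least 5 (the
    classical minimal TOP tract) and fit inside the 5'UTR of the caller.
    """
    if run_length < 5:
        raise ValueError("TOP run_length must be >= 5")
    if run_length > len(sequence):
        raise ValueError("TOP run exceeds sequence length")
    rng = rng or np.random.default_rng(0)
    tract = _PYRIMIDINES[rng.integers(0, 2, size=run_length)]
    tract[0] = ord("C")
    # guarantee the maximal pyrimidine run terminates where intended
    tail = sequence[run_length:]
    if tail[:1] in ("C", "T"):
        tail = "A" + tail[1:]
    return tract.tobytes().decode() + tail


# ---------------------------------------------------------------------------
# transcriptome


def generate_transcriptome(config: TruthConfig) -> tuple[Annotation, pd.DataFrame]:
    """Random transcriptome plus the per-gene truth table.

    Each gene gets one designated representative transcript (CDS length a
    multiple of 3) and, for a ``decoy_fraction`` of genes, 1-3 decoy isoforms
    with strictly shorter CDS so that representative selection is exercised.
    Genes are assigned to archetypes by the configured fractions; genes of
    TOP-flagged archetypes (or an equally sized random set when
    ``plant_top_random``) receive a planted 5'-TOP start. ``n_rrna`` rRNA
    transcripts are appended, flagged, and excluded from the truth table.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = config.n_genes
    ann = Annotation()

    # archetype assignment: deterministic blocks over a shuffled gene order
    labels = np.array(["flat"] * n, dtype=object)
    order = rng.permutation(n)
    pos = 0
    for name, a in config.archetypes.items():
        k = int(round(a.fraction * n))
        labels[order[pos : pos + k]] = name
        pos += k

    top_flags = np.zeros(n, dtype=bool)
    archetype_top = np.array(
        [lbl != "flat" and config.archetypes[lbl].plant_top for lbl in labels]
    )
    if config.plant_top_random:
        k = int(archetype_top.sum())
        top_flags[rng.choice(n, size=k, replace=False)] = True
    else:
        top_flags = archetype_top

    base_abundance = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
    utr5 = rng.integers(*config.utr5_range, size=n, endpoint=True)
    codons = rng.integers(*config.cds_codons_range, size=n, endpoint=True)
    utr3 = rng.integers(*config.utr3_range, size=n, endpoint=True)
    decoy_genes = rng.random(n) < config.decoy_fraction

    rows = []
    for i in range(n):
        gid = f"G{i:05d}"
        tid = f"T{i:05d}"
        length = int(utr5[i] + 3 * codons[i] + utr3[i])
        seq = _random_seq(rng, length).tobytes().decode()
        if top_flags[i]:
            run = int(rng.integers(config.top_run_range[0], config.top_run_range[1] + 1))
            run = min(run, int(utr5[i]))
            seq = plant_top(seq, run, rng)
        ann.add(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                length=length,
                cds_start=int(utr5[i]),
                cds_end=int(utr5[i] + 3 * codons[i]),
                sequence=seq,
            )
        )
        if decoy_genes[i]:
            for d in range(int(rng.integers(1, 4))):
                # strictly shorter CDS than the representative
                dcod = int(rng.integers(10, codons[i]))
                du5 = int(rng.integers(*config.utr5_range, endpoint=True))
                du3 = int(rng.integers(*config.utr3_range, endpoint=True))
                dlen = du5 + 3 * dcod + du3
                ann.add(
                    TranscriptModel(
                        transcript_id=f"{tid}.d{d + 1}",
                        gene_id=gid,
                        length=dlen,
                        cds_start=du5,
                        cds_end=du5 + 3 * dcod,
                        sequence=_random_seq(rng, dlen).tobytes().decode(),
                    )
                )
        lbl = labels[i]
        expr = config.archetypes[lbl].expr if lbl != "flat" else (1.0,) * len(config.conditions)
        te = config.archetypes[lbl].te if lbl != "flat" else (1.0,) * len(config.conditions)
        gene_set = config.archetypes[lbl].gene_set if lbl != "flat" else None
        row = {
            "gene_id": gid,
            "transcript_id": tid,
            "archetype": lbl,
            "top_planted": bool(top_flags[i]),
            "gene_set": gene_set or "",
            "base_abundance": base_abundance[i],
        }
        for j, c in enumerate(config.conditions):
            row[f"expr_{c}"] = expr[j]
        for j, c in enumerate(config.conditions):
            row[f"te_{c}"] = te[j]
        rows.append(row)

    for r in range(config.n_rrna):
        length = int(rng.integers(1500, 5000))
        ann.add(
            TranscriptModel(
                transcript_id=f"RNA45S_{r + 1}",
                gene_id=f"rRNA_{r + 1}",
                length=length,
                cds_start=0,
                cds_end=0,
                is_rRNA=True,
                sequence=_random_seq(rng, length).tobytes().decode(),
            )
        )

    return ann, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# read generation


def _sample_sheet(config: TruthConfig) -> pd.DataFrame:
    rows = []
    for batch in sorted(config.batches):
        for cond in ("control",) + tuple(config.batches[batch]):
            for assay in ("rna", "ribo"):
                for rep in range(1, config.replicates + 1):
                    sid = f"{assay}_{cond}_{batch}_r{rep}"
                    rows.append(
                        {
                            "sample_id": sid,
                            "assay": assay,
                            "condition": cond,
                            "batch": batch,
                            "replicate": rep,
                            "path": f"{sid}.sam",
                        }
                    )
    return pd.DataFrame(rows)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson counts: Var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.maximum(mean, 1e-12) * dispersion)
    return rng.poisson(lam)


def _ribo_starts(
    rng: np.random.Generator,
    t: TranscriptModel,
    n: int,
    config: TruthConfig,
    lengths_pool: np.ndarray,
    length_probs: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized footprint placement on one transcript; returns (starts, lens)."""
    lens = rng.choice(lengths_pool, size=n, p=length_probs)
    u = rng.random(n)
    in_utr3 = u < config.utr3_leak
    in_utr5 = (~in_utr3) & (u < config.utr3_leak + config.utr5_leak)
    in_cds = ~(in_utr3 | in_utr5)
    starts = np.empty(n, dtype=np.int64)

    if in_cds.any():
        m = int(in_cds.sum())
        frames = np.where(
            rng.random(m) < config.frame0_prob, 0, rng.integers(1, 3, size=m)
        )
        lmax = np.minimum(t.cds_end - 1, t.length - lens[in_cds])
        n_slots = (lmax - t.cds_start - frames) // 3 + 1
        n_slots = np.maximum(n_slots, 1)
        k = (rng.random(m) * n_slots).astype(np.int64)
        starts[in_cds] = t.cds_start + 3 * k + frames
    if in_utr5.any():
        m = int(in_utr5.sum())
        hi = max(t.cds_start, 1)
        starts[in_utr5] = rng.integers(0, hi, size=m)
    if in_utr3.any():
        m = int(in_utr3.sum())
        lo = t.cds_end
        hi = np.maximum(t.length - lens[in_utr3], lo + 1)
        starts[in_utr3] = lo + (rng.random(m) * (hi - lo)).astype(np.int64)
    np.minimum(starts, t.length - lens, out=starts)
    np.maximum(starts, 0, out=starts)
    return starts, lens


def _write_sam(
    path: Path,
    ann: Annotation,
    per_transcript: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]],
    sample_id: str,
) -> None:
    """Emit a headerful transcript-space SAM; '*' sequence, NH uniqueness tag."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for tid in sorted(ann.transcripts):
            fh.write(f"@SQ\tSN:{tid}\tLN:{ann[tid].length}\n")
        fh.write(f"@PG\tID:ribotrans-simulate\tPN:ribotrans\n")
        i = 0
        for tid, starts, lens, multi in per_transcript:
            lines = []
            for s, ln, mm in zip(starts.tolist(), lens.tolist(), multi.tolist()):
                nh = 2 if mm else 1
                mapq = 0 if mm else 255
                lines.append(
                    f"{sample_id}.{i}\t0\t{tid}\t{s + 1}\t{mapq}\t{ln}M\t*\t0\t0\t*\t*\tNH:i:{nh}"
                )
                i += 1
            if lines:
                fh.write("\n".join(lines) + "\n")


def generate_reads(
    ann: Annotation,
    truth: pd.DataFrame,
    config: TruthConfig,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write one SAM per sample; returns the sample sheet.

    Expected reads per transcript are ``library_size x batch_scale x relative
    abundance`` where relative abundance is the baseline abundance times the
    condition's expression multiplier (times the TE multiplier for ribosome
    footprints), realized as overdispersed (gamma-Poisson) counts. rRNA
    transcripts soak up ``rrna_fraction`` of each ribosome-profiling library.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sheet = _sample_sheet(config)
    cond_idx = {c: j for j, c in enumerate(config.conditions)}

    reps = {t.transcript_id: t for t in ann.non_rrna()}
    truth = truth.set_index("transcript_id", drop=False)
    tids = [tid for tid in sorted(reps) if tid in truth.index]
    models = [reps[tid] for tid in tids]
    short = [t.transcript_id for t in models if t.length < config.rna_read_length]
    if short:
        warnings.warn(f"{len(short)} transcripts shorter than the read length excluded")
        models = [t for t in models if t.length >= config.rna_read_length]
        tids = [t.transcript_id for t in models]
    base = truth.loc[tids, "base_abundance"].to_numpy()
    rrna_models = sorted(
        (t for t in ann.transcripts.values() if t.is_rRNA), key=lambda t: t.transcript_id
    )

    lengths_pool = np.array(sorted(config.footprint_lengths), dtype=np.int64)
    w = np.array([config.footprint_lengths[k] for k in lengths_pool], dtype=float)
    length_probs = w / w.sum()

    for si, row in sheet.iterrows():
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202, int(si)]))
        cond, assay, batch = row["condition"], row["assay"], row["batch"]
        j = cond_idx[cond]
        mult = truth.loc[tids, f"expr_{cond}"].to_numpy()
        if assay == "ribo":
            mult = mult * truth.loc[tids, f"te_{cond}"].to_numpy()
        rel = base * mult
        rel = rel / rel.sum()
        depth = config.library_size * config.batch_scale.get(batch, 1.0)
        rrna_frac = config.rrna_fraction if assay == "ribo" else 0.0
        mean = depth * (1.0 - rrna_frac) * rel
        counts = _nb_counts(rng, mean, config.dispersion)

        per_transcript = []
        for t, c in zip(models, counts):
            c = int(c)
            if c == 0:
                continue
            if assay == "rna":
                starts = rng.integers(0, t.length - config.rna_read_length + 1, size=c)
                lens = np.full(c, config.rna_read_length, dtype=np.int64)
            else:
                starts, lens = _ribo_starts(rng, t, c, config, lengths_pool, length_probs)
            multi = rng.random(c) < config.multimap_fraction
            per_transcript.append((t.transcript_id, starts, lens, multi))
        if rrna_frac > 0 and rrna_models:
            n_rrna_reads = _nb_counts(
                rng,
                np.full(len(rrna_models), depth * rrna_frac / len(rrna_models)),
                config.dispersion,
            )
            for t, c in zip(rrna_models, n_rrna_reads):
                c = int(c)
                if c == 0:
                    continue
                ln = int(lengths_pool[0])
                starts = rng.integers(0, t.length - ln + 1, size=c)
                lens = np.full(c, ln, dtype=np.int64)
                multi = rng.random(c) < config.multimap_fraction
                per_transcript.append((t.transcript_id, starts, lens, multi))

        _write_sam(out_dir / row["path"], ann, per_transcript, row["sample_id"])

    sheet.to_csv(out_dir / "samples.tsv", sep="\t", index=False)
    return sheet


# ---------------------------------------------------------------------------
# writers


def write_fasta(ann: Annotation, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for tid in sorted(ann.transcripts):
            seq = ann[tid].sequence
            if seq is None:
                raise ValueError(f"transcript {tid} has no sequence")
            fh.write(f">{tid}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


def write_gtf(ann: Annotation, path: str | Path) -> None:
    """Transcript-space GTF: each transcript is its own reference sequence."""
    with open(path, "w") as fh:
        for tid in sorted(ann.transcripts):
            t = ann[tid]
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            if t.is_rRNA:
                attrs += ' gene_biotype "rRNA";'
            fh.write(
                f"{tid}\tribotrans\texon\t1\t{t.length}\t.\t+\t.\t{attrs}\n"
            )
            if not t.is_rRNA:
                fh.write(
                    f"{tid}\tribotrans\tCDS\t{t.cds_start + 1}\t{t.cds_end}\t.\t+\t.\t{attrs}\n"
                )


def write_gmt(truth: pd.DataFrame, path: str | Path) -> None:
    """Write the synthetic gene sets (archetype-derived) as a GMT file."""
    sets: dict[str, list[str]] = {}
    for _, r in truth.iterrows():
        if r["gene_set"]:
            sets.setdefault(r["gene_set"], []).append(r["gene_id"])
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tsynthetic archetype set\t{members}\n")


def simulate(config: TruthConfig, out_dir: str | Path) -> dict[str, Path]:
    """Full simulation: transcriptome, truth, gene sets, reads, sample sheet."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ann, truth = generate_transcriptome(config)
    paths = {
        "fasta": out_dir / "transcripts.fa",
        "gtf": out_dir / "transcripts.gtf",
        "truth": out_dir / "truth.tsv",
        "gmt": out_dir / "gene_sets.gmt",
        "sample_sheet": out_dir / "samples.tsv",
        "config": out_dir / "config.json",
    }
    write_fasta(ann, paths["fasta"])
    write_gtf(ann, paths["gtf"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    write_gmt(truth, paths["gmt"])
    config.to_json(paths["config"])
    generate_reads(ann, truth, config, out_dir)
    return paths
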