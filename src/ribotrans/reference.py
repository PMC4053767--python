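"""Quantification reference: representative transcripts with UTR/CDS structure.

Reads a transcript annotation (Ensembl-style GTF/GFF or BED12, plus an
optional transcript FASTA), builds one coordinate model per transcript in
*transcript space* (0-based, half-open; strand resolved once at load), and
reduces multi-isoform genes to a single representative per gene: the isoform
with the longest CDS, ties broken by the longest total UTR, remaining ties
lexicographically by transcript id.

rRNA entries are carried so that contaminant alignments have somewhere to
land, but they are flagged and excluded from all per-gene analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "Annotation",
    "load_annotation",
    "select_representative_isoforms",
    "write_reference_tsv",
    "read_reference_tsv",
]


@dataclass
class TranscriptModel:
    """One transcript in transcript coordinates.

    ``cds_start``/``cds_end`` are 0-based half-open offsets on the spliced
    transcript, so the 5'UTR length is ``cds_start`` and the 3'UTR length is
    ``length - cds_end``. rRNA transcripts carry no meaningful CDS; their CDS
    span is stored as (0, 0) and never used.
    """

    transcript_id: str
    gene_id: str
    length: int
    cds_start: int
    cds_end: int
    gene_symbol: str | None = None
    is_rRNA: bool = False
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.transcript_id}: non-positive length {self.length}")
        if not self.is_rRNA:
            if not (0 <= self.cds_start < self.cds_end <= self.length):
                raise ValueError(
                    f"{self.transcript_id}: invalid CDS span "
                    f"[{self.cds_start}, {self.cds_end}) on length {self.length}"
                )
            if self.cds_len < 3:
                raise ValueError(f"{self.transcript_id}: CDS shorter than one codon")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} "
                f"!= annotated length {self.length}"
            )

    @property
    def utr5_len(self) -> int:
        return 0 if self.is_rRNA else self.cds_start

    @property
    def cds_len(self) -> int:
        return 0 if self.is_rRNA else self.cds_end - self.cds_start

    @property
    def utr3_len(self) -> int:
        return 0 if self.is_rRNA else self.length - self.cds_end

    @property
    def total_utr_len(self) -> int:
        return self.utr5_len + self.utr3_len


@dataclass
class Annotation:
    """Transcript models keyed by id, with a gene -> transcripts index."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)

    @property
    def gene_index(self) -> dict[str, list[str]]:
        idx: dict[str, list[str]] = {}
        for tid, t in self.transcripts.items():
            idx.setdefault(t.gene_id, []).append(tid)
        return idx

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self.transcripts:
            raise ValueError(f"duplicate transcript id {t.transcript_id}")
        self.transcripts[t.transcript_id] = t

    def __len__(self) -> int:
        return len(self.transcripts)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def non_rrna(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts.values() if not t.is_rRNA]


# ---------------------------------------------------------------------------
# loading


def _genomic_to_transcript_offsets(exons: list[tuple[int, int]], strand: str):
    """Map genomic position -> transcript offset for sorted exon blocks.

    Exons are (start, end) half-open genomic intervals sorted by start. On the
    minus strand the transcript runs over the reversed exon order with each
    exon read right-to-left. Returns a callable genomic_pos -> offset of that
    base in the spliced transcript.
    """
    blocks = sorted(exons)
    if strand == "-":
        ordered = blocks[::-1]
    else:
        ordered = blocks
    cum = 0
    table = []  # (gstart, gend, transcript offset of first base in 5'->3' order)
    for gstart, gend in ordered:
        table.append((gstart, gend, cum))
        cum += gend - gstart

    def lookup(gpos: int) -> int:
        for gstart, gend, off in table:
            if gstart <= gpos < gend:
                if strand == "-":
                    return off + (gend - 1 - gpos)
                return off + (gpos - gstart)
        raise ValueError(f"genomic position {gpos} not in any exon")

    return lookup, cum


_RRNA_BIOTYPES = {"rRNA", "rRNA_pseudogene", "Mt_rRNA"}


def _load_gtf(path: str | Path) -> Annotation:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        if tid is None:
            continue
        biotype = (
            feat.attributes.get("gene_biotype", [None])[0]
            or feat.attributes.get("transcript_biotype", [None])[0]
            or feat.attributes.get("gene_type", [None])[0]
        )
        symbol = feat.attributes.get("gene_name", [None])[0]
        meta.setdefault(
            tid,
            {"gene_id": gid, "strand": feat.strand, "symbol": symbol, "biotype": biotype},
        )
        # gffutils features are 1-based inclusive; convert to 0-based half-open
        iv = (feat.start - 1, feat.end)
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(iv)
        else:
            cds.setdefault(tid, []).append(iv)

    ann = Annotation()
    for tid, ex in exons.items():
        info = meta[tid]
        strand = info["strand"] or "+"
        lookup, length = _genomic_to_transcript_offsets(ex, strand)
        is_rrna = info["biotype"] in _RRNA_BIOTYPES
        if tid not in cds:
            if is_rrna:
                ann.add(
                    TranscriptModel(
                        transcript_id=tid,
                        gene_id=info["gene_id"],
                        gene_symbol=info["symbol"],
                        length=length,
                        cds_start=0,
                        cds_end=0,
                        is_rRNA=True,
                    )
                )
            else:
                warnings.warn(f"transcript {tid} has no CDS feature; skipped")
            continue
        # transcript offsets of every CDS base extreme; CDS may span exons
        offsets = []
        for gstart, gend in cds[tid]:
            offsets.append(lookup(gstart))
            offsets.append(lookup(gend - 1))
        cds_start = min(offsets)
        cds_end = max(offsets) + 1
        ann.add(
            TranscriptModel(
                transcript_id=tid,
                gene_id=info["gene_id"],
                gene_symbol=info["symbol"],
                length=length,
                cds_start=cds_start,
                cds_end=cds_end,
                is_rRNA=is_rrna,
            )
        )
    return ann


def _load_bed12(path: str | Path) -> Annotation:
    """BED12 with thickStart/thickEnd as the CDS span.

    The name field may be ``gene_id|transcript_id``; a bare name serves as
    both. Coordinates are taken per-record with exon blocks; thickStart ==
    thickEnd means no CDS (record skipped unless flagged rRNA via a name
    ending in ``|rRNA`` marker convention is NOT used -- BED carries no
    biotype, so rRNA flagging is unavailable from BED input).
    """
    ann = Annotation()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 columns")
            chrom_start = int(f[1])
            name = f[3]
            strand = f[5] if f[5] in "+-" else "+"
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [
                (chrom_start + s, chrom_start + s + sz) for s, sz in zip(starts, sizes)
            ]
            if "|" in name:
                gid, tid = name.split("|", 1)
            else:
                gid = tid = name
            if thick_start >= thick_end:
                warnings.warn(f"BED12 record {name} has no CDS; skipped")
                continue
            lookup, length = _genomic_to_transcript_offsets(exons, strand)
            a = lookup(thick_start)
            b = lookup(thick_end - 1)
            cds_start, cds_end = min(a, b), max(a, b) + 1
            ann.add(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gid,
                    length=length,
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
    return ann


def attach_sequences(ann: Annotation, fasta_path: str | Path) -> None:
    """Attach transcript sequences from a transcript-space FASTA in place."""
    with pysam.FastxFile(str(fasta_path)) as fh:
        seqs = {rec.name: rec.sequence.upper() for rec in fh}
    for tid, t in ann.transcripts.items():
        if tid not in seqs:
            continue
        if len(seqs[tid]) != t.length:
            raise ValueError(
                f"transcript {tid}: FASTA length {len(seqs[tid])} "
                f"!= annotated length {t.length}"
            )
        t.sequence = seqs[tid]


def load_annotation(
    annotation_path: str | Path, fasta_path: str | Path | None = None
) -> Annotation:
    """Load a GTF/GFF or BED12 annotation into transcript-coordinate models."""
    path = Path(annotation_path)
    suffix = path.suffix.lower()
    if suffix in (".bed", ".bed12"):
        ann = _load_bed12(path)
    elif suffix in (".gtf", ".gff", ".gff3"):
        ann = _load_gtf(path)
    else:
        raise ValueError(f"unrecognized annotation format: {path}")
    if fasta_path is not None:
        attach_sequences(ann, fasta_path)
    return ann


# ---------------------------------------------------------------------------
# representative-isoform selection


def select_representative_isoforms(ann: Annotation) -> Annotation:
    """One transcript per gene: longest CDS, then longest total UTR, then id.

    rRNA transcripts pass through untouched (they are their own genes for the
    purpose of absorbing contaminant alignments).
    """
    out = Annotation()
    for gene_id, tids in sorted(ann.gene_index.items()):
        models = [ann[t] for t in tids]
        rrna = [m for m in models if m.is_rRNA]
        coding = [m for m in models if not m.is_rRNA]
        for m in rrna:
            out.add(m)
        if not coding:
            if not rrna:
                warnings.warn(f"gene {gene_id} has no valid isoform; dropped")
            continue
        best = min(coding, key=lambda m: (-m.cds_len, -m.total_utr_len, m.transcript_id))
        out.add(best)
    return out


# ---------------------------------------------------------------------------
# TSV round-trip of the representative set

_TSV_COLS = ["transcript_id", "gene_id", "length", "cds_start", "cds_end", "is_rRNA"]


def write_reference_tsv(ann: Annotation, path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(_TSV_COLS) + "\n")
        for tid in sorted(ann.transcripts):
            t = ann[tid]
            fh.write(
                f"{t.transcript_id}\t{t.gene_id}\t{t.length}\t"
                f"{t.cds_start}\t{t.cds_end}\t{int(t.is_rRNA)}\n"
            )


def read_reference_tsv(path: str | Path) -> Annotation:
    ann = Annotation()
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if header[: len(_TSV_COLS)] != _TSV_COLS:
                    raise ValueError(f"{path}: unexpected reference TSV header")
                continue
            f = dict(zip(header, line.split("\t")))
            ann.add(
                TranscriptModel(
                    transcript_id=f["transcript_id"],
                    gene_id=f["gene_id"],
                    length=int(f["length"]),
                    cds_start=int(f["cds_start"]),
                    cds_end=int(f["cds_end"]),
                    is_rRNA=bool(int(f["is_rRNA"])),
                )
            )
    return ann
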