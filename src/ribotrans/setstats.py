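"""Gene-set statistics: hypergeometric enrichment, Wilcoxon shift tests,
the 1.5-fold variable-subset rule, and 5'-TOP motif scoring/enrichment.

The hypergeometric upper tail asks whether a cluster overlaps a gene set
more than chance sampling from the universe would allow. The shift test
compares the fold-change distribution (expression or dTE) of a gene set
against all other genes in the dataset with a two-sided Wilcoxon rank-sum
test, reporting the median shift and its direction. The TOP scanner
operationalizes the classical 5'-terminal oligopyrimidine consensus: a
cytosine at the cap-proximal position followed by an uninterrupted
pyrimidine (C/T) run of at least ``min_run`` bases in total.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .reference import Annotation, TranscriptModel

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "ShiftTestResult",
    "TopCall",
    "read_gmt",
    "hypergeometric_enrichment",
    "shift_test",
    "variable_subset",
    "score_top",
    "top_enrichment",
    "kmer_enrichment",
]

EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_iterable(cls, name: str, members) -> "GeneSet":
        return cls(name, frozenset(members))


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Parse a GMT file (name, description, members...) into GeneSets."""
    from gseapy.parser import read_gmt as _read_gmt

    raw = _read_gmt(str(path))
    return {name: GeneSet.from_iterable(name, members) for name, members in raw.items()}


@dataclass
class EnrichmentResult:
    set_name: str
    cluster_id: str
    overlap: int
    set_size: int
    cluster_size: int
    universe_size: int
    p: float


@dataclass
class ShiftTestResult:
    condition: str
    set_name: str
    statistic: float
    p: float
    median_shift: float
    direction: str  # up | down
    n_set: int
    n_background: int


@dataclass
class TopCall:
    transcript_id: str
    first_base: str
    pyr_run: int
    is_top: bool


def hypergeometric_enrichment(
    cluster_members, gene_set: GeneSet, universe
) -> EnrichmentResult:
    """Upper-tail hypergeometric P(X >= overlap) of a set within a cluster.

    Set and cluster are intersected with the universe before testing.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    cluster = set(cluster_members) & universe
    members = gene_set.members & universe
    overlap = len(cluster & members)
    M, n, N = len(universe), len(members), len(cluster)
    p = float(stats.hypergeom.sf(overlap - 1, M, n, N))
    return EnrichmentResult(
        set_name=gene_set.name,
        cluster_id="",
        overlap=overlap,
        set_size=n,
        cluster_size=N,
        universe_size=M,
        p=min(p, 1.0),
    )


def shift_test(
    values: pd.Series, gene_set: GeneSet, condition: str = ""
) -> ShiftTestResult:
    """Two-sided Wilcoxon rank-sum of set vs all-other-gene fold changes.

    ``values`` maps gene id -> log2 fold change (expression or dTE) for one
    condition. Uses the exact null distribution when the smaller group has
    at most 25 members and the data are tie-free, otherwise the
    tie-corrected normal approximation.
    """
    in_set = values.index.isin(gene_set.members)
    x = values[in_set].to_numpy(dtype=float)
    y = values[~in_set].to_numpy(dtype=float)
    if x.size == 0:
        raise ValueError(f"gene set {gene_set.name!r} does not intersect the dataset")
    if y.size == 0:
        raise ValueError("background is empty: set covers the whole universe")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = (
        "exact"
        if (min(x.size, y.size) <= EXACT_WILCOXON_MAX_N and not has_ties)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    shift = float(np.median(x) - np.median(y))
    return ShiftTestResult(
        condition=condition,
        set_name=gene_set.name,
        statistic=float(res.statistic),
        p=float(res.pvalue),
        median_shift=shift,
        direction="up" if shift >= 0 else "down",
        n_set=int(x.size),
        n_background=int(y.size),
    )


def variable_subset(
    max_abs_log2fc: pd.Series, gene_set: GeneSet, min_fold: float = 1.5
) -> GeneSet:
    """Set members whose maximal |log2FC| across conditions reaches min_fold."""
    thr = np.log2(min_fold)
    in_set = max_abs_log2fc.index.isin(gene_set.members)
    keep = max_abs_log2fc[in_set & (max_abs_log2fc >= thr)].index
    return GeneSet.from_iterable(f"{gene_set.name}|variable>={min_fold}x", keep)


def score_top(transcript: TranscriptModel, min_run: int = 5) -> TopCall:
    """Call a 5'-TOP element: cap-proximal C plus a >= min_run pyrimidine run."""
    seq = transcript.sequence
    if not seq:
        raise ValueError(f"transcript {transcript.transcript_id} has no sequence")
    seq = seq.upper()
    run = 0
    for base in seq:
        if base in "CT":
            run += 1
        else:
            break
    return TopCall(
        transcript_id=transcript.transcript_id,
        first_base=seq[0],
        pyr_run=run,
        is_top=(seq[0] == "C" and run >= min_run),
    )


def top_enrichment(
    gene_set: GeneSet, ann: Annotation, min_run: int = 5, by_gene: bool = True
) -> EnrichmentResult:
    """Hypergeometric enrichment of TOP-positive transcripts inside a set.

    The universe is every non-rRNA transcript with a sequence; membership is
    matched on gene ids when ``by_gene`` (GMT files list genes), else on
    transcript ids.
    """
    calls = {}
    keys = {}
    for t in ann.non_rrna():
        if t.sequence is None:
            continue
        calls[t.transcript_id] = score_top(t, min_run=min_run)
        keys[t.transcript_id] = t.gene_id if by_gene else t.transcript_id
    if not calls:
        raise ValueError("no sequences available for TOP scanning")
    universe = set(calls)
    in_set = {tid for tid in universe if keys[tid] in gene_set.members}
    if in_set == universe:
        raise ValueError("set covers the whole universe; enrichment undefined")
    top_ids = {tid for tid in universe if calls[tid].is_top}
    if top_ids:
        res = hypergeometric_enrichment(in_set, GeneSet.from_iterable("TOP", top_ids), universe)
    else:
        res = EnrichmentResult(
            set_name="TOP",
            cluster_id="",
            overlap=0,
            set_size=0,
            cluster_size=len(in_set),
            universe_size=len(universe),
            p=1.0,
        )
    res.set_name = f"5'-TOP in {gene_set.name}"
    return res


def kmer_enrichment(
    set_sequences: dict[str, str],
    universe_sequences: dict[str, str],
    k: int = 6,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-k-mer over-representation in 5'UTR sequences, Bonferroni-corrected.

    A deliberately simple surrogate for de novo motif discovery: for each
    k-mer, a hypergeometric upper tail on presence/absence in the set versus
    the universe. Returns k-mers with corrected p below ``alpha``, most
    significant first.
    """
    if not set_sequences or not universe_sequences:
        raise ValueError("empty sequence collection")

    def kmers(seq: str) -> set[str]:
        seq = seq.upper()
        return {seq[i : i + k] for i in range(len(seq) - k + 1)}

    uni_presence: dict[str, set[str]] = {}
    for sid, seq in universe_sequences.items():
        for km in kmers(seq):
            uni_presence.setdefault(km, set()).add(sid)
    set_ids = set(set_sequences)
    M = len(universe_sequences)
    N = len(set_ids)
    n_tests = len(uni_presence)
    rows = []
    for km, carriers in uni_presence.items():
        overlap = len(carriers & set_ids)
        if overlap == 0:
            continue
        p = float(stats.hypergeom.sf(overlap - 1, M, len(carriers), N))
        p_adj = min(p * n_tests, 1.0)
        if p_adj < alpha:
            rows.append(
                {
                    "kmer": km,
                    "set_with": overlap,
                    "universe_with": len(carriers),
                    "p": p,
                    "p_bonferroni": p_adj,
                }
            )
    df = pd.DataFrame(rows, columns=["kmer", "set_with", "universe_with", "p", "p_bonferroni"])
    return df.sort_values(["p", "kmer"]).reset_index(drop=True)
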