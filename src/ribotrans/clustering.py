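"""Response-pattern clustering of responsive transcripts.

Each responsive transcript contributes a joint profile: condition-level log2
floored RNA FPKM values followed by the Ribo values in the same condition
order (5 + 5 points in the emulated design). Rows are standardized to mean 0,
SD 1 so that transcripts cluster by response *shape* rather than magnitude,
then partitioned by k-means (k-means++ initialization, multiple restarts,
Euclidean distance). Cluster labels are canonicalized by descending size and
first-member id so outputs are comparable across runs; each cluster is
summarized by its mean pattern with a per-point SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .quantify import QuantTable, condition_log2

__all__ = [
    "ResponseMatrix",
    "ClusterResult",
    "build_response_matrix",
    "cluster_profiles",
    "summarize_clusters",
]


@dataclass
class ResponseMatrix:
    """Standardized per-transcript response profiles.

    ``values`` rows have mean 0 and (sample, ddof=1) SD 1; ``columns`` records
    provenance as ``<assay>:<condition>`` in fixed order.
    """

    values: pd.DataFrame
    columns: list[str]

    def __post_init__(self) -> None:
        if list(self.values.columns) != self.columns:
            raise ValueError("column provenance does not match the matrix")


def standardize_rows(values: np.ndarray, ddof: int = 1) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    return (values - mu) / sd


def build_response_matrix(
    quant: QuantTable,
    responsive: list[str],
    condition_order: list[str] | None = None,
) -> ResponseMatrix:
    """Standardized RNA-then-Ribo condition profiles for the responsive set.

    Condition-level values are replicate means of log2 floored FPKM pooled
    over batches (the control condition averages its per-batch controls).
    Constant rows, for which standardization is undefined, are dropped with a
    warning.
    """
    rna = condition_log2(quant, "rna")
    ribo = condition_log2(quant, "ribo")
    if condition_order is None:
        condition_order = [c for c in rna.columns]
    cols = [f"rna:{c}" for c in condition_order] + [f"ribo:{c}" for c in condition_order]
    raw = np.hstack(
        [rna[condition_order].to_numpy(), ribo[condition_order].to_numpy()]
    )
    idx = pd.Index(sorted(responsive), name="transcript_id")
    pos = [rna.index.get_loc(t) for t in idx]
    raw = raw[pos]
    sd = raw.std(axis=1, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant profiles removed before clustering")
        idx = idx[~const]
        raw = raw[~const]
    z = standardize_rows(raw)
    return ResponseMatrix(pd.DataFrame(z, index=idx, columns=cols), cols)


@dataclass
class ClusterResult:
    assignment: pd.Series  # transcript_id -> cluster id (0..k-1, canonical order)
    centroids: pd.DataFrame  # cluster x column means
    dispersion: pd.DataFrame  # cluster x column SDs
    sizes: pd.Series
    inertia: float


def cluster_profiles(
    matrix: ResponseMatrix, k: int, seed: int = 0, restarts: int = 20
) -> ClusterResult:
    """k-means partition of the standardized profiles, best of ``restarts``."""
    if k < 2:
        raise ValueError("k must be >= 2")
    X = matrix.values.to_numpy()
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} clusterable rows")
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, random_state=seed)
    labels = km.fit_predict(X)
    # canonical label order: descending size, tie-break by first member id
    order = sorted(
        range(k),
        key=lambda c: (
            -int((labels == c).sum()),
            matrix.values.index[labels == c][0] if (labels == c).any() else "",
        ),
    )
    remap = {old: new for new, old in enumerate(order)}
    canon = np.array([remap[c] for c in labels])
    assignment = pd.Series(canon, index=matrix.values.index, name="cluster")
    centroids, dispersion, sizes = summarize_clusters(matrix, assignment)
    return ClusterResult(assignment, centroids, dispersion, sizes, float(km.inertia_))


def summarize_clusters(
    matrix: ResponseMatrix, assignment: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Per-cluster mean pattern and per-point SD (population SD; singleton -> 0)."""
    cents, disps, sizes = {}, {}, {}
    for c in sorted(assignment.unique()):
        member_rows = matrix.values.loc[assignment[assignment == c].index]
        if len(member_rows) == 0:
            raise ValueError(f"cluster {c} is empty")
        if len(member_rows) == 1:
            warnings.warn(f"cluster {c} is a singleton; SD reported as 0")
        cents[c] = member_rows.mean(axis=0)
        disps[c] = member_rows.std(axis=0, ddof=0)
        sizes[c] = len(member_rows)
    centroids = pd.DataFrame(cents).T
    dispersion = pd.DataFrame(disps).T
    return centroids, dispersion, pd.Series(sizes, name="size")


def write_cluster_tsvs(
    result: ClusterResult, out_prefix: str | Path, header_comment: str | None = None
) -> None:
    """Assignment TSV plus a centroid/SD TSV laid out for pattern plotting."""
    prefix = str(out_prefix)
    hdr = f"# {header_comment}\n" if header_comment else ""
    with open(prefix + ".assignment.tsv", "w") as fh:
        fh.write(hdr)
        result.assignment.rename_axis("transcript_id").to_frame().to_csv(fh, sep="\t")
    summary = result.centroids.copy()
    summary.columns = [f"mean:{c}" for c in summary.columns]
    for c in result.dispersion.columns:
        summary[f"sd:{c}"] = result.dispersion[c]
    summary.insert(0, "size", result.sizes)
    with open(prefix + ".clusters.tsv", "w") as fh:
        fh.write(hdr)
        summary.rename_axis("cluster").to_csv(fh, sep="\t")
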