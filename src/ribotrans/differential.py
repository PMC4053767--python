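"""Batch-paired fold changes and dynamic-threshold selection of responders.

Every test condition is compared to the control profiled in the same batch
(sequencer run), cancelling run effects. Expression fold change is the
difference of condition-level log2 floored RNA FPKM; the Ribo analogue and
the TE difference follow the same pairing, so dTE = ribo_log2fc -
expr_log2fc identically.

Because variability is larger for lowly expressed transcripts, responders
are selected by an abundance-dependent cut-off on |log2FC|:

    threshold(a) = t_inf + slope / sqrt(a)

with ``a`` the geometric mean of condition and control floored RNA FPKM.
The threshold decays to ``t_inf`` (default log2 1.5 = 0.585) for abundant
transcripts and inflates for sparse ones. An optional calibration picks the
slope so that a target fraction of the dataset passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .quantify import QuantTable, condition_log2

__all__ = [
    "CutoffParams",
    "batch_paired_fold_changes",
    "dynamic_threshold",
    "select_responsive",
    "calibrate_slope",
]

LOG2_1P5 = float(np.log2(1.5))


@dataclass
class CutoffParams:
    """Dynamic cut-off: asymptote ``t_inf``, low-abundance inflation ``slope``."""

    t_inf: float = LOG2_1P5
    slope: float = 4.0
    applied_to: str = "both"  # expression | te | both

    def __post_init__(self) -> None:
        if self.t_inf <= 0:
            raise ValueError("t_inf must be positive")
        if self.slope < 0:
            raise ValueError("slope must be >= 0")
        if self.applied_to not in ("expression", "te", "both"):
            raise ValueError(f"applied_to: bad value {self.applied_to!r}")


def batch_paired_fold_changes(quant: QuantTable) -> pd.DataFrame:
    """Long-format TE profile: one row per transcript x test condition.

    Columns: transcript_id, condition, batch, expr_log2fc, ribo_log2fc, te,
    te_control, delta_te, mean_abundance (geometric mean of condition and
    control floored RNA FPKM). Control conditions are represented implicitly
    (all-zero fold changes) and omitted from the rows.
    """
    meta = quant.samples
    batches = sorted(meta["batch"].unique())
    control = "control"
    rows = []
    for batch in batches:
        sub = meta[meta["batch"] == batch]
        conds = set(sub["condition"])
        if control not in conds:
            raise ValueError(f"batch {batch!r} lacks a control sample")
        rna = condition_log2(quant, "rna", batch=batch)
        ribo = condition_log2(quant, "ribo", batch=batch)
        for cond in sorted(conds - {control}):
            if cond not in rna.columns or cond not in ribo.columns:
                raise ValueError(f"batch {batch!r}: condition {cond!r} missing an assay")
            expr_fc = rna[cond] - rna[control]
            ribo_fc = ribo[cond] - ribo[control]
            te_cond = ribo[cond] - rna[cond]
            te_ctrl = ribo[control] - rna[control]
            abundance = np.power(2.0, (rna[cond] + rna[control]) / 2.0)
            rows.append(
                pd.DataFrame(
                    {
                        "transcript_id": rna.index,
                        "condition": cond,
                        "batch": batch,
                        "expr_log2fc": expr_fc.to_numpy(),
                        "ribo_log2fc": ribo_fc.to_numpy(),
                        "te": te_cond.to_numpy(),
                        "te_control": te_ctrl.to_numpy(),
                        "delta_te": (te_cond - te_ctrl).to_numpy(),
                        "mean_abundance": abundance.to_numpy(),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def dynamic_threshold(mean_abundance, params: CutoffParams | None = None):
    """|log2FC| needed at a given abundance: t_inf + slope / sqrt(abundance)."""
    params = params or CutoffParams()
    a = np.asarray(mean_abundance, dtype=float)
    if np.any(a < 1):
        raise ValueError("mean_abundance below the FPKM floor of 1.0")
    return params.t_inf + params.slope / np.sqrt(a)


def _passes(profile: pd.DataFrame, params: CutoffParams) -> np.ndarray:
    thr = dynamic_threshold(profile["mean_abundance"].to_numpy(), params)
    expr_hit = np.abs(profile["expr_log2fc"].to_numpy()) >= thr
    te_hit = np.abs(profile["delta_te"].to_numpy()) >= thr
    if params.applied_to == "expression":
        return expr_hit
    if params.applied_to == "te":
        return te_hit
    return expr_hit | te_hit


def select_responsive(
    profile: pd.DataFrame, params: CutoffParams | None = None
) -> list[str]:
    """Transcripts passing the dynamic cut-off in at least one condition."""
    params = params or CutoffParams()
    hit = _passes(profile, params)
    return sorted(profile.loc[hit, "transcript_id"].unique())


def calibrate_slope(
    profile: pd.DataFrame,
    target_fraction: float,
    params: CutoffParams | None = None,
    slope_bounds: tuple[float, float] = (0.0, 200.0),
    tol: float = 1e-3,
) -> CutoffParams:
    """Pick the slope so ~``target_fraction`` of transcripts are selected.

    Bisection on the (monotone non-increasing in slope) selected fraction;
    ``t_inf`` is kept fixed. Useful to mimic a study-scale selection rate on
    a dataset whose noise structure differs from the defaults.
    """
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must be in (0, 1)")
    base = params or CutoffParams()
    universe = profile["transcript_id"].nunique()

    def frac(slope: float) -> float:
        p = CutoffParams(base.t_inf, slope, base.applied_to)
        return len(select_responsive(profile, p)) / universe

    lo, hi = slope_bounds
    if frac(lo) < target_fraction:
        return CutoffParams(base.t_inf, lo, base.applied_to)
    if frac(hi) > target_fraction:
        return CutoffParams(base.t_inf, hi, base.applied_to)
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if frac(mid) >= target_fraction:
            lo = mid
        else:
            hi = mid
    return CutoffParams(base.t_inf, (lo + hi) / 2, base.applied_to)


def write_profile_tsv(
    profile: pd.DataFrame, path: str | Path, header_comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        profile.to_csv(fh, sep="\t", index=False)
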