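"""End-to-end orchestration: simulate -> quantify -> qc -> diff -> cluster ->
enrich/shift/top, driven by a single JSON config, with a run manifest.

Every stage writes its artifacts under the output directory with a header
comment naming the producing stage and a hash of its parameters, and can be
re-run in isolation through the CLI; a missing upstream artifact raises a
``StageError`` naming the stage and the file it needs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import build_response_matrix, cluster_profiles, write_cluster_tsvs
from .differential import (
    CutoffParams,
    batch_paired_fold_changes,
    select_responsive,
    write_profile_tsv,
)
from .quantify import coverage_filter, qc_report, quantify_samples
from .reference import (
    load_annotation,
    read_reference_tsv,
    select_representative_isoforms,
    write_reference_tsv,
)
from .setstats import (
    hypergeometric_enrichment,
    read_gmt,
    shift_test,
    top_enrichment,
    variable_subset,
)
from .simulate import TruthConfig, simulate

logger = logging.getLogger("ribotrans")


class StageError(RuntimeError):
    """A pipeline stage failed or is missing an upstream artifact."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    """Paths plus per-stage parameters; defaults follow the analysis protocol
    (40-read coverage filter, FPKM floor 1.0, 1.5-fold asymptote and variable
    threshold, 5-pyrimidine minimal TOP run)."""

    out_dir: str = "ribotrans_out"
    annotation: str | None = None
    fasta: str | None = None
    sample_sheet: str | None = None
    gmt: str | None = None
    simulate: dict | None = None  # TruthConfig overrides; None = use given inputs
    min_reads: int = 40
    fpkm_floor: float = 1.0
    min_mapq: int = 10
    t_inf: float = float(np.log2(1.5))
    slope: float = 4.0
    applied_to: str = "both"
    k: int = 13
    cluster_seed: int = 7
    restarts: int = 20
    min_fold: float = 1.5
    min_run: int = 5
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def params_hash(params: dict) -> str:
    js = json.dumps(params, sort_keys=True, default=str)
    return hashlib.md5(js.encode()).hexdigest()[:10]


def _stage_header(stage: str, params: dict) -> str:
    return f"stage={stage} ribotrans={__version__} params_hash={params_hash(params)}"


def _require(stage: str, path: Path) -> Path:
    if not path.exists():
        raise StageError(stage, f"missing required input {path}")
    return path


def _checksum(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in dependency order; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)

    manifest: dict = {
        "ribotrans_version": __version__,
        "config": dataclasses.asdict(config),
        "stages": {},
        "inputs": {},
    }

    def timed(stage, fn):
        t0 = time.time()
        logger.info("stage %s: start", stage)
        try:
            result = fn()
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StageError(stage, str(exc)) from exc
        dt = time.time() - t0
        manifest["stages"][stage] = {"seconds": round(dt, 3)}
        logger.info("stage %s: done in %.1fs", stage, dt)
        return result

    # -- simulate (optional) -------------------------------------------------
    if config.simulate is not None:
        def _simulate():
            overrides = dict(config.simulate)
            overrides.setdefault("seed", config.seed)
            tc_path = out / "sim" / "truth_config.json"
            tc = TruthConfig(**overrides) if overrides else TruthConfig(seed=config.seed)
            paths = simulate(tc, out / "sim")
            tc.to_json(tc_path)
            config.annotation = str(paths["gtf"])
            config.fasta = str(paths["fasta"])
            config.sample_sheet = str(paths["sample_sheet"])
            config.gmt = str(paths["gmt"])

        timed("simulate", _simulate)

    for name in ("annotation", "fasta", "sample_sheet"):
        val = getattr(config, name)
        if val is None:
            raise StageError("inputs", f"no {name} given and simulate disabled")
        manifest["inputs"][name] = {"path": val, "md5": _checksum(_require("inputs", Path(val)))}
    if config.gmt:
        manifest["inputs"]["gmt"] = {"path": config.gmt, "md5": _checksum(Path(config.gmt))}

    # -- reference ------------------------------------------------------------
    ref_params = {"annotation": config.annotation, "fasta": config.fasta}

    def _reference():
        ann = load_annotation(config.annotation, config.fasta)
        rep = select_representative_isoforms(ann)
        write_reference_tsv(rep, out / "reference.tsv", _stage_header("reference", ref_params))
        return rep

    ann = timed("reference", _reference)

    # -- quantify + qc ---------------------------------------------------------
    q_params = {"min_mapq": config.min_mapq, "fpkm_floor": config.fpkm_floor}

    def _quantify():
        sheet = pd.read_csv(_require("quantify", Path(config.sample_sheet)), sep="\t", comment="#")
        quant, tallies = quantify_samples(
            sheet, ann, Path(config.sample_sheet).parent, min_mapq=config.min_mapq
        )
        quant.floor = config.fpkm_floor
        quant.to_tsv(out / "quant.tsv", _stage_header("quantify", q_params))
        return quant, tallies

    quant, tallies = timed("quantify", _quantify)

    def _qc():
        report = qc_report(quant, tallies, ann)
        with open(out / "qc.json", "w") as fhh:
            json.dump({"_stage": _stage_header("qc", q_params), **report}, fhh, indent=2)
        return report

    timed("qc", _qc)

    # -- differential ----------------------------------------------------------
    d_params = {
        "min_reads": config.min_reads,
        "t_inf": config.t_inf,
        "slope": config.slope,
        "applied_to": config.applied_to,
    }

    def _diff():
        covered = coverage_filter(quant, min_reads=config.min_reads)
        profile = batch_paired_fold_changes(quant)
        profile = profile[profile["transcript_id"].isin(covered)].reset_index(drop=True)
        cutoff = CutoffParams(config.t_inf, config.slope, config.applied_to)
        responsive = select_responsive(profile, cutoff)
        write_profile_tsv(profile, out / "te_profile.tsv", _stage_header("diff", d_params))
        with open(out / "responsive.txt", "w") as fhh:
            fhh.write(f"# {_stage_header('diff', d_params)}\n")
            fhh.writelines(f"{t}\n" for t in responsive)
        return covered, profile, responsive

    covered, profile, responsive = timed("diff", _diff)

    # -- clustering ------------------------------------------------------------
    c_params = {"k": config.k, "seed": config.cluster_seed, "restarts": config.restarts}

    def _cluster():
        if len(responsive) < max(config.k, 2):
            logger.warning("too few responsive transcripts (%d) to cluster", len(responsive))
            return None
        matrix = build_response_matrix(quant, responsive)
        result = cluster_profiles(matrix, config.k, config.cluster_seed, config.restarts)
        write_cluster_tsvs(result, out / "responsive", _stage_header("cluster", c_params))
        return result

    clusters = timed("cluster", _cluster)

    # -- gene-set statistics ----------------------------------------------------
    s_params = {"min_fold": config.min_fold, "min_run": config.min_run}

    def _setstats():
        if not config.gmt:
            logger.warning("no GMT supplied; gene-set stages skipped")
            return
        sets = read_gmt(config.gmt)
        t2g = {tid: ann[tid].gene_id for tid in quant.counts.index}
        cov_genes = {t2g[t] for t in covered}

        rows = []
        if clusters is not None:
            for cid in sorted(clusters.sizes.index):
                members = {
                    t2g[t] for t in clusters.assignment[clusters.assignment == cid].index
                }
                for gs in sets.values():
                    res = hypergeometric_enrichment(members, gs, cov_genes)
                    res.cluster_id = str(cid)
                    rows.append(dataclasses.asdict(res))
        pd.DataFrame(rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)

        shift_rows = []
        prof2 = profile.assign(gene=profile["transcript_id"].map(t2g))
        max_abs = prof2.groupby("gene")["expr_log2fc"].apply(lambda s: float(np.abs(s).max()))
        for measure in ("expr_log2fc", "delta_te"):
            for cond, grp in prof2.groupby("condition"):
                values = pd.Series(grp[measure].to_numpy(), index=grp["gene"].to_numpy())
                for gs in sets.values():
                    if not gs.members & set(values.index):
                        continue
                    res = shift_test(values, gs, condition=cond)
                    row = dataclasses.asdict(res)
                    row["measure"] = measure
                    row["subset"] = "full"
                    shift_rows.append(row)
                    if measure == "expr_log2fc":
                        try:
                            sub = variable_subset(max_abs, gs, config.min_fold)
                            res2 = shift_test(values, sub, condition=cond)
                            row2 = dataclasses.asdict(res2)
                            row2["measure"] = measure
                            row2["subset"] = f"variable>={config.min_fold}x"
                            shift_rows.append(row2)
                        except ValueError:
                            pass
        pd.DataFrame(shift_rows).to_csv(out / "shift_tests.tsv", sep="\t", index=False)

        top_rows = []
        has_seq = any(t.sequence for t in ann.non_rrna())
        if has_seq:
            for gs in sets.values():
                try:
                    res = top_enrichment(gs, ann, min_run=config.min_run)
                except ValueError:
                    continue
                top_rows.append(dataclasses.asdict(res))
        pd.DataFrame(top_rows).to_csv(out / "top_enrichment.tsv", sep="\t", index=False)

    timed("setstats", _setstats)

    manifest["seed"] = config.seed
    with open(out / "manifest.json", "w") as fhh:
        json.dump(manifest, fhh, indent=2)
    return manifest
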