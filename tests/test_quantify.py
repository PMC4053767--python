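"""Counting, FPKM, TE and ribosome-profiling QC."""

import numpy as np
import pandas as pd
import pytest

from ribotrans.quantify import (
    AlignedRead,
    QuantTable,
    count_reads,
    coverage_filter,
    floor_fpkm,
    fpkm,
    frame_distribution,
    region_density,
    replicate_correlation,
    translation_efficiency,
)

from conftest import write_sam


class TestCountReads:
    def test_cds_boundary_membership(self, toy_annotation):
        # TX1: CDS [100, 700). A 5' end at 100 is in; at 700 it is out.
        reads = [AlignedRead("TX1", 100, 30), AlignedRead("TX1", 700, 30)]
        counts, total = count_reads(reads, toy_annotation, "ribo")
        assert counts == {"TX1": 1}
        assert total == 2  # denominator counts all transcript-mapped reads

    def test_hand_enumerated_regions(self, toy_annotation):
        # 3 reads in the 5'UTR, 7 in the CDS, 2 in the 3'UTR of TX1
        reads = (
            [AlignedRead("TX1", s, 31) for s in (0, 50, 99)]
            + [AlignedRead("TX1", s, 31) for s in (100, 200, 300, 400, 500, 600, 699)]
            + [AlignedRead("TX1", s, 31) for s in (700, 900)]
        )
        ribo, _ = count_reads(reads, toy_annotation, "ribo")
        rna, _ = count_reads(reads, toy_annotation, "rna")
        assert ribo == {"TX1": 7}
        assert rna == {"TX1": 12}

    def test_nonunique_discarded_and_rrna_excluded_from_total(self, toy_annotation):
        reads = [
            AlignedRead("TX1", 150, 31, is_unique=True),
            AlignedRead("TX1", 150, 31, is_unique=False),
            AlignedRead("RRN1", 10, 31, is_unique=True),
        ]
        counts, total = count_reads(reads, toy_annotation, "rna")
        assert counts == {"TX1": 1}
        assert total == 1

    def test_missing_reference_policies(self, toy_annotation):
        reads = [AlignedRead("NOPE", 0, 31)]
        with pytest.raises(KeyError, match="NOPE"):
            count_reads(reads, toy_annotation, "rna")
        with pytest.warns(UserWarning, match="absent"):
            counts, total = count_reads(
                reads, toy_annotation, "rna", on_missing_reference="skip"
            )
        assert counts == {} and total == 0

    def test_sam_and_read_list_agree(self, tmp_path, toy_annotation):
        rng = np.random.default_rng(0)
        reads = []
        for _ in range(500):
            tid = rng.choice(["TX1", "TX2"])
            t = toy_annotation[tid]
            start = int(rng.integers(0, t.length - 31))
            reads.append((tid, start, 31, int(rng.choice([1, 2], p=[0.9, 0.1]))))
        sam = write_sam(tmp_path / "x.sam", toy_annotation, reads)
        as_objects = [AlignedRead(t, s, l, nh == 1) for t, s, l, nh in reads]
        for assay in ("rna", "ribo"):
            c1, t1 = count_reads(sam, toy_annotation, assay)
            c2, t2 = count_reads(as_objects, toy_annotation, assay)
            assert c1 == c2 and t1 == t2


class TestFpkm:
    def test_hand_arithmetic_and_conservation(self):
        counts = np.array([900, 100])
        lengths = np.array([2000, 500])
        vals = fpkm(counts, lengths, 1000)
        assert np.allclose(vals, [450_000, 200_000])
        assert np.isclose((vals * lengths / 1e3).sum(), 1e6)

    def test_zero_count_and_scale_invariance(self):
        assert fpkm(0, 1500, 10_000) == 0.0
        a = fpkm(np.array([10, 20]), np.array([100, 200]), 1000)
        b = fpkm(np.array([20, 40]), np.array([100, 200]), 2000)
        assert np.allclose(a, b)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="mapped_total"):
            fpkm(5, 100, 0)

    @pytest.mark.parametrize("x,expected", [(0.5, 1.0), (1.0, 1.0), (7.3, 7.3), (0.0, 1.0)])
    def test_floor(self, x, expected):
        assert floor_fpkm(x) == expected

    @pytest.mark.parametrize(
        "ribo,rna,te", [(8.0, 2.0, 2.0), (5.0, 5.0, 0.0), (1.0, 4.0, -2.0)]
    )
    def test_translation_efficiency(self, ribo, rna, te):
        # the (1.0, 4.0) case is raw ribo FPKM 0.5 after flooring
        assert translation_efficiency(ribo, rna) == pytest.approx(te)


class TestQC:
    def test_frame_distribution_hand_counts(self, toy_annotation):
        reads = [AlignedRead("TX1", 100 + o, 31) for o in (0, 3, 6)]
        assert np.allclose(frame_distribution(reads, toy_annotation), [1, 0, 0])
        reads = [AlignedRead("TX1", 100 + o, 31) for o in (0, 0, 1, 2)]
        assert np.allclose(frame_distribution(reads, toy_annotation), [0.5, 0.25, 0.25])

    def test_frame_undefined_without_cds_reads(self, toy_annotation):
        assert frame_distribution([AlignedRead("TX1", 0, 31)], toy_annotation) is None

    def test_region_density_hand_arithmetic(self):
        from ribotrans.reference import Annotation, TranscriptModel

        ann = Annotation()
        ann.add(TranscriptModel("T", "G", length=1800, cds_start=100, cds_end=800))
        # 7 CDS reads over 700 nt and 1 3'UTR read over 1000 nt -> depletion 0.1
        reads = [AlignedRead("T", 100 + 10 * i, 31) for i in range(7)]
        reads.append(AlignedRead("T", 900, 31))
        density, depletion = region_density(reads, ann)
        assert density["cds"] == pytest.approx(10.0)
        assert density["utr3"] == pytest.approx(1.0)
        assert depletion == pytest.approx(0.1)

    def test_all_cds_gives_zero_depletion(self, toy_annotation):
        reads = [AlignedRead("TX1", 150, 31)]
        _, depletion = region_density(reads, toy_annotation)
        assert depletion == 0.0

    def test_replicate_correlation_contract(self):
        a = np.log2(np.array([1.0, 4.0, 16.0, 64.0]))
        assert replicate_correlation(a, a) == pytest.approx(1.0)
        assert replicate_correlation(a, 2 * a + 3) == pytest.approx(1.0)
        with pytest.warns(UserWarning, match="constant"):
            assert replicate_correlation(a, np.ones(4)) is None


def _quant_fixture(design):
    """Build a QuantTable from {tid: {(assay, cond): count}} with unit lengths."""
    from ribotrans.reference import Annotation, TranscriptModel

    ann = Annotation()
    tids = sorted(design)
    for tid in tids:
        ann.add(TranscriptModel(tid, "g" + tid, length=1200, cds_start=100, cds_end=1000))
    samples = sorted({k for d in design.values() for k in d})
    counts = pd.DataFrame(
        {
            f"{assay}_{cond}": [design[t].get((assay, cond), 0) for t in tids]
            for assay, cond in samples
        },
        index=pd.Index(tids, name="transcript_id"),
    )
    meta = pd.DataFrame(
        [
            {
                "sample_id": f"{assay}_{cond}",
                "assay": assay,
                "condition": cond,
                "batch": "b1",
                "replicate": 1,
                "mapped_total": max(int(counts[f"{assay}_{cond}"].sum()), 1),
            }
            for assay, cond in samples
        ]
    )
    return QuantTable(counts, meta, ann)


class TestCoverageFilter:
    def test_boundary_and_and_semantics(self):
        design = {
            "A": {("rna", "c1"): 40, ("ribo", "c1"): 40},  # boundary: retained
            "B": {("rna", "c1"): 39, ("ribo", "c1"): 10**6},  # AND fails
            "C": {("rna", "c1"): 39, ("ribo", "c1"): 39, ("rna", "c2"): 45, ("ribo", "c2"): 41},
            "D": {("rna", "c1"): 0, ("ribo", "c1"): 0},
        }
        quant = _quant_fixture(design)
        assert coverage_filter(quant) == ["A", "C"]

    def test_designed_pass_set_of_25(self):
        rng = np.random.default_rng(42)
        design = {}
        expected = []
        for i in range(25):
            tid = f"T{i:02d}"
            if i < 17:
                design[tid] = {("rna", "c1"): int(rng.integers(40, 500)),
                               ("ribo", "c1"): int(rng.integers(40, 500))}
                expected.append(tid)
            else:
                design[tid] = {("rna", "c1"): int(rng.integers(0, 40)),
                               ("ribo", "c1"): int(rng.integers(0, 40))}
        quant = _quant_fixture(design)
        assert coverage_filter(quant) == expected

    def test_replicates_pooled_by_summing(self, small_quant, small_config):
        quant, _ = small_quant
        meta = quant.samples
        kept = coverage_filter(quant, min_reads=40)
        # manual recomputation on one transcript
        tid = quant.counts.index[0]
        ok = False
        for cond in small_config.conditions:
            rna = quant.counts.loc[tid, meta[(meta.assay == "rna") & (meta.condition == cond)]["sample_id"]].sum()
            ribo = quant.counts.loc[tid, meta[(meta.assay == "ribo") & (meta.condition == cond)]["sample_id"]].sum()
            ok = ok or (rna >= 40 and ribo >= 40)
        assert (tid in kept) == ok


def test_prefloor_conservation_on_synthetic_rna(small_quant):
    """With every counted read assigned, sum fpkm x len_kb recovers 1e6."""
    quant, _ = small_quant
    rna_cols = quant.samples[quant.samples["assay"] == "rna"]["sample_id"]
    lengths = quant.feature_lengths("rna").to_numpy()
    fp = quant.fpkm
    for sid in rna_cols:
        total = (fp[sid].to_numpy() * lengths / 1e3).sum()
        assert total == pytest.approx(1e6, rel=1e-9)
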