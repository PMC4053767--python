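"""Hypergeometric enrichment, Wilcoxon shift tests, variable subset, 5'-TOP."""

import math

import numpy as np
import pandas as pd
import pytest

from ribotrans.reference import Annotation, TranscriptModel
from ribotrans.setstats import (
    GeneSet,
    hypergeometric_enrichment,
    kmer_enrichment,
    read_gmt,
    score_top,
    shift_test,
    top_enrichment,
    variable_subset,
)


def hypergeom_tail_enumeration(overlap, M, n, N):
    """Independent oracle: P(X >= overlap) by direct combinatorial summation."""
    total = math.comb(M, N)
    acc = 0
    for k in range(overlap, min(n, N) + 1):
        acc += math.comb(n, k) * math.comb(M - n, N - k)
    return acc / total


class TestHypergeometric:
    def test_complete_overlap_worked_case(self):
        res = hypergeometric_enrichment(
            [f"g{i}" for i in range(5)],
            GeneSet.from_iterable("s", [f"g{i}" for i in range(5)]),
            [f"g{i}" for i in range(20)],
        )
        assert res.overlap == 5
        assert res.p == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_zero_overlap_p_one(self):
        res = hypergeometric_enrichment(
            ["g0", "g1"], GeneSet.from_iterable("s", ["g5", "g6"]), [f"g{i}" for i in range(10)]
        )
        assert res.p == 1.0

    def test_matches_enumeration_on_random_universes(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            M = int(rng.integers(5, 51))
            universe = [f"g{i}" for i in range(M)]
            n = int(rng.integers(1, M + 1))
            N = int(rng.integers(1, M + 1))
            gene_set = GeneSet.from_iterable("s", rng.choice(universe, n, replace=False))
            cluster = list(rng.choice(universe, N, replace=False))
            res = hypergeometric_enrichment(cluster, gene_set, universe)
            expected = hypergeom_tail_enumeration(res.overlap, M, n, N)
            assert res.p == pytest.approx(expected, rel=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeometric_enrichment([], GeneSet.from_iterable("s", ["a"]), [])

    def test_items_outside_universe_ignored(self):
        res = hypergeometric_enrichment(
            ["g0", "zz"], GeneSet.from_iterable("s", ["g0", "yy"]), ["g0", "g1"]
        )
        assert (res.cluster_size, res.set_size, res.universe_size) == (1, 1, 2)


class TestShiftTest:
    def test_extreme_configuration_exact_probability(self):
        """All 10 set values above all 100 background values: the two-sided p
        is twice the probability of the single most extreme rank assignment."""
        values = pd.Series(
            np.concatenate([np.arange(100, 110) + 1000.0, np.arange(100)]),
            index=[f"s{i}" for i in range(10)] + [f"b{i}" for i in range(100)],
        )
        gs = GeneSet.from_iterable("top10", [f"s{i}" for i in range(10)])
        res = shift_test(values, gs)
        assert res.direction == "up"
        assert res.p == pytest.approx(2 / math.comb(110, 10), rel=1e-9)

    def test_monotone_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        vals = pd.Series(rng.normal(size=300), index=[f"g{i}" for i in range(300)])
        gs = GeneSet.from_iterable("s", [f"g{i}" for i in range(40)])
        p1 = shift_test(vals, gs).p
        shuffled = vals.sample(frac=1, random_state=1)  # background order irrelevant
        p2 = shift_test(shuffled, gs).p
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_direction_matches_median_shift(self):
        vals = pd.Series(
            np.concatenate([np.full(30, -1.0) + np.linspace(0, 0.1, 30), np.zeros(200) + np.linspace(0, 0.2, 200)]),
            index=[f"s{i}" for i in range(30)] + [f"b{i}" for i in range(200)],
        )
        res = shift_test(vals, GeneSet.from_iterable("s", [f"s{i}" for i in range(30)]))
        assert res.direction == "down" and res.median_shift < 0

    def test_degenerate_sets_rejected(self):
        vals = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="intersect"):
            shift_test(vals, GeneSet.from_iterable("s", ["zz"]))
        with pytest.raises(ValueError, match="background"):
            shift_test(vals, GeneSet.from_iterable("s", ["a", "b"]))


class TestVariableSubset:
    def test_boundary_1p5_fold_retained(self):
        vals = pd.Series({"a": 0.6, "b": 0.485, "c": 2.0})
        gs = GeneSet.from_iterable("s", ["a", "b", "c"])
        sub = variable_subset(vals, gs, min_fold=1.5)
        assert sub.members == frozenset({"a", "c"})  # 0.6 >= log2(1.5)=0.585

    def test_designed_seven_of_twelve(self):
        passing = {f"p{i}": 0.6 + i * 0.1 for i in range(7)}
        failing = {f"f{i}": 0.1 + i * 0.05 for i in range(5)}
        vals = pd.Series({**passing, **failing})
        gs = GeneSet.from_iterable("s", list(vals.index))
        assert len(variable_subset(vals, gs).members) == 7


class TestScoreTop:
    @pytest.mark.parametrize(
        "seq,run,is_top",
        [
            ("CTTTCTAAAA", 6, True),
            ("ATTTTTTTTT", 0, False),  # purine start: run anchored at position 0
            ("CCTGAAAAAA", 3, False),  # run below min_run
            ("TTTTTTTTTT", 10, False),  # pyrimidine-rich but starts with T
            ("CCCCCAAAAA", 5, True),
        ],
    )
    def test_rule_application(self, seq, run, is_top):
        t = TranscriptModel("T", "G", length=10, cds_start=1, cds_end=10, sequence=seq)
        call = score_top(t, min_run=5)
        assert call.pyr_run == run
        assert call.is_top is is_top
        assert call.first_base == seq[0]

    def test_empty_sequence_rejected(self):
        t = TranscriptModel("T", "G", length=10, cds_start=1, cds_end=10)
        with pytest.raises(ValueError, match="sequence"):
            score_top(t)


def _seq_annotation(seqs):
    ann = Annotation()
    for tid, seq in seqs.items():
        ann.add(
            TranscriptModel(
                tid, "g" + tid, length=len(seq), cds_start=10, cds_end=len(seq) - 10,
                sequence=seq,
            )
        )
    return ann


class TestTopEnrichment:
    def test_no_top_anywhere_p_one(self):
        ann = _seq_annotation({f"T{i}": "A" * 60 for i in range(20)})
        gs = GeneSet.from_iterable("s", [f"gT{i}" for i in range(5)])
        assert top_enrichment(gs, ann).p == 1.0

    def test_set_equal_universe_rejected(self):
        ann = _seq_annotation({f"T{i}": "A" * 60 for i in range(5)})
        gs = GeneSet.from_iterable("s", [f"gT{i}" for i in range(5)])
        with pytest.raises(ValueError, match="universe"):
            top_enrichment(gs, ann)

    def test_planted_set_detected(self):
        seqs = {f"T{i}": "G" + "A" * 59 for i in range(40)}
        for i in range(8):  # plant TOP on the first eight
            seqs[f"T{i}"] = "C" + "T" * 7 + "G" + "A" * 51
        ann = _seq_annotation(seqs)
        gs = GeneSet.from_iterable("planted", [f"gT{i}" for i in range(8)])
        res = top_enrichment(gs, ann)
        assert res.overlap == 8
        assert res.p == pytest.approx(1 / math.comb(40, 8), rel=1e-9)


def test_gmt_round_trip(tmp_path):
    from ribotrans.simulate import write_gmt

    truth = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4"],
            "gene_set": ["rp", "rp", "cc", ""],
        }
    )
    path = tmp_path / "sets.gmt"
    write_gmt(truth, path)
    sets = read_gmt(path)
    assert sets["rp"].members == frozenset({"g1", "g2"})
    assert sets["cc"].members == frozenset({"g3"})


def test_kmer_enrichment_finds_planted_motif():
    rng = np.random.default_rng(0)

    def rand_seq(n):
        return "".join(rng.choice(list("ACGT"), n))

    universe = {f"u{i}": rand_seq(80) for i in range(200)}
    motif = "CTCTCT"
    set_seqs = {}
    for i in range(20):
        s = rand_seq(80)
        set_seqs[f"s{i}"] = s[:30] + motif + s[36:]
        universe[f"s{i}"] = set_seqs[f"s{i}"]
    hits = kmer_enrichment(set_seqs, universe, k=6)
    assert motif in set(hits["kmer"])
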