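import numpy as np
import pytest

from ribotrans.reference import Annotation, TranscriptModel
from ribotrans.simulate import TruthConfig, generate_reads, generate_transcriptome


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study design: 5 conditions in 2 batches, 2 replicates."""
    return TruthConfig(n_genes=300, library_size=120_000, replicates=2, seed=11)


@pytest.fixture(scope="session")
def small_run(small_config, tmp_path_factory):
    """One shared simulated dataset: (annotation, truth table, sheet, dir)."""
    out = tmp_path_factory.mktemp("simdata")
    ann, truth = generate_transcriptome(small_config)
    sheet = generate_reads(ann, truth, small_config, out)
    return ann, truth, sheet, out


@pytest.fixture(scope="session")
def small_quant(small_run):
    from ribotrans.quantify import quantify_samples

    ann, truth, sheet, out = small_run
    quant, tallies = quantify_samples(sheet, ann, out)
    return quant, tallies


@pytest.fixture()
def toy_annotation():
    """Two coding transcripts and one rRNA with round-number segmentation."""
    ann = Annotation()
    ann.add(TranscriptModel("TX1", "G1", length=1000, cds_start=100, cds_end=700))
    ann.add(TranscriptModel("TX2", "G2", length=2000, cds_start=200, cds_end=1400))
    ann.add(TranscriptModel("RRN1", "rRNA_1", length=1500, cds_start=0, cds_end=0, is_rRNA=True))
    return ann


def write_sam(path, ann, reads):
    """Hand-rolled SAM fixture writer for tests: reads = (tid, start, length, nh)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for tid in sorted(ann.transcripts):
            fh.write(f"@SQ\tSN:{tid}\tLN:{ann[tid].length}\n")
        for i, (tid, start, length, nh) in enumerate(reads):
            mapq = 255 if nh == 1 else 0
            fh.write(
                f"r{i}\t0\t{tid}\t{start + 1}\t{mapq}\t{length}M\t*\t0\t0\t*\t*\tNH:i:{nh}\n"
            )
    return path
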