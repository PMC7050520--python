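"""Shared fixtures: hand-built annotations and cached simulation runs."""

import numpy as np
import pyfaidx
import pytest

from fulltx import pipeline, simulate
from fulltx.annotation import GenomeAnnotation, TranscriptModel


def write_fasta(path, seqs: dict):
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    return path


@pytest.fixture
def make_ann(tmp_path):
    """Factory: GenomeAnnotation from transcripts + explicit sequences."""

    def _make(transcripts, seqs=None):
        if seqs is None:
            chroms = {t.chrom for t in transcripts}
            rng = np.random.default_rng(0)
            seqs = {
                c: "".join(rng.choice(list("ACGT"), size=5000)) for c in chroms
            }
        fa = write_fasta(tmp_path / "genome.fa", seqs)
        return GenomeAnnotation(
            {t.transcript_id: t for t in transcripts}, pyfaidx.Fasta(str(fa))
        )

    return _make


def two_exon_transcript(tid="t1", gene="gA", chrom="chrT", strand="+",
                        exons=((100, 200), (300, 400)), **kw):
    return TranscriptModel(
        transcript_id=tid, gene_id=gene, chrom=chrom, strand=strand,
        exons=exons, **kw,
    )


@pytest.fixture(scope="session")
def sim_clean_small(tmp_path_factory):
    """Small defect-free simulation plus its pipeline run."""
    out = tmp_path_factory.mktemp("sim_clean")
    cfg = simulate.clean_config(seed=11, n_genes=12, n_reads=1500)
    res = simulate.simulate_dataset(cfg, out)
    result = pipeline.run_pipeline(
        res.annotation_gff3, res.genome_fasta, res.reads_sam, res.polya_tsv
    )
    return res, result


@pytest.fixture(scope="session")
def sim_default_small(tmp_path_factory):
    """Small simulation at the default artifact mix plus its pipeline run."""
    out = tmp_path_factory.mktemp("sim_default")
    cfg = simulate.SimConfig(seed=12, n_genes=15, n_reads=2500)
    res = simulate.simulate_dataset(cfg, out)
    result = pipeline.run_pipeline(
        res.annotation_gff3, res.genome_fasta, res.reads_sam, res.polya_tsv
    )
    return res, result
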