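"""End-to-end orchestration of the full-length transcript pipeline."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import alignments, annotation, filtering, isoforms, polya_stats, utr


@dataclass
class PipelineResult:
    ann: annotation.GenomeAnnotation
    outcomes: list
    report: filtering.FilterReport
    iso_calls: list
    utr_calls: list
    utr_assignment: dict
    pairing: pd.DataFrame
    records: pd.DataFrame  # per-read tail + structure labels


def run_pipeline(gff3, fasta, reads_path, polya_path,
                 filter_cfg: filtering.FilterConfig | None = None,
                 kde_cfg: utr.KdeConfig | None = None,
                 hexamers=None,
                 tss_point_beds=(), tss_cluster_beds=(),
                 outdir=None) -> PipelineResult:
    """Filter reads, call isoforms and UTRs, pair them, join tails.

    Reads are sorted internally by position and id, so the result is
    invariant to input read order.  When `outdir` is given, the standard
    artifact set (filter report, BED12 tracks, isoform/UTR/pairing tables)
    is written there.
    """
    filter_cfg = filter_cfg or filtering.FilterConfig()
    kde_cfg = kde_cfg or utr.KdeConfig()
    hexamers = hexamers if hexamers is not None else utr.DEFAULT_HEXAMERS
    ann = annotation.load_annotation(gff3, fasta)
    for p in tss_point_beds:
        ann.tss.load_point_bed(p)
    for p in tss_cluster_beds:
        ann.tss.load_cluster_bed(p)
    reads = sorted(
        alignments.read_alignments(reads_path),
        key=lambda r: (r.chrom, r.start, r.read_id),
    )
    polya_table = polya_stats.load_polya_table(polya_path)
    qc = polya_stats.polya_qc_map(polya_table)
    outcomes, report = filtering.run_filter_pipeline(
        reads, ann, qc, filter_cfg, hexamers
    )
    passing = filtering.passing(outcomes)
    iso_calls = isoforms.cluster_isoforms(passing, ann)
    utr_calls, assignment = utr.call_utrs(passing, ann, kde_cfg, hexamers)
    pairing = polya_stats.full_length_pairing(iso_calls, utr_calls)
    records = polya_stats.build_records(
        polya_table, outcomes, iso_calls, utr_calls, assignment
    )
    result = PipelineResult(
        ann=ann, outcomes=outcomes, report=report, iso_calls=iso_calls,
        utr_calls=utr_calls, utr_assignment=assignment, pairing=pairing,
        records=records,
    )
    if outdir is not None:
        write_artifacts(result, outdir, filter_cfg, kde_cfg, hexamers)
    return result


def write_artifacts(result: PipelineResult, outdir, filter_cfg, kde_cfg,
                    hexamers):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.report.write_tsv(outdir / "filter_report.tsv")
    alignments.write_bed12(
        [o.read for o in filtering.passing(result.outcomes)],
        outdir / "passing_reads.bed12",
    )
    alignments.write_bed12(
        [o.read for o in filtering.retained(result.outcomes)],
        outdir / "retained_intron_reads.bed12",
    )
    isoforms.write_isoform_tsv(result.iso_calls, outdir / "isoforms.tsv")
    # full-length isoforms with a called UTR in blue, UTR-less in red
    # (browser-track convention)
    with_utr = set(result.pairing.dropna(subset=["utr_id"])["isoform_id"])
    rgb = {
        c.isoform_id: ("0,0,255" if c.isoform_id in with_utr else "255,0,0")
        for c in result.iso_calls
    }
    alignments.write_bed12(
        isoforms.isoform_bed12_records(result.iso_calls),
        outdir / "isoforms.bed12", rgb_by_name=rgb,
    )
    utr.write_utr_bed(result.utr_calls, outdir / "utrs.bed")
    result.pairing.to_csv(outdir / "full_length_isoforms.tsv", sep="\t",
                          index=False)
    result.records.to_csv(outdir / "polya_records.tsv", sep="\t", index=False)
    with open(outdir / "run_config.json", "w") as fh:
        json.dump(
            {
                "filter": {
                    k: (sorted(v) if isinstance(v, frozenset) else v)
                    for k, v in asdict(filter_cfg).items()
                },
                "kde": asdict(kde_cfg),
                "hexamers": list(hexamers),
            },
            fh, indent=2,
        )


def summary_counts(result: PipelineResult) -> dict:
    """Headline counts: splice isoforms, UTR isoforms, full-length pairs."""
    n_full = len(result.pairing)
    return {
        "n_reads_pass": len(filtering.passing(result.outcomes)),
        "n_reads_retained_intron": len(filtering.retained(result.outcomes)),
        "n_splice_isoforms": len(result.iso_calls),
        "n_utr_isoforms": len(result.utr_calls),
        "n_full_length_isoforms": n_full,
        "n_utr_less_full_length": int(result.pairing["utr_id"].isna().sum()),
        "n_novel_isoforms": sum(
            1 for c in result.iso_calls if c.novelty != "ANNOTATED"
        ),
    }
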