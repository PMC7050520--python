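"""Six-stage full-length read filter.

A read is called full length only if it survives, in order:

1. structural sanity — no insertion > 20 nt, no 3' softclip > 20 nt
   (applied before realignment);
2. poly(A) QC — the signal-level tail estimator reported a usable tail;
3. TSS support — the 5' end falls within -100..+15 of an annotated 5' end,
   inside an external TSS cluster, or within 10 nt of a point TSS;
4. splice correction — every donor/acceptor snaps to a canonical site
   within 15 nt and all sites belong to exactly one gene (unspliced reads
   are assigned by overlap with single-exon genes);
5. intron retention — reads whose exonic block fully spans an annotated
   intron (not itself spanned by any annotated exon) are diverted, not
   dropped: they re-enter only the poly(A) analyses;
6. 3' support — the read overlaps an annotated stop codon, or carries both
   a PAS hexamer within 60 nt upstream of its 3' end and a complete ORF.

Reads passing all stages with an original 3' softclip of at most 10 nt are
additionally flagged UTR-eligible and feed cleavage-site calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .alignments import ReadAlignment, RealignmentScoring, realign_3prime_softclip
from .annotation import GenomeAnnotation
from .isoforms import longest_orf
from .utr import DEFAULT_HEXAMERS, scan_pas, transcript_to_genomic

STAGES = ("INS_CLIP", "POLYA_QC", "TSS", "SPLICE", "INTRON_RETENTION", "THREE_PRIME")


@dataclass(frozen=True)
class FilterConfig:
    max_insertion: int = 20
    max_softclip3: int = 20
    polya_fail_tags: frozenset = frozenset(
        {"READ_FAILED_LOAD", "SUFFCLIP", "NOREGION"}
    )
    splice_tol: int = 15
    pas_window: int = 60
    utr_softclip3_max: int = 10

    def __post_init__(self):
        if min(self.max_insertion, self.max_softclip3, self.splice_tol,
               self.pas_window, self.utr_softclip3_max) < 0:
            raise ValueError("tolerances must be >= 0")


@dataclass
class FilterOutcome:
    read_id: str
    stage_reached: str  # first failed stage, INTRON_RETENTION, or PASS
    read: ReadAlignment | None = None  # splice-corrected, post-realignment
    gene_id: str | None = None
    corrected_chain: tuple | None = None
    intron_retained: bool = False
    utr_eligible: bool = False
    stop_pos: int | None = None  # strand-aware 5'-most base of stop codon
    stop_source: str | None = None  # "annotated" | "orf"
    orf: tuple | None = None  # (start, end) in transcript coords

    @property
    def passed(self) -> bool:
        return self.stage_reached == "PASS"


@dataclass
class FilterReport:
    """Surviving-read accounting after each stage (order = Methods order)."""

    n_input: int = 0
    surviving: dict = field(default_factory=dict)
    n_retained_diverted: int = 0
    n_missing_polya: int = 0
    insertion_filter_inactive: bool = False  # BED12 input: no CIGAR

    def to_rows(self):
        rows = [("input", self.n_input)]
        rows += [(s, self.surviving.get(s, 0)) for s in STAGES]
        rows.append(("retained_intron_diverted", self.n_retained_diverted))
        return rows

    def write_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("stage\tsurviving_reads\n")
            for stage, n in self.to_rows():
                fh.write(f"{stage}\t{n}\n")


def stage1_structural(read: ReadAlignment, cfg: FilterConfig) -> bool:
    """True iff insertions and the (pre-realignment) 3' softclip are small."""
    return (
        read.max_insertion <= cfg.max_insertion
        and read.softclip3 <= cfg.max_softclip3
    )


def stage2_polya_qc(read_id: str, polya_qc: dict, cfg: FilterConfig) -> bool:
    """True iff the read has a tail record whose QC tag is not a fail tag.

    Reads absent from the table fail: no detectable tail evidence.
    """
    tag = polya_qc.get(read_id)
    return tag is not None and tag not in cfg.polya_fail_tags


def stage3_tss(read: ReadAlignment, ann: GenomeAnnotation) -> bool:
    return ann.tss.supports(read.chrom, read.strand, read.end5)


def _snap(index, kind, chrom, strand, pos, tol):
    hit = index.nearest(kind, chrom, strand, pos)
    if hit is None or hit[1] > tol:
        return None
    return hit[0]


def stage4_splice_correct(read: ReadAlignment, ann: GenomeAnnotation,
                          cfg: FilterConfig):
    """Snap junctions to canonical sites and assign the unique gene.

    Returns (corrected_read, corrected_chain, gene_id) or None on failure.
    For unspliced reads the gene is assigned by overlap with single-exon
    genes (chain is empty).
    """
    index = ann.splice_index
    if not read.spliced:
        genes = ann.single_exon_gene_overlaps(
            read.chrom, read.strand, read.start, read.end
        )
        if len(genes) != 1:
            return None
        return read, (), next(iter(genes))
    corrected = []
    gene_union: set = set()
    for (s, e) in read.junctions:
        donor_pos = s if read.strand == "+" else e
        acceptor_pos = e if read.strand == "+" else s
        donor = _snap(index, "donor", read.chrom, read.strand, donor_pos,
                      cfg.splice_tol)
        acceptor = _snap(index, "acceptor", read.chrom, read.strand,
                         acceptor_pos, cfg.splice_tol)
        if donor is None or acceptor is None:
            return None
        gene_union |= index.site_genes.get(
            (read.chrom, read.strand, "donor", donor), set()
        )
        gene_union |= index.site_genes.get(
            (read.chrom, read.strand, "acceptor", acceptor), set()
        )
        intron = (donor, acceptor) if read.strand == "+" else (acceptor, donor)
        if intron[0] >= intron[1]:
            return None
        corrected.append(intron)
    if len(gene_union) != 1:
        return None
    chain = tuple(sorted(corrected))
    # rebuild blocks around the corrected junctions
    bounds = [read.start]
    for s, e in chain:
        bounds += [s, e]
    bounds.append(read.end)
    blocks = []
    for i in range(0, len(bounds), 2):
        b0, b1 = bounds[i], bounds[i + 1]
        if b0 >= b1:
            return None  # snapping produced a degenerate block
        blocks.append((b0, b1))
    for (a, b), (c, d) in zip(blocks, blocks[1:]):
        if b >= c:
            return None
    new_read = replace(read, blocks=tuple(blocks))
    return new_read, chain, next(iter(gene_union))


def stage5_intron_retention(read: ReadAlignment, ann: GenomeAnnotation) -> bool:
    """True iff a read block fully spans a retention-eligible intron."""
    return bool(ann.retained_introns(read.chrom, read.strand, read.blocks))


def stage6_three_prime(read: ReadAlignment, ann: GenomeAnnotation,
                       cfg: FilterConfig, hexamers=None):
    """3'-end support: stop-codon overlap, or PAS hexamer + complete ORF.

    Returns (passed, stop_pos, stop_source, orf).  The putative stop
    position (strand-aware 5'-most base of the stop codon) keys UTR
    grouping downstream: the annotated stop the read overlaps when there is
    one (closest to the read 3' end if several), else the predicted ORF
    stop.
    """
    hexamers = hexamers if hexamers is not None else DEFAULT_HEXAMERS
    tree = ann.stop_trees.get((read.chrom, read.strand))
    overlapped = []
    if tree is not None:
        for b0, b1 in read.blocks:
            for iv in tree.overlap(b0, b1):
                t = ann.transcripts[iv.data]
                overlapped.append(t.stop_pos)
    if overlapped:
        stop = min(overlapped, key=lambda p: (abs(p - read.end3), p))
        return True, stop, "annotated", None
    seq = ann.spliced_sequence(read.chrom, read.strand, read.blocks)
    upstream = seq[max(0, len(seq) - 1 - cfg.pas_window): len(seq) - 1]
    pas = scan_pas(upstream, hexamers)
    if pas.pas_type == "NONE":
        return False, None, None, None
    orf = longest_orf(seq)
    if orf is None:
        return False, None, None, None
    # genomic position of the stop codon's 5'-most base (transcript coords
    # orf.end-3)
    stop = transcript_to_genomic(read.blocks, read.strand, orf[1] - 3)
    return True, stop, "orf", (orf[0], orf[1])


def run_filter_pipeline(reads, ann: GenomeAnnotation, polya_qc: dict,
                        cfg: FilterConfig | None = None, hexamers=None,
                        scoring: RealignmentScoring | None = None):
    """Apply all six stages in order; returns (outcomes, report).

    `polya_qc` maps read_id -> QC tag (see
    :func:`fulltx.polya_stats.load_polya_table`).  Passing and diverted
    retained-intron reads are distinguished by
    ``outcome.stage_reached in ("PASS", "INTRON_RETENTION")``.
    """
    cfg = cfg or FilterConfig()
    hexamers = hexamers if hexamers is not None else DEFAULT_HEXAMERS
    outcomes: list[FilterOutcome] = []
    report = FilterReport()
    surv = {s: 0 for s in STAGES}
    for read in reads:
        report.n_input += 1
        if not read.from_bam:
            report.insertion_filter_inactive = True
        if not stage1_structural(read, cfg):
            outcomes.append(FilterOutcome(read.read_id, "INS_CLIP", read=read))
            continue
        surv["INS_CLIP"] += 1
        if not stage2_polya_qc(read.read_id, polya_qc, cfg):
            if read.read_id not in polya_qc:
                report.n_missing_polya += 1
            outcomes.append(FilterOutcome(read.read_id, "POLYA_QC", read=read))
            continue
        surv["POLYA_QC"] += 1
        read = realign_3prime_softclip(read, ann, scoring)
        if not stage3_tss(read, ann):
            outcomes.append(FilterOutcome(read.read_id, "TSS", read=read))
            continue
        surv["TSS"] += 1
        corrected = stage4_splice_correct(read, ann, cfg)
        if corrected is None:
            # an unassignable read spanning a retained intron is diverted as
            # retained (gene taken from the intron), not discarded
            retained = ann.retained_introns(read.chrom, read.strand, read.blocks)
            if retained:
                surv["SPLICE"] += 1  # assigned via the intron, diverted at 5
                outcomes.append(
                    FilterOutcome(
                        read.read_id, "INTRON_RETENTION", read=read,
                        gene_id=retained[0][2], intron_retained=True,
                    )
                )
                report.n_retained_diverted += 1
            else:
                outcomes.append(FilterOutcome(read.read_id, "SPLICE", read=read))
            continue
        read, chain, gene_id = corrected
        surv["SPLICE"] += 1
        if stage5_intron_retention(read, ann):
            outcomes.append(
                FilterOutcome(
                    read.read_id, "INTRON_RETENTION", read=read,
                    gene_id=gene_id, corrected_chain=chain,
                    intron_retained=True,
                )
            )
            report.n_retained_diverted += 1
            continue
        surv["INTRON_RETENTION"] += 1
        ok3, stop_pos, stop_source, orf = stage6_three_prime(
            read, ann, cfg, hexamers
        )
        if not ok3:
            outcomes.append(
                FilterOutcome(
                    read.read_id, "THREE_PRIME", read=read, gene_id=gene_id,
                    corrected_chain=chain,
                )
            )
            continue
        surv["THREE_PRIME"] += 1
        outcomes.append(
            FilterOutcome(
                read.read_id, "PASS", read=read, gene_id=gene_id,
                corrected_chain=chain,
                utr_eligible=read.softclip3_original <= cfg.utr_softclip3_max,
                stop_pos=stop_pos, stop_source=stop_source, orf=orf,
            )
        )
    report.surviving = surv
    return outcomes, report


def passing(outcomes):
    return [o for o in outcomes if o.stage_reached == "PASS"]


def retained(outcomes):
    return [o for o in outcomes if o.stage_reached == "INTRON_RETENTION"]
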