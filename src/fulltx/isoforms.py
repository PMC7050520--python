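"""Splice-isoform calling: clustering, ORF extraction, novelty, support.

Reads sharing a corrected junction chain within a gene are one splice
isoform; the longest supporting read represents it and provides the ORF.
Novelty is judged against the annotated chains *and all their 5'-truncated
suffixes*, so a read that merely lost its 5' end can never mint a novel
isoform.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation import GenomeAnnotation, SpliceSiteIndex, fulllength_supported_isoforms, restricted_isoform_universe
from .utr import transcript_to_genomic

STOP_CODONS = {"TAA", "TAG", "TGA"}

ANNOTATED = "ANNOTATED"
NOVEL_COMBINATION = "NOVEL_COMBINATION"
NOVEL_JUNCTION = "NOVEL_JUNCTION"
NOVEL_EXON = "NOVEL_EXON"


def longest_orf(seq: str):
    """Longest ATG..stop span over the three forward frames.

    `seq` is the transcript-oriented (5'->3') nucleotide string.  Returns
    ``(start, end, frame)`` with `end` exclusive and including the stop
    codon, or None when no ORF with both a start and a stop codon exists.
    Ties go to the 5'-most start.
    """
    s = seq.upper().replace("U", "T")
    best = None  # (-length, start, end, frame)
    for frame in range(3):
        open_start = None
        for i in range(frame, len(s) - 2, 3):
            codon = s[i:i + 3]
            if codon == "ATG" and open_start is None:
                open_start = i
            elif codon in STOP_CODONS and open_start is not None:
                cand = (-(i + 3 - open_start), open_start, i + 3, frame)
                if best is None or cand < best:
                    best = cand
                open_start = None
    if best is None:
        return None
    return best[1], best[2], best[3]


@dataclass
class SpliceIsoformCall:
    isoform_id: str
    gene_id: str
    chrom: str
    strand: str
    chain: tuple
    read_ids: set
    representative_read: str
    representative_blocks: tuple
    orf: tuple | None = None  # (start, end) transcript coords
    orf_stop_genomic: int | None = None  # 5'-most base of the stop codon
    novelty: str = ANNOTATED
    matched_annotation_ids: frozenset = frozenset()

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)


def classify_novelty(chrom, strand, chain, index: SpliceSiteIndex) -> str:
    """Novelty class of a canonical junction chain.

    ANNOTATED when the chain equals an annotated chain or any of its 5'
    truncations; NOVEL_JUNCTION when some (donor, acceptor) pair is not
    annotated anywhere; NOVEL_EXON when all junctions are annotated but
    some internal exon (between adjacent junctions) is not; otherwise
    NOVEL_COMBINATION (annotated parts, unseen combination).
    """
    if not chain:
        return ANNOTATED
    if index.matching_transcripts(chrom, strand, chain):
        return ANNOTATED
    for j in chain:
        if not index.is_annotated_junction(chrom, strand, j):
            return NOVEL_JUNCTION
    for (s1, e1), (s2, e2) in zip(chain, chain[1:]):
        if (chrom, strand, (e1, s2)) not in index.internal_exons:
            return NOVEL_EXON
    return NOVEL_COMBINATION


def cluster_isoforms(passing_outcomes, ann: GenomeAnnotation):
    """Group passing reads into splice isoforms by (gene, junction chain).

    The representative is the longest aligned read (ties: lexicographically
    smallest read id); its spliced sequence supplies the isoform ORF.
    """
    groups: dict = {}
    for o in passing_outcomes:
        key = (o.gene_id, o.read.chrom, o.read.strand, o.corrected_chain or ())
        groups.setdefault(key, []).append(o)
    calls = []
    per_gene_counter: dict = {}
    for (gene, chrom, strand, chain), members in sorted(
        groups.items(), key=lambda kv: (kv[0][1], kv[0][0], kv[0][3])
    ):
        rep = min(members, key=lambda o: (-o.read.aligned_length, o.read_id))
        seq = ann.spliced_sequence(chrom, strand, rep.read.blocks)
        orf = longest_orf(seq)
        orf_stop = None
        if orf is not None:
            orf_stop = transcript_to_genomic(rep.read.blocks, strand, orf[1] - 3)
        if chain:
            matched = ann.splice_index.matching_transcripts(chrom, strand, chain)
        else:
            matched = frozenset(
                tid for tid in ann.genes.get(gene, [])
                if not ann.transcripts[tid].introns
            )
        per_gene_counter[gene] = per_gene_counter.get(gene, 0) + 1
        calls.append(
            SpliceIsoformCall(
                isoform_id=f"{gene}.iso{per_gene_counter[gene]}",
                gene_id=gene,
                chrom=chrom,
                strand=strand,
                chain=chain,
                read_ids={m.read_id for m in members},
                representative_read=rep.read_id,
                representative_blocks=rep.read.blocks,
                orf=(orf[0], orf[1]) if orf else None,
                orf_stop_genomic=orf_stop,
                novelty=classify_novelty(chrom, strand, chain, ann.splice_index),
                matched_annotation_ids=frozenset(matched),
            )
        )
    return calls


def support_comparison(calls, ann: GenomeAnnotation):
    """Full-length support overlap between read data and annotation evidence.

    The universe is the annotated isoforms with at least one intron
    (single-exon and intron-less models are excluded on both sides).  An
    annotated isoform is read-supported when some called chain matches it
    (full chain or 5'-truncation); evidence-supported when all its introns
    share an EST/cDNA identifier.  Gene tallies project the same sets onto
    gene ids.
    """
    universe = restricted_isoform_universe(ann)
    evidence = fulllength_supported_isoforms(ann) & universe
    read_supported = set()
    for c in calls:
        read_supported |= set(c.matched_annotation_ids) & universe
    def genes_of(tids):
        return {ann.transcripts[t].gene_id for t in tids}
    iso = {
        "both": len(read_supported & evidence),
        "reads_only": len(read_supported - evidence),
        "evidence_only": len(evidence - read_supported),
        "neither": len(universe - read_supported - evidence),
    }
    g_univ = genes_of(universe)
    g_reads = genes_of(read_supported)
    g_ev = genes_of(evidence)
    genes = {
        "both": len(g_reads & g_ev),
        "reads_only": len(g_reads - g_ev),
        "evidence_only": len(g_ev - g_reads),
        "neither": len(g_univ - g_reads - g_ev),
    }
    return {
        "isoforms": iso,
        "genes": genes,
        "read_supported_isoforms": read_supported,
        "evidence_supported_isoforms": evidence,
        "universe": universe,
    }


def coding_filter(calls, coding_prob: dict, threshold: float = 0.5):
    """Partition isoforms into coding / noncoding / unknown at `threshold`.

    `coding_prob` maps isoform_id -> coding probability in [0, 1]; isoforms
    absent from the table are flagged unknown.
    """
    for k, v in coding_prob.items():
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"coding probability for {k} outside [0,1]: {v}")
    out = {"coding": set(), "noncoding": set(), "unknown": set()}
    for c in calls:
        p = coding_prob.get(c.isoform_id)
        if p is None:
            out["unknown"].add(c.isoform_id)
        elif p >= threshold:
            out["coding"].add(c.isoform_id)
        else:
            out["noncoding"].add(c.isoform_id)
    return out


def write_isoform_tsv(calls, path, coding_prob=None):
    with open(path, "w") as fh:
        fh.write("isoform_id\tgene_id\tn_reads\tnovelty\tcoding_prob\n")
        for c in calls:
            p = (coding_prob or {}).get(c.isoform_id)
            fh.write(
                f"{c.isoform_id}\t{c.gene_id}\t{c.n_reads}\t{c.novelty}\t"
                f"{'' if p is None else p}\n"
            )


def isoform_bed12_records(calls):
    """(name, chrom, strand, blocks, thick) tuples; thick marks the ORF."""
    out = []
    for c in calls:
        thick = None
        if c.orf is not None:
            g1 = transcript_to_genomic(c.representative_blocks, c.strand, c.orf[0])
            g2 = transcript_to_genomic(c.representative_blocks, c.strand, c.orf[1] - 1)
            thick = (min(g1, g2), max(g1, g2) + 1)
        out.append((c.isoform_id, c.chrom, c.strand, c.representative_blocks, thick))
    return out
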