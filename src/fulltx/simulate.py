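"""Synthetic dRNA-seq data with planted ground truth.

Generates a toy genome, a GFF3 annotation, read alignments (BED12 and SAM)
and a per-read tail-length table in which every structural feature the
pipeline tests for is planted deliberately: 5' truncations, splice-site
jitter, retained introns, 3'-end jitter around planted cleavage sites, PAS
hexamers 19 nt upstream of cleavage sites, insertion/softclip artifacts,
poly(A) QC failures, and per-read tail lengths with planted
tail-expression, tail-UTR-length and tail-intron-retention relationships.

Every read carries exactly one planted feature class, so the filter stage
at which it should drop out (or pass) is unambiguous and stage accounting
can be compared to truth exactly.  Sequence regions that could make an
outcome stochastic are controlled: cleavage-site upstream windows are
scrubbed of all listed PAS hexamers before the intended one is planted,
and the 60 nt beyond each terminal cleavage site is an A/C-free pattern so
that adapter-like clip suffixes ("CCCCCC") can never realign there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import TranscriptModel, write_gff3
from .seq import revcomp, to_dna
from .utr import DEFAULT_HEXAMERS

# planted per-read feature classes and the filter stage each should reach
CLASS_STAGE = {
    "CLEAN": "PASS",
    "REALIGN_CLIP": "PASS",
    "INS": "INS_CLIP",
    "CLIP3": "INS_CLIP",
    "POLYA_FAIL": "POLYA_QC",
    "POLYA_MISSING": "POLYA_QC",
    "TRUNC": "TSS",
    "SPLICE_ERR": "SPLICE",
    "RETAINED": "INTRON_RETENTION",
}

_POLYA_FAIL_TAGS = ("READ_FAILED_LOAD", "SUFFCLIP", "NOREGION")
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic data set.

    Artifact fractions and jitters default to the mix a real library shows
    (a substantial 5'-truncated population, small alignment jitter, a few
    percent structural and QC artifacts); zero them for a defect-free
    data set.
    """

    seed: int = 0
    n_genes: int = 50
    n_noncoding_genes: int = 4  # no CDS, no PAS: reads lack 3' support
    n_single_exon_genes: int = 3
    n_reads: int = 20000
    isoforms_per_gene: tuple = (0.6, 0.3, 0.1)  # P(1), P(2), P(3)
    exons_per_isoform: tuple = (2, 6)
    exon_length: tuple = (120, 400)
    intron_length: tuple = (60, 200)
    utr_length: tuple = (80, 300)  # stop codon -> first cleavage site
    expression_sigma: float = 1.0  # log-normal isoform expression
    sites_per_gene: tuple = (0.7, 0.3)  # P(1), P(2)
    min_site_gap: int = 80  # keeps PAS windows of adjacent sites disjoint
    pas_fractions: tuple = (0.55, 0.30, 0.15)  # canonical, alternative, none
    pas_offset: int = 19  # hexamer start -> cleavage site
    tss_jitter: tuple = (-20, 10)  # read start around TSS, nt
    end_jitter_sd: float = 3.0
    splice_jitter_sd: float = 2.0
    truncation_prob: float = 0.30
    truncation_length: tuple = (50, 1000)
    retained_intron_frac: float = 0.03
    frac_insertion: float = 0.02
    frac_softclip: float = 0.02
    frac_polya_fail: float = 0.04
    frac_polya_missing: float = 0.01
    frac_splice_err: float = 0.02
    frac_realign_clip: float = 0.05
    realign_match_len: int = 4  # genomic-matching clip prefix
    tail_mu0: float = 45.0
    tail_beta_expr: float = -5.0  # per log10 supporting reads
    tail_beta_utr: float = 8.0  # per log10 UTR length
    tail_delta_retained: float = 8.0
    tail_sigma: float = 18.0
    tail_floor: float = 10.0
    hexamers: tuple = DEFAULT_HEXAMERS

    def __post_init__(self):
        fr = (self.truncation_prob, self.retained_intron_frac,
              self.frac_insertion, self.frac_softclip, self.frac_polya_fail,
              self.frac_polya_missing, self.frac_splice_err,
              self.frac_realign_clip)
        if any(not (0 <= f <= 1) for f in fr) or sum(fr) > 1:
            raise ValueError("feature fractions must be in [0,1] and sum <= 1")
        if self.min_site_gap <= 2 * 10:
            raise ValueError("min_site_gap must exceed twice the support window")
        if self.intron_length[0] < 30:
            raise ValueError("introns shorter than 30 nt are not representable")


def clean_config(**overrides) -> SimConfig:
    """Defaults with all artifact fractions and jitters zeroed."""
    base = dict(
        end_jitter_sd=0.0, splice_jitter_sd=0.0, truncation_prob=0.0,
        retained_intron_frac=0.0, frac_insertion=0.0, frac_softclip=0.0,
        frac_polya_fail=0.0, frac_polya_missing=0.0, frac_splice_err=0.0,
        frac_realign_clip=0.0,
    )
    base.update(overrides)
    return SimConfig(**base)


# -- gene construction (local coordinates = transcript orientation) --------

@dataclass
class _Isoform:
    transcript_id: str
    chain_local: tuple  # introns in local coords, ascending
    exons_local: tuple
    site_tx: tuple  # transcript coords of each cleavage site
    expression: float = 1.0


@dataclass
class _Gene:
    gene_id: str
    strand: str
    coding: bool
    local_len: int
    seq_local: list  # mutable list of bases, transcript orientation
    exons_local: tuple  # full exon set
    cds_local: tuple
    stop_local: int | None  # local coord of stop codon first base
    sites_local: tuple  # cleavage sites, local coords (last transcribed base)
    site_pas: tuple  # (pas_type, hexamer) per site
    site_weights: tuple
    isoforms: list = field(default_factory=list)
    offset: int = 0  # genomic offset once placed
    chrom: str = "chrI"

    def local_to_genomic(self, p: int) -> int:
        if self.strand == "+":
            return self.offset + p
        return self.offset + self.local_len - 1 - p

    def interval_to_genomic(self, s: int, e: int) -> tuple:
        if self.strand == "+":
            return (self.offset + s, self.offset + e)
        return (self.offset + self.local_len - e, self.offset + self.local_len - s)


def _tx_to_local(exons_local, t: int) -> int:
    """Transcript coordinate -> local coordinate along an exon chain."""
    off = t
    for s, e in exons_local:
        if off < e - s:
            return s + off
        off -= e - s
    raise IndexError(t)


def _local_to_tx(exons_local, p: int) -> int:
    t = 0
    for s, e in exons_local:
        if p < e:
            return t + (p - s)
        t += e - s
    raise IndexError(p)


def _scrub_hexamers(seq: list, lo: int, hi: int, banned_dna, rng,
                    protected=frozenset()):
    """Mutate bases until no banned hexamer overlaps [lo, hi)."""
    lo = max(0, lo - 5)
    hi = min(len(seq), hi + 5)
    for _ in range(500):
        region = "".join(seq[lo:hi])
        hit = None
        for h in banned_dna:
            p = region.find(h)
            if p >= 0:
                hit = p
                break
        if hit is None:
            return
        for k in (2, 3, 1, 4, 0, 5):
            tgt = lo + hit + k
            if tgt not in protected:
                seq[tgt] = "C" if seq[tgt] != "C" else "G"
                break
        else:
            raise RuntimeError("all bases of a banned hexamer are protected")
    raise RuntimeError("hexamer scrub failed to converge")


def _build_gene(gene_id, strand, coding, single_exon, cfg: SimConfig, rng
                ) -> _Gene:
    pad5, pad3 = 120, 120
    hex_dna = [to_dna(h) for h in cfg.hexamers]
    n_ex = 1 if single_exon else int(
        rng.integers(cfg.exons_per_isoform[0], cfg.exons_per_isoform[1] + 1)
    )
    ex_lens = [int(rng.integers(*cfg.exon_length)) for _ in range(n_ex)]
    in_lens = [int(rng.integers(*cfg.intron_length)) for _ in range(n_ex - 1)]
    # cleavage sites: spacing keeps adjacent PAS windows independent
    n_sites = 1 + int(rng.random() < cfg.sites_per_gene[1])
    utr1 = int(rng.integers(*cfg.utr_length))
    gaps = [int(rng.integers(cfg.min_site_gap, cfg.min_site_gap + 60))
            for _ in range(n_sites - 1)]
    total_utr = utr1 + sum(gaps)
    # enough room in the last exon for (single-exon case) ATG + a short CDS,
    # the stop codon, the UTR with its sites, and the controlled 3' zone
    ex_lens[-1] = max(ex_lens[-1], 100 + 3 + total_utr + pad3)
    cur = pad5
    exons = []
    for i, ln in enumerate(ex_lens):
        exons.append((cur, cur + ln))
        cur += ln
        if i < n_ex - 1:
            cur += in_lens[i]
    local_len = cur + pad3
    seq = list(rng.choice(_BASES, size=local_len))
    tx_len = sum(ex_lens)
    # stop codon sits in the last exon, UTR and sites downstream of it
    stop_tx = None
    cds = ()
    if coding:
        atg_tx = 30
        stop_tx = tx_len - pad3 - total_utr - 3  # transcript coord of T of TAA
        stop_local = _tx_to_local(exons, stop_tx)
        atg_local = _tx_to_local(exons, atg_tx)
        seq[atg_local:atg_local + 3] = list("ATG")
        seq[stop_local:stop_local + 3] = list("TAA")
        cds_segments = []
        for s, e in exons:
            a, b = max(s, atg_local), min(e, stop_local + 3)
            if a < b:
                cds_segments.append((a, b))
        cds = tuple(cds_segments)
    else:
        stop_local = None
    # plant cleavage sites in the last exon (contiguous local coords)
    first_site_local = (
        (stop_local + 2 + utr1) if coding
        else exons[-1][1] - pad3 - total_utr + utr1
    )
    sites = [first_site_local]
    for g in gaps:
        sites.append(sites[-1] + g)
    pas_draws = rng.random(n_sites)
    site_pas = []
    protected = set()
    for s_loc in sites:
        _scrub_hexamers(seq, s_loc - 60, s_loc, hex_dna, rng, frozenset(protected))
    for s_loc, u in zip(sites, pas_draws):
        if not coding:
            pas = ("NONE", None)
        elif u < cfg.pas_fractions[0]:
            pas = ("CANONICAL", "AAUAAA")
        elif u < cfg.pas_fractions[0] + cfg.pas_fractions[1]:
            alt = cfg.hexamers[1 + int(rng.integers(0, len(cfg.hexamers) - 1))]
            pas = ("ALTERNATIVE", alt)
        else:
            pas = ("NONE", None)
        if pas[1] is not None:
            start = s_loc - cfg.pas_offset
            seq[start:start + 6] = list(to_dna(pas[1]))
            protected.update(range(start, start + 6))
        site_pas.append(pas)
    # A/C-free zone beyond the terminal site: benign clip suffixes cannot
    # realign into it
    zone0 = sites[-1] + 1
    pattern = "GGT" * 40
    for i in range(zone0, min(local_len, zone0 + 60)):
        seq[i] = pattern[i - zone0]
    gene = _Gene(
        gene_id=gene_id, strand=strand, coding=coding, local_len=local_len,
        seq_local=seq, exons_local=tuple(exons), cds_local=cds,
        stop_local=stop_local, sites_local=tuple(sites),
        site_pas=tuple(site_pas),
        site_weights=tuple((lambda w: w / w.sum())(rng.random(n_sites) + 0.5)),
    )
    # isoforms: the full exon chain, plus exon-skipping variants
    n_iso = 1 + int(np.searchsorted(
        np.cumsum(cfg.isoforms_per_gene), rng.random()
    ))
    if n_ex < 3:
        n_iso = 1
    skippable = list(range(1, n_ex - 1))
    rng.shuffle(skippable)
    variants = [None] + skippable[: n_iso - 1]
    for k, skip in enumerate(variants):
        ex = [e for i, e in enumerate(exons) if i != skip]
        chain = tuple((a[1], b[0]) for a, b in zip(ex, ex[1:]))
        iso_exons = tuple(ex)
        site_tx = tuple(_local_to_tx(iso_exons, s) for s in sites)
        gene.isoforms.append(
            _Isoform(
                transcript_id=f"{gene_id}.t{k + 1}",
                chain_local=chain,
                exons_local=iso_exons,
                site_tx=site_tx,
                expression=float(rng.lognormal(0.0, cfg.expression_sigma)),
            )
        )
    return gene


# -- read construction -----------------------------------------------------

def _class_probs(cfg: SimConfig):
    names = ["TRUNC", "INS", "CLIP3", "POLYA_FAIL", "POLYA_MISSING",
             "SPLICE_ERR", "RETAINED", "REALIGN_CLIP"]
    probs = [cfg.truncation_prob, cfg.frac_insertion, cfg.frac_softclip,
             cfg.frac_polya_fail, cfg.frac_polya_missing, cfg.frac_splice_err,
             cfg.retained_intron_frac, cfg.frac_realign_clip]
    names.append("CLEAN")
    probs.append(1.0 - sum(probs))
    return names, np.array(probs)


def _read_blocks(gene: _Gene, iso: _Isoform, start_tx: int, end_tx: int,
                 retained_intron=None):
    """Local-coordinate blocks for transcript interval [start_tx, end_tx].

    A negative start extends the first exon upstream into the promoter pad
    (contiguous sequence).  `retained_intron` merges blocks across one
    intron of the isoform chain.
    """
    exons = iso.exons_local
    if start_tx < 0:
        p0 = exons[0][0] + start_tx
        start_tx = 0
    else:
        p0 = _tx_to_local(exons, start_tx)
    p1 = _tx_to_local(exons, end_tx)
    blocks = []
    for s, e in exons:
        if e <= p0 or s > p1:
            continue
        blocks.append((max(s, p0), min(e, p1 + 1)))
    if blocks and p0 < exons[0][0]:
        blocks[0] = (p0, blocks[0][1])
    if retained_intron is not None:
        s_i, e_i = retained_intron
        merged = []
        for b in blocks:
            if merged and merged[-1][1] == s_i and b[0] == e_i:
                merged[-1] = (merged[-1][0], b[1])
            else:
                merged.append(list(b))
        blocks = [tuple(b) for b in merged]
    return [tuple(b) for b in blocks]


def _apply_splice_jitter(blocks, sd, rng, limit=14):
    if sd <= 0 or len(blocks) < 2:
        return blocks
    out = [list(b) for b in blocks]
    for i in range(len(out) - 1):
        for side in (0, 1):
            j = int(round(rng.normal(0.0, sd)))
            j = max(-limit, min(limit, j))
            if side == 0:
                out[i][1] += j
            else:
                out[i + 1][0] += j
    # keep blocks valid after jitter
    for i in range(len(out)):
        if out[i][1] - out[i][0] < 5:
            out[i][1] = out[i][0] + 5
        if i and out[i][0] <= out[i - 1][1]:
            out[i][0] = out[i - 1][1] + 1
    return [tuple(b) for b in out]


@dataclass
class SimTruth:
    reads: pd.DataFrame
    isoforms: pd.DataFrame
    sites: pd.DataFrame


@dataclass
class SimResult:
    genome_fasta: Path
    annotation_gff3: Path
    reads_bed12: Path
    reads_sam: Path
    polya_tsv: Path
    truth: SimTruth
    config: SimConfig


def simulate_dataset(cfg: SimConfig, outdir) -> SimResult:
    """Write a complete synthetic data set; deterministic under cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes: list[_Gene] = []
    total = cfg.n_genes
    if cfg.n_noncoding_genes + cfg.n_single_exon_genes >= total:
        raise ValueError("special gene counts exceed n_genes")
    for i in range(total):
        coding = i >= cfg.n_noncoding_genes
        single = (
            cfg.n_noncoding_genes <= i < cfg.n_noncoding_genes + cfg.n_single_exon_genes
        )
        genes.append(
            _build_gene(
                f"gene{i + 1:03d}", "+" if i % 2 == 0 else "-", coding,
                coding and single, cfg, rng,
            )
        )
    # place genes on one chromosome with intergenic gaps
    chrom = "chrI"
    parts = []
    cursor = 0
    for g in genes:
        gap = "".join(rng.choice(_BASES, size=500))
        parts.append(gap)
        cursor += 500
        g.offset = cursor
        g.chrom = chrom
        s = "".join(g.seq_local)
        parts.append(s if g.strand == "+" else revcomp(s))
        cursor += g.local_len
    parts.append("".join(rng.choice(_BASES, size=500)))
    genome_seq = "".join(parts)
    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(genome_seq), 70):
            fh.write(genome_seq[i:i + 70] + "\n")
    # annotation
    models = []
    iso_by_id = {}
    for g in genes:
        for iso in g.isoforms:
            exons_g = tuple(sorted(g.interval_to_genomic(s, e)
                                   for s, e in iso.exons_local))
            cds_within = []
            for s, e in g.cds_local:
                # CDS segments of this isoform: restrict to its exons
                for xs, xe in iso.exons_local:
                    a, b = max(s, xs), min(e, xe)
                    if a < b:
                        cds_within.append(g.interval_to_genomic(a, b))
            shared = rng.random() < 0.5
            t = TranscriptModel(
                transcript_id=iso.transcript_id,
                gene_id=g.gene_id,
                chrom=g.chrom,
                strand=g.strand,
                exons=exons_g,
                cds=tuple(sorted(cds_within)),
            )
            t.stop_segments = t.derive_stop_from_cds()
            if t.introns:
                if shared:
                    t.intron_evidence = tuple(
                        frozenset({f"EST_{iso.transcript_id}"})
                        for _ in t.introns
                    )
                else:
                    t.intron_evidence = tuple(
                        frozenset({f"EST_{iso.transcript_id}_{i}"})
                        for i in range(len(t.introns))
                    )
            models.append(t)
            iso_by_id[iso.transcript_id] = (g, iso, t)
    gff = outdir / "annotation.gff3"
    write_gff3(models, gff)
    # expression-weighted read allocation
    iso_ids = sorted(iso_by_id)
    weights = np.array([iso_by_id[i][1].expression for i in iso_ids])
    p_iso = weights / weights.sum()
    expected_reads = p_iso * cfg.n_reads
    class_names, class_p = _class_probs(cfg)
    iso_choice = rng.choice(len(iso_ids), size=cfg.n_reads, p=p_iso)
    class_choice = rng.choice(len(class_names), size=cfg.n_reads, p=class_p)
    read_rows = []
    bed_lines = []
    sam_lines = []
    polya_rows = []
    for ridx in range(cfg.n_reads):
        tid = iso_ids[int(iso_choice[ridx])]
        g, iso, model = iso_by_id[tid]
        cls = class_names[int(class_choice[ridx])]
        if cls == "SPLICE_ERR" and not iso.chain_local:
            cls = "CLEAN"
        if cls == "RETAINED" and not iso.chain_local:
            cls = "CLEAN"
        rid = f"read{ridx + 1:06d}"
        si = int(rng.choice(len(g.sites_local), p=np.array(g.site_weights)))
        site_tx = iso.site_tx[si]
        jitter = int(round(rng.normal(0.0, cfg.end_jitter_sd))) if cfg.end_jitter_sd > 0 else 0
        end_tx = max(10, min(site_tx + jitter, site_tx + 40))
        start_tx = int(rng.integers(cfg.tss_jitter[0], cfg.tss_jitter[1] + 1))
        if cls == "TRUNC":
            hi = max(17, min(cfg.truncation_length[1], end_tx - 120))
            lo = min(max(16, cfg.truncation_length[0]), hi)
            start_tx = int(rng.integers(lo, hi + 1))
        retained_intron = None
        if cls == "RETAINED":
            k = int(rng.integers(0, len(iso.chain_local)))
            retained_intron = iso.chain_local[k]
        aligned_end_tx = end_tx
        clip_seq = ""
        if cls == "REALIGN_CLIP":
            k = cfg.realign_match_len
            aligned_end_tx = end_tx - k
            matched = "".join(
                g.seq_local[_tx_to_local(iso.exons_local, aligned_end_tx) + 1:
                            _tx_to_local(iso.exons_local, aligned_end_tx) + 1 + k]
            )
            clip_seq = matched + "CCCCCC"
        elif cls == "CLIP3":
            clip_seq = "".join(rng.choice(_BASES, size=25))
        blocks_local = _read_blocks(g, iso, start_tx, aligned_end_tx,
                                    retained_intron)
        if cls != "SPLICE_ERR":
            blocks_local = _apply_splice_jitter(
                blocks_local, cfg.splice_jitter_sd, rng
            )
        else:
            k = int(rng.integers(0, len(blocks_local) - 1))
            shift = int(rng.integers(16, 31))
            b = list(blocks_local[k])
            b[1] += shift  # donor pushed into the intron
            blocks_local = blocks_local[:k] + [tuple(b)] + blocks_local[k + 1:]
        blocks_g = sorted(g.interval_to_genomic(s, e) for s, e in blocks_local)
        ins_len = 25 if cls == "INS" else 0
        # truth bookkeeping
        expected = CLASS_STAGE[cls]
        if expected == "PASS" and not g.coding:
            expected = "THREE_PRIME"
        site_g = g.local_to_genomic(g.sites_local[si])
        if g.coding:
            utr_len = g.sites_local[si] - (g.stop_local + 2)
        else:
            utr_len = 150
        qc_tag = "PASS"
        if cls == "POLYA_FAIL":
            qc_tag = _POLYA_FAIL_TAGS[int(rng.integers(0, 3))]
        tail = (
            cfg.tail_mu0
            + cfg.tail_beta_expr * np.log10(max(expected_reads[int(iso_choice[ridx])], 1.0))
            + cfg.tail_beta_utr * np.log10(max(utr_len, 10))
            + (cfg.tail_delta_retained if cls == "RETAINED" else 0.0)
            + rng.normal(0.0, cfg.tail_sigma)
        )
        tail = float(max(cfg.tail_floor, tail))
        read_rows.append({
            "read_id": rid, "transcript_id": tid, "gene_id": g.gene_id,
            "chrom": g.chrom, "strand": g.strand, "feature_class": cls,
            "expected_stage": expected, "site_id": f"{g.gene_id}.s{si + 1}",
            "true_site": site_g,
            "true_end3": g.local_to_genomic(
                _tx_to_local(iso.exons_local, end_tx)
            ),
            "aligned_end3": g.local_to_genomic(
                _tx_to_local(iso.exons_local, aligned_end_tx)
            ),
            "tail_length": round(tail, 2), "qc_tag": qc_tag,
            "utr_length": utr_len,
            "retained": cls == "RETAINED",
        })
        # BED12
        start, end = blocks_g[0][0], blocks_g[-1][1]
        sizes = ",".join(str(e - s) for s, e in blocks_g) + ","
        offs = ",".join(str(s - start) for s, e in blocks_g) + ","
        bed_lines.append(
            f"{g.chrom}\t{start}\t{end}\t{rid}\t0\t{g.strand}\t{start}\t{end}"
            f"\t0,0,0\t{len(blocks_g)}\t{sizes}\t{offs}"
        )
        # SAM
        sam_lines.append(
            _sam_line(rid, g, blocks_g, clip_seq, ins_len, genome_seq, rng)
        )
        if cls != "POLYA_MISSING":
            polya_rows.append(
                f"{rid}\t{g.chrom}\t{start}\t0.0\t10.0\t20.0\t80.0\t100.0"
                f"\t{tail:.2f}\t{qc_tag}"
            )
    bed = outdir / "reads.bed12"
    bed.write_text("\n".join(bed_lines) + "\n")
    sam = outdir / "reads.sam"
    with open(sam, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{chrom}\tLN:{len(genome_seq)}\n")
        fh.write("\n".join(sam_lines) + "\n")
    polya = outdir / "polya.tsv"
    with open(polya, "w") as fh:
        fh.write("\t".join(
            ("readname", "contig", "position", "leader_start", "adapter_start",
             "polya_start", "transcript_start", "read_rate", "polya_length",
             "qc_tag")
        ) + "\n")
        fh.write("\n".join(polya_rows) + "\n")
    reads_df = pd.DataFrame(read_rows)
    iso_rows = []
    for tid in iso_ids:
        g, iso, model = iso_by_id[tid]
        iso_rows.append({
            "transcript_id": tid, "gene_id": g.gene_id, "chrom": g.chrom,
            "strand": g.strand, "coding": g.coding,
            "expression": iso.expression,
            "n_reads": int((reads_df["transcript_id"] == tid).sum()),
            "chain": ";".join(
                f"{a}-{b}" for a, b in
                sorted(g.interval_to_genomic(s, e) for s, e in iso.chain_local)
            ),
        })
    site_rows = []
    for g in genes:
        for si, s_loc in enumerate(g.sites_local):
            sid = f"{g.gene_id}.s{si + 1}"
            site_rows.append({
                "site_id": sid, "gene_id": g.gene_id, "chrom": g.chrom,
                "strand": g.strand, "site": g.local_to_genomic(s_loc),
                "pas_type": g.site_pas[si][0],
                "hexamer": g.site_pas[si][1] or "",
                "stop_pos": (
                    g.local_to_genomic(g.stop_local) if g.coding else -1
                ),
                "utr_length": (
                    s_loc - (g.stop_local + 2) if g.coding else -1
                ),
                "coding": g.coding,
            })
    truth = SimTruth(
        reads=reads_df,
        isoforms=pd.DataFrame(iso_rows),
        sites=pd.DataFrame(site_rows),
    )
    truth.reads.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
    truth.isoforms.to_csv(outdir / "truth_isoforms.tsv", sep="\t", index=False)
    truth.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    return SimResult(
        genome_fasta=fasta, annotation_gff3=gff, reads_bed12=bed,
        reads_sam=sam, polya_tsv=polya, truth=truth, config=cfg,
    )


def _sam_line(rid, g: _Gene, blocks_g, clip_seq_tx, ins_len, genome_seq, rng):
    """One SAM record; CIGAR and sequence kept mutually consistent."""
    flag = 0 if g.strand == "+" else 16
    seq_parts = []
    cigar_parts = []
    ins_seq = "".join(rng.choice(_BASES, size=ins_len)) if ins_len else ""
    for i, (s, e) in enumerate(blocks_g):
        block_seq = genome_seq[s:e]
        if i == 0 and ins_len:
            mid = (e - s) // 2
            seq_parts.append(block_seq[:mid] + ins_seq + block_seq[mid:])
            cigar_parts.append(f"{mid}M{ins_len}I{e - s - mid}M")
        else:
            seq_parts.append(block_seq)
            cigar_parts.append(f"{e - s}M")
        if i < len(blocks_g) - 1:
            gap = blocks_g[i + 1][0] - e
            cigar_parts.append(f"{gap}N")
    body = "".join(seq_parts)
    cigar = "".join(cigar_parts)
    clip_ref = to_dna(clip_seq_tx)
    if clip_ref:
        if g.strand == "+":
            body = body + clip_ref
            cigar = cigar + f"{len(clip_ref)}S"
        else:
            body = revcomp(clip_ref) + body
            cigar = f"{len(clip_ref)}S" + cigar
    return (
        f"{rid}\t{flag}\t{g.chrom}\t{blocks_g[0][0] + 1}\t60\t{cigar}\t*\t0\t0"
        f"\t{body}\t*"
    )


# -- evaluation against truth ----------------------------------------------

def truth_eval(outcomes, iso_calls, utr_calls, truth: SimTruth,
               tolerance: int = 10) -> dict:
    """Recovery metrics for a pipeline run against planted truth.

    Site recall counts planted cleavage sites with >= 3 expected-passing
    reads that are matched by a called site within `tolerance` nt; site
    precision counts called sites within `tolerance` of any planted site.
    Isoform recall counts planted isoforms with >= 1 expected-passing read
    whose (gene, junction chain) was called.  The stage table crosses
    expected against observed filter stages.
    """
    reads = truth.reads
    observed = {o.read_id: o.stage_reached for o in outcomes}
    obs_series = reads["read_id"].map(observed).fillna("ABSENT")
    stage_table = pd.crosstab(reads["expected_stage"], obs_series)
    exact = float((reads["expected_stage"] == obs_series).mean())
    # sites
    passing_reads = reads[reads["expected_stage"] == "PASS"]
    support = passing_reads.groupby("site_id").size()
    site_info = truth.sites.set_index("site_id")
    eligible_sites = [
        s for s in support.index
        if support[s] >= 3 and site_info.loc[s, "coding"]
    ]
    called_positions = sorted(c.site for c in utr_calls)
    called_arr = np.array(called_positions) if called_positions else np.empty(0)
    n_matched = 0
    for s in eligible_sites:
        pos = site_info.loc[s, "site"]
        if called_arr.size and np.min(np.abs(called_arr - pos)) <= tolerance:
            n_matched += 1
    site_recall = n_matched / len(eligible_sites) if eligible_sites else float("nan")
    planted_arr = np.array(sorted(truth.sites["site"]))
    n_good_calls = sum(
        1 for c in utr_calls
        if planted_arr.size and np.min(np.abs(planted_arr - c.site)) <= tolerance
    )
    site_precision = n_good_calls / len(utr_calls) if utr_calls else float("nan")
    # isoforms
    chains_called = {(c.gene_id, c.chain) for c in iso_calls}
    iso_truth = truth.isoforms.set_index("transcript_id")
    expected_iso = sorted(set(passing_reads["transcript_id"]))
    n_rec = 0
    for tid in expected_iso:
        row = iso_truth.loc[tid]
        chain = tuple(
            tuple(int(x) for x in part.split("-"))
            for part in str(row["chain"]).split(";") if part
        )
        if (row["gene_id"], chain) in chains_called:
            n_rec += 1
    iso_recall = n_rec / len(expected_iso) if expected_iso else float("nan")
    novel = sum(1 for c in iso_calls if c.novelty != "ANNOTATED")
    return {
        "stage_table": stage_table,
        "stage_exact_fraction": exact,
        "site_recall": site_recall,
        "site_precision": site_precision,
        "n_eligible_sites": len(eligible_sites),
        "isoform_recall": iso_recall,
        "n_expected_isoforms": len(expected_iso),
        "false_novelty_rate": novel / len(iso_calls) if iso_calls else 0.0,
    }
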