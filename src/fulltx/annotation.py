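"""Genome annotation model: transcripts, splice-site indices, TSS evidence.

Coordinates are 0-based half-open throughout (BED convention); GFF3 input
(1-based closed) is converted on load and converted back on write, bit-exactly.
Strand-aware quantities ("5' end", "upstream") are always in transcript
orientation: upstream of a minus-strand feature lies at larger genomic
coordinates.

A splice junction is represented by its intron as a genomic half-open
``(start, end)`` pair.  On the plus strand ``start`` is the donor coordinate
and ``end`` the acceptor; on the minus strand the roles swap.  Junction
chains are stored in ascending genomic order regardless of strand; helpers
below handle transcript-orientation suffixes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gffutils
import numpy as np
import pyfaidx
from intervaltree import IntervalTree

from .seq import revcomp

Junction = tuple[int, int]
Chain = tuple[Junction, ...]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


def chain_suffixes(chain: Chain, strand: str) -> list[Chain]:
    """All 5'-truncated suffixes of a junction chain, in transcript orientation.

    Includes the full chain, excludes the empty chain; for a chain of k
    junctions exactly k suffixes are returned.  Chains are stored in
    ascending genomic order, so a transcript-orientation suffix drops
    junctions from the left on '+' and from the right on '-'.
    """
    if strand == "+":
        return [chain[i:] for i in range(len(chain))]
    return [chain[: len(chain) - i] for i in range(len(chain))]


@dataclass
class TranscriptModel:
    """One annotated transcript: exon chain plus derived structure."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # sorted, non-overlapping, ascending
    cds: tuple[tuple[int, int], ...] = ()
    stop_segments: tuple[tuple[int, int], ...] = ()
    intron_evidence: tuple[frozenset, ...] = ()

    def __post_init__(self):
        self.exons = tuple(sorted(tuple(e) for e in self.exons))
        for (s, e) in self.exons:
            if not s < e:
                raise ValueError(f"{self.transcript_id}: bad exon [{s},{e})")
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if b >= c:
                raise ValueError(f"{self.transcript_id}: overlapping/abutting exons")
        if self.intron_evidence and len(self.intron_evidence) != len(self.introns):
            raise ValueError(f"{self.transcript_id}: evidence/intron count mismatch")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (a[1], b[0]) for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def chain(self) -> Chain:
        return self.introns

    @property
    def five_prime_end(self) -> int:
        """Genomic position of the annotated 5'-most transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime_end(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def stop_pos(self) -> int | None:
        """Strand-aware key position of the stop codon (its 5'-most base)."""
        if not self.stop_segments:
            return None
        if self.strand == "+":
            return self.stop_segments[0][0]
        return self.stop_segments[-1][1] - 1

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def derive_stop_from_cds(self) -> tuple[tuple[int, int], ...]:
        """3'-terminal 3 nt of the CDS, walking segments from the 3' end."""
        if not self.cds:
            return ()
        segs = sorted(self.cds)
        need, out = 3, []
        it = reversed(segs) if self.strand == "+" else iter(segs)
        for s, e in it:
            take = min(need, e - s)
            if self.strand == "+":
                out.append((e - take, e))
            else:
                out.append((s, s + take))
            need -= take
            if need == 0:
                break
        if need:
            return ()
        return tuple(sorted(out))


class SpliceSiteIndex:
    """Sorted canonical donor/acceptor positions plus annotated chains.

    The truncation set maps every transcript-orientation suffix of every
    annotated junction chain (full chain included, empty chain excluded) to
    the transcript ids it came from; it absolves 5'-truncated reads of
    novelty.
    """

    def __init__(self, transcripts: dict[str, TranscriptModel]):
        donors: dict = {}
        acceptors: dict = {}
        self.site_genes: dict = {}
        self.junction_genes: dict = {}
        self.chains: dict = {}
        self.truncations: dict = {}
        self.internal_exons: set = set()
        for t in transcripts.values():
            key = (t.chrom, t.strand)
            for (s, e) in t.introns:
                donor = s if t.strand == "+" else e
                acceptor = e if t.strand == "+" else s
                donors.setdefault(key, set()).add(donor)
                acceptors.setdefault(key, set()).add(acceptor)
                self.site_genes.setdefault(key + ("donor", donor), set()).add(t.gene_id)
                self.site_genes.setdefault(key + ("acceptor", acceptor), set()).add(
                    t.gene_id
                )
                self.junction_genes.setdefault(key + ((s, e),), set()).add(t.gene_id)
            ch = t.chain
            if ch:
                self.chains.setdefault(key + (ch,), set()).add(t.transcript_id)
                for suf in chain_suffixes(ch, t.strand):
                    self.truncations.setdefault(key + (suf,), set()).add(
                        t.transcript_id
                    )
                for (s1, e1), (s2, e2) in zip(ch, ch[1:]):
                    self.internal_exons.add(key + ((e1, s2),))
        self.donors = {k: np.array(sorted(v)) for k, v in donors.items()}
        self.acceptors = {k: np.array(sorted(v)) for k, v in acceptors.items()}

    def junction_gene_ids(self, chrom, strand, junction) -> frozenset:
        return frozenset(self.junction_genes.get((chrom, strand, junction), ()))

    def is_annotated_junction(self, chrom, strand, junction) -> bool:
        return (chrom, strand, junction) in self.junction_genes

    def matching_transcripts(self, chrom, strand, chain) -> frozenset:
        """Transcripts whose chain equals `chain` or has it as a 5' suffix."""
        return frozenset(self.truncations.get((chrom, strand, chain), ()))

    def nearest(self, kind: str, chrom: str, strand: str, pos: int):
        """Nearest canonical site of `kind`; ties -> smaller coordinate.

        Returns (site, distance) or None if no sites exist on that
        chrom/strand.
        """
        arr = (self.donors if kind == "donor" else self.acceptors).get(
            (chrom, strand)
        )
        if arr is None or len(arr) == 0:
            return None
        i = int(np.searchsorted(arr, pos))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(arr):
                site = int(arr[j])
                d = abs(site - pos)
                if best is None or d < best[1] or (d == best[1] and site < best[0]):
                    best = (site, d)
        return best


class TssEvidence:
    """Annotated 5' ends plus optional external TSS clusters and points.

    A read 5' end is supported if it lies within ``-window_lo..+window_hi``
    of an annotated 5' end (transcript orientation), inside any cluster
    interval, or within ``point_tolerance`` of a point TSS, on the matching
    strand.
    """

    def __init__(self, window_lo: int = 100, window_hi: int = 15,
                 point_tolerance: int = 10):
        if min(window_lo, window_hi, point_tolerance) < 0:
            raise ValueError("TSS window parameters must be >= 0")
        self.window_lo = window_lo
        self.window_hi = window_hi
        self.point_tolerance = point_tolerance
        self._annotated: dict = {}
        self._points: dict = {}
        self._clusters: dict = {}

    def add_annotated(self, chrom, strand, positions):
        key = (chrom, strand)
        prev = self._annotated.get(key, np.empty(0, dtype=int))
        self._annotated[key] = np.unique(
            np.concatenate([prev, np.asarray(list(positions), dtype=int)])
        )

    def add_points(self, chrom, strand, positions):
        key = (chrom, strand)
        prev = self._points.get(key, np.empty(0, dtype=int))
        self._points[key] = np.unique(
            np.concatenate([prev, np.asarray(list(positions), dtype=int)])
        )

    def add_cluster(self, chrom, strand, start, end):
        self._clusters.setdefault((chrom, strand), IntervalTree()).addi(start, end)

    def load_point_bed(self, path):
        """BED6 of point TSS calls (start used as the position)."""
        for chrom, start, _end, strand in _iter_bed6(path):
            self.add_points(chrom, strand, [start])

    def load_cluster_bed(self, path):
        for chrom, start, end, strand in _iter_bed6(path):
            self.add_cluster(chrom, strand, start, end)

    def _window_hit(self, arr, end5, strand) -> bool:
        # transcript orientation: upstream (window_lo) is lower coordinates
        # on '+', higher on '-'
        if strand == "+":
            lo, hi = end5 - self.window_hi, end5 + self.window_lo
        else:
            lo, hi = end5 - self.window_lo, end5 + self.window_hi
        i = np.searchsorted(arr, lo, side="left")
        j = np.searchsorted(arr, hi, side="right")
        return j > i

    def supports(self, chrom: str, strand: str, end5: int) -> bool:
        key = (chrom, strand)
        arr = self._annotated.get(key)
        if arr is not None and len(arr) and self._window_hit(arr, end5, strand):
            return True
        tree = self._clusters.get(key)
        if tree is not None and tree.overlaps(end5):
            return True
        pts = self._points.get(key)
        if pts is not None and len(pts):
            i = np.searchsorted(pts, end5 - self.point_tolerance, side="left")
            j = np.searchsorted(pts, end5 + self.point_tolerance, side="right")
            if j > i:
                return True
        return False


def _iter_bed6(path):
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) > 5 else "+"
            yield f[0], int(f[1]), int(f[2]), strand


class GenomeAnnotation:
    """Parsed annotation plus genome sequence and derived filter indices."""

    def __init__(self, transcripts: dict[str, TranscriptModel],
                 genome: pyfaidx.Fasta):
        self.transcripts = transcripts
        self.genome = genome
        self.genes: dict[str, list[str]] = {}
        for t in transcripts.values():
            self.genes.setdefault(t.gene_id, []).append(t.transcript_id)
        self.splice_index = SpliceSiteIndex(transcripts)
        self.tss = TssEvidence()
        for t in transcripts.values():
            self.tss.add_annotated(t.chrom, t.strand, [t.five_prime_end])
        # stop-codon segments, strand-aware
        self.stop_trees: dict = {}
        for t in transcripts.values():
            for (s, e) in t.stop_segments:
                self.stop_trees.setdefault((t.chrom, t.strand), IntervalTree()).addi(
                    s, e, t.transcript_id
                )
        # introns eligible for the retention test: annotated introns not fully
        # spanned by any annotated exon
        exon_trees: dict = {}
        for t in transcripts.values():
            for (s, e) in t.exons:
                exon_trees.setdefault(t.chrom, IntervalTree()).addi(s, e)
        self.retention_trees: dict = {}
        seen = set()
        for t in transcripts.values():
            tree = exon_trees.get(t.chrom, IntervalTree())
            for (s, e) in t.introns:
                k = (t.chrom, t.strand, s, e)
                if k in seen:
                    continue
                seen.add(k)
                spanned = any(iv.begin <= s and e <= iv.end for iv in tree.overlap(s, e))
                if not spanned:
                    self.retention_trees.setdefault(
                        (t.chrom, t.strand), IntervalTree()
                    ).addi(s, e, t.gene_id)
        # single-exon genes (every transcript has one exon), for unspliced
        # read assignment
        self.single_exon_trees: dict = {}
        for g, tids in self.genes.items():
            if all(len(transcripts[i].exons) == 1 for i in tids):
                t0 = transcripts[tids[0]]
                lo = min(transcripts[i].start for i in tids)
                hi = max(transcripts[i].end for i in tids)
                self.single_exon_trees.setdefault(
                    (t0.chrom, t0.strand), IntervalTree()
                ).addi(lo, hi, g)

    # -- sequence access ---------------------------------------------------
    def chrom_length(self, chrom: str) -> int:
        return len(self.genome[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        start = max(0, start)
        end = min(end, self.chrom_length(chrom))
        if end <= start:
            return ""
        return str(self.genome[chrom][start:end]).upper()

    def spliced_sequence(self, chrom: str, strand: str, blocks) -> str:
        s = "".join(self.fetch(chrom, b0, b1) for b0, b1 in blocks)
        return s if strand == "+" else revcomp(s)

    # -- queries -----------------------------------------------------------
    def overlaps_stop_codon(self, chrom, strand, blocks) -> bool:
        tree = self.stop_trees.get((chrom, strand))
        if tree is None:
            return False
        return any(tree.overlap(b0, b1) for b0, b1 in blocks)

    def retained_introns(self, chrom, strand, blocks):
        """Annotated retention-eligible introns fully inside a read block."""
        tree = self.retention_trees.get((chrom, strand))
        if tree is None:
            return []
        out = []
        for b0, b1 in blocks:
            for iv in tree.overlap(b0, b1):
                if b0 <= iv.begin and iv.end <= b1:
                    out.append((iv.begin, iv.end, iv.data))
        return out

    def single_exon_gene_overlaps(self, chrom, strand, start, end):
        tree = self.single_exon_trees.get((chrom, strand))
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}


def load_annotation(gff3_path, fasta_path, evidence_key: str = "evidence"
                    ) -> GenomeAnnotation:
    """Load a GFF3 + FASTA pair into a :class:`GenomeAnnotation`.

    Accepts gene/mRNA (or transcript)/exon/CDS records; explicit
    ``stop_codon`` features override the CDS-derived stop.  Per-intron
    EST/cDNA support is read from ``intron`` features carrying a
    comma-separated attribute named by `evidence_key`.
    """
    genome = pyfaidx.Fasta(str(fasta_path), as_raw=False)
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    transcripts: dict[str, TranscriptModel] = {}
    tx_types = {"mRNA", "transcript", "ncRNA"}
    for f in db.all_features():
        if f.featuretype not in tx_types:
            continue
        tid = f.id
        gene_id = (f.attributes.get("Parent") or [f.attributes.get("gene_id", [tid])[0]])[0]
        exons, cds, stops, intron_feats = [], [], [], []
        for c in db.children(tid):
            iv = (c.start - 1, c.end)  # GFF3 1-based closed -> half-open
            if c.featuretype == "exon":
                exons.append(iv)
            elif c.featuretype == "CDS":
                cds.append(iv)
            elif c.featuretype == "stop_codon":
                stops.append(iv)
            elif c.featuretype == "intron":
                ev = c.attributes.get(evidence_key, [])
                names = set()
                for item in ev:
                    names.update(x for x in item.split(",") if x)
                intron_feats.append((iv, frozenset(names)))
        if not exons:
            warnings.warn(f"transcript {tid} has no exons; skipped")
            continue
        if f.seqid not in genome.keys():
            raise ValueError(f"{tid}: chromosome {f.seqid} absent from FASTA")
        clen = len(genome[f.seqid])
        for s, e in exons:
            if s < 0 or e > clen:
                raise ValueError(
                    f"{tid}: exon [{s},{e}) outside {f.seqid} bounds (0,{clen})"
                )
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=gene_id,
            chrom=f.seqid,
            strand=f.strand,
            exons=tuple(sorted(exons)),
            cds=tuple(sorted(cds)),
        )
        t.stop_segments = tuple(sorted(stops)) or t.derive_stop_from_cds()
        if intron_feats:
            ev_by_intron = {iv: names for iv, names in intron_feats}
            t.intron_evidence = tuple(
                ev_by_intron.get(i, frozenset()) for i in t.introns
            )
        transcripts[tid] = t
    if not transcripts:
        raise ValueError(
            f"{gff3_path}: no transcript records found (malformed or empty GFF3)"
        )
    return GenomeAnnotation(transcripts, genome)


def write_gff3(transcripts, path, evidence_key: str = "evidence"):
    """Write transcripts back to GFF3 (coordinate round-trip is bit-exact)."""
    txs = list(transcripts.values()) if isinstance(transcripts, dict) else list(transcripts)
    genes: dict[str, list[TranscriptModel]] = {}
    for t in txs:
        genes.setdefault(t.gene_id, []).append(t)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(genes):
            ts = sorted(genes[gid], key=lambda t: t.transcript_id)
            g0 = min(t.start for t in ts)
            g1 = max(t.end for t in ts)
            t0 = ts[0]
            fh.write(
                f"{t0.chrom}\tfulltx\tgene\t{g0 + 1}\t{g1}\t.\t{t0.strand}\t.\t"
                f"ID={gid}\n"
            )
            for t in ts:
                fh.write(
                    f"{t.chrom}\tfulltx\tmRNA\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id};Parent={gid}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{t.chrom}\tfulltx\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                        f"Parent={t.transcript_id}\n"
                    )
                for s, e in t.cds:
                    fh.write(
                        f"{t.chrom}\tfulltx\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t0\t"
                        f"Parent={t.transcript_id}\n"
                    )
                for (s, e), ev in zip(
                    t.introns,
                    t.intron_evidence or [frozenset()] * len(t.introns),
                ):
                    attrs = f"Parent={t.transcript_id}"
                    if ev:
                        attrs += f";{evidence_key}=" + ",".join(sorted(ev))
                    fh.write(
                        f"{t.chrom}\tfulltx\tintron\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                        f"{attrs}\n"
                    )


def fulllength_supported_isoforms(ann: GenomeAnnotation) -> set:
    """Transcripts whose introns all share at least one EST/cDNA identifier.

    The universe excludes transcripts without annotated introns (single-exon
    genes and intron-less models carry no full-length evidence of this kind).
    """
    out = set()
    for t in ann.transcripts.values():
        if not t.introns:
            continue
        ev = t.intron_evidence or tuple(frozenset() for _ in t.introns)
        common = ev[0]
        for s in ev[1:]:
            common = common & s
        if common:
            out.add(t.transcript_id)
    return out


def restricted_isoform_universe(ann: GenomeAnnotation) -> set:
    """Annotated transcripts with at least one intron."""
    return {tid for tid, t in ann.transcripts.items() if t.introns}
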