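"""Read-alignment ingest and anchored 3' softclip realignment.

Direct RNA reads enter the pore 3' end first, so the poly(A)-proximal (3')
end of the molecule is the reference-right clip on '+' alignments and the
reference-left clip on '-' alignments.  All strand-aware fields below
("softclip3", "end3") follow transcript orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pysam

from .seq import revcomp

Junction = tuple[int, int]


@dataclass
class ReadAlignment:
    """One primary alignment of a long read.

    `blocks` are exonic segments in ascending genomic order; gaps between
    adjacent blocks are the splice junctions (N CIGAR ops, or BED12 block
    gaps).  `softclip3_original` preserves the pre-realignment clip, which
    gates UTR eligibility downstream.
    """

    read_id: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    softclip5: int = 0
    softclip3: int = 0
    softclip3_original: int = 0
    max_insertion: int = 0
    clip3_seq: str = ""  # 3' clipped bases, transcript orientation (5'->3')
    from_bam: bool = False

    def __post_init__(self):
        self.blocks = tuple((int(s), int(e)) for s, e in self.blocks)
        for (a, b), (c, d) in zip(self.blocks, self.blocks[1:]):
            if b >= c:
                raise ValueError(f"{self.read_id}: unsorted/overlapping blocks")

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def end5(self) -> int:
        """First aligned base at the 5' (cap-proximal) end."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def end3(self) -> int:
        """Final aligned base at the 3' (poly(A)-proximal) end."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def junctions(self) -> tuple[Junction, ...]:
        return tuple((a[1], b[0]) for a, b in zip(self.blocks, self.blocks[1:]))

    @property
    def spliced(self) -> bool:
        return len(self.blocks) > 1

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


def _from_cigar(rec: pysam.AlignedSegment) -> ReadAlignment:
    blocks: list[tuple[int, int]] = []
    pos = rec.reference_start
    cur = pos
    max_ins = 0
    left_clip = right_clip = 0
    seen_aligned = False
    for op, ln in rec.cigartuples:
        if op in (0, 7, 8):  # M, =, X
            cur += ln
            seen_aligned = True
        elif op == 2:  # D: reference gap inside a block
            cur += ln
        elif op == 3:  # N: splice junction -> close block
            blocks.append((pos, cur))
            pos = cur = cur + ln
        elif op == 1:  # I
            max_ins = max(max_ins, ln)
        elif op == 4:  # S
            if seen_aligned:
                right_clip = ln
            else:
                left_clip = ln
        # H (5) and P (6) consume nothing we track
    blocks.append((pos, cur))
    strand = "-" if rec.is_reverse else "+"
    seq = rec.query_sequence or ""
    if strand == "+":
        sc5, sc3 = left_clip, right_clip
        clip3 = seq[len(seq) - right_clip:] if right_clip and seq else ""
    else:
        sc5, sc3 = right_clip, left_clip
        clip3 = revcomp(seq[:left_clip]) if left_clip and seq else ""
    return ReadAlignment(
        read_id=rec.query_name,
        chrom=rec.reference_name,
        strand=strand,
        blocks=tuple(blocks),
        softclip5=sc5,
        softclip3=sc3,
        softclip3_original=sc3,
        max_insertion=max_ins,
        clip3_seq=clip3,
        from_bam=True,
    )


def read_alignments(path, skipped_counter: list | None = None):
    """Stream :class:`ReadAlignment` from BAM/SAM or BED12.

    Secondary and supplementary records are excluded; unmapped records and
    records whose CIGAR/sequence lengths disagree are skipped and counted in
    `skipped_counter` (a single-element list) when given.  BED12 input
    carries no CIGAR, so softclips and insertions are reported as 0.
    """
    path = str(path)
    if path.endswith((".bam", ".sam", ".cram")):
        mode = "rb" if path.endswith(".bam") else "r"
        with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                try:
                    if rec.query_sequence is not None and rec.infer_query_length() not in (
                        None, len(rec.query_sequence)
                    ):
                        raise ValueError("CIGAR/sequence length mismatch")
                    yield _from_cigar(rec)
                except ValueError:
                    if skipped_counter is not None:
                        skipped_counter[0] += 1
    else:
        yield from read_bed12(path)


def read_bed12(path):
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start = f[0], int(f[1])
            name, strand = f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = tuple(
                (start + o, start + o + sz) for o, sz in zip(starts, sizes)
            )
            yield ReadAlignment(
                read_id=name, chrom=chrom, strand=strand, blocks=blocks
            )


def write_bed12(records, path, rgb_by_name=None, default_rgb="0,0,0"):
    """Write alignments or (name, chrom, strand, blocks, thick) tuples as BED12.

    `rgb_by_name` maps record name -> "r,g,b" track colour (used to mark
    categories such as full-length-with-UTR vs UTR-less in browser tracks).
    """
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, ReadAlignment):
                name, chrom, strand, blocks = rec.read_id, rec.chrom, rec.strand, rec.blocks
                thick = None
            else:
                name, chrom, strand, blocks = rec[0], rec[1], rec[2], rec[3]
                thick = rec[4] if len(rec) > 4 else None
            start, end = blocks[0][0], blocks[-1][1]
            t0, t1 = thick if thick else (start, start)
            rgb = (rgb_by_name or {}).get(name, default_rgb)
            sizes = ",".join(str(e - s) for s, e in blocks) + ","
            offs = ",".join(str(s - start) for s, e in blocks) + ","
            fh.write(
                f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\t{t0}\t{t1}\t"
                f"{rgb}\t{len(blocks)}\t{sizes}\t{offs}\n"
            )


@dataclass(frozen=True)
class RealignmentScoring:
    """Affine-gap scores for the anchored 3'-clip realignment."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1
    window_margin: int = 50

    def __post_init__(self):
        if not (self.gap_open <= self.gap_extend <= 0 <= self.match):
            raise ValueError("require gap_open <= gap_extend <= 0 <= match")


def _anchored_semiglobal(query: str, target: str, sc: RealignmentScoring):
    """Best-scoring anchored prefix alignment of query vs target.

    The alignment is anchored at offset 0 of both sequences (no free leading
    gap); both trailing ends are free.  Returns (score, q_used, t_used):
    the number of query and target bases consumed by the best-scoring cell.
    Ties prefer fewer target bases consumed, then fewer query bases
    (conservative extension).
    """
    m, n = len(query), len(target)
    if m == 0 or n == 0:
        return 0, 0, 0
    NEG = -(10 ** 9)
    # H: best ending in match/mismatch; E: gap in target (query consumed);
    # F: gap in query (target consumed).  Affine: open applies at first gap
    # base.
    H = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    H[0, 0] = 0
    for i in range(1, m + 1):
        E[i, 0] = sc.gap_open + (i - 1) * sc.gap_extend
    for j in range(1, n + 1):
        F[0, j] = sc.gap_open + (j - 1) * sc.gap_extend
    for i in range(1, m + 1):
        qi = query[i - 1]
        for j in range(1, n + 1):
            s = sc.match if qi == target[j - 1] else sc.mismatch
            H[i, j] = max(H[i - 1, j - 1], E[i - 1, j - 1], F[i - 1, j - 1]) + s
            E[i, j] = max(H[i - 1, j] + sc.gap_open, E[i - 1, j] + sc.gap_extend)
            F[i, j] = max(H[i, j - 1] + sc.gap_open, F[i, j - 1] + sc.gap_extend)
    best = (0, 0, 0)
    for i in range(m + 1):
        for j in range(n + 1):
            score = int(max(H[i, j], E[i, j], F[i, j]))
            if i == j == 0:
                score = 0
            cand = (score, i, j)
            if score > best[0] or (
                score == best[0] and (j < best[2] or (j == best[2] and i < best[1]))
            ):
                best = cand
    return best


def realign_3prime_softclip(read: ReadAlignment, annotation,
                            scoring: RealignmentScoring | None = None
                            ) -> ReadAlignment:
    """Extend the 3'-terminal block by realigning clipped bases downstream.

    A semiglobal affine-gap alignment anchored at the read's current 3'
    terminus aligns the clipped suffix against the genomic window
    immediately downstream (transcript orientation), up to
    ``softclip3 + window_margin`` nt, truncated at the chromosome end.  The
    terminal block absorbs the aligned span; the unaligned clip suffix
    remains as the residual softclip3.  `softclip3_original` is preserved.
    Never moves end3 upstream and never touches other blocks.
    """
    scoring = scoring or RealignmentScoring()
    if read.softclip3 <= 0 or not read.clip3_seq:
        return read
    clip = read.clip3_seq.upper()
    wlen = len(clip) + scoring.window_margin
    if read.strand == "+":
        w0 = read.end
        w1 = min(w0 + wlen, annotation.chrom_length(read.chrom))
        window = annotation.fetch(read.chrom, w0, w1)
    else:
        w1 = read.start
        w0 = max(0, w1 - wlen)
        window = revcomp(annotation.fetch(read.chrom, w0, w1))
    if not window:
        return read
    score, q_used, t_used = _anchored_semiglobal(clip, window, scoring)
    if score <= 0 or t_used == 0:
        return read
    blocks = list(read.blocks)
    if read.strand == "+":
        s, e = blocks[-1]
        blocks[-1] = (s, e + t_used)
    else:
        s, e = blocks[0]
        blocks[0] = (s - t_used, e)
    return replace(
        read,
        blocks=tuple(blocks),
        softclip3=len(clip) - q_used,
        clip3_seq=clip[q_used:],
    )
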