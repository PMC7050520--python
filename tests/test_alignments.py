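"""Alignment ingest (CIGAR/BED12) and anchored 3'-clip realignment."""

import numpy as np
import pytest

from fulltx.alignments import (
    ReadAlignment,
    RealignmentScoring,
    _anchored_semiglobal,
    read_alignments,
    read_bed12,
    realign_3prime_softclip,
    write_bed12,
)
from fulltx.seq import revcomp



def make_sam(tmp_path, records, chrom="chrT", length=5000):
    path = tmp_path / "reads.sam"
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\n")
        fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for rec in records:
            fh.write(rec + "\n")
    return path


def test_cigar_parsing_plus_strand(tmp_path):
    seq = "A" * 225
    sam = make_sam(tmp_path, [f"r1\t0\tchrT\t101\t60\t10S90M5I100M20S\t*\t0\t0\t{seq}\t*"])
    (r,) = list(read_alignments(sam))
    assert r.softclip5 == 10
    assert r.softclip3 == 20
    assert r.max_insertion == 5
    assert r.blocks == ((100, 290),)


def test_cigar_junction_and_minus_strand_clip_orientation(tmp_path):
    # '-' strand: the 3' (poly(A)-proximal) clip is the reference-left clip,
    # and the stored clip sequence is its reverse complement
    clip = "ACGTT"
    body = "G" * 150
    sam = make_sam(
        tmp_path,
        [f"r2\t16\tchrT\t201\t60\t5S100M50N50M\t*\t0\t0\t{clip + body}\t*"],
    )
    (r,) = list(read_alignments(sam))
    assert r.strand == "-"
    assert r.blocks == ((200, 300), (350, 400))
    assert r.junctions == ((300, 350),)
    assert r.softclip3 == 5 and r.softclip5 == 0
    assert r.clip3_seq == revcomp(clip)
    assert r.end3 == 200 and r.end5 == 399


def test_bed12_block_arithmetic(tmp_path):
    bed = tmp_path / "r.bed"
    bed.write_text(
        "chrT\t1000\t1300\tr3\t0\t+\t1000\t1300\t0,0,0\t2\t100,100,\t0,200,\n"
    )
    (r,) = list(read_bed12(bed))
    assert r.blocks == ((1000, 1100), (1200, 1300))
    assert r.junctions == ((1100, 1200),)
    assert r.softclip3 == 0 and r.max_insertion == 0


def test_bed12_round_trip(tmp_path):
    r = ReadAlignment("rw", "chrT", "-", ((10, 50), (80, 120)))
    write_bed12([r], tmp_path / "o.bed")
    (back,) = list(read_bed12(tmp_path / "o.bed"))
    assert back.blocks == r.blocks and back.strand == "-"


def test_secondary_and_supplementary_excluded(tmp_path):
    sam = make_sam(
        tmp_path,
        [
            "p\t0\tchrT\t1\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*",
            "s\t256\tchrT\t1\t60\t50M\t*\t0\t0\t*\t*",
            "u\t2048\tchrT\t1\t60\t25M\t*\t0\t0\t" + "A" * 25 + "\t*",
        ],
    )
    assert [r.read_id for r in read_alignments(sam)] == ["p"]


class _FakeGenome:
    def __init__(self, seq, chrom="chrT"):
        self.seq = seq
        self.chrom = chrom

    def chrom_length(self, chrom):
        return len(self.seq)

    def fetch(self, chrom, start, end):
        return self.seq[max(0, start):min(end, len(self.seq))].upper()


def test_realign_perfect_match_extends_and_clears_clip():
    genome = _FakeGenome("A" * 100 + "ACGTACGT" + "T" * 100)
    read = ReadAlignment(
        "r", "chrT", "+", ((50, 100),), softclip3=8, softclip3_original=8,
        clip3_seq="ACGTACGT",
    )
    out = realign_3prime_softclip(read, genome)
    assert out.blocks == ((50, 108),)
    assert out.softclip3 == 0
    assert out.softclip3_original == 8


def test_realign_partial_match_leaves_residual_clip():
    # 8 matching bases then 12 poly(A)-like As absent from the genome:
    # end3 advances 8, residual clip 12
    genome = _FakeGenome("G" * 100 + "ACGTACGT" + "GGTGGTGGTGGTGGTGGTGGT" + "G" * 50)
    read = ReadAlignment(
        "r", "chrT", "+", ((50, 100),), softclip3=20, softclip3_original=20,
        clip3_seq="ACGTACGT" + "A" * 12,
    )
    out = realign_3prime_softclip(read, genome)
    assert out.blocks == ((50, 108),)
    assert out.softclip3 == 12


def test_realign_no_clip_is_identity():
    genome = _FakeGenome("A" * 200)
    read = ReadAlignment("r", "chrT", "+", ((50, 100),))
    assert realign_3prime_softclip(read, genome) is read


def test_realign_minus_strand_and_junction_preservation():
    up = "GGT" * 30
    seq = up + "TTAACC" + "C" * 200
    genome = _FakeGenome(seq)
    # '-' read: 3' end at genomic start; downstream = lower coordinates.
    # clip (transcript orientation) = revcomp of genome[84:90] = "TTAACC"
    clip = revcomp(seq[84:90])
    read = ReadAlignment(
        "r", "chrT", "-", ((90, 140), (170, 200)), softclip3=6,
        softclip3_original=6, clip3_seq=clip,
    )
    out = realign_3prime_softclip(read, genome)
    assert out.blocks == ((84, 140), (170, 200))
    assert out.junctions == read.junctions
    assert out.softclip3 == 0
    assert out.end3 == 84


def test_realign_never_moves_end3_upstream_random():
    rng = np.random.default_rng(5)
    bases = np.array(list("ACGT"))
    for _ in range(50):
        genome = _FakeGenome("".join(rng.choice(bases, size=400)))
        clip = "".join(rng.choice(bases, size=int(rng.integers(1, 20))))
        read = ReadAlignment(
            "r", "chrT", "+", ((100, 200),), softclip3=len(clip),
            softclip3_original=len(clip), clip3_seq=clip,
        )
        out = realign_3prime_softclip(read, genome)
        assert out.end3 >= read.end3
        assert out.blocks[0][0] == read.blocks[0][0]
        assert 0 <= out.softclip3 <= len(clip)


def _brute_force_anchored(query, target, sc):
    """Exponential-free oracle: plain DP without the affine bookkeeping,
    implemented independently with explicit gap-run scoring."""
    best = (0, 0, 0)
    m, n = len(query), len(target)
    # dynamic program over (i, j, state) with explicit recursion, memoized
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def score(i, j, state):
        # best score of an alignment consuming query[:i], target[:j],
        # ending in `state` (0 diag, 1 gap-in-target, 2 gap-in-query)
        if i == 0 and j == 0:
            return 0 if state == 0 else -(10 ** 9)
        cands = []
        if state == 0 and i > 0 and j > 0:
            s = sc.match if query[i - 1] == target[j - 1] else sc.mismatch
            cands += [score(i - 1, j - 1, st) + s for st in (0, 1, 2)]
        if state == 1 and i > 0:
            cands.append(score(i - 1, j, 0) + sc.gap_open)
            cands.append(score(i - 1, j, 1) + sc.gap_extend)
        if state == 2 and j > 0:
            cands.append(score(i, j - 1, 0) + sc.gap_open)
            cands.append(score(i, j - 1, 2) + sc.gap_extend)
        return max(cands) if cands else -(10 ** 9)

    for i in range(m + 1):
        for j in range(n + 1):
            s = max(score(i, j, st) for st in (0, 1, 2)) if (i or j) else 0
            if s > best[0]:
                best = (s, i, j)
    return best[0]


def test_anchored_dp_matches_independent_oracle():
    sc = RealignmentScoring()
    rng = np.random.default_rng(9)
    bases = np.array(list("ACGT"))
    for _ in range(30):
        q = "".join(rng.choice(bases, size=int(rng.integers(1, 12))))
        t = "".join(rng.choice(bases, size=int(rng.integers(1, 15))))
        got, _, _ = _anchored_semiglobal(q, t, sc)
        assert got == _brute_force_anchored(q, t, sc)


def test_scoring_validation():
    with pytest.raises(ValueError):
        RealignmentScoring(gap_open=-1, gap_extend=-2)
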