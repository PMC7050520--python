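"""Cleavage-site KDE calling, read assignment, PAS scan, UTR comparison."""

import numpy as np
import pytest

from fulltx.alignments import ReadAlignment
from fulltx.filtering import FilterOutcome
from fulltx.utr import (
    CANONICAL,
    NONE,
    CleavageSiteCall,
    KdeConfig,
    PasCall,
    UtrGroupKey,
    assign_reads_to_sites,
    call_cleavage_sites,
    call_pas,
    collapse_utr_records,
    compare_utr_sets,
    downstream_junctions,
    group_reads_for_utr,
    nucleotide_matrix,
    scan_pas,
    spliced_distance,
    transcript_to_genomic,
    upstream_spliced_window,
)

from conftest import two_exon_transcript

CFG = KdeConfig()


def _outcome(rid, end_blocks, stop_pos, strand="+", utr_eligible=True):
    read = ReadAlignment(rid, "chrT", strand, tuple(end_blocks))
    return FilterOutcome(
        rid, "PASS", read=read, gene_id="gA", utr_eligible=utr_eligible,
        stop_pos=stop_pos, stop_source="annotated",
    )


def test_transcript_to_genomic_both_strands():
    blocks = ((100, 200), (300, 400))
    assert transcript_to_genomic(blocks, "+", 0) == 100
    assert transcript_to_genomic(blocks, "+", 99) == 199
    assert transcript_to_genomic(blocks, "+", 100) == 300
    assert transcript_to_genomic(blocks, "-", 0) == 399
    assert transcript_to_genomic(blocks, "-", 100) == 199
    with pytest.raises(IndexError):
        transcript_to_genomic(blocks, "+", 200)


def test_grouping_by_stop_and_downstream_junctions():
    a = _outcome("a", [(100, 300)], stop_pos=150)
    b = _outcome("b", [(120, 300)], stop_pos=150)
    c = _outcome("c", [(100, 200), (250, 320)], stop_pos=150)  # UTR junction
    groups, n_excl = group_reads_for_utr([a, b, c])
    assert n_excl == 0
    keys = sorted(groups, key=lambda k: len(k.downstream_junctions))
    assert len(groups) == 2
    assert [len(groups[k]) for k in keys] == [2, 1]
    assert keys[1].downstream_junctions == ((200, 250),)


def test_grouping_excludes_non_utr_eligible_reads():
    a = _outcome("a", [(100, 300)], stop_pos=150)
    clipped = _outcome("x", [(100, 300)], stop_pos=150, utr_eligible=False)
    groups, n_excl = group_reads_for_utr([a, clipped])
    assert n_excl == 1
    assert sum(len(v) for v in groups.values()) == 1


def test_downstream_junction_selection_minus_strand():
    # on '-' the 3' side is at lower coordinates
    juncs = ((50, 80), (200, 250))
    assert downstream_junctions("-", 150, juncs) == ((50, 80),)
    assert downstream_junctions("+", 150, juncs) == ((200, 250),)


def test_kde_single_atom_three_reads():
    assert call_cleavage_sites([100, 100, 100], CFG) == [(100, 3)]


def test_kde_two_reads_insufficient_support():
    assert call_cleavage_sites([100, 100], CFG) == []


def test_kde_two_separated_clusters():
    ends = [100] * 3 + [130] * 3
    assert [s for s, _ in call_cleavage_sites(ends, CFG)] == [100, 130]


def test_kde_translation_invariance():
    rng = np.random.default_rng(2)
    ends = list(rng.integers(500, 560, size=12))
    base = call_cleavage_sites(ends, CFG)
    for shift in (-1000, 17, 100000):
        shifted = call_cleavage_sites([e + shift for e in ends], CFG)
        assert [(s - shift, n) for s, n in shifted] == base


def test_kde_minus_strand_single_site():
    assert call_cleavage_sites([200] * 4, CFG, strand="-") == [(200, 4)]


def test_assignment_distance_and_ties():
    sites = [(100, 5), (130, 3)]
    cfg = KdeConfig()
    # simple within-10 assignment and the 11-nt boundary
    assert assign_reads_to_sites([105], [(100, 5)], cfg) == [100]
    assert assign_reads_to_sites([111], [(100, 5)], cfg) == [None]
    # 115 is 15 from both sites: beyond the cutoff, unassigned
    assert assign_reads_to_sites([115], sites, cfg) == [None]
    # 108 is 8 from 100 and 8 from 116: tie goes to higher support
    tie_sites = [(100, 5), (116, 3)]
    assert assign_reads_to_sites([108], tie_sites, cfg) == [100]
    # equal support: tie goes to the 5'-most site (strand-aware)
    eq = [(100, 3), (116, 3)]
    assert assign_reads_to_sites([108], eq, cfg, strand="+") == [100]
    assert assign_reads_to_sites([108], eq, cfg, strand="-") == [116]


def test_scan_pas_offsets_and_priority():
    u = ["G"] * 60  # positions -60..-1
    u[60 - 19:60 - 13] = "AATAAA"
    got = scan_pas("".join(u))
    assert got == PasCall(CANONICAL, "AAUAAA", 19)
    assert scan_pas("G" * 60).pas_type == NONE
    # canonical at -40 beats a closer alternative at -19
    u2 = ["G"] * 60
    u2[60 - 40:60 - 34] = "AATAAA"
    u2[60 - 19:60 - 13] = "AATGAA"
    got2 = scan_pas("".join(u2))
    assert got2.hexamer == "AAUAAA" and got2.offset == 40


def test_scan_pas_inner_loop_prefers_3prime_most():
    u = ["G"] * 60
    u[60 - 50:60 - 44] = "AATAAA"
    u[60 - 19:60 - 13] = "AATAAA"
    assert scan_pas("".join(u)).offset == 19


def test_call_pas_uses_spliced_coordinates(make_ann):
    seq = list("G" * 5000)
    # hexamer split by an intron (960, 980): AATAA ends exon, A resumes
    seq[955:960] = "AATAA"
    seq[980] = "A"
    t = two_exon_transcript(exons=((900, 960), (980, 1100)))
    ann = make_ann([t], {"chrT": "".join(seq)})
    key = UtrGroupKey("gA", "chrT", "+", stop_pos=910,
                      downstream_junctions=((960, 980),))
    got = call_pas(ann, key, site=1000)
    assert got.pas_type == CANONICAL and got.offset == 25
    # the unspliced genomic window does not contain the canonical hexamer
    # (the broken junction leaves AATAAG, an alternative signal)
    flat = UtrGroupKey("gA", "chrT", "+", stop_pos=910,
                       downstream_junctions=())
    assert call_pas(ann, flat, site=1000).pas_type != CANONICAL


def test_upstream_window_minus_strand(make_ann):
    seq = ["G"] * 5000
    # hexamer start (5'-most base in transcript orientation) at genomic
    # 2006, 19 nt upstream of the site at 1987
    seq[2001:2007] = "TTTATT"  # revcomp = AATAAA
    t = two_exon_transcript(strand="-", exons=((1900, 2300),))
    ann = make_ann([t], {"chrT": "".join(seq)})
    w = upstream_spliced_window(ann, "chrT", "-", 1987, (), 61)
    assert w.endswith("C" * 10)  # G background reads as C on '-'
    got = scan_pas(w[:-1])
    assert got.pas_type == CANONICAL and got.offset == 19


def test_spliced_utr_length_subtracts_introns():
    assert spliced_distance("+", 100, 200, ()) == 98
    assert spliced_distance("+", 100, 200, ((120, 150),)) == 68
    assert spliced_distance("-", 200, 100, ()) == 98
    assert spliced_distance("-", 200, 100, ((150, 180),)) == 68


def _site_call(site, pas, chrom="chrT", strand="+", stop=None):
    key = UtrGroupKey("gA", chrom, strand,
                      stop_pos=stop if stop is not None else site - 100,
                      downstream_junctions=())
    return CleavageSiteCall(
        utr_id=f"u{site}", site=site, group=key, read_ids=set(),
        n_support_window=3, pas=pas,
    )


def test_nucleotide_matrix_point_mass_and_normalization(make_ann):
    seq = ["G"] * 5000
    seq[1000 - 19:1000 - 13] = "AATAAA"  # hexamer start 19 nt before site
    t = two_exon_transcript(exons=((800, 1200),))
    ann = make_ann([t], {"chrT": "".join(seq)})
    call = _site_call(1000, PasCall(CANONICAL, "AAUAAA", 19))
    mat, pos = nucleotide_matrix([call], ann, "PAS_MINUS_19", window=(-25, 5))
    assert np.allclose(mat.sum(axis=0), 1.0)
    cols = {p: mat[:, i] for i, p in enumerate(pos)}
    for off, base_row in zip(range(-19, -13), [0, 0, 3, 0, 0, 0]):
        assert cols[off][base_row] == 1.0


def test_nucleotide_matrix_uniform_background(make_ann):
    rng = np.random.default_rng(31)
    seq = "".join(rng.choice(np.array(list("ACGT")), size=60000))
    t = two_exon_transcript(exons=((10, 59990),))
    ann = make_ann([t], {"chrT": seq})
    calls = [
        _site_call(int(s), PasCall(NONE))
        for s in rng.integers(200, 59000, size=600)
    ]
    mat, _ = nucleotide_matrix(calls, ann, "CLEAVAGE_0", window=(-30, 5))
    assert np.allclose(mat.sum(axis=0), 1.0)
    assert np.abs(mat - 0.25).max() < 0.09


def test_compare_utr_sets_boundaries():
    ours = [("chrT", "+", 100, 200)]
    assert len(compare_utr_sets(ours, [("chrT", "+", 100, 210)])["matched"]) == 1
    assert len(compare_utr_sets(ours, [("chrT", "+", 100, 211)])["matched"]) == 0
    # stop codons must match identically
    assert len(compare_utr_sets(ours, [("chrT", "+", 101, 200)])["matched"]) == 0


def test_collapse_never_increases_count():
    calls = [
        _site_call(200, PasCall(NONE), stop=100),
        _site_call(200, PasCall(NONE), stop=100),
        _site_call(300, PasCall(NONE), stop=100),
    ]
    assert len(collapse_utr_records(calls)) <= len(calls)
    assert len(collapse_utr_records(calls)) == 2
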