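"""3'-UTR cleavage-site calling, PAS classification, and UTR comparisons.

Read 3' ends are grouped by putative stop codon and any splice junctions
downstream of it; within a group a Gaussian kernel density (sigma = 10 nt
on a 1-nt grid) over the end positions is scanned for local maxima, and a
maximum with at least three read ends within 10 nt becomes a cleavage-site
call.  The 60 nt of spliced sequence upstream of each site is scanned for
polyadenylation-signal hexamers in a fixed priority order (canonical
AAUAAA first); the hexamer list is user-replaceable, one hexamer per line,
priority = file order.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np

from .seq import to_dna, to_rna

# AAUAAA followed by common 1-2 nt variants; a stand-in priority order for
# the published C. elegans hexamer table, replaceable via load_hexamer_list.
DEFAULT_HEXAMERS = (
    "AAUAAA",
    "AAUGAA",
    "UAUAAA",
    "AAUACA",
    "AAUAUA",
    "AAUAAU",
    "AAUAAG",
    "AAUAAC",
    "AAUGGA",
    "AAGAAA",
    "ACUAAA",
    "CAUAAA",
    "GAUAAA",
    "UUUAAA",
    "AUUAAA",
    "AAUUAA",
)

CANONICAL_HEXAMER = "AAUAAA"
CANONICAL = "CANONICAL"
ALTERNATIVE = "ALTERNATIVE"
NONE = "NONE"


def load_hexamer_list(path):
    """One hexamer per line (RNA or DNA alphabet); priority = file order."""
    out = []
    with open(path) as fh:
        for line in fh:
            h = line.strip().upper()
            if not h or h.startswith("#"):
                continue
            if len(h) != 6:
                raise ValueError(f"not a hexamer: {h!r}")
            out.append(to_rna(h))
    return tuple(out)


@dataclass(frozen=True)
class KdeConfig:
    bandwidth: float = 10.0  # Gaussian sigma, nt
    grid_pad: int = 30  # grid extension beyond extreme ends (3 sigma)
    support_window: int = 10  # nt window for the >=3-read support rule
    assign_max_dist: int = 10  # nt: read end -> site assignment cutoff
    min_support: int = 3

    def __post_init__(self):
        if min(self.bandwidth, self.grid_pad, self.support_window,
               self.assign_max_dist) <= 0:
            raise ValueError("KDE parameters must be > 0")


@dataclass(frozen=True)
class PasCall:
    pas_type: str  # CANONICAL | ALTERNATIVE | NONE
    hexamer: str | None = None  # RNA notation
    offset: int | None = None  # hexamer start -> cleavage site, nt in [6,60]


@dataclass(frozen=True)
class UtrGroupKey:
    gene_id: str
    chrom: str
    strand: str
    stop_pos: int  # strand-aware 5'-most base of the stop codon
    downstream_junctions: tuple  # introns strictly 3' of the stop codon


@dataclass
class CleavageSiteCall:
    utr_id: str
    site: int
    group: UtrGroupKey
    read_ids: set
    n_support_window: int
    pas: PasCall | None = None
    utr_length_spliced: int | None = None
    utr_span: tuple | None = None  # (chrom, start, end, strand), splice-collapsed

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)


# -- coordinate helpers ----------------------------------------------------

def transcript_to_genomic(blocks, strand: str, t_index: int) -> int:
    """Genomic coordinate of transcript position `t_index` (0-based, 5'->3')."""
    if t_index < 0:
        raise IndexError(t_index)
    it = blocks if strand == "+" else reversed(blocks)
    off = t_index
    for s, e in it:
        size = e - s
        if off < size:
            return s + off if strand == "+" else e - 1 - off
        off -= size
    raise IndexError(f"transcript index {t_index} beyond spliced length")


def spliced_distance(strand: str, stop_pos: int, site: int, junctions) -> int:
    """Spliced 3'-UTR length: bases from just after the stop codon to the
    cleavage site inclusive, minus any intervening intron lengths."""
    if strand == "+":
        raw = site - stop_pos - 2
        introns = sum(e - s for s, e in junctions if s >= stop_pos + 3 and e <= site + 1)
    else:
        raw = stop_pos - 2 - site
        introns = sum(e - s for s, e in junctions if e <= stop_pos - 2 and s >= site)
    return max(0, raw - introns)


def downstream_junctions(strand: str, stop_pos: int, junctions) -> tuple:
    """Read junctions lying strictly 3' of the stop codon."""
    if strand == "+":
        return tuple(j for j in junctions if j[0] >= stop_pos + 3)
    return tuple(j for j in junctions if j[1] <= stop_pos - 2)


def upstream_spliced_window(ann, chrom: str, strand: str, pos: int,
                            junctions, n: int) -> str:
    """`n` exonic bases ending at (and including) `pos`, transcript
    orientation, skipping the given introns."""
    blocks = []
    need = n
    if strand == "+":
        cur = pos + 1  # exclusive
        for (s, e) in sorted(junctions, key=lambda j: -j[1]):
            if e > cur:
                continue
            take = min(need, cur - e)
            if take > 0:
                blocks.append((cur - take, cur))
                need -= take
            if need == 0:
                break
            cur = s
        if need > 0:
            blocks.append((max(0, cur - need), cur))
    else:
        cur = pos  # inclusive start
        for (s, e) in sorted(junctions):
            if s < cur:
                continue
            take = min(need, s - cur)
            if take > 0:
                blocks.append((cur, cur + take))
                need -= take
            if need == 0:
                break
            cur = e
        if need > 0:
            blocks.append((cur, cur + need))
    blocks = sorted(b for b in blocks if b[0] < b[1])
    return ann.spliced_sequence(chrom, strand, blocks)


# -- operations ------------------------------------------------------------

def group_reads_for_utr(passing_outcomes):
    """Partition UTR-eligible passing reads by (gene, stop codon, junctions
    downstream of the stop).  Returns (groups, n_excluded) where groups maps
    :class:`UtrGroupKey` -> list of (read_id, end3)."""
    groups: dict = {}
    n_excluded = 0
    for o in passing_outcomes:
        if not (o.passed and o.utr_eligible):
            n_excluded += 1
            continue
        if o.stop_pos is None:
            n_excluded += 1
            continue
        r = o.read
        key = UtrGroupKey(
            gene_id=o.gene_id,
            chrom=r.chrom,
            strand=r.strand,
            stop_pos=o.stop_pos,
            downstream_junctions=downstream_junctions(
                r.strand, o.stop_pos, r.junctions
            ),
        )
        groups.setdefault(key, []).append((o.read_id, r.end3))
    return groups, n_excluded


def call_cleavage_sites(end_positions, cfg: KdeConfig | None = None,
                        strand: str = "+"):
    """Cleavage-site candidates from a Gaussian KDE over read 3' ends.

    The density ``d(x) = sum_i exp(-(x - e_i)^2 / (2 sigma^2))`` is
    evaluated at every integer of the padded range; local maxima
    (strictly above the 5' neighbour, at least the 3' neighbour, so
    plateaus collapse to their 5'-most point) with at least
    ``min_support`` read ends within ``support_window`` nt are returned as
    ``(site, n_support)`` pairs in ascending genomic order.
    """
    cfg = cfg or KdeConfig()
    ends = np.asarray(list(end_positions), dtype=float)
    if ends.size == 0:
        return []
    oriented = ends if strand == "+" else -ends
    lo = int(np.floor(oriented.min())) - cfg.grid_pad
    hi = int(np.ceil(oriented.max())) + cfg.grid_pad
    grid = np.arange(lo, hi + 1)
    d = np.exp(
        -((grid[:, None] - oriented[None, :]) ** 2)
        / (2.0 * cfg.bandwidth ** 2)
    ).sum(axis=1)
    is_max = np.zeros(len(grid), dtype=bool)
    is_max[1:-1] = (d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])
    sites = []
    for x in grid[is_max]:
        gx = int(x) if strand == "+" else int(-x)
        n = int(np.sum(np.abs(ends - gx) <= cfg.support_window))
        if n >= cfg.min_support:
            sites.append((gx, n))
    sites.sort()
    return sites


def assign_reads_to_sites(ends, sites, cfg: KdeConfig | None = None,
                          strand: str = "+"):
    """Assign each read end to its nearest called site within the cutoff.

    `sites` are (position, support) pairs.  Distance ties between two sites
    go to the site with greater support, then to the 5'-most site.  Returns
    a list parallel to `ends` of site positions (or None).
    """
    cfg = cfg or KdeConfig()
    out = []
    for e in ends:
        best = None
        for pos, supp in sites:
            d = abs(e - pos)
            if d > cfg.assign_max_dist:
                continue
            # rank: smaller distance, then greater support, then 5'-most
            five_most = pos if strand == "+" else -pos
            rank = (d, -supp, five_most)
            if best is None or rank < best[0]:
                best = (rank, pos)
        out.append(None if best is None else best[1])
    return out


def scan_pas(upstream: str, hexamers=DEFAULT_HEXAMERS) -> PasCall:
    """Priority-ordered hexamer scan of the upstream window.

    `upstream` holds the bases immediately 5' of the cleavage site
    (transcript orientation, site itself excluded; at most 60 nt).  The
    outer loop runs over hexamers in priority order, the inner loop over
    window positions from the 3' end; the first hit wins, so a
    higher-priority hexamer beats a closer lower-priority one.  The offset
    reported is the distance from hexamer start to the cleavage site.
    """
    u = to_dna(upstream)
    n = len(u)
    for h in hexamers:
        hd = to_dna(h)
        best_u = u.rfind(hd)
        if best_u >= 0:
            offset = n - best_u
            hexamer = to_rna(h)
            pas_type = CANONICAL if hexamer == CANONICAL_HEXAMER else ALTERNATIVE
            return PasCall(pas_type=pas_type, hexamer=hexamer, offset=offset)
    return PasCall(pas_type=NONE)


def call_pas(ann, key: UtrGroupKey, site: int, hexamers=DEFAULT_HEXAMERS,
             pas_window: int = 60) -> PasCall:
    """PAS classification of one cleavage site (spliced coordinates)."""
    seq = upstream_spliced_window(
        ann, key.chrom, key.strand, site, key.downstream_junctions,
        pas_window + 1,
    )
    return scan_pas(seq[:-1], hexamers)


def call_utrs(passing_outcomes, ann, cfg: KdeConfig | None = None,
              hexamers=DEFAULT_HEXAMERS):
    """Full 3'-UTR calling: group, KDE, assign, classify PAS, measure.

    Returns (calls, assignment) where `assignment` maps read_id -> utr_id
    for every read end assigned to a called site.
    """
    cfg = cfg or KdeConfig()
    groups, _ = group_reads_for_utr(passing_outcomes)
    calls: list[CleavageSiteCall] = []
    assignment: dict = {}
    per_gene_counter: dict = {}
    for key in sorted(groups, key=lambda k: (k.chrom, k.gene_id, k.stop_pos,
                                             k.downstream_junctions)):
        members = groups[key]
        ends = [e for _, e in members]
        sites = call_cleavage_sites(ends, cfg, key.strand)
        if not sites:
            continue
        assigned = assign_reads_to_sites(ends, sites, cfg, key.strand)
        by_site: dict = {pos: set() for pos, _ in sites}
        for (rid, _), pos in zip(members, assigned):
            if pos is not None:
                by_site[pos].add(rid)
        for pos, supp in sites:
            per_gene_counter[key.gene_id] = per_gene_counter.get(key.gene_id, 0) + 1
            utr_id = f"{key.gene_id}.utr{per_gene_counter[key.gene_id]}"
            if key.strand == "+":
                span = (key.chrom, key.stop_pos + 3, pos + 1, key.strand)
            else:
                span = (key.chrom, pos, key.stop_pos - 2, key.strand)
            calls.append(
                CleavageSiteCall(
                    utr_id=utr_id,
                    site=pos,
                    group=key,
                    read_ids=by_site[pos],
                    n_support_window=supp,
                    pas=call_pas(ann, key, pos, hexamers),
                    utr_length_spliced=spliced_distance(
                        key.strand, key.stop_pos, pos, key.downstream_junctions
                    ),
                    utr_span=span,
                )
            )
            for rid in by_site[pos]:
                assignment[rid] = utr_id
    return calls, assignment


def nucleotide_matrix(calls, ann, anchor: str = "PAS_MINUS_19",
                      window=(-50, 10), pas_window: int = 60):
    """Per-position nucleotide frequencies around PAS or cleavage sites.

    `anchor` is ``PAS_MINUS_19`` (hexamer start pinned at -19, for
    canonical/alternative calls) or ``CLEAVAGE_0`` (cleavage site at 0, for
    no-PAS calls).  Returns (matrix, positions) where matrix is 4 x L in
    row order A, C, G, U and every column sums to 1 over the calls whose
    sequence covers it.
    """
    rmin, rmax = window
    length = rmax - rmin + 1
    counts = np.zeros((4, length))
    row = {"A": 0, "C": 1, "G": 2, "T": 3}
    for c in calls:
        if anchor == "PAS_MINUS_19":
            if c.pas is None or c.pas.offset is None:
                continue
            shift = c.pas.offset - 19  # plot r maps to actual r + shift
        elif anchor == "CLEAVAGE_0":
            shift = 0
        else:
            raise ValueError(f"unknown anchor {anchor!r}")
        lo_actual = rmin + shift
        hi_actual = rmax + shift
        # upstream (<=0) part comes from spliced sequence ending at the
        # site; downstream (>0) is untranscribed, taken from the genome
        n_up = max(0, -lo_actual) + 1
        up = upstream_spliced_window(
            ann, c.group.chrom, c.group.strand, c.site,
            c.group.downstream_junctions, n_up,
        )
        if c.group.strand == "+":
            down = ann.fetch(c.group.chrom, c.site + 1, c.site + 1 + max(0, hi_actual))
        else:
            from .seq import revcomp
            down = revcomp(
                ann.fetch(c.group.chrom, c.site - max(0, hi_actual), c.site)
            )
        seq = up + down  # index of actual position r: r - lo_actual (if covered)
        for i in range(length):
            r_actual = lo_actual + i
            idx = r_actual - (1 - len(up))  # up[0] is position 1-len(up)
            if 0 <= idx < len(seq):
                base = to_dna(seq[idx])
                if base in row:
                    counts[row[base], i] += 1
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(totals > 0, counts / totals, 0.0)
    return freq, np.arange(rmin, rmax + 1)


def utr_record(call: CleavageSiteCall):
    """Splice-collapsed (chrom, strand, stop_pos, end) comparison record."""
    return (call.group.chrom, call.group.strand, call.group.stop_pos, call.site)


def compare_utr_sets(ours, theirs, tol: int = 10):
    """Match UTRs across data sets: identical stop codon, ends within `tol`.

    Both inputs are iterables of (chrom, strand, stop_pos, end) records
    (see :func:`utr_record`); splice structure is already collapsed.
    Returns dict with matched / ours_only / theirs_only record lists.
    """
    theirs_by_stop: dict = {}
    for rec in theirs:
        theirs_by_stop.setdefault(rec[:3], []).append(rec)
    matched, ours_only = [], []
    matched_theirs = set()
    for rec in ours:
        cands = theirs_by_stop.get(rec[:3], [])
        hit = next((c for c in cands if abs(c[3] - rec[3]) <= tol), None)
        if hit is not None:
            matched.append((rec, hit))
            matched_theirs.add(hit)
        else:
            ours_only.append(rec)
    theirs_only = [r for r in theirs if r not in matched_theirs]
    return {"matched": matched, "ours_only": ours_only, "theirs_only": theirs_only}


def novel_utrs(ours, reference_sets, tol: int = 10):
    """Our UTR records matching none of the reference sets (novelty call)."""
    novel = list(ours)
    for ref in reference_sets:
        novel = compare_utr_sets(novel, ref, tol)["ours_only"]
    return novel


def collapse_utr_records(calls):
    """Distinct splice-collapsed records (never more than distinct calls)."""
    return sorted({utr_record(c) for c in calls})


def write_utr_bed(calls, path):
    """BED6+ with n_reads, pas_type, hexamer, offset extra columns."""
    with open(path, "w") as fh:
        for c in sorted(calls, key=lambda c: (c.group.chrom, c.utr_span[1])):
            chrom, s, e, strand = c.utr_span
            s, e = (s, e) if s < e else (e, s)
            pas = c.pas or PasCall(NONE)
            fh.write(
                f"{chrom}\t{s}\t{max(e, s + 1)}\t{c.utr_id}\t{c.n_reads}\t{strand}\t"
                f"{c.n_support_window}\t{pas.pas_type}\t{pas.hexamer or '.'}\t"
                f"{pas.offset if pas.offset is not None else '.'}\n"
            )
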