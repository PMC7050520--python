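# Methods

This note documents the models and procedures `fulltx` implements, the
parameters that matter, what the simulator does and does not emulate, and
the design choices made where the design was genuinely open.

## Coordinate and junction conventions

All coordinates are 0-based half-open (BED convention); GFF3 input is
converted on load and written back bit-exactly. A splice junction is its
intron, a genomic `(start, end)` pair; on the plus strand `start` is the
donor and `end` the acceptor, on the minus strand the roles swap.
Strand-aware notions ("5′ end", "upstream", "downstream of the stop
codon") always follow transcript orientation. Junction chains are stored
in ascending genomic order; 5′-truncation suffixes drop junctions from
the transcript-5′ side, so a chain of k junctions has exactly k suffixes
(the full chain included, the empty chain excluded).

## The full-length filter

Stages run in a fixed order; per-stage surviving counts are reported so
library quality can be audited. Thresholds (all configurable, echoed to
logs and the run-config JSON):

| parameter | default | role |
|---|---|---|
| max insertion | 20 nt | stage 1, poorly aligned internal exons |
| max 3′ softclip | 20 nt | stage 1, poorly aligned 3′ exons |
| poly(A) QC fail tags | READ_FAILED_LOAD, SUFFCLIP, NOREGION | stage 2 |
| TSS window | −100..+15 nt | stage 3, around annotated 5′ ends |
| point-TSS tolerance | 10 nt | stage 3, external TSS calls |
| splice tolerance | 15 nt | stage 4, snap distance to annotated sites |
| PAS window | 60 nt | stage 6, upstream hexamer scan |
| UTR-eligibility clip | 10 nt | max original 3′ softclip for UTR calling |

Reads absent from the tail table fail stage 2: with no signal-level tail
record there is no evidence the 3′ end is intact. Stage 4 assigns each
spliced read to the unique gene its snapped sites belong to; unspliced
reads are assigned by overlap with single-exon genes. An unspliced read
that cannot be assigned but fully spans an annotated intron is diverted
as intron retention (gene taken from the intron) rather than discarded —
otherwise such clearly retained molecules would be counted as splice
failures. Snap ties at exactly equal distance resolve to the smaller
genomic coordinate, deterministically.

### 3′ softclip realignment

The realignment step is a semiglobal affine-gap alignment of
the clipped 3′ bases against the genomic window immediately downstream
(window = clip length + 50 nt margin), *anchored*: the alignment must
start at offset 0 of both the clip and the window, with free gaps only at
the distal ends. Scores are +1 match, −1 mismatch, −2 gap open, −1 gap
extend; these values and the margin are declared defaults (the algorithm
class fixes none of them) and are configurable. The best-scoring cell
determines how far the terminal block extends and how much clip remains;
ties prefer the shortest extension. Realignment never moves the 3′ end
upstream and never touches non-terminal blocks. The original clip length
is preserved because UTR eligibility is judged on it, not on the
post-realignment residual.

## Cleavage-site calling

Within a group (gene, stop codon, junctions downstream of the stop) the
read 3′ ends `e_i` define a density d(x) = Σ_i exp(−(x−e_i)²/(2σ²)) with
σ = 10 nt, evaluated at every integer in the padded range (±30 nt = 3σ).
"Kernel width 10" is interpreted as the Gaussian σ on a 1-nt grid because
plotting-library bandwidth semantics vary by version; σ is declared and
tested against a dense-grid oracle. Local maxima must be strictly above
their 5′ neighbour and at least their 3′ neighbour, so plateaus collapse
to their 5′-most point, deterministically. A maximum is reported only
with ≥ 3 read ends within 10 nt; reads are then assigned to the nearest
site within 10 nt (distance ties → greater support, then 5′-most site).
Calls are invariant under translating all ends by a constant.

The putative stop codon for a read is the annotated stop it overlaps
(closest to its 3′ end if several); reads rescued at stage 6 by the
PAS+ORF route use their predicted ORF stop. Groups are keyed by genomic
stop-codon position, so isoforms sharing a stop pool their reads.

## PAS classification

The 60 nt of *spliced* sequence upstream of each cleavage site (junctions
inside the window are skipped; an open question resolved in favour of
spliced coordinates, since the signal functions on the transcript) is
scanned hexamer-by-hexamer in priority order, inner loop 3′→5′; the first
hit wins, so AAUAAA anywhere in the window always beats a closer
alternative hexamer. The default list is AAUAAA followed by common
1–2-nt variants; published hexamer tables can be substituted via a plain
text file (one hexamer per line, priority = file order). Offsets are
reported from hexamer start to cleavage site and lie in [6, 60].
Nucleotide-distribution matrices anchor canonical/alternative calls with
the hexamer start at −19 nt and no-PAS calls with the cleavage site at 0.

## Novelty classification

A chain is ANNOTATED if it equals an annotated chain or any 5′-truncation
suffix of one; else NOVEL_JUNCTION if some (donor, acceptor) pair is
nowhere annotated; else NOVEL_EXON if some internal exon (both boundaries
splice sites) is not an annotated internal exon; else NOVEL_COMBINATION.
Terminal exons cannot trigger NOVEL_EXON — their outer boundaries are TSS
and cleavage sites, not splice sites. When one chain matches several
annotated isoforms the assignment is ambiguous; all matching annotation
ids are recorded and the chain counted once.

## Poly(A) statistics

Only QC-PASS tail estimates enter analyses. Expression is proxied by
supporting-read count; regressions of per-isoform median tail on
log10(reads) and per-UTR median tail on log10(UTR length) use OLS and
require ≥ 10 reads per isoform/UTR. Distribution comparisons report
two-sided KS and Mann-Whitney U (exact enumeration for tie-free samples
with both n ≤ 20, tie-corrected normal approximation otherwise). PAS
usage across conditions is compared by Pearson χ² without continuity
correction, dropping zero-margin rows/columns. Splice–UTR coupling is a
per-gene Fisher exact test; r×c read-count tables are collapsed to 2×2
(top splice isoform vs rest × top UTR vs rest) to keep the test exact,
and p-values are Benjamini-Hochberg corrected — the correction method and
the r×c handling are this package's explicit choices.

The metagene profile accumulates coverage in spliced (exonic) coordinates
of each gene's longest transcript so introns do not dilute the gene body,
partitions it by CDS into 5′-UTR / body / 3′-UTR, rescales the regions to
20/60/20 bins (declared defaults; only the equal scaling is prescribed),
sums over genes and normalizes to 1. Saturation curves subsample reads
without replacement at given fractions with a seeded generator.

## The simulator

`fulltx.simulate` generates one toy chromosome carrying coding,
noncoding, and single-exon genes with 1–3 isoforms each (exon skipping
variants), planted cleavage sites, PAS hexamers 19 nt upstream of each
site, and per-read tail lengths following
tail ~ N(μ₀ + β_expr·log10(reads) + β_utr·log10(UTR length) +
δ_retained·retained, σ), floored at 10 nt
(defaults μ₀ = 45, β_expr = −5, β_utr = +8, δ_retained = +8, σ = 18 nt,
chosen to give tails with a median near 55 nt and relationships of the
sign and rough magnitude seen in real nematode dRNA-seq libraries).

Default scale is 50 genes and 20,000 reads — every code path exercised in
well under a minute on one CPU; tests use smaller instances of the same
conditions. The default artifact mix (30% 5′ truncation, σ = 2 nt splice
jitter truncated at ±14 nt, σ = 3 nt end jitter, 3% intron retention, 2%
large insertions, 2% large softclips, 5% QC failures or missing tail
records, 5% benign realignable 3′ clips) approximates a real library in
which roughly a third of aligned reads are not full length.

Design choices that make truth labels *exact* rather than probable:

- each read carries exactly one planted feature class, so the stage at
  which it should leave the filter is unambiguous;
- cleavage-site upstream windows are scrubbed of every listed hexamer
  before the intended one is planted, so PAS calls cannot be confounded
  by background sequence, and noncoding genes (the stage-6-failure
  class) deterministically lack both stop codons and PAS;
- the 60 nt beyond each terminal cleavage site is an A/C-free pattern so
  the planted adapter-like clip suffix ("CCCCCC") can never realign into
  it, making 3′-end recovery after realignment exact;
- splice jitter for reads labelled clean is truncated at ±14 nt (inside
  the 15-nt correction tolerance); the splice-error class shifts one
  site by 16–30 nt instead. Cleavage sites are spaced ≥ 80 nt so the
  60-nt PAS windows of neighbouring sites cannot interact.

What the simulator does **not** emulate: base-level sequencing errors
(mismatches inside aligned blocks), trans-splicing / splice-leader
structure, expression differences between conditions, multi-chromosome
genomes, and overlapping gene models. Passing tests therefore demonstrate
the pipeline's logic and numerics, not robustness to raw nanopore error
profiles — splice-site jitter and softclip artifacts stand in for the
aggregate effect of those errors on alignments.

The uniform-coverage metagene check uses reads planted exactly at the
annotated TSS: 5′-start spread inside the −100..+15 acceptance window is
legitimate full-length variation but produces a real coverage ramp over
the first transcript bases, which is not what that check measures. The
truncation check asserts monotone growth over the 5′-UTR and body bins
only, since the 3′-UTR bins are shaped by cleavage-site choice rather
than truncation.

## Known limitations

- Stage 6's ORF rescue accepts any complete ORF regardless of length, so
  short spurious ORFs suffice when a PAS is present; the
  procedure does the same, but a minimum-length option would be a
  reasonable hardening.
- Gene assignment ignores antisense overlap (strand must match) and
  cannot split chimeric reads.
- BED12 input carries no CIGAR, so the insertion filter is inactive and
  softclips are unobservable on that route; this is recorded in the
  filter report.
- The default alternative-hexamer list is a stand-in ordered by
  similarity to AAUAAA; analyses of PAS usage on real data should
  substitute a published, organism-specific table.
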