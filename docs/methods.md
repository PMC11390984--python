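# Methods

This note documents the models, rules and numerical choices implemented in
`dsbrepair`, in the package's own words.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and the cut-site convention

All coordinates are 0-based, half-open.  A cut site is an integer `c`
denoting a blunt cut between positions `c-1` and `c`.  Relative positions
have no zero: `+k` maps to `ref[c+k-1]` and `-k` to `ref[c-k]`, so the
±10 DSB-sequence window covers exactly the 20 reference nucleotides
`ref[c-10 : c+10]`, and each ±30 anchor covers 20 more on either side.

## Constructs and references

A construct is a DNA sequence with three ordered regions (Exon1, Intron,
Exon2), named cut sites, excluded intervals (e.g. the 55-bp branch-site
interval whose deletion produces the non-splicing control), and a primer
span.  Three references are derived per cut selection: the intact amplicon
(primer-span sequence), the gap-repaired amplicon (intact with `[cutA,
cutB)` removed), and the flipped amplicon (the inter-cut segment replaced
by its reverse complement — an involution, tested as such).  On-disk format
is FASTA plus a BED-like interval TSV and a YAML stanza for cut sites and
scalar metadata; both are 0-based half-open and diff-able.

Antisense constructs are stored in the sequenced orientation with an
`orientation` flag; classification always operates on the sequenced strand.

## Barcode scheme

Fragments carry NN + 4-nt code at the 5' end and code + NN at the 3' end.
A forward read must begin NN+code+*first-six* (the first six reference
nucleotides).  Because the 3' tag of an intron-retaining fragment lies
beyond a 150-nt read, reads longer than the 140-nt gate whose last 12 nt do
not contain the *last-six* hexamer skip the 3' check; all other reads must
end *last-six*+code+NN.  Reverse-strand reads are checked against the
reverse-complemented hexamers and codes (the self-consistent mirror of the
fragment model) and are reverse-complemented to forward orientation after
stripping, halving the downstream rule surface.  NN positions accept any
base.  One code is used at both ends by default; the 3' code is
independently configurable.

The built-in trimmer removes a 3' adapter at ≥90 % identity overlap and
then trims 3' bases below Q20.  Externally pre-trimmed FASTQ can be
ingested unchanged; parity is asserted on the barcode rules, not the
trimmer internals.

## Alignment and the NHEJ rule

Reads are aligned semi-globally: the read start is pinned to reference
position 0 (reads begin at the primer) and the read 3' end is free.  The
candidate path is produced by edlib (unit-cost edit distance); the package
then evaluates its own contract on the parsed match/mismatch/in/del runs
with an affine-style score (match +1, mismatch −4, gap −5 open −1/nt — a
short-read-aligner-like weighting under which one small in/del outranks two
substitutions).  Two canonicalisations correct unit-cost artifacts that an
affine-gap aligner would never emit: (1) if the substitution-only
representation of the read scores at least as well as the edit path, it is
adopted; (2) during realignment the candidate block shapes include every
sub-total of the path's in/del bases, so spurious insertion+deletion pairs
encoding substitutions or free-end slippage can collapse.  Reads are
rejected when alignment fails, when the first reference base is unaligned,
or when the score is below 0.5 × read length (a floor that rejects shuffled
sequence; verified on random reads).

Realignment then constructs candidates in which all in/del bases form one
consecutive block adjacent to or spanning the cut, scanning every placement
whose deletion touches the cut (a pure insertion sits exactly at the cut).
The best candidate (fewest mismatches, then best affine score, then
smallest cut distance) replaces the original alignment **iff its mismatch
count does not increase** — the acceptance rule, kept as a tested
invariant.  Reads whose final in/dels are consecutive and encapsulate the
cut are *NHEJ in/del*; reads with no in/dels are *error-free/uncut*;
substitutions are ignored throughout as sequencing error.  The minimum read
length is 130 nt for single-cut libraries and 50 nt for double-cut
libraries.

The exhaustive-placement candidate generator is one admissible realisation
of the realignment, validated against the acceptance rule and against an
independent all-placements oracle in the tests, not against any external
script.

## Microhomology pairs and MMEJ

A microhomology pair is two identical reference segments ≥ 3 bp, the
upstream one ending at or before the (upstream) cut, the downstream one
starting at or after the (downstream) cut, both inside the primer span and
outside excluded intervals (pairs overlapping the branch site are excluded
so catalogs are comparable between the splicing and deletion constructs).
Only maximal pairs are kept: extending both segments one base in either
direction must break the identity.  Enumeration scans, for each segment
offset `d`, the runs of equality between the sequence and itself shifted by
`d`; each run is exactly one maximal pair.  A brute-force (i, j, length)
oracle confirms agreement on hundreds of random sequences.

Pairs are categorised by the region holding each segment and the region 5'
of the cut (Exon1-Exon2, Exon1-Intron, Exon2-Exon1, Exon2-Intron, plus
same-exon categories for exon-internal gaps) and named
`<category-abbrev><ordinal>_<segment>`; a `strand_label` field and alias
table accommodate reverse-strand reporting conventions.

MMEJ detection is exact substring search of each *deletion signature*
(10-nt upstream flank + segment + 10-nt downstream flank, flanks truncated
at the primer span) over raw, barcode-stripped reads.  A signature that
also occurs in the intact amplicon — which happens exactly when flank
truncation at the primer boundary degenerates the junction context — cannot
distinguish an MMEJ product from an uncut molecule and is excluded from the
detection set (it stays in the catalog).  A read matching several
signatures counts once per pair but once in the MMEJ total; the denominator
is all barcode-accepted reads.  Reads classified MMEJ that also satisfy the
NHEJ rule (possible only for cut-proximal pairs) are assigned to MMEJ for
reporting, with the overlap frequency recorded separately so the category
partition still sums to one.

## Double-cut (gap) classification

Intron status is called by length: reads strictly longer than 130 nt are
*with intron* (intact: 229/253 bp sense/antisense-scale, 174/247 bp for the
deletion constructs; pop-out: ~118 bp — the filter separates the two
perfectly at zero error, which is asserted).  Shorter reads are pop-out
products: MMEJ first (signature match), otherwise NHEJ.  Flipped insertion
is detected independently by a 20-nt probe taken from the flipped reference
10 nt downstream of the upstream cut — i.e. the reverse complement of the
far end of the excised segment, placed so it falls early in the read; probe
diagnosticity (absence from the intact and gap-repaired references) is
enforced when the probe is built, and constructs are generated to satisfy
it.  For gaps internal to one exon the length rule is replaced by
best-of-three alignment against the intact / gap-repaired / flipped
references, with intact and flipped winners jointly reported as *segment
retention* and flipped winners also counted for the flip frequency.

Yeast-mode amplicons (425/392 bp with intron, 196 bp without) all exceed
the read length, so intron loss is called by the presence of any 20-mer of
the 3' exon.  R-TDR frequency is the fraction of reads containing the exact
spliced-junction sequence (the portion of the spliced product that fits the
read capture range); the package, like the underlying assay, cannot
distinguish R-TDR from error-free end joining of an already-spliced
template.

## DSB-sequence windows and graphs

From each NHEJ or error-free read the window is the read sequence aligned
to reference positions −10..+10, with insertions inside the window included
and substitutions masked back to the reference base.  Reads are discarded
unless both 20-nt anchors (−30..−11 and +11..+30) align with ≤ 1 mismatch
and no in/del; insertion points on a window/anchor boundary are assigned
deterministically (left anchor `(c-30, c-10]`, window `(c-10, c+10)`, right
anchor `[c+10, c+30)`).  Windows are merged per repeat by sequence
(frequencies summed; denominator: all barcode-accepted reads) and averaged
across repeats, with absent windows contributing zero; two sequencing runs
of the same libraries can be merged by concatenating reads and recomputing.

The variation-distance graph drops windows whose frequency is ≤ 1e-5 in at
least one repeat, places the reference window at y = 0, insertions at
y = +variation count and deletions at y = −count, with x by base-4
lexicographic fraction of the inserted sequence (A left, T right; dense
insertion levels ≥ 3 staggered deterministically across three sublines) or
by first-deleted position, and vertex radius affine in log10 mean
frequency.  Edges join windows differing by exactly one single-nucleotide
in/del (one sequence equals the other with one base removed; substitutions
are impossible after masking); the edge predicate is validated against an
LCS-based in/del-distance oracle.  Mixed insertion+deletion windows are
excluded from the layout and reported in a side table, since the layout
rules are defined only for pure types.  Comparison graphs take the union of
retained windows, colour by signed log10 ratio of mean frequencies (capped
at ±3; absence saturates) and size by the larger mean.  The position
histogram adds each deletion window's mean frequency to every deleted
position bin and each insertion window's to its junction bin, giving the
conservation identities asserted in the tests.

## Splicing classification

cDNA reads are aligned with a splice-aware single-gap model: reference
prefix + one gap ≥ 20 nt + reference suffix, anchored at position 0, read
3' end free; the gap is cheap regardless of length, and among
equal-mismatch placements canonical GT..AG boundaries are preferred (the
tie-break splice aligners use).  A gapped reading must beat the contiguous
one by more than two mismatches.  No event → non-spliced; an event whose
gap length equals the intron length → spliced (gap-length equality, per
the definition adopted here; a stricter positional mode is available);
events over other GT..AG intervals → alt-spliced; anything else →
non-canonical.  The 20-nt minimum separates splice gaps from NHEJ
deletions.  External splice-aware SAM (N or D cigar operations) can be
ingested instead; reads here span at most one junction, so the single-gap
model is not limiting for this amplicon design.

## Statistics

`mwu_exact` computes the two-tailed Mann-Whitney U with midranks for ties;
for pooled sizes ≤ 12 the p-value is exact, from full enumeration of all
C(n, n_a) group assignments, two-tailed by doubling the smaller tail and
capping at 1.  Complete separation of 4 vs 4 yields 2/70 ≈ 0.0286, printed
0.029 — the smallest attainable at this design size.  Ratio comparisons
form per-replicate ratios (replicates paired by library-ID order) before
the rank test.  Box summaries use type-7 (linear-interpolation) quartiles
and 1.5·IQR whiskers; repeat summaries report mean ± sample (n−1) SD,
conventional for N = 4 biological replicates.

## The synthetic-data generator

`make_construct` emits a random reporter with the study's structural
features: GT..AG intron, centred branch interval (default 55 bp; deleting
it yields the control construct with identical flanking sequence), cut
sites at the intron junctions (optionally offset into the exons — yeast
constructs use 6-nt offsets so the gap-repair junction differs from the
splice junction and R-TDR stays detectable) and inside Exon1.  Default
dimensions give the 229/174/118 length arithmetic; yeast dimensions
(exons 104+104, intron 217, 33-bp deletion variant) give 425/392/196.
Constructs are rejection-sampled deterministically until diagnostic: flip
probe absent from unbroken references, at least one detectable
microhomology pair per cut configuration, no spurious last-hexamer
occurrence in a truncated read's final 12 nt — properties the real
constructs have by design.

`simulate_reads` assigns one event per fragment by inverse-CDF over the mix
in sorted kind order from a single seeded generator (identical seeds give
byte-identical FASTQ), wraps the product in NN+code barcodes, truncates to
the read length (default 150), and applies a flat per-base substitution
error (each hit base becomes one of the three other bases).  Insertion
content is uniform over {A,C,G,T}^len unless given.  Paired mode emits the
reverse-complement mate.  The `noise` kind is the first reference hexamer
followed by random sequence: it passes the barcode gate and exercises the
aligner's score-floor rejection.  Not modelled: quality-score error
profiles, PCR duplicates/chimeras, indel sequencing errors.  Passing tests
therefore demonstrate correctness of the classification rules under
substitution-type noise, not robustness to every artifact of real
libraries.

Exact-substring detectors are attenuated by sequencing error: a planted
fraction `f` with an L-nt signature is recovered at `f·(1−e)^L` among
accepted reads, and short products additionally pass a second 10-base
barcode check.  The recovery tests therefore compare each recovered
frequency to its analytic expectation under the generative model, at
3-sigma binomial tolerance — the statistically correct oracle for a
known-biased estimator.

## Problem sizes

The acceptance script simulates 50,000-read libraries for the single- and
double-cut recovery checks, 20,000 reads for survival and R-TDR, and
16 × 2,000 reads for the ratio contrast; the analysis drivers use 24
libraries of 4,000 reads.  These sizes put binomial noise well inside the
tolerances while keeping a full run in the minutes range on one CPU.

## Known limitations

* Unit-cost candidate paths occasionally interact with substitution errors
  near true junctions so that a genuine NHEJ read fails encapsulation
  (~0.04 % of reads at 0.5 % error in the recovery simulations) — the
  mirror of the unclassified-read category real libraries exhibit.
* MMEJ detection is exact by definition; no fuzzy matching, no
  microhomologies with internal mismatches.
* The three-reference exon-internal mode decides by best affine score;
  near-tie reads (e.g. very short fragments) fall into an unclassified
  bucket rather than being forced into a category.
* Paired mates are processed independently and deduplicated by read id;
  no mate merging.
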