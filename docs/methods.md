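# Methods

This note documents the models, conventions and numerical choices behind
plastomekit, in the spirit of a methods supplement: what each component
assumes, which knobs matter, and what the synthetic data do and do not
emulate.

## Coordinates, circularity and the quadripartite frame

All coordinates are 0-based half-open internally; GenBank/GFF3 emission and
human-readable reports use 1-based inclusive coordinates. The circular
molecule is linearized at LSC base 1, so the regions tile the sequence in
the order LSC, IRa, SSC, IRb and the junction coordinates are the region
boundaries (J<sub>LB</sub> equals the genome length, i.e. position 0
circularly). A feature crossing the origin (trnH in the reference layout)
is stored as two intervals flagged `wraps_origin`; the pair is one
contiguous feature, not an exon/intron structure. Percentages in report
tables are rounded half-away-from-zero, to 1 decimal for composition and 2
decimals for PI%.

## IR detection

`detect_ir` anchors k-mers (default k = 21) of the sequence against its
reverse complement. A pairing of positions p and q with
s[q] = complement(s[p]) lies on the anti-diagonal d = p + q; anchors on one
anti-diagonal are chained, the chained extent is extended base-by-base, and
within the extent the longest window whose mismatch count stays within
`max_mismatch_frac` of its length is selected (enumeration over mismatch
boundaries, O(M²) in the number of mismatches). The default mismatch budget
is 0 because plastome IRs are typically deposited as identical copies; the
budget is configurable for accessions where the copies differ. For circular
records a second scan of the half-rotated sequence catches a pair flanking
the origin; a genome whose best IR cannot be represented without wrapping
in the LSC-first frame is reported as needing rotation rather than silently
re-framed. The longer inter-IR arc becomes the LSC. Ties between equally
long candidate pairs break toward the smaller IRa start; exactly equal arcs
are an error requiring explicit labels, since no majority rule can decide
them.

## SSR scanning

For each motif length m ∈ 1..6 the scanner finds maximal runs of
s[i] = s[i+m] (vectorized), converts each to whole-copy tandem runs, and
reports runs whose copy number reaches the cutoff (8/4/3/3/3/3 by default)
with a primitive motif (not a repetition of a shorter motif), taking the
motif as written at the leftmost position. Overlapping candidates of
different period — e.g. a homopolymer embedded in a dinucleotide run — are
resolved by keeping the longer total span (ties: shorter motif, then
leftmost). Compound SSRs are not merged. Genomic context (coding / intron /
intergenic) is assigned by majority base over a per-base class mask in
which exon bases win over intron bases, so a gene nested in another gene's
intron (matK in trnK) counts as coding; region (LSC/SSC/IR) is assigned by
majority base over the partition. Since every IR locus exists twice,
`collapse_ir=True` counts mirrored IR loci once; the flag is exposed on the
CLI because published SSR tallies are ambiguous about this accounting.

## Long repeats

The four repeat classes are gapless pairings of two loci: forward
(identity), reverse (reversal), complement (base complement), palindromic
(reverse complement). Identity is Hamming identity over the pairing —
deterministic, and easy to verify with an independent oracle — rather than
an edit-distance variant. A reported hit is a window on one
(anti-)diagonal satisfying: length ≥ `min_len` (default 30), identity ≥
`min_identity` (default 0.90), match at both endpoints, and, when the
window contains mismatches, terminal exact runs of at least 8 bp. The
terminal-run condition is what keeps a 29 bp exact duplicate from being
dragged over the 30 bp cutoff by chance single-base flank matches, while a
35 bp copy with three interior substitutions (identity 0.914) still
qualifies; 8 bp matches the scanner's lower bound on `min_len`. Windows
contained in a longer qualifying window are dropped and remaining overlaps
on a diagonal resolve to the longest window (ties: fewest mismatches, then
leftmost). Post-filters remove nested hits (both intervals inside another
hit's intervals) and low-complexity hits (an interval with ≥ 90% one
nucleotide). With a partition supplied, the genome-scale IR pair itself is
excluded (it is the quadripartite structure, not a "repeat"), and hits
lying with both intervals inside the IRs are deduplicated to one mirrored
representative. Candidate diagonals come from shared exact seeds (default
11 bp; any qualifying window contains an 8 bp terminal run, so a seed of
≤ 8 is exhaustive and the tests use 7–8 when comparing against the
brute-force oracle).

## In-silico PCR

The forward primer is matched on the plus strand, the reverse primer as its
reverse complement downstream; every pairing with product length between
the combined primer lengths and a cap (default 10 kb) is emitted. Product
length is the outer-coordinate distance including both primer footprints,
matching gel sizing. Default matching is exact; when mismatches are
allowed, the 3'-terminal three bases of each primer must still match
exactly, since 3' mismatches abolish extension. Circular templates allow
origin-spanning products (capped at one full circle). Whether a published
"about 550 bp" product includes primer footprints is not decidable from gel
data; the synthetic construct fixes 550 bp as the outer-coordinate length.

## Intron accounting and loss calls

Gene models are alternating exon/intron lengths. Trans-spliced rps12
records its trans junction as a `None` slot: the junction is not a cis
intron, so rps12 contributes one cis intron while clpP and ycf3 carry two.
When rebuilding models from evolved annotations, gaps over 10 kb in a
trans-spliced gene are classified as trans junctions (plastid cis introns
are < 3 kb). Intron presence/absence across taxa compares cis intron
counts against a reference taxon: fewer introns → `intron_loss`, gene
absent → `gene_loss`. Intron detection is annotation-based only; inferring
unannotated introns by spliced alignment is out of scope.

## Variability statistics

Gaps and N are missing data throughout: a column is conserved when all
non-missing tokens are identical (an all-missing column counts as
conserved), parsimony-informative when ≥ 2 states each occur in ≥ 2 taxa,
and missing leaves take the union of all four states in the Fitch pass.
Sequence identity (SI) is the mean over row pairs of the fraction of
identical positions among positions where neither row is gapped — the
definition chosen here because published tables do not state theirs.
CI and RI are computed over variable columns; per column, m = observed
states − 1, g = non-missing tokens − largest state frequency, s = Fitch
steps, and m ≤ s ≤ g always. RI is defined as 1 when Σg = Σm (no
homoplasy potential), and both indices are 1 for an invariant alignment.
The tree is user-supplied; absent one, a neighbor-joining topology from
uncorrected p-distances is used — full ML/Bayesian inference is out of
scope, and NJ on the identity-derived distances suffices for index
computation. Gene ranking sorts by PI% descending (ties: aligned length,
then name) and by default drops genes whose unaligned reference length is
≤ 200 bp; an unfiltered variant is provided because short genes (petL,
96 bp) can still rank among the most informative.

## Dot plot and inversion detection

Anchors are k-mers (default 21) occurring exactly once on the plus strand
of each sequence; forward and reverse-complement co-occurrences are emitted
separately, so the quadripartite IR contributes its expected anti-diagonal
anchors between collinear genomes while multi-copy repeat noise is
suppressed. Chaining is single-linkage along each (anti-)diagonal with a
positional gap tolerance of max(2k, 200) bp — one substitution erases k
consecutive anchors, so at percent-level divergence a tolerance of only 2k
fragments genuine blocks — and segments need ≥ 5 anchors. Inverted
segments of at least `min_block` (default 5,000 bp) are called inversions,
except segments lying inside the annotated/detected IRs of both genomes,
which are the quadripartite structure itself. Indel-free divergence keeps
every segment on a single diagonal; the generator introduces no indels, so
cross-diagonal chaining is not attempted.

## The synthetic-data generator

`PlastomeSpec` defaults to the reference layout: region sizes
86,315 / 26,577 / 18,491 / 26,577 bp; per-region GC targets 35.1% / 42.7% /
31.8%; the 112-name inventory with 17 IR-duplicated genes (7 tRNA, 4 rRNA,
6 protein including trans-spliced rps12); exact exon/intron lengths for
the 17 intron-bearing genes and for the genes whose lengths are published,
typical angiosperm values otherwise; and the canonical junction layout
(rps19 46 bp before J<sub>LA</sub>, ndhF 29 bp after J<sub>SA</sub>, ycf1
1,200 bp into IRb with a mirrored ψycf1 at J<sub>SA</sub>, trnH wrapping
the origin 8 bp into IRb). Backgrounds are sampled i.i.d. per region to
the GC target (re-drawn until within ±0.5%), IRb is written as the exact
reverse complement of IRa, and the four IR boundary flanks are edited so
chance complementarity cannot extend the planted IR by a base. The
background is then screened: accidental SSRs or ≥ 30 bp repeats outside
planted loci are destroyed by point edits (mirrored into the partner IR),
with a 1,000-edit budget after which survivors are listed as residual
features in the truth table instead of failing the run. Planted SSR and
repeat flanks are likewise edited so detected hits equal the planted
coordinates exactly. Everything is reproducible from the seed.

`evolve_taxa` walks a tree with branch lengths, applying an equal-rates
(Jukes–Cantor) substitution model — per site, p = ¾(1 − e^(−4/3·t·rate))
on a branch of length t. A single-parameter model suffices because no
reported quantity depends on rate-matrix richness; this is a documented
limitation, as are the absence of indels (alignments stay gap-free except
for loss events) and of rate heterogeneity across sites. Intron- and
gene-loss events apply once on the stem of the named clade as deletion
masks in ancestor coordinates, so per-gene alignments are emitted from the
known homology (deleted bases appear as gaps) and no realignment is ever
involved. Consequently, passing tests demonstrate correctness of the
detectors and statistics on idealized data — uniform composition within
regions, no gene conversion between IR copies, no rearrangements other
than those planted — not robustness to the full messiness of real
accessions.

## Problem sizes

The test suite exercises full-size (157,960 bp) genomes where layout
matters (census, junctions, composition, the 30 kb inversion) and 10–20 kb
genomes for seeded property sweeps: IR parameter recovery across 100 + 25
seeds, scanner/oracle equivalence on 40 × 2 kb (SSRs) and 12 × 400 bp
(long repeats, where the brute-force oracle is quadratic per diagonal),
20 PCR templates, 15 exhaustive Fitch comparisons on 4–6 taxa, and
5-replicate rate grids for the monotonicity checks. These sizes keep the
full suite under a minute while leaving every code path covered.

## Known limitations

- IR detection assumes the two copies are near-identical and disjoint;
  genomes with degraded or absent IRs yield an explicit "no IR" result.
- SSR scanning reports perfect repeats only; interrupted/compound SSRs are
  reported as separate runs.
- The long-repeat identity model is substitution-only (no indels within a
  repeat unit).
- The comparison report recomputes per-genome statistics from the single
  canonical code paths; it does not align genomes against each other.
- rps12's trans junction and the origin-wrapping trnH are handled
  structurally, but no other trans-spliced or origin-crossing genes are
  modeled by the default inventory.
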