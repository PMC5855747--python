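# plastomekit

Comparative analysis of plastid (chloroplast) genomes, built around the
standard workflow for characterizing a newly assembled plastome against its
relatives: quadripartite structure and inverted-repeat (IR) junction
dynamics, microsatellite (SSR) and long-repeat landscapes, exon/intron
accounting with in-silico PCR verification of intron loss, per-gene
variability ranking with parsimony indices, and whole-genome dot-plot
comparison. The reference layout throughout is the *Catha edulis* (qat)
plastome, GenBank KT861471, and its published comparison set
(*Euonymus japonicus*, *Hevea brasiliensis*, *Manihot esculenta*,
*Populus euphratica*, *Ricinus communis*, *Salix purpurea*,
*Viola seoulensis*).

It is intended for researchers doing organellar comparative genomics who
need the steps between an annotated assembly and the summary tables of a
plastome paper to be reproducible and testable.

## What it computes

A land-plant plastome is a circular molecule with the quadripartite layout
LSC + IRa + SSC + IRb, where IRb is the reverse complement of IRa. The four
junctions J<sub>LA</sub>, J<sub>SA</sub>, J<sub>SB</sub>, J<sub>LB</sub>
between single-copy regions and the IRs migrate over evolutionary time
("expansion/contraction"), truncating or duplicating boundary genes.
plastomekit detects the IR pair by k-mer anchoring of the sequence against
its own reverse complement, derives the partition, and reports each gene's
distance to (or extension past) each junction.

SSRs are maximal perfect tandem runs of a primitive 1–6 bp motif with
copy-number cutoffs 8 / 4 / 3 / 3 / 3 / 3 for mono- through hexanucleotide
motifs. Long repeats are maximal gapless locus pairs of ≥ 30 bp at ≥ 90%
Hamming identity in four classes — forward, reverse, complement,
palindromic — with nested and low-complexity hits removed and the
genome-scale IR pair itself excluded.

Per-gene variability uses aligned coding genes: a site is
parsimony-informative when at least two states each occur in at least two
taxa; with a tree (supplied, or neighbor-joining from p-distances), Fitch
small parsimony gives per-site step counts *s*, from which the consistency
index CI = Σm/Σs and retention index RI = (Σg−Σs)/(Σg−Σm) follow, where
*m* is the minimum conceivable and *g* the worst-case step count per site.

A synthetic-genome generator emits ground-truth plastomes (screened random
background, planted SSRs/repeats/primer constructs, full 112-gene inventory
with 17 IR-duplicated genes and trans-spliced rps12) and evolves taxon sets
along a known tree under an equal-rates substitution model, so every
detector can be scored against exact truth without downloading anything.

## Worked example

```bash
plastomekit simulate --seed 7 --out demo      # full-size synthetic plastome
plastomekit summarize demo/genome.gb | head -6
```

prints

```
region  length_bp  gc_percent  length_percent
LSC     86315      35.1        54.6
IRa     26577      42.8        16.8
SSC     18491      32.0        11.7
IRb     26577      42.8        16.8
```

i.e. the canonical 157,960 bp layout: the LSC is 54.6% of the genome, the
SSC 11.7%, and the two IRs together 33.6%. The gene census

```bash
plastomekit census demo/genome.gb | head -6
```

```
total_copies      129
distinct_names    112
duplicated_names  17
copies_protein    84
copies_rRNA       8
copies_tRNA       37
```

shows 129 gene copies from 112 distinct genes, 17 of them duplicated across
the IRs (84 protein-coding, 37 tRNA, 8 rRNA copies). The junction report
(`plastomekit junctions demo/genome.gb`) places rps19 46 bp before
J<sub>LA</sub>, ndhF 29 bp after J<sub>SA</sub>, ycf1 running 1,200 bp
across J<sub>SB</sub> into IRb with a mirrored ψycf1 fragment at
J<sub>SA</sub>, and trnH 8 bp into IRb at J<sub>LB</sub>. In-silico PCR
with the rps16 intron-flanking primer pair
(`plastomekit pcr demo/genome.gb --fwd ACTTCGTTTGAGACGGTGTG --rev AAAAACCCCGATTTCTTTGA`)
predicts a 550 bp exon-joined product — the gel signature of the lost
intron.

From Python, the same objects are available directly:

```python
from plastomekit import PlastomeSpec, generate_plastome, detect_ir, partition_from_ir

record, truth = generate_plastome(PlastomeSpec(seed=7))
pair = detect_ir(record)                 # IRPair(length=26577, mismatches=0)
part = partition_from_ir(record, pair)   # junctions at 86315/112892/131383/157960
```

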