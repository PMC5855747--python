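"""Published reference values for the *Catha edulis* plastome (GenBank
KT861471) and its comparison set.

These are the printed summary values from the deposited annotation and the
seven related plastomes used throughout comparative work on Celastraceae
(*Euonymus japonicus* KP189362, *Hevea brasiliensis*, *Manihot esculenta*,
*Populus euphratica* NC_024747, *Ricinus communis*, *Salix purpurea*
NC_026722, *Viola seoulensis*).  They drive the report-layer fixtures and
the default parameters of the synthetic-genome generator; sequence-level
data are not stored here.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Region sizes and GC content (bp; GC as percent) for the eight plastomes.
# ---------------------------------------------------------------------------

REGION_SIZES: dict[str, dict[str, int]] = {
    "C_edulis": {"LSC": 86315, "SSC": 18491, "IR": 26577, "total": 157960},
    "E_japonicus": {"LSC": 85941, "SSC": 18340, "IR": 26678, "total": 157637},
    "H_brasiliensis": {"LSC": 89209, "SSC": 18362, "IR": 26810, "total": 161191},
    "M_esculenta": {"LSC": 89295, "SSC": 18250, "IR": 26954, "total": 161453},
    "P_euphratica": {"LSC": 84888, "SSC": 16586, "IR": 27646, "total": 156766},
    "R_communis": {"LSC": 89651, "SSC": 18816, "IR": 27347, "total": 163161},
    "S_purpurea": {"LSC": 84452, "SSC": 16220, "IR": 27459, "total": 155590},
    "V_seoulensis": {"LSC": 85691, "SSC": 18008, "IR": 26404, "total": 156507},
}

REGION_GC: dict[str, dict[str, float]] = {
    "C_edulis": {"LSC": 35.1, "SSC": 31.8, "IR": 42.7, "total": 37.3},
    "E_japonicus": {"LSC": 35.1, "SSC": 31.8, "IR": 42.7, "total": 37.3},
    "H_brasiliensis": {"LSC": 33.2, "SSC": 29.5, "IR": 42.2, "total": 35.7},
    "M_esculenta": {"LSC": 33.3, "SSC": 29.6, "IR": 42.3, "total": 35.9},
    "P_euphratica": {"LSC": 34.5, "SSC": 30.6, "IR": 41.9, "total": 36.7},
    "R_communis": {"LSC": 33.3, "SSC": 29.5, "IR": 41.9, "total": 35.7},
    "S_purpurea": {"LSC": 34.4, "SSC": 31.0, "IR": 41.9, "total": 36.7},
    "V_seoulensis": {"LSC": 33.8, "SSC": 29.6, "IR": 42.6, "total": 36.3},
}

# Coding/non-coding class sizes (bp) for C. edulis.
CLASS_SIZES_C_EDULIS: dict[str, int] = {
    "protein": 78471,
    "tRNA": 2806,
    "rRNA": 9050,
    "intron": 18474,
    "intergenic": 49159,
}

# ---------------------------------------------------------------------------
# Gene inventory of the C. edulis plastome.
#
# Each entry: (name, category, region, segments, strand) where segments is a
# tuple of alternating exon/intron lengths (exon I, intron I, exon II, ...).
# Genes in region "IR" are present once in each inverted repeat.  Exact
# exon/intron lengths come from the deposited annotation where printed;
# remaining lengths are typical angiosperm plastome values (they matter only
# for synthetic-genome layout, not for any reported statistic).
# ---------------------------------------------------------------------------

GENE_INVENTORY: list[tuple[str, str, str, tuple[int, ...], str]] = [
    # --- LSC, in canonical order following the J_LB boundary ---
    ("psbA", "protein", "LSC", (1062,), "-"),
    ("trnK-UUU", "tRNA", "LSC", (29, 2495, 37), "-"),
    ("matK", "protein", "LSC", (1518,), "-"),
    ("rps16", "protein", "LSC", (258,), "-"),  # intron lost in Celastraceae
    ("trnQ-UUG", "tRNA", "LSC", (72,), "-"),
    ("psbK", "protein", "LSC", (186,), "+"),
    ("psbI", "protein", "LSC", (111,), "+"),
    ("trnS-GCU", "tRNA", "LSC", (88,), "-"),
    ("trnG-UCC", "tRNA", "LSC", (23, 761, 48), "+"),
    ("trnR-UCU", "tRNA", "LSC", (72,), "+"),
    ("atpA", "protein", "LSC", (1524,), "-"),
    ("atpF", "protein", "LSC", (396, 699, 159), "-"),
    ("atpH", "protein", "LSC", (246,), "-"),
    ("atpI", "protein", "LSC", (744,), "-"),
    ("rps2", "protein", "LSC", (711,), "-"),
    ("rpoC2", "protein", "LSC", (4185,), "-"),
    ("rpoC1", "protein", "LSC", (1632, 817, 441), "-"),
    ("rpoB", "protein", "LSC", (3213,), "-"),
    ("trnC-GCA", "tRNA", "LSC", (71,), "+"),
    ("petN", "protein", "LSC", (90,), "+"),
    ("psbM", "protein", "LSC", (105,), "-"),
    ("trnD-GUC", "tRNA", "LSC", (74,), "-"),
    ("trnY-GUA", "tRNA", "LSC", (84,), "-"),
    ("trnE-UUC", "tRNA", "LSC", (73,), "-"),
    ("trnT-GGU", "tRNA", "LSC", (72,), "+"),
    ("psbD", "protein", "LSC", (1062,), "+"),
    ("psbC", "protein", "LSC", (1422,), "+"),
    ("trnS-UGA", "tRNA", "LSC", (93,), "-"),
    ("psbZ", "protein", "LSC", (189,), "+"),
    ("trnG-GCC", "tRNA", "LSC", (71,), "+"),
    ("trnfM-CAU", "tRNA", "LSC", (74,), "-"),
    ("rps14", "protein", "LSC", (303,), "-"),
    ("psaB", "protein", "LSC", (2205,), "-"),
    ("psaA", "protein", "LSC", (2253,), "-"),
    ("ycf3", "protein", "LSC", (153, 727, 228, 731, 126), "-"),
    ("trnS-GGA", "tRNA", "LSC", (87,), "-"),
    ("rps4", "protein", "LSC", (606,), "-"),
    ("trnT-UGU", "tRNA", "LSC", (73,), "-"),
    ("trnL-UAA", "tRNA", "LSC", (37, 540, 50), "+"),
    ("trnF-GAA", "tRNA", "LSC", (73,), "+"),
    ("ndhJ", "protein", "LSC", (477,), "-"),
    ("ndhK", "protein", "LSC", (678,), "-"),
    ("ndhC", "protein", "LSC", (363,), "-"),
    ("trnV-UAC", "tRNA", "LSC", (37, 663, 39), "-"),
    ("trnM-CAU", "tRNA", "LSC", (73,), "+"),
    ("atpE", "protein", "LSC", (402,), "-"),
    ("atpB", "protein", "LSC", (1497,), "-"),
    ("rbcL", "protein", "LSC", (1428,), "+"),
    ("accD", "protein", "LSC", (1509,), "+"),
    ("psaI", "protein", "LSC", (111,), "+"),
    ("ycf4", "protein", "LSC", (555,), "+"),
    ("cemA", "protein", "LSC", (690,), "+"),
    ("petA", "protein", "LSC", (963,), "+"),
    ("psbJ", "protein", "LSC", (123,), "-"),
    ("psbL", "protein", "LSC", (117,), "-"),
    ("psbF", "protein", "LSC", (120,), "-"),
    ("psbE", "protein", "LSC", (252,), "-"),
    ("petL", "protein", "LSC", (96,), "+"),
    ("petG", "protein", "LSC", (114,), "+"),
    ("trnW-CCA", "tRNA", "LSC", (74,), "-"),
    ("trnP-UGG", "tRNA", "LSC", (74,), "-"),
    ("psaJ", "protein", "LSC", (135,), "+"),
    ("rpl33", "protein", "LSC", (201,), "+"),
    ("rps18", "protein", "LSC", (306,), "+"),
    ("rpl20", "protein", "LSC", (354,), "-"),
    ("clpP", "protein", "LSC", (231, 676, 291, 849, 69), "-"),
    ("psbB", "protein", "LSC", (1527,), "+"),
    ("psbT", "protein", "LSC", (108,), "+"),
    ("psbN", "protein", "LSC", (132,), "-"),
    ("psbH", "protein", "LSC", (222,), "+"),
    ("petB", "protein", "LSC", (6, 773, 642), "+"),
    ("petD", "protein", "LSC", (8, 784, 475), "+"),
    ("rpoA", "protein", "LSC", (1014,), "-"),
    ("rps11", "protein", "LSC", (417,), "-"),
    ("rpl36", "protein", "LSC", (114,), "-"),
    ("rps8", "protein", "LSC", (405,), "-"),
    ("rpl14", "protein", "LSC", (369,), "-"),
    ("rpl16", "protein", "LSC", (399, 1119, 9), "-"),
    ("rps3", "protein", "LSC", (648,), "-"),
    ("rpl22", "protein", "LSC", (399,), "-"),
    ("rps19", "protein", "LSC", (279,), "-"),  # last LSC gene, near J_LA
    # --- inverted repeat (annotated in IRa, mirrored into IRb) ---
    ("rpl2", "protein", "IR", (471, 648, 393), "-"),
    ("rpl23", "protein", "IR", (282,), "-"),
    ("trnI-CAU", "tRNA", "IR", (74,), "-"),
    ("ycf2", "protein", "IR", (6828,), "+"),
    ("trnL-CAA", "tRNA", "IR", (81,), "-"),
    ("ndhB", "protein", "IR", (756, 687, 777), "-"),
    ("rps7", "protein", "IR", (468,), "-"),
    # trans-spliced: 5' exon in the LSC, exons II/III (and intron II) in the
    # IRs; the None slot is the trans junction (placement is special-cased)
    ("rps12", "protein", "IR", (114, None, 27, 546, 231), "-"),
    ("trnV-GAC", "tRNA", "IR", (72,), "+"),
    ("rrn16", "rRNA", "IR", (1491,), "+"),
    ("trnI-GAU", "tRNA", "IR", (42, 939, 35), "+"),
    ("trnA-UGC", "tRNA", "IR", (38, 801, 35), "+"),
    ("rrn23", "rRNA", "IR", (2810,), "+"),
    ("rrn4.5", "rRNA", "IR", (103,), "+"),
    ("rrn5", "rRNA", "IR", (121,), "+"),
    ("trnR-ACG", "tRNA", "IR", (74,), "+"),
    ("trnN-GUU", "tRNA", "IR", (72,), "-"),
    # --- SSC, in order following J_SA ---
    ("ndhF", "protein", "SSC", (2232,), "-"),  # first SSC gene, near J_SA
    ("rpl32", "protein", "SSC", (180,), "+"),
    ("trnL-UAG", "tRNA", "SSC", (80,), "+"),
    ("ccsA", "protein", "SSC", (969,), "+"),
    ("ndhD", "protein", "SSC", (1503,), "-"),
    ("psaC", "protein", "SSC", (246,), "-"),
    ("ndhE", "protein", "SSC", (306,), "-"),
    ("ndhG", "protein", "SSC", (531,), "-"),
    ("ndhI", "protein", "SSC", (504,), "-"),
    ("ndhA", "protein", "SSC", (540, 1178, 573), "-"),
    ("ndhH", "protein", "SSC", (1182,), "-"),
    ("rps15", "protein", "SSC", (273,), "-"),
]

# Boundary-layout genes handled separately by the generator: trnH-GUG wraps
# the circular origin 8 bp into IRb; ycf1 runs from the SSC across J_SB into
# IRb (with a mirrored pseudogene fragment at J_SA); rps12 is trans-spliced
# with a 5' exon in the LSC and duplicated 3' exons in the IRs.
TRNH_LENGTH = 75
TRNH_IRB_OVERLAP = 8
YCF1_LENGTH = 5640
YCF1_IRB_OVERLAP = 1200
RPS19_JLA_GAP = 46
NDHF_JSA_GAP = 29
RPS12_5P_EXON = 114
RPS12_IR_SEGMENTS = (27, 546, 231)  # exon II, intron II, exon III

# Junction distances (bp) printed for the eight-species comparison: distance
# of rps19 to J_LA (gap or extension into IRa), of ndhF to J_SA, and of trnH
# to J_LB.
JUNCTION_DISTANCES: dict[str, dict[str, int]] = {
    "rps19_into_IRa": {"H_brasiliensis": 96, "M_esculenta": 186, "V_seoulensis": 67},
    "rps19_gap_J_LA": {"C_edulis": 46, "E_japonicus": 12, "S_purpurea": 202},
    "rpl22_into_IRa": {"P_euphratica": 50, "R_communis": 30},
    "ndhF_gap_J_SA": {
        "C_edulis": 29,
        "E_japonicus": 27,
        "H_brasiliensis": 28,
        "P_euphratica": 98,
        "R_communis": 19,
        "S_purpurea": 129,
        "V_seoulensis": 33,
    },
    "ndhF_into_IRa": {"M_esculenta": 26},
    "trnH_into_IRb": {"C_edulis": 8},
}

# Long-repeat counts (forward/palindromic/reverse classes) per genome.
REPEAT_COUNTS: dict[str, dict[str, int]] = {
    "E_japonicus": {"palindromic": 14, "forward": 19, "reverse": 8},
}
REPEAT_TOTALS: dict[str, int] = {
    "C_edulis": 8,
    "E_japonicus": 41,
    "H_brasiliensis": 29,
    "M_esculenta": 35,
    "P_euphratica": 20,
    "R_communis": 22,
    "S_purpurea": 10,
    "V_seoulensis": 10,
}

# SSR counts for C. edulis: by genomic context and by motif length.
SSR_CONTEXT_COUNTS: dict[str, int] = {"coding": 89, "intron": 34, "intergenic": 155}
SSR_MOTIF_COUNTS: dict[int, int] = {1: 165, 2: 43, 3: 65, 4: 3, 5: 1}
SSR_REGION_COUNTS: dict[str, int] = {"LSC": 195, "SSC": 36, "IR": 37}

# SSR copy-number cutoffs by motif length (SSR Hunter-style).
SSR_THRESHOLDS: dict[int, int] = {1: 8, 2: 4, 3: 3, 4: 3, 5: 3, 6: 3}

# rps16 intron-verification primer pair; the exon-joined amplicon in
# Celastraceae species is ~550 bp (outer-coordinate product).
RPS16_PRIMER_FORWARD = "ACTTCGTTTGAGACGGTGTG"
RPS16_PRIMER_REVERSE = "AAAAACCCCGATTTCTTTGA"
RPS16_AMPLICON_LENGTH = 550

# ---------------------------------------------------------------------------
# Per-gene variability statistics for the ten most informative coding genes
# (eight-taxon alignments): unaligned length in C. edulis, aligned length,
# conserved sites, parsimony-informative sites, PI%, CI, RI, SI.
# ---------------------------------------------------------------------------

VARIABILITY_ROWS: list[dict] = [
    {"gene": "matK", "length": 1518, "aligned": 1575, "conserved": 1028,
     "informative": 265, "pi_percent": 16.83, "ci": 0.82, "ri": 0.7, "si": 0.9},
    {"gene": "ycf1", "length": 5640, "aligned": 6327, "conserved": 3970,
     "informative": 1063, "pi_percent": 16.80, "ci": 0.82, "ri": 0.6, "si": 0.8},
    {"gene": "ccsA", "length": 969, "aligned": 987, "conserved": 689,
     "informative": 160, "pi_percent": 16.21, "ci": 0.84, "ri": 0.7, "si": 0.9},
    {"gene": "accD", "length": 1509, "aligned": 1401, "conserved": 242,
     "informative": 227, "pi_percent": 16.20, "ci": 0.83, "ri": 0.7, "si": 0.8},
    {"gene": "rps3", "length": 648, "aligned": 663, "conserved": 467,
     "informative": 107, "pi_percent": 16.14, "ci": 0.82, "ri": 0.7, "si": 0.9},
    {"gene": "ndhF", "length": 2232, "aligned": 2331, "conserved": 1606,
     "informative": 368, "pi_percent": 15.79, "ci": 0.81, "ri": 0.6, "si": 0.8},
    {"gene": "rps8", "length": 405, "aligned": 411, "conserved": 294,
     "informative": 64, "pi_percent": 15.57, "ci": 0.8, "ri": 0.7, "si": 0.9},
    {"gene": "rpl22", "length": 399, "aligned": 551, "conserved": 345,
     "informative": 82, "pi_percent": 14.88, "ci": 0.83, "ri": 0.6, "si": 0.7},
    {"gene": "petL", "length": 96, "aligned": 96, "conserved": 70,
     "informative": 14, "pi_percent": 14.58, "ci": 0.9, "ri": 0.8, "si": 0.9},
    {"gene": "ndhD", "length": 1503, "aligned": 1527, "conserved": 1116,
     "informative": 207, "pi_percent": 13.56, "ci": 0.82, "ri": 0.7, "si": 0.9},
]
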