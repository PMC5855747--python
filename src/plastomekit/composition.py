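"""Region and coding-class composition summaries and the gene census.

Reproduces the standard comparative-plastome report layer: per-region
lengths, GC content and length proportions; per-class (protein / tRNA /
rRNA / intron / intergenic) lengths; and the gene-copy census with
IR-duplication accounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import (
    GeneAnnotation,
    PlastomeRecord,
    RegionPartition,
    ValidationError,
    majority_region,
)

__all__ = [
    "gc_content",
    "round_half_away",
    "region_table",
    "composition_summary",
    "gene_census",
    "CompositionTable",
    "GeneCensus",
]


def gc_content(sequence: str) -> float:
    """G+C fraction of a sequence; N bases are excluded from the denominator.

    Raises ValueError on an empty or all-N sequence.
    """
    if not sequence:
        raise ValueError("gc_content of empty sequence is undefined")
    seq = sequence.upper()
    n_count = seq.count("N")
    denom = len(seq) - n_count
    if denom == 0:
        raise ValueError("gc_content undefined: sequence is all N")
    return (seq.count("G") + seq.count("C")) / denom


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of printed report tables)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass
class CompositionTable:
    """Per-region and per-class composition of one genome."""

    regions: pd.DataFrame  # region, length_bp, gc_percent, length_percent
    classes: pd.DataFrame  # class, length_bp, gc_percent, length_percent
    genome_length: int

    def validate(self) -> None:
        if int(self.regions["length_bp"].sum()) != self.genome_length:
            raise ValidationError("region lengths do not sum to genome length")
        if int(self.classes["length_bp"].sum()) != self.genome_length:
            raise ValidationError("class lengths do not sum to genome length")
        for df in (self.regions, self.classes):
            pct = df["length_percent"]
            if (pct < 0).any() or (pct > 100).any():
                raise ValidationError("percentage outside [0, 100]")
            if abs(pct.sum() - 100.0) > 0.3:
                raise ValidationError("length percentages do not sum to 100")

    def to_tsv(self) -> str:
        parts = [
            self.regions.to_csv(sep="\t", index=False),
            self.classes.to_csv(sep="\t", index=False),
        ]
        return "\n".join(parts)


def region_table(
    lengths: dict[str, int], gc: dict[str, float] | None = None
) -> pd.DataFrame:
    """Region composition from plain region lengths (LSC, IRa, SSC, IRb).

    ``lengths`` maps region name to bp; ``gc`` optionally maps region to a GC
    fraction.  Percentages are rounded half-away-from-zero to one decimal, as
    in printed comparative tables.
    """
    total = sum(lengths.values())
    rows = []
    for region in ("LSC", "IRa", "SSC", "IRb"):
        if region not in lengths:
            raise ValidationError(f"missing region {region}")
        L = lengths[region]
        rows.append(
            {
                "region": region,
                "length_bp": L,
                "gc_percent": (
                    round_half_away(100 * gc[region], 1)
                    if gc and region in gc
                    else float("nan")
                ),
                "length_percent": round_half_away(100 * L / total, 1),
            }
        )
    return pd.DataFrame(rows)


# integer labels for the class mask
_INTERGENIC, _INTRON, _PROTEIN, _TRNA, _RRNA = 0, 1, 2, 3, 4
_CLASS_NAMES = {
    _PROTEIN: "protein",
    _TRNA: "tRNA",
    _RRNA: "rRNA",
    _INTRON: "intron",
    _INTERGENIC: "intergenic",
}
_CATEGORY_LABEL = {"protein": _PROTEIN, "tRNA": _TRNA, "rRNA": _RRNA}


def class_mask(record: PlastomeRecord) -> np.ndarray:
    """Per-base class labels: exon (by category) > intron > intergenic.

    Overlapping features are resolved by set union: each base is counted
    once, exonic state winning over intronic (so e.g. a protein gene nested
    inside another gene's intron is counted as protein).
    """
    n = len(record.sequence)
    mask = np.zeros(n, dtype=np.int8)
    for ann in record.annotations:
        for s, e in ann.intron_intervals():
            mask[s:e] = np.maximum(mask[s:e], _INTRON)
    for ann in record.annotations:
        label = _CATEGORY_LABEL[ann.category]
        for s, e in ann.exons:
            mask[s:e] = np.maximum(mask[s:e], label)
    return mask


def composition_summary(
    record: PlastomeRecord, partition: RegionPartition
) -> CompositionTable:
    """Full composition table for one annotated genome.

    Intron length is each intron-bearing gene's span minus its exon lengths;
    intergenic is everything not covered by a gene span.  Bases covered by
    more than one feature are counted once (union), exon beating intron.
    """
    partition.validate(record)
    n = len(record.sequence)
    seq_arr = np.frombuffer(record.sequence.encode(), dtype=np.uint8)
    is_gc = (seq_arr == ord("G")) | (seq_arr == ord("C"))
    is_n = seq_arr == ord("N")

    lengths = {
        "LSC": partition.lsc[1] - partition.lsc[0],
        "IRa": partition.ira[1] - partition.ira[0],
        "SSC": partition.ssc[1] - partition.ssc[0],
        "IRb": partition.irb[1] - partition.irb[0],
    }
    gc = {}
    for region, iv in (
        ("LSC", partition.lsc),
        ("IRa", partition.ira),
        ("SSC", partition.ssc),
        ("IRb", partition.irb),
    ):
        sl = slice(*iv)
        denom = (iv[1] - iv[0]) - int(is_n[sl].sum())
        gc[region] = int(is_gc[sl].sum()) / denom if denom else float("nan")
    regions = region_table(lengths, gc)

    mask = class_mask(record)
    rows = []
    for label in (_PROTEIN, _TRNA, _RRNA, _INTRON, _INTERGENIC):
        sel = mask == label
        length = int(sel.sum())
        denom = length - int(is_n[sel].sum())
        rows.append(
            {
                "class": _CLASS_NAMES[label],
                "length_bp": length,
                "gc_percent": (
                    round_half_away(100 * int(is_gc[sel].sum()) / denom, 1)
                    if denom
                    else float("nan")
                ),
                "length_percent": round_half_away(100 * length / n, 1),
            }
        )
    classes = pd.DataFrame(rows)
    table = CompositionTable(regions=regions, classes=classes, genome_length=n)
    table.validate()
    return table


@dataclass
class GeneCensus:
    """Gene-copy accounting with IR duplication.

    ``total_copies`` counts every annotation (an IR-duplicated gene twice);
    ``distinct_names`` counts each name once; ``duplicated_names`` counts
    names present in both IRs.  Pseudogenes are excluded throughout.
    """

    total_copies: int
    distinct_names: int
    duplicated_names: int
    per_category: dict[str, int] = field(default_factory=dict)
    per_region: dict[str, int] = field(default_factory=dict)
    boundary_spanning: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.total_copies != self.distinct_names + self.duplicated_names:
            raise ValidationError("census totals inconsistent")
        if sum(self.per_category.values()) != self.total_copies:
            raise ValidationError("per-category copies do not sum to total")

    def to_tsv(self) -> str:
        rows = [
            ("total_copies", self.total_copies),
            ("distinct_names", self.distinct_names),
            ("duplicated_names", self.duplicated_names),
        ]
        rows += [(f"copies_{k}", v) for k, v in sorted(self.per_category.items())]
        rows += [(f"region_{k}", v) for k, v in sorted(self.per_region.items())]
        rows.append(("boundary_spanning", ",".join(self.boundary_spanning)))
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def gene_census(
    annotations: list[GeneAnnotation], partition: RegionPartition | None = None
) -> GeneCensus:
    """Census of gene copies, names, duplications and regional placement.

    A gene is assigned to the region holding the majority of its exonic
    bases (the two IRs pooled); genes whose span crosses a junction are also
    listed in ``boundary_spanning``.
    """
    genes = [a for a in annotations if not a.is_pseudo]
    warnings: list[str] = []
    by_name: dict[str, list[GeneAnnotation]] = {}
    for ann in genes:
        by_name.setdefault(ann.name, []).append(ann)

    duplicated = 0
    for name, copies in by_name.items():
        if len(copies) > 2:
            warnings.append(f"{name}: {len(copies)} copies")
        if len(copies) < 2:
            continue
        tags = {a.copy_tag for a in copies}
        if not {"IR_A", "IR_B"} <= tags:
            warnings.append(f"{name}: multiple copies without IR_A/IR_B tags")
        # extra copies always enter the duplicated count so that
        # total_copies == distinct_names + duplicated_names holds
        duplicated += len(copies) - 1

    per_category: dict[str, int] = {"protein": 0, "tRNA": 0, "rRNA": 0}
    for ann in genes:
        per_category[ann.category] += 1

    per_region: dict[str, int] = {"LSC": 0, "SSC": 0, "IR": 0}
    boundary: list[str] = []
    if partition is not None and genes:
        seen_names: set[str] = set()
        for ann in genes:
            if ann.name in seen_names:
                continue
            seen_names.add(ann.name)
            per_region[majority_region(ann, partition)] += 1
        junctions = set(partition.junctions.values())
        n = partition.genome_length
        for ann in genes:
            s, e = ann.span
            spans = any(s < j < e for j in junctions)
            if ann.wraps_origin or spans or (0 in {j % n for j in junctions} and ann.wraps_origin):
                if ann.name not in boundary:
                    boundary.append(ann.name)
        # trans-spliced genes with pieces in more than one region also span
        for ann in genes:
            if ann.trans_spliced and ann.name not in boundary:
                regions = {
                    partition.region_of((s + e) // 2) for s, e in ann.exons
                }
                if len(regions) > 1:
                    boundary.append(ann.name)

    census = GeneCensus(
        total_copies=len(genes),
        distinct_names=len(by_name),
        duplicated_names=duplicated,
        per_category=per_category,
        per_region=per_region,
        boundary_spanning=sorted(boundary),
        warnings=warnings,
    )
    census.validate()
    return census
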