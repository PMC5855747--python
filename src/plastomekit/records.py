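"""Core data model for annotated plastid genomes.

A plastome is stored as a linearized circular sequence, by convention
starting at the first base of the large single-copy (LSC) region.  All
coordinates are 0-based half-open internally; human-readable reports use
1-based inclusive coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def complement(seq: str) -> str:
    """Base-wise complement (no reversal)."""
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement."""
    return seq.translate(_COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """Raised when a record, annotation or partition violates its invariants."""


@dataclass
class GeneAnnotation:
    """A named, stranded, possibly multi-exon gene on the linearized sequence.

    ``exons`` are 0-based half-open ``(start, end)`` intervals sorted by
    start.  A gene duplicated across the two inverted repeats appears as two
    annotations with the same name, tagged ``IR_A`` and ``IR_B``.  A feature
    that crosses the circular origin is stored with the wrap resolved into
    two intervals and ``wraps_origin=True``; such a pair is one contiguous
    feature, not an exon/intron structure.
    """

    name: str
    category: str  # protein | tRNA | rRNA
    strand: str  # + | -
    exons: list[tuple[int, int]]
    is_pseudo: bool = False
    copy_tag: str = "single"  # single | IR_A | IR_B
    trans_spliced: bool = False
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        self.exons = [(int(s), int(e)) for s, e in self.exons]

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_introns(self) -> int:
        """Cis intron count implied by the exon structure."""
        if self.trans_spliced or self.wraps_origin:
            # trans-spliced pieces and origin-wrapped features do not imply
            # cis introns between all consecutive intervals; callers needing
            # exact counts use GeneModel instead.
            return 0
        return max(0, len(self.exons) - 1)

    def intron_intervals(self) -> list[tuple[int, int]]:
        if self.trans_spliced or self.wraps_origin:
            return []
        ex = sorted(self.exons)
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)]

    def validate(self, genome_length: int | None = None) -> None:
        if self.category not in ("protein", "tRNA", "rRNA"):
            raise ValidationError(f"{self.name}: bad category {self.category!r}")
        if self.strand not in "+-":
            raise ValidationError(f"{self.name}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"{self.name}: no exons")
        ex = sorted(self.exons)
        for s, e in ex:
            if s >= e:
                raise ValidationError(f"{self.name}: empty interval {(s, e)}")
            if genome_length is not None and not (0 <= s < e <= genome_length):
                raise ValidationError(
                    f"{self.name}: interval {(s, e)} outside [0, {genome_length})"
                )
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if e1 > s2:
                raise ValidationError(f"{self.name}: overlapping exons")


@dataclass
class RegionPartition:
    """Quadripartite partition of the linearized genome.

    Intervals are 0-based half-open and, with the standard linearization at
    LSC base 1, tile ``[0, n)`` in the order LSC, IRa, SSC, IRb.  The four
    junction coordinates are boundary positions: ``J_LA`` is the first base
    of IRa, ``J_SA`` the first base of the SSC, ``J_SB`` the first base of
    IRb, and ``J_LB`` the wrap point back to the LSC (equal to the genome
    length in this frame; position 0 circularly).
    """

    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]

    @property
    def genome_length(self) -> int:
        return self.irb[1]

    @property
    def junctions(self) -> dict[str, int]:
        return {
            "J_LA": self.lsc[1],
            "J_SA": self.ira[1],
            "J_SB": self.ssc[1],
            "J_LB": self.irb[1],
        }

    @property
    def ir_length(self) -> int:
        return self.ira[1] - self.ira[0]

    def region_of(self, pos: int) -> str:
        n = self.genome_length
        pos %= n
        for name, (s, e) in (
            ("LSC", self.lsc),
            ("IRa", self.ira),
            ("SSC", self.ssc),
            ("IRb", self.irb),
        ):
            if s <= pos < e:
                return name
        raise ValidationError(f"position {pos} not covered by partition")

    def validate(self, record: "PlastomeRecord | None" = None) -> None:
        ivs = [self.lsc, self.ira, self.ssc, self.irb]
        if self.lsc[0] != 0:
            raise ValidationError("partition must start at LSC base 0")
        for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
            if e1 != s2:
                raise ValidationError("partition intervals must be contiguous")
        if (self.ira[1] - self.ira[0]) != (self.irb[1] - self.irb[0]):
            raise ValidationError("IRa and IRb lengths differ")
        if record is not None:
            if self.genome_length != len(record.sequence):
                raise ValidationError(
                    f"partition covers {self.genome_length} bp but genome is "
                    f"{len(record.sequence)} bp"
                )

    def to_bed(self, chrom: str = "plastome") -> str:
        rows = [
            (chrom, *self.lsc, "LSC"),
            (chrom, *self.ira, "IRa"),
            (chrom, *self.ssc, "SSC"),
            (chrom, *self.irb, "IRb"),
        ]
        return "\n".join("\t".join(map(str, r)) for r in rows) + "\n"


@dataclass
class PlastomeRecord:
    """A linearized circular plastid genome with gene annotations."""

    id: str
    sequence: str
    is_circular: bool = True
    annotations: list[GeneAnnotation] = field(default_factory=list)
    source: str = "synthetic"

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if len(self.sequence) < 1:
            raise ValidationError("empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValidationError(f"invalid characters in sequence: {sorted(bad)}")
        for ann in self.annotations:
            ann.validate(len(self.sequence))

    def subseq(self, start: int, end: int) -> str:
        """Sequence slice honoring circular wrap when end > length."""
        n = len(self.sequence)
        start %= n
        if end <= n and start < end:
            return self.sequence[start:end]
        end = start + ((end - start) % n or (end - start))
        doubled = self.sequence + self.sequence
        return doubled[start:end]

    def annotations_by_name(self) -> dict[str, list[GeneAnnotation]]:
        out: dict[str, list[GeneAnnotation]] = {}
        for ann in self.annotations:
            out.setdefault(ann.name, []).append(ann)
        return out


def assign_copy_tags(
    annotations: Iterable[GeneAnnotation], partition: RegionPartition
) -> None:
    """Tag duplicated gene names with IR_A / IR_B by the IR holding them.

    Names with exactly two copies, one in each IR, get the tags; everything
    else keeps ``single``.  Mutates the annotations in place.
    """
    by_name: dict[str, list[GeneAnnotation]] = {}
    for ann in annotations:
        by_name.setdefault(ann.name, []).append(ann)
    for name, copies in by_name.items():
        if len(copies) != 2:
            continue
        tags = []
        for ann in copies:
            mid = _majority_position(ann)
            region = partition.region_of(mid)
            tags.append(region)
        if set(tags) == {"IRa", "IRb"}:
            for ann, tag in zip(copies, tags):
                ann.copy_tag = "IR_A" if tag == "IRa" else "IR_B"


def _majority_position(ann: GeneAnnotation) -> int:
    """A representative position: midpoint of the largest exon."""
    s, e = max(ann.exons, key=lambda iv: iv[1] - iv[0])
    return (s + e) // 2


def majority_region(ann: GeneAnnotation, partition: RegionPartition) -> str:
    """Region containing the majority of the gene's exonic bases.

    The two IRs are pooled as ``IR``.
    """
    counts = {"LSC": 0, "IR": 0, "SSC": 0}
    for s, e in ann.exons:
        for region, (rs, re_) in (
            ("LSC", partition.lsc),
            ("IR", partition.ira),
            ("SSC", partition.ssc),
            ("IR", partition.irb),
        ):
            lo, hi = max(s, rs), min(e, re_)
            if hi > lo:
                counts[region] += hi - lo
    return max(counts, key=lambda r: (counts[r], r))
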