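"""Inverted-repeat detection, quadripartite partitioning and junction reports.

The IR pair is found by k-mer anchoring of the sequence against its reverse
complement: every shared k-mer defines an anchor on an anti-diagonal
(constant ``p + q`` for paired positions ``p``, ``q``), anchors on one
anti-diagonal are chained, the chained extent is extended gaplessly, and the
best extent satisfying the mismatch budget wins.  Plastome IRs are reported
as identical in most accessions, so the default mismatch budget is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import (
    GeneAnnotation,
    PlastomeRecord,
    RegionPartition,
    ValidationError,
    complement,
    revcomp,
)

__all__ = [
    "IRPair",
    "JunctionContext",
    "NoIRDetected",
    "detect_ir",
    "partition_from_ir",
    "junction_report",
    "mirror_position",
]


class NoIRDetected(Exception):
    """No inverted-repeat pair satisfying the constraints was found."""


@dataclass
class IRPair:
    """A pair of disjoint intervals whose sequences are reverse complements
    of each other within the mismatch budget."""

    ira: tuple[int, int]
    irb: tuple[int, int]
    length: int
    mismatches: int

    def validate(self, record: PlastomeRecord | None = None) -> None:
        if self.ira[1] - self.ira[0] != self.length or self.irb[1] - self.irb[0] != self.length:
            raise ValidationError("IR interval lengths inconsistent")
        if self.ira[1] > self.irb[0]:
            raise ValidationError("IR intervals overlap or are out of order")
        if record is not None:
            a = record.sequence[self.ira[0] : self.ira[1]]
            b = record.sequence[self.irb[0] : self.irb[1]]
            mism = sum(1 for x, y in zip(revcomp(a), b) if x != y)
            if mism != self.mismatches:
                raise ValidationError(
                    f"recorded mismatches {self.mismatches} != actual {mism}"
                )


def _antidiagonal_anchors(seq: str, k: int) -> dict[int, list[int]]:
    """Anchors between seq and its own reverse complement.

    A k-mer at position ``i`` whose reverse complement occurs at position
    ``j`` (with j > i, to count each pairing once) yields base pairings
    ``(i + t, j + k - 1 - t)``; all lie on the anti-diagonal
    ``d = i + j + k - 1``.  Returns ``d -> sorted list of left endpoints i``.
    """
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    diags: dict[int, set[int]] = {}
    for i in range(len(seq) - k + 1):
        rc = revcomp(seq[i : i + k])
        for j in index.get(rc, ()):
            if j >= i:  # count each pair once; j == i handles self-palindromes
                diags.setdefault(i + j + k - 1, set()).add(i)
    return {d: sorted(v) for d, v in diags.items()}


def _best_run_on_diagonal(
    seq: str, d: int, anchors: list[int], k: int, max_mismatch_frac: float
) -> tuple[int, int, int] | None:
    """Longest valid (p_start, length, mismatches) run on anti-diagonal d.

    A run pairs positions ``p`` with ``d - p``; it is valid while ``p < d-p``
    (blocks stay disjoint).  Within the extent spanned by the chained anchors
    (plus gapless extension), the longest window whose Hamming mismatch count
    stays within ``max_mismatch_frac`` of its length is selected, trimmed to
    matching endpoints.
    """
    n = len(seq)
    # pairing p <-> q = d - p; blocks stay disjoint while p <= (d-1)//2,
    # and q must be a real position: p >= d - n + 1
    lo = max(anchors[0], d - n + 1, 0)
    hi = min(anchors[-1] + k - 1, (d - 1) // 2)
    # extend the extent outward while bases keep pairing
    while lo > 0 and d - lo + 1 < n and seq[lo - 1] == complement(seq[d - lo + 1]):
        lo -= 1
    while hi + 1 <= (d - 1) // 2 and seq[hi + 1] == complement(seq[d - hi - 1]):
        hi += 1
    if hi < lo:
        return None
    ps = np.arange(lo, hi + 1)
    qs = d - ps
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp_map = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp_map[a] = b
    match = s[ps] == comp_map[s[qs]]
    mismatch_pos = np.flatnonzero(~match)
    total = len(match)
    if len(mismatch_pos) == 0:
        return (lo, total, 0)
    # candidate windows are bounded by mismatch positions; enumerate the
    # O(M^2) choices of first/last retained mismatch block
    bounds = np.concatenate(([-1], mismatch_pos, [total]))
    best: tuple[int, int, int] | None = None
    m = len(mismatch_pos)
    for a in range(m + 1):
        start = bounds[a] + 1  # window starts right after mismatch a-1
        for b in range(m, a - 1, -1):
            end = bounds[b + 1] - 1  # window ends right before mismatch b
            if end < start:
                continue
            length = end - start + 1
            mism = b - a
            if mism <= max_mismatch_frac * length:
                if best is None or length > best[1]:
                    best = (lo + start, length, mism)
                break  # longer windows for this `a` were already tried
    return best


def detect_ir(
    record: PlastomeRecord,
    min_ir_length: int = 1000,
    max_mismatch_frac: float = 0.0,
    k: int = 21,
) -> IRPair:
    """Locate the inverted-repeat pair of a plastome.

    Returns the longest pair of disjoint intervals whose sequences are
    reverse complements of one another with at most
    ``max_mismatch_frac x length`` mismatches; ties break toward the smaller
    IRa start.  Raises :class:`NoIRDetected` when no qualifying pair exists
    (single-copy-only genomes occur in nature).

    The search runs on the linearized sequence; for circular records a
    second pass on the genome rotated by half its length catches a pair
    whose copies flank the origin.
    """
    n = len(record.sequence)
    if n < 2 * min_ir_length:
        raise NoIRDetected(
            f"genome ({n} bp) shorter than two IR copies of {min_ir_length} bp"
        )

    def _scan(seq: str) -> tuple[int, int, int, int] | None:
        diags = _antidiagonal_anchors(seq, k)
        best = None
        for d in sorted(diags):
            run = _best_run_on_diagonal(seq, d, diags[d], k, max_mismatch_frac)
            if run is None:
                continue
            p, length, mism = run
            if length < min_ir_length:
                continue
            # blocks: A = [p, p+length), B = [d-p-length+1, d-p+1)
            cand = (length, -p, p, d, mism)
            if best is None or cand[:2] > best[:2]:
                best = cand
        if best is None:
            return None
        length, _, p, d, mism = best
        return (p, d, length, mism)

    result = _scan(record.sequence)
    rotated = None
    if record.is_circular:
        shift = n // 2
        rot = record.sequence[shift:] + record.sequence[:shift]
        rotated = _scan(rot)
    candidates = []
    if result is not None:
        p, d, L, mism = result
        candidates.append((L, (p, p + L), (d - p - L + 1, d - p + 1), mism))
    if rotated is not None:
        p, d, L, mism = rotated
        shift = n // 2
        a = ((p + shift) % n, (p + L + shift - 1) % n + 1)
        b = ((d - p - L + 1 + shift) % n, (d - p + shift) % n + 1)
        # keep only if both blocks avoid the original origin (else the
        # unrotated scan already found them)
        if a[0] < a[1] and b[0] < b[1]:
            lo, hi = sorted([a, b])
            candidates.append((L, lo, hi, mism))
    if not candidates:
        raise NoIRDetected("no inverted repeat pair found")
    candidates.sort(key=lambda c: (-c[0], c[1][0]))
    L, ira, irb, mism = candidates[0]
    pair = IRPair(ira=ira, irb=irb, length=L, mismatches=mism)
    # re-count mismatches over the final blocks
    a = record.sequence[ira[0] : ira[1]]
    b = record.sequence[irb[0] : irb[1]]
    pair.mismatches = sum(1 for x, y in zip(revcomp(a), b) if x != y)
    return pair


def partition_from_ir(record: PlastomeRecord, ir: IRPair) -> RegionPartition:
    """Quadripartite partition from a detected IR pair.

    The longer inter-IR arc becomes the LSC, the shorter the SSC.  The
    returned partition is expressed in a frame starting at LSC base 1; when
    the record is already linearized that way (the package convention), the
    coordinates match the record directly.
    """
    n = len(record.sequence)
    arc1 = (ir.ira[1], ir.irb[0])  # between the two copies
    arc2_len = n - ir.irb[1] + ir.ira[0]  # wrapping arc
    arc1_len = arc1[1] - arc1[0]
    if arc1_len == arc2_len:
        raise ValidationError(
            "inter-IR arcs have equal length; explicit LSC/SSC labels required"
        )
    if arc2_len > arc1_len:
        # the wrapping arc is the LSC: valid only when it does not actually
        # wrap, i.e. the record is already linearized at LSC base 1
        if ir.irb[1] != n or ir.ira[0] == 0:
            raise ValidationError(
                "record is not linearized at LSC base 1; rotate the sequence "
                f"so the LSC starts at 0 (LSC arc wraps {ir.irb[1]}..{ir.ira[0]})"
            )
        return RegionPartition(
            lsc=(0, ir.ira[0]),
            ira=ir.ira,
            ssc=(ir.ira[1], ir.irb[0]),
            irb=ir.irb,
        )
    # the arc between the copies is the longer one: the LSC sits mid-sequence
    raise ValidationError(
        "record is not linearized at LSC base 1: the LSC lies between the "
        "two IR copies; rotate the sequence so position 0 is the LSC start"
    )


def mirror_position(pos: int, partition: RegionPartition) -> int:
    """Mirrored coordinate in the opposite IR copy.

    A base at offset ``d`` inside IRa (measured from J_LA) pairs with the
    base at offset ``d`` inward from J_LB in IRb, because IRb is the reverse
    complement of IRa.
    """
    ira, irb = partition.ira, partition.irb
    if ira[0] <= pos < ira[1]:
        return irb[1] - 1 - (pos - ira[0])
    if irb[0] <= pos < irb[1]:
        return ira[0] + (irb[1] - 1 - pos)
    raise ValueError(f"position {pos} is not inside either IR")


@dataclass
class JunctionContext:
    """One gene's relation to one junction."""

    junction: str  # J_LA | J_SA | J_SB | J_LB
    gene: str
    relation: str  # spans_junction | upstream_gap | downstream_gap
    distance: int
    pseudogene_partner: str | None = None


def junction_report(
    record: PlastomeRecord, partition: RegionPartition
) -> list[JunctionContext]:
    """Genes flanking and spanning each of the four junctions.

    Distances follow the convention: a gap is the number of bases strictly
    between the gene end and the junction; a spanning gene reports how far
    it extends past the junction into the adjacent region.  For a gene whose
    body runs from a single-copy region into an IR, the mirrored locus in
    the other IR is checked for an annotated pseudogene partner.
    """
    n = len(record.sequence)
    out: list[JunctionContext] = []
    genes = [a for a in record.annotations if not a.is_pseudo]
    for jname, jpos in partition.junctions.items():
        spanning: list[GeneAnnotation] = []
        before: tuple[int, GeneAnnotation] | None = None
        after: tuple[int, GeneAnnotation] | None = None
        for ann in genes:
            if ann.wraps_origin:
                # a feature crossing the origin spans J_LB; its two pieces
                # act as flanking candidates for the other junctions
                if jpos % n == 0 or jpos == n:
                    spanning.append(ann)
                    continue
                pieces = sorted(ann.exons)
            elif ann.trans_spliced:
                # distant trans-spliced pieces are independent bodies
                pieces = sorted(ann.exons)
            else:
                pieces = [ann.span]
            spanned = False
            for s, e in pieces:
                for j in ([jpos] if jpos != n else [n, 0]):
                    if s < j < e:
                        spanned = True
            if spanned:
                spanning.append(ann)
                continue
            for s, e in pieces:
                for j in ([jpos] if jpos != n else [n, 0]):
                    if e <= j and (before is None or j - e < before[0]):
                        before = (j - e, ann)
                    if s >= j and (after is None or s - j < after[0]):
                        after = (s - j, ann)
        for ann in spanning:
            out.append(
                JunctionContext(
                    junction=jname,
                    gene=ann.name,
                    relation="spans_junction",
                    distance=_span_extent(ann, jpos, n),
                    pseudogene_partner=_psi_partner(ann, record, partition, jpos),
                )
            )
        if before is not None:
            out.append(
                JunctionContext(jname, before[1].name, "upstream_gap", before[0])
            )
        if after is not None:
            out.append(
                JunctionContext(jname, after[1].name, "downstream_gap", after[0])
            )
    return out


def _span_extent(ann: GeneAnnotation, jpos: int, n: int) -> int:
    """Extent of a spanning gene beyond the junction into the adjacent
    region: the smaller of the two pieces the junction cuts the span into."""
    if ann.wraps_origin:
        # pieces are [s, n) and [0, e); the extent past the origin junction
        # is the shorter piece
        return min(e2 - s2 for s2, e2 in ann.exons)
    s, e = ann.span
    return min(jpos - s, e - jpos)


def _psi_partner(
    ann: GeneAnnotation,
    record: PlastomeRecord,
    partition: RegionPartition,
    jpos: int,
) -> str | None:
    """Annotated pseudogene copy at the mirrored locus in the opposite IR."""
    n = len(record.sequence)
    s, e = ann.span
    if ann.wraps_origin:
        in_ir = (s, n)  # the piece inside IRb at the end of the sequence
    else:
        ira, irb = partition.ira, partition.irb
        pieces = []
        lo, hi = max(s, ira[0]), min(e, ira[1])
        if hi > lo:
            pieces.append((lo, hi))
        lo, hi = max(s, irb[0]), min(e, irb[1])
        if hi > lo:
            pieces.append((lo, hi))
        if not pieces:
            return None
        in_ir = max(pieces, key=lambda iv: iv[1] - iv[0])
    try:
        m1 = mirror_position(in_ir[0], partition)
        m2 = mirror_position(in_ir[1] - 1, partition)
    except ValueError:
        return None
    lo, hi = min(m1, m2), max(m1, m2) + 1
    for other in record.annotations:
        if other is ann:
            continue
        os_, oe = other.span
        if os_ < hi and lo < oe and (
            other.is_pseudo or other.name in (ann.name, f"psi_{ann.name}")
        ):
            return other.name if other.name.startswith("psi_") else f"psi_{ann.name}"
    return None
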