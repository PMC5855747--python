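"""Ground-truth plastome simulation.

The generator emits a circular quadripartite genome (LSC + IRa + SSC + IRb,
with IRb the exact reverse complement of IRa), a full gene complement with
IR-duplicated and multi-exon genes, and optional planted SSRs, long repeats
and primer target constructs, all recorded in a truth table so every
detector in the pipeline can be scored against known coordinates.  The
default layout mirrors the *Catha edulis* plastome: region sizes 86,315 /
26,577 / 18,491 / 26,577 bp, per-region GC targets, the 112-name gene
inventory with 17 IR-duplicated genes, rps19 ending 46 bp before J_LA, ndhF
starting 29 bp after J_SA, ycf1 running 1,200 bp across J_SB into IRb (with
a mirrored pseudogene fragment at J_SA), trnH wrapping the origin 8 bp into
IRb, and trans-spliced rps12.

Sequence backgrounds are sampled i.i.d. per region to the GC target and
then *screened*: any accidental SSR or >= 30 bp repeat that would qualify
under the default thresholds is destroyed by point edits (mirrored into the
other IR copy where needed), so that detectors see exactly the planted
features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from . import refdata
from .introns import GeneModel
from .records import (
    GeneAnnotation,
    PlastomeRecord,
    RegionPartition,
    revcomp,
)
from .repeats import find_long_repeats, find_ssrs
from .variability import Alignment

__all__ = [
    "GenePlan",
    "PlastomeSpec",
    "TruthTable",
    "generate_plastome",
    "evolve_taxa",
    "EvolvedTaxa",
    "spec_from_yaml",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GenePlan:
    """One gene to place: name, category, region, alternating exon/intron
    lengths (None marks a trans-splicing junction), strand."""

    name: str
    category: str
    region: str  # LSC | IR | SSC
    segments: tuple[int | None, ...]
    strand: str = "+"


def _default_inventory() -> list[GenePlan]:
    return [
        GenePlan(name, cat, region, seg, strand)
        for name, cat, region, seg, strand in refdata.GENE_INVENTORY
    ]


@dataclass
class PlastomeSpec:
    """Parameters of one synthetic plastome."""

    lsc_len: int = 86315
    ssc_len: int = 18491
    ir_len: int = 26577
    gc_targets: dict[str, float] = field(
        default_factory=lambda: {"LSC": 0.351, "SSC": 0.318, "IR": 0.427}
    )
    gene_inventory: list[GenePlan] = field(default_factory=_default_inventory)
    planted_ssrs: list[tuple[str, int, str]] = field(default_factory=list)
    planted_repeats: list[tuple[str, int, float]] = field(default_factory=list)
    # the reference genome carries the rps16 intron-verification primer
    # sites bracketing a 550 bp exon-joined product
    primer_constructs: list[tuple[str, str, int]] = field(
        default_factory=lambda: [
            (
                refdata.RPS16_PRIMER_FORWARD,
                refdata.RPS16_PRIMER_REVERSE,
                refdata.RPS16_AMPLICON_LENGTH,
            )
        ]
    )
    # boundary layout (bp); None disables the corresponding feature
    rps19_jla_gap: int | None = refdata.RPS19_JLA_GAP
    ndhf_jsa_gap: int | None = refdata.NDHF_JSA_GAP
    ycf1_irb_overlap: int | None = refdata.YCF1_IRB_OVERLAP
    trnh_irb_overlap: int | None = refdata.TRNH_IRB_OVERLAP
    seed: int = 0

    @property
    def genome_length(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len

    @classmethod
    def minimal(
        cls,
        lsc_len: int = 8000,
        ssc_len: int = 2000,
        ir_len: int = 3000,
        seed: int = 0,
        **kwargs,
    ) -> "PlastomeSpec":
        """A small genome without the gene complement, for fast tests."""
        kwargs.setdefault("gene_inventory", [])
        kwargs.setdefault("rps19_jla_gap", None)
        kwargs.setdefault("ndhf_jsa_gap", None)
        kwargs.setdefault("ycf1_irb_overlap", None)
        kwargs.setdefault("trnh_irb_overlap", None)
        return cls(lsc_len=lsc_len, ssc_len=ssc_len, ir_len=ir_len, seed=seed, **kwargs)


@dataclass
class TruthTable:
    """Exact coordinates and attributes of everything the generator planted."""

    partition: RegionPartition
    junctions: dict[str, int]
    genes: dict[str, list[tuple[tuple[int, int], ...]]]
    ssrs: list[dict]
    repeats: list[dict]
    amplicons: list[dict]
    residual_features: list[str] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["kind\tdetail"]
        for name, (s, e) in [
            ("LSC", self.partition.lsc),
            ("IRa", self.partition.ira),
            ("SSC", self.partition.ssc),
            ("IRb", self.partition.irb),
        ]:
            lines.append(f"region\t{name}:{s}-{e}")
        for j, pos in self.junctions.items():
            lines.append(f"junction\t{j}:{pos}")
        for name, copies in sorted(self.genes.items()):
            for exons in copies:
                lines.append(f"gene\t{name}:" + ",".join(f"{s}-{e}" for s, e in exons))
        for ssr in self.ssrs:
            lines.append(f"ssr\t{ssr}")
        for rep in self.repeats:
            lines.append(f"repeat\t{rep}")
        for amp in self.amplicons:
            lines.append(f"amplicon\t{amp}")
        for res in self.residual_features:
            lines.append(f"residual\t{res}")
        return "\n".join(lines) + "\n"


class CapacityError(ValueError):
    """Planted features/genes do not fit in their region."""


def spec_from_yaml(path) -> PlastomeSpec:
    """Load a :class:`PlastomeSpec` from a YAML key/value file.

    Scalar fields map directly (``lsc_len``, ``ssc_len``, ``ir_len``,
    ``seed``, the ``*_gap``/``*_overlap`` layout values); ``gc_targets`` is
    a region->fraction mapping; ``planted_ssrs``, ``planted_repeats`` and
    ``primer_constructs`` are lists of their tuple fields;
    ``gene_inventory`` entries are mappings with name/category/region/
    segments/strand.  Omitted keys keep the reference defaults.
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in (
        "lsc_len", "ssc_len", "ir_len", "seed",
        "rps19_jla_gap", "ndhf_jsa_gap", "ycf1_irb_overlap", "trnh_irb_overlap",
    ):
        if key in data:
            kwargs[key] = data[key]
    if "gc_targets" in data:
        kwargs["gc_targets"] = {k: float(v) for k, v in data["gc_targets"].items()}
    if "gene_inventory" in data:
        kwargs["gene_inventory"] = [
            GenePlan(
                name=g["name"],
                category=g["category"],
                region=g["region"],
                segments=tuple(g["segments"]),
                strand=g.get("strand", "+"),
            )
            for g in data["gene_inventory"]
        ]
    for key in ("planted_ssrs", "planted_repeats", "primer_constructs"):
        if key in data:
            kwargs[key] = [tuple(item) for item in data[key]]
    return PlastomeSpec(**kwargs)


def _sample_region(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    """i.i.d. background with realized GC within +/-0.5% of the target."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    for _ in range(50):
        seq = rng.choice(_BASES, size=length, p=p)
        realized = ((seq == ord("G")) | (seq == ord("C"))).mean()
        if abs(realized - gc) <= 0.005 or length < 200:
            return seq
    raise RuntimeError("could not hit GC target")  # pragma: no cover


def _enforce_ir_flanks(
    genome: np.ndarray, spec: PlastomeSpec, rng: np.random.Generator
) -> None:
    """Stop the IR pair from extending by chance complementarity.

    The base before IRa must not pair with the base after IRb (circularly,
    the last LSC base vs the first LSC base), and the first SSC base must
    not pair with the last SSC base; otherwise the detected IR would be one
    base longer than planted.
    """
    comp = {ord("A"): ord("T"), ord("T"): ord("A"), ord("C"): ord("G"), ord("G"): ord("C")}
    n = len(genome)
    ira_start = spec.lsc_len
    ssc_start = spec.lsc_len + spec.ir_len
    ssc_end = ssc_start + spec.ssc_len
    for p, q in ((ira_start - 1, 0), (ssc_start, ssc_end - 1)):
        if int(genome[q]) == comp[int(genome[p])]:
            choices = [
                int(b)
                for b in _BASES
                if int(b) != int(genome[q]) and int(b) != comp[int(genome[p])]
            ]
            genome[q] = choices[int(rng.integers(0, len(choices)))]


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    table = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        table[a] = b
    return table[arr][::-1]


def generate_plastome(
    spec: PlastomeSpec, seed: int | None = None
) -> tuple[PlastomeRecord, TruthTable]:
    """Build a synthetic plastome and its truth table.

    Fully deterministic given the seed (``spec.seed`` unless overridden).
    Raises :class:`CapacityError` when genes or planted features cannot be
    placed.  Background screening retries up to 1,000 edits; any accidental
    feature still present afterwards is listed in
    ``TruthTable.residual_features`` rather than failing the run.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    lsc = _sample_region(rng, spec.lsc_len, spec.gc_targets["LSC"])
    ira = _sample_region(rng, spec.ir_len, spec.gc_targets["IR"])
    ssc = _sample_region(rng, spec.ssc_len, spec.gc_targets["SSC"])
    genome = np.concatenate([lsc, ira, ssc, _revcomp_arr(ira)])
    n = len(genome)
    _enforce_ir_flanks(genome, spec, rng)
    partition = RegionPartition(
        lsc=(0, spec.lsc_len),
        ira=(spec.lsc_len, spec.lsc_len + spec.ir_len),
        ssc=(spec.lsc_len + spec.ir_len, spec.lsc_len + spec.ir_len + spec.ssc_len),
        irb=(spec.lsc_len + spec.ir_len + spec.ssc_len, n),
    )

    annotations, gene_truth = _place_genes(spec, partition, rng)

    planted_ssrs, planted_repeats, planted_amplicons, protected = _plant_features(
        spec, genome, partition, annotations, rng
    )

    residual = _screen_background(genome, partition, protected, rng)
    # screening edits may have landed on the IR boundary flanks
    _enforce_ir_flanks(genome, spec, rng)

    record = PlastomeRecord(
        id="synthetic_plastome",
        sequence=genome.tobytes().decode(),
        is_circular=True,
        annotations=annotations,
        source="synthetic",
    )
    record.validate()
    truth = TruthTable(
        partition=partition,
        junctions=partition.junctions,
        genes=gene_truth,
        ssrs=planted_ssrs,
        repeats=planted_repeats,
        amplicons=planted_amplicons,
        residual_features=residual,
    )
    return record, truth


# ---------------------------------------------------------------------------
# gene placement
# ---------------------------------------------------------------------------


def _segments_to_exons(start: int, segments: Sequence[int | None]) -> list[tuple[int, int]]:
    """Exon intervals of a cis gene laid down left-to-right from ``start``."""
    exons = []
    pos = start
    for i, seg in enumerate(segments):
        if seg is None:
            continue
        if i % 2 == 0:
            exons.append((pos, pos + seg))
        pos += seg
    return exons


def _mirror_interval(iv: tuple[int, int], partition: RegionPartition) -> tuple[int, int]:
    ira, irb = partition.ira, partition.irb
    if ira[0] <= iv[0] and iv[1] <= ira[1]:
        return (irb[1] - (iv[1] - ira[0]), irb[1] - (iv[0] - ira[0]))
    return (ira[0] + (irb[1] - iv[1]), ira[0] + (irb[1] - iv[0]))


def _place_genes(
    spec: PlastomeSpec, partition: RegionPartition, rng: np.random.Generator
) -> tuple[list[GeneAnnotation], dict[str, list[tuple[tuple[int, int], ...]]]]:
    annotations: list[GeneAnnotation] = []
    truth: dict[str, list[tuple[tuple[int, int], ...]]] = {}
    n = partition.genome_length

    def add(ann: GeneAnnotation) -> None:
        annotations.append(ann)
        truth.setdefault(ann.name, []).append(tuple(ann.exons))

    by_region: dict[str, list[GenePlan]] = {"LSC": [], "IR": [], "SSC": []}
    for plan in spec.gene_inventory:
        by_region[plan.region].append(plan)

    # --- fixed boundary features -------------------------------------------
    lsc_start_reserved = 0
    if spec.trnh_irb_overlap:
        over = spec.trnh_irb_overlap
        body = refdata.TRNH_LENGTH - over
        ann = GeneAnnotation(
            name="trnH-GUG",
            category="tRNA",
            strand="-",
            exons=[(0, body), (n - over, n)],
            wraps_origin=True,
        )
        add(ann)
        lsc_start_reserved = body
    lsc_end_reserved = 0
    if spec.rps19_jla_gap is not None and by_region["LSC"]:
        # the last LSC gene will be pinned to end exactly at J_LA - gap
        lsc_end_reserved = spec.rps19_jla_gap
    ssc_lead_gap = spec.ndhf_jsa_gap if spec.ndhf_jsa_gap is not None else None

    rps12_ir_plan: GenePlan | None = None
    for plan in list(by_region["IR"]):
        if plan.name == "rps12":
            rps12_ir_plan = plan
            by_region["IR"].remove(plan)

    # --- LSC ----------------------------------------------------------------
    lsc_genes = list(by_region["LSC"])
    rps12_lsc_exon: tuple[int, int] | None = None
    extra_lsc = refdata.RPS12_5P_EXON if rps12_ir_plan is not None else 0
    footprint = sum(
        sum(s for s in p.segments if s is not None) for p in lsc_genes
    ) + extra_lsc
    free = spec.lsc_len - lsc_start_reserved - lsc_end_reserved - footprint
    n_gaps = len(lsc_genes) + (1 if rps12_ir_plan is not None else 0)
    if free < 2 * (n_gaps + 1):
        raise CapacityError(f"LSC too small: need {footprint + 2 * (n_gaps + 1)} bp")
    gaps = _random_gaps(rng, free, n_gaps + 1, min_gap=2)
    pos = lsc_start_reserved
    slots: list[GenePlan | str] = list(lsc_genes)
    if rps12_ir_plan is not None:
        # 5' exon sits among the late-LSC ribosomal-protein genes
        slots.insert(max(len(slots) - 16, 0), "rps12_5p")
    for i, slot in enumerate(slots):
        pos += gaps[i]
        if slot == "rps12_5p":
            rps12_lsc_exon = (pos, pos + refdata.RPS12_5P_EXON)
            pos += refdata.RPS12_5P_EXON
            continue
        exons = _segments_to_exons(pos, slot.segments)
        add(GeneAnnotation(slot.name, slot.category, slot.strand, exons))
        pos = exons[-1][1]
    last_end = partition.lsc[1] - (spec.rps19_jla_gap or 0)
    if lsc_end_reserved and slots:
        # shift the final gene so it ends exactly gap bp before J_LA
        final = annotations[-1]
        delta = last_end - final.exons[-1][1]
        if delta < 0:
            raise CapacityError("LSC layout overflows into the junction gap")
        final.exons = [(s + delta, e + delta) for s, e in final.exons]
        truth[final.name][-1] = tuple(final.exons)

    # --- IRa (mirrored into IRb) ---------------------------------------------
    ir_genes = list(by_region["IR"])
    ir_footprint = sum(
        sum(s for s in p.segments if s is not None) for p in ir_genes
    )
    rps12_ir_len = (
        sum(s for s in refdata.RPS12_IR_SEGMENTS) if rps12_ir_plan is not None else 0
    )
    psi_len = spec.ycf1_irb_overlap or 0  # mirrored pseudo-fragment sits at J_SA
    free = spec.ir_len - ir_footprint - rps12_ir_len - psi_len
    n_slots = len(ir_genes) + (1 if rps12_ir_plan is not None else 0)
    if free < 2 * (n_slots + 1):
        raise CapacityError("IR too small for its gene complement")
    gaps = _random_gaps(rng, free, n_slots + 1, min_gap=2)
    pos = partition.ira[0]
    ira_annotations: list[GeneAnnotation] = []
    slot_plans: list[GenePlan | str] = list(ir_genes)
    if rps12_ir_plan is not None:
        idx = min(7, len(slot_plans))
        slot_plans.insert(idx, "rps12_ir")
    for i, slot in enumerate(slot_plans):
        pos += gaps[i]
        if slot == "rps12_ir":
            exons_ir = _segments_to_exons(pos, refdata.RPS12_IR_SEGMENTS)
            pos = exons_ir[-1][1]
            assert rps12_lsc_exon is not None
            ann_a = GeneAnnotation(
                "rps12",
                "protein",
                "-",
                exons=sorted([rps12_lsc_exon, *exons_ir]),
                copy_tag="IR_A",
                trans_spliced=True,
            )
            mirrored = sorted(_mirror_interval(iv, partition) for iv in exons_ir)
            ann_b = GeneAnnotation(
                "rps12",
                "protein",
                "+",
                exons=sorted([rps12_lsc_exon, *mirrored]),
                copy_tag="IR_B",
                trans_spliced=True,
            )
            add(ann_a)
            add(ann_b)
            continue
        exons = _segments_to_exons(pos, slot.segments)
        ann = GeneAnnotation(slot.name, slot.category, slot.strand, exons, copy_tag="IR_A")
        ira_annotations.append(ann)
        add(ann)
        pos = exons[-1][1]
    for ann in ira_annotations:
        mirrored = sorted(_mirror_interval(iv, partition) for iv in ann.exons)
        add(
            GeneAnnotation(
                ann.name,
                ann.category,
                "-" if ann.strand == "+" else "+",
                mirrored,
                copy_tag="IR_B",
            )
        )

    # --- SSC ------------------------------------------------------------------
    ssc_genes = list(by_region["SSC"])
    ycf1_total = refdata.YCF1_LENGTH if spec.ycf1_irb_overlap else 0
    footprint = sum(
        sum(s for s in p.segments if s is not None) for p in ssc_genes
    ) + (ycf1_total - (spec.ycf1_irb_overlap or 0) if ycf1_total else 0)
    lead = ssc_lead_gap if ssc_lead_gap is not None else 2
    free = spec.ssc_len - footprint - lead
    n_slots = len(ssc_genes) + (1 if ycf1_total else 0)
    if free < 2 * n_slots:
        raise CapacityError("SSC too small for its gene complement")
    # last gap is zero when ycf1 runs into IRb
    gaps = _random_gaps(rng, free, max(n_slots - 1, 1), min_gap=2) if n_slots > 1 else [free]
    pos = partition.ssc[0] + lead
    for i, plan in enumerate(ssc_genes):
        if i > 0:
            pos += gaps[i - 1]
        exons = _segments_to_exons(pos, plan.segments)
        add(GeneAnnotation(plan.name, plan.category, plan.strand, exons))
        pos = exons[-1][1]
    if ycf1_total:
        start = partition.ssc[1] - (ycf1_total - spec.ycf1_irb_overlap)
        if ssc_genes and start < pos + 2:
            raise CapacityError("SSC cannot hold ycf1 at the J_SB boundary")
        ycf1 = GeneAnnotation(
            "ycf1", "protein", "+", [(start, start + ycf1_total)]
        )
        add(ycf1)
        # mirrored pseudogene fragment at J_SA in IRa
        frag = (partition.ssc[1], partition.ssc[1] + spec.ycf1_irb_overlap)
        m = _mirror_interval(frag, partition)
        annotations.append(
            GeneAnnotation("psi_ycf1", "protein", "-", [m], is_pseudo=True)
        )

    annotations.sort(key=lambda a: (a.start, a.name))
    return annotations, truth


def _random_gaps(
    rng: np.random.Generator, total: int, count: int, min_gap: int = 2
) -> list[int]:
    """``count`` non-negative gaps summing to ``total``, each >= min_gap."""
    if count == 0:
        return []
    spare = total - min_gap * count
    if spare < 0:
        raise CapacityError("not enough intergenic space")
    cuts = np.sort(rng.integers(0, spare + 1, size=count - 1))
    parts = np.diff(np.concatenate(([0], cuts, [spare])))
    return [int(p) + min_gap for p in parts]


# ---------------------------------------------------------------------------
# feature planting and background screening
# ---------------------------------------------------------------------------


def _intergenic_intervals(
    annotations: list[GeneAnnotation],
    region_iv: tuple[int, int],
    min_len: int,
) -> list[tuple[int, int]]:
    """Annotation-free stretches inside a region interval."""
    marks: list[tuple[int, int]] = []
    for ann in annotations:
        # trans-spliced and origin-wrapping features occupy only their
        # exon intervals, not the whole min-max span
        pieces = (
            sorted(ann.exons)
            if ann.trans_spliced or ann.wraps_origin
            else [ann.span]
        )
        for s, e in pieces:
            if s < region_iv[1] and e > region_iv[0]:
                marks.append((max(s, region_iv[0]), min(e, region_iv[1])))
    marks.sort()
    out = []
    cursor = region_iv[0]
    for s, e in marks + [(region_iv[1], region_iv[1])]:
        if s - cursor >= min_len:
            out.append((cursor, s))
        cursor = max(cursor, e)
    return out


def _mirror_write(
    genome: np.ndarray, partition: RegionPartition, start: int, payload: np.ndarray
) -> None:
    """Write payload at start, mirroring into the other IR copy if inside an IR."""
    genome[start : start + len(payload)] = payload
    iv = (start, start + len(payload))
    ira, irb = partition.ira, partition.irb
    if (ira[0] <= iv[0] and iv[1] <= ira[1]) or (irb[0] <= iv[0] and iv[1] <= irb[1]):
        ms, me = _mirror_interval(iv, partition)
        genome[ms:me] = _revcomp_arr(payload)


def _plant_features(
    spec: PlastomeSpec,
    genome: np.ndarray,
    partition: RegionPartition,
    annotations: list[GeneAnnotation],
    rng: np.random.Generator,
) -> tuple[list[dict], list[dict], list[dict], list[tuple[int, int]]]:
    """Write planted SSRs, repeats and primer constructs into intergenic
    space.  Returns the truth entries plus the protected intervals."""
    region_map = {
        "LSC": [partition.lsc],
        "SSC": [partition.ssc],
        "IR": [partition.ira],
    }
    protected: list[tuple[int, int]] = []

    def protect(iv: tuple[int, int]) -> None:
        protected.append(iv)
        ira, irb = partition.ira, partition.irb
        if (ira[0] <= iv[0] and iv[1] <= ira[1]) or (irb[0] <= iv[0] and iv[1] <= irb[1]):
            protected.append(_mirror_interval(iv, partition))

    def free_slot(region: str, length: int) -> int:
        pad = 2  # flanking bases we may edit to stop run extension
        for _ in range(200):
            candidates = []
            for region_iv in region_map[region]:
                for s, e in _intergenic_intervals(annotations, region_iv, length + 2 * pad):
                    candidates.append((s + pad, e - length - pad))
            candidates = [c for c in candidates if c[1] >= c[0]]
            if not candidates:
                raise CapacityError(f"no intergenic space in {region} for {length} bp")
            lo, hi = candidates[int(rng.integers(0, len(candidates)))]
            start = int(rng.integers(lo, hi + 1))
            iv = (start - pad, start + length + pad)
            if all(iv[1] <= p[0] or p[1] <= iv[0] for p in protected):
                return start
        raise CapacityError(f"could not place a {length} bp feature in {region}")

    ssr_truth = []
    for motif, copies, region in spec.planted_ssrs:
        motif = motif.upper()
        payload = np.frombuffer((motif * copies).encode(), dtype=np.uint8)
        start = free_slot(region, len(payload))
        _mirror_write(genome, partition, start, payload)
        # break extension at the flanks: make the borders mismatch the motif
        _set_breaking_base(genome, partition, start - 1, motif[-1], rng)
        _set_breaking_base(genome, partition, start + len(payload), motif[0], rng)
        ssr_truth.append(
            {
                "motif": motif,
                "copies": copies,
                "start": start,
                "end": start + len(payload),
                "region": region,
            }
        )
        protect((start - 1, start + len(payload) + 1))

    repeat_truth = []
    for rtype, length, identity in spec.planted_repeats:
        n_mut = round((1 - identity) * length)
        for _ in range(100):
            segment = rng.choice(_BASES, size=length)
            seg_str = segment.tobytes().decode()
            if find_ssrs(seg_str) or _single_base_frac(segment) >= 0.85:
                continue
            break
        else:  # pragma: no cover
            raise CapacityError("could not draw a clean repeat segment")
        if rtype == "forward":
            partner = segment.copy()
        elif rtype == "reverse":
            partner = segment[::-1].copy()
        elif rtype == "complement":
            partner = _revcomp_arr(segment)[::-1].copy()
        elif rtype == "palindromic":
            partner = _revcomp_arr(segment)
        else:
            raise ValueError(f"unknown repeat type {rtype!r}")
        if n_mut:
            sites = rng.choice(np.arange(1, length - 1), size=n_mut, replace=False)
            for site in sites:
                old = partner[site]
                choices = _BASES[_BASES != old]
                partner[site] = choices[int(rng.integers(0, 3))]
        s1 = free_slot("LSC", length)
        _mirror_write(genome, partition, s1, segment)
        protect((s1, s1 + length))
        s2 = free_slot("LSC", length)
        _mirror_write(genome, partition, s2, partner)
        protect((s2, s2 + length))
        _break_repeat_flanks(genome, partition, rtype, s1, s2, length, rng)
        p1, p2 = sorted([(s1, s1 + length), (s2, s2 + length)])
        repeat_truth.append(
            {
                "type": rtype,
                "pos1": p1,
                "pos2": p2,
                "length": length,
                "identity": (length - n_mut) / length,
            }
        )

    amplicon_truth = []
    for fwd, rev, product in spec.primer_constructs:
        fwd, rev = fwd.upper(), rev.upper()
        if product < len(fwd) + len(rev):
            raise ValueError("product shorter than the two primers")
        start = free_slot("LSC", product)
        genome[start : start + len(fwd)] = np.frombuffer(fwd.encode(), dtype=np.uint8)
        tail = np.frombuffer(revcomp(rev).encode(), dtype=np.uint8)
        genome[start + product - len(rev) : start + product] = tail
        # only the primer footprints need protection; the spacer stays
        # subject to background screening (edits there keep the length)
        protect((start, start + len(fwd)))
        protect((start + product - len(rev), start + product))
        amplicon_truth.append(
            {"forward": fwd, "reverse": rev, "start": start, "length": product}
        )

    return ssr_truth, repeat_truth, amplicon_truth, protected


_COMP_BYTE = {ord("A"): ord("T"), ord("T"): ord("A"), ord("C"): ord("G"), ord("G"): ord("C")}


def _break_repeat_flanks(
    genome: np.ndarray,
    partition: RegionPartition,
    rtype: str,
    s1: int,
    s2: int,
    length: int,
    rng: np.random.Generator,
) -> None:
    """Make the bases just outside a planted repeat pair mismatch under the
    class transform, so the detected hit is exactly the planted interval."""
    if rtype in ("forward", "complement"):
        pairs = [(s1 - 1, s2 - 1), (s1 + length, s2 + length)]
    else:  # reverse / palindromic pair across opposite flanks
        pairs = [(s1 - 1, s2 + length), (s1 + length, s2 - 1)]
    complemented = rtype in ("complement", "palindromic")
    n = len(genome)
    for p, q in pairs:
        if not (0 <= p < n and 0 <= q < n):
            continue
        partner = _COMP_BYTE[int(genome[p])] if complemented else int(genome[p])
        if int(genome[q]) == partner:
            choices = [int(b) for b in _BASES if int(b) not in (partner, int(genome[q]))]
            payload = np.array(
                [choices[int(rng.integers(0, len(choices)))]], dtype=np.uint8
            )
            _mirror_write(genome, partition, q, payload)


def _single_base_frac(arr: np.ndarray) -> float:
    return max(int((arr == b).sum()) for b in _BASES) / len(arr)


def _set_breaking_base(
    genome: np.ndarray,
    partition: RegionPartition,
    pos: int,
    avoid: str,
    rng: np.random.Generator,
) -> None:
    n = len(genome)
    if not (0 <= pos < n):
        return
    forbidden = {ord(avoid), int(genome[pos])}
    choices = [b for b in _BASES if int(b) not in forbidden]
    payload = np.array([choices[int(rng.integers(0, len(choices)))]], dtype=np.uint8)
    _mirror_write(genome, partition, pos, payload)


def _screen_background(
    genome: np.ndarray,
    partition: RegionPartition,
    protected: list[tuple[int, int]],
    rng: np.random.Generator,
    max_edits: int = 1000,
) -> list[str]:
    """Destroy accidental SSRs/long repeats outside the protected intervals.

    Each offending feature gets a point edit near its middle (mirrored into
    the other IR where applicable); anything still present after the edit
    budget is reported as a residual feature.
    """

    def overlaps_protected(iv: tuple[int, int]) -> bool:
        return any(iv[0] < p[1] and p[0] < iv[1] for p in protected)

    edits = 0
    for _ in range(30):
        seq = genome.tobytes().decode()
        offenders: list[tuple[int, int]] = []
        for hit in find_ssrs(seq, partition=None):
            if not overlaps_protected((hit.start, hit.end)):
                offenders.append((hit.start, hit.end))
        for rep in find_long_repeats(seq, partition=partition):
            for iv in (rep.pos1, rep.pos2):
                if not overlaps_protected(iv):
                    offenders.append(iv)
                    break
        if not offenders:
            return []
        for s, e in offenders:
            if edits >= max_edits:
                break
            mid = (s + e) // 2
            old = genome[mid]
            choices = _BASES[_BASES != old]
            payload = np.array(
                [choices[int(rng.integers(0, 3))]], dtype=np.uint8
            )
            _mirror_write(genome, partition, mid, payload)
            edits += 1
        if edits >= max_edits:
            break
    seq = genome.tobytes().decode()
    residual = []
    for hit in find_ssrs(seq, partition=None):
        if not overlaps_protected((hit.start, hit.end)):
            residual.append(f"ssr:{hit.motif}x{hit.copies}@{hit.start}")
    for rep in find_long_repeats(seq, partition=partition):
        if not (
            overlaps_protected(rep.pos1) or overlaps_protected(rep.pos2)
        ):
            residual.append(f"repeat:{rep.type}:{rep.pos1}-{rep.pos2}")
    return residual


# ---------------------------------------------------------------------------
# taxon evolution
# ---------------------------------------------------------------------------


@dataclass
class EvolvedTaxa:
    """Descendant genomes plus per-gene alignments from known homology."""

    records: dict[str, PlastomeRecord]
    alignments: dict[str, Alignment]
    models_by_taxon: dict[str, list[GeneModel]]
    tree: dendropy.Tree
    event_taxa: dict[tuple[str, str], list[str]]  # (kind, gene) -> taxa affected


def evolve_taxa(
    ancestor: PlastomeRecord,
    tree: dendropy.Tree | str,
    sub_rate: float = 1.0,
    events: Sequence[tuple[Sequence[str], str, str]] = (),
    seed: int = 0,
) -> EvolvedTaxa:
    """Evolve an annotated ancestor along a tree with branch lengths.

    Substitutions follow an equal-rates (Jukes-Cantor) model: on a branch of
    length ``t`` each site substitutes with probability
    ``3/4 * (1 - exp(-4/3 * t * sub_rate))``.  Each event
    ``(clade_taxa, kind, gene)`` with kind ``intron_loss`` or ``gene_loss``
    is applied once on the stem edge of the named clade's MRCA, deleting the
    gene's intron bases (all copies) or its whole span.  Alignments are
    emitted from the known homology in ancestor coordinates, so no
    realignment is ever needed; deleted bases appear as gaps.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    tree.is_rooted = True  # evolution proceeds from the seed node
    rng = np.random.default_rng(seed)
    n = len(ancestor.sequence)
    anc = np.frombuffer(ancestor.sequence.encode(), dtype=np.uint8)
    base_index = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        base_index[b] = i
    anc_codes = base_index[anc]

    by_name = ancestor.annotations_by_name()
    event_deletions: dict[int, np.ndarray] = {}  # node id -> deletion mask
    event_taxa: dict[tuple[str, str], list[str]] = {}
    for clade_taxa, kind, gene in events:
        if gene not in by_name:
            raise KeyError(f"event references unknown gene {gene!r}")
        labels = set(clade_taxa)
        mrca = tree.mrca(taxon_labels=labels)
        mask = np.zeros(n, dtype=bool)
        for ann in by_name[gene]:
            if kind == "gene_loss":
                for s, e in ann.exons:
                    mask[s:e] = True
                for s, e in ann.intron_intervals():
                    mask[s:e] = True
            elif kind == "intron_loss":
                for s, e in ann.intron_intervals():
                    mask[s:e] = True
            else:
                raise ValueError(f"unknown event kind {kind!r}")
        key = id(mrca)
        event_deletions[key] = event_deletions.get(key, np.zeros(n, dtype=bool)) | mask
        event_taxa[(kind, gene)] = sorted(
            leaf.taxon.label for leaf in mrca.leaf_iter()
        )

    seqs: dict[int, np.ndarray] = {id(tree.seed_node): anc_codes.copy()}
    deleted: dict[int, np.ndarray] = {id(tree.seed_node): np.zeros(n, dtype=bool)}
    if id(tree.seed_node) in event_deletions:
        deleted[id(tree.seed_node)] |= event_deletions[id(tree.seed_node)]
    leaf_results: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for node in tree.preorder_node_iter():
        nid = id(node)
        if node.parent_node is not None:
            parent = id(node.parent_node)
            t = (node.edge.length or 0.0) * sub_rate
            p_sub = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
            codes = seqs[parent].copy()
            if p_sub > 0:
                hit = rng.random(n) < p_sub
                shifts = rng.integers(1, 4, size=int(hit.sum()))
                codes[hit] = (codes[hit] + shifts) % 4
            seqs[nid] = codes
            deleted[nid] = deleted[parent].copy()
            if nid in event_deletions:
                deleted[nid] |= event_deletions[nid]
        if node.is_leaf():
            leaf_results[node.taxon.label] = (seqs[nid], deleted[nid])
        else:
            pass
    # free internal sequences lazily (small trees; no action needed)

    records: dict[str, PlastomeRecord] = {}
    models_by_taxon: dict[str, list[GeneModel]] = {}
    for taxon, (codes, dmask) in leaf_results.items():
        keep = ~dmask
        new_coord = np.concatenate(([0], np.cumsum(keep)))
        seq = _BASES[codes[keep]].tobytes().decode()
        new_annotations = []
        models: list[GeneModel] = []
        seen_model: set[str] = set()
        for ann in ancestor.annotations:
            exons = []
            for s, e in sorted(ann.exons):
                ns, ne = int(new_coord[s]), int(new_coord[e])
                if ne > ns:
                    exons.append((ns, ne))
            if not exons:
                continue
            new_annotations.append(
                GeneAnnotation(
                    ann.name,
                    ann.category,
                    ann.strand,
                    exons,
                    is_pseudo=ann.is_pseudo,
                    copy_tag=ann.copy_tag,
                    trans_spliced=ann.trans_spliced,
                    wraps_origin=ann.wraps_origin,
                )
            )
            if ann.is_pseudo or ann.name in seen_model or ann.wraps_origin:
                continue
            seen_model.add(ann.name)
            models.append(_model_from_annotation(ann, new_coord, taxon))
        records[taxon] = PlastomeRecord(
            id=taxon,
            sequence=seq,
            is_circular=ancestor.is_circular,
            annotations=new_annotations,
            source="synthetic",
        )
        models_by_taxon[taxon] = models

    alignments: dict[str, Alignment] = {}
    taxa = sorted(leaf_results)
    for name, copies in by_name.items():
        ann = copies[0]
        if ann.is_pseudo:
            continue
        if ann.wraps_origin:
            continue
        if ann.trans_spliced:
            cols = [p for s, e in sorted(ann.exons) for p in range(s, e)]
        else:
            cols = list(range(*ann.span))
        rows = []
        for taxon in taxa:
            codes, dmask = leaf_results[taxon]
            chars = np.where(
                dmask[cols], ord("-"), _BASES[codes[cols]]
            ).astype(np.uint8)
            rows.append(chars.tobytes().decode())
        alignments[name] = Alignment(taxa=list(taxa), rows=rows)

    return EvolvedTaxa(
        records=records,
        alignments=alignments,
        models_by_taxon=models_by_taxon,
        tree=tree,
        event_taxa=event_taxa,
    )


def _model_from_annotation(
    ann: GeneAnnotation, new_coord: np.ndarray, taxon: str
) -> GeneModel:
    """Rebuild the exon/intron model after deletions, merging exons whose
    separating intron vanished."""
    exons = []
    introns = []
    sorted_exons = sorted(ann.exons)
    for i, (s, e) in enumerate(sorted_exons):
        exons.append(int(new_coord[e]) - int(new_coord[s]))
        if i + 1 < len(sorted_exons):
            introns.append(int(new_coord[sorted_exons[i + 1][0]]) - int(new_coord[e]))
    # merge exons across vanished introns; for a trans-spliced gene the gap
    # between its distant pieces is a trans junction, not an intron (cis
    # introns in plastomes are < 3 kb, so a 10 kb threshold separates them)
    segments: list[int | None] = [exons[0]]
    for intron, exon in zip(introns, exons[1:]):
        if intron == 0:
            segments[-1] = (segments[-1] or 0) + exon
        else:
            if ann.trans_spliced and intron > 10_000:
                segments.append(None)
            else:
                segments.append(intron)
            segments.append(exon)
    location = "IR" if ann.copy_tag != "single" else "LSC"
    return GeneModel(
        name=ann.name,
        location=location,
        segments=tuple(segments),
        trans_spliced=ann.trans_spliced,
    )
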