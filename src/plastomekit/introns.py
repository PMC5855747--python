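"""Exon/intron accounting, cross-taxon intron presence/absence, and
in-silico PCR.

The in-silico PCR predictor reproduces the classic intron-verification
experiment: a primer pair flanking an intron yields a short product when the
intron has been lost and a long one when it is retained, so predicted
product lengths discriminate intron presence without annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import revcomp

__all__ = [
    "GeneModel",
    "PrimerPair",
    "Amplicon",
    "intron_table",
    "in_silico_pcr",
    "intron_presence",
    "pairwise_global_align",
]


@dataclass
class GeneModel:
    """Exon/intron structure of one gene, as alternating segment lengths.

    ``segments`` alternates exon and intron lengths (exon I, intron I,
    exon II, ...).  For a trans-spliced gene (plastid rps12) the trans
    junction is recorded as ``None`` in an intron slot and is not counted as
    a cis intron.
    """

    name: str
    location: str  # LSC | SSC | IR
    segments: tuple[int | None, ...]
    trans_spliced: bool = False

    def __post_init__(self) -> None:
        if not self.segments or len(self.segments) % 2 == 0:
            raise ValueError(
                f"{self.name}: segments must alternate exon/intron and "
                "start and end with an exon"
            )
        for idx, s in enumerate(self.segments):
            if s is None:
                if idx % 2 == 0 or not self.trans_spliced:
                    raise ValueError(
                        f"{self.name}: None segments are only allowed in "
                        "intron slots of trans-spliced genes"
                    )
            elif s <= 0:
                raise ValueError(f"{self.name}: all segment lengths must be > 0")

    @property
    def exons(self) -> tuple[int, ...]:
        return tuple(s for s in self.segments[0::2])

    @property
    def introns(self) -> tuple[int, ...]:
        return tuple(s for s in self.segments[1::2] if s is not None)

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    @property
    def span(self) -> int:
        """Total cis length (trans junctions contribute nothing)."""
        return sum(s for s in self.segments if s is not None)


def intron_table(models: list[GeneModel]) -> pd.DataFrame:
    """Per-gene exon/intron lengths with derived totals.

    Columns: gene, location, exon lengths, intron lengths, intron count,
    total intron length, and the longest intron; trans-spliced genes count
    only cis introns.
    """
    rows = []
    for model in models:
        introns = model.introns
        rows.append(
            {
                "gene": model.name,
                "location": model.location,
                "exon_lengths": ",".join(map(str, model.exons)),
                "intron_lengths": ",".join(map(str, introns)),
                "n_introns": model.n_introns,
                "intron_total_bp": sum(introns),
                "longest_intron_bp": max(introns) if introns else None,
                "trans_spliced": model.trans_spliced,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PrimerPair:
    """A PCR primer pair, both written 5'->3'."""

    forward: str
    reverse: str
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()
        for primer in (self.forward, self.reverse):
            if len(primer) < 15:
                raise ValueError("primers must be >= 15 bases")
            if set(primer) - set("ACGT"):
                raise ValueError(f"primer {primer} has non-ACGT characters")


@dataclass
class Amplicon:
    start: int
    end: int  # exclusive; end > template length indicates an origin-spanning product
    length: int
    fwd_mismatches: int = 0
    rev_mismatches: int = 0


def _site_matches(
    template: str, site: str, max_mismatch: int, anchor3: int = 3
) -> list[tuple[int, int]]:
    """Positions where ``site`` occurs on the template's plus strand.

    The 3'-terminal ``anchor3`` bases must match exactly; up to
    ``max_mismatch`` mismatches are allowed elsewhere.  ``site`` is given in
    plus-strand orientation with its 3' end at the right.
    """
    L = len(site)
    out = []
    if max_mismatch == 0:
        start = 0
        while True:
            i = template.find(site, start)
            if i == -1:
                break
            out.append((i, 0))
            start = i + 1
        return out
    t = np.frombuffer(template.encode(), dtype=np.uint8)
    p = np.frombuffer(site.encode(), dtype=np.uint8)
    for i in range(len(template) - L + 1):
        window = t[i : i + L]
        if not np.array_equal(window[L - anchor3 :], p[L - anchor3 :]):
            continue
        mism = int((window != p).sum())
        if mism <= max_mismatch:
            out.append((i, mism))
    return out


def in_silico_pcr(
    template: str,
    primers: PrimerPair,
    circular: bool = False,
    max_product: int = 10_000,
) -> list[Amplicon]:
    """Predict PCR products of a primer pair on a template.

    The forward primer binds the plus strand as written; the reverse primer
    binds downstream as its reverse complement.  Product length is the
    outer-coordinate distance (both primer footprints included, matching gel
    sizing).  Circular templates also yield origin-spanning products.  With
    mismatches enabled, the 3'-terminal three bases of each primer must
    still match exactly.
    """
    template = template.upper()
    if not template:
        raise ValueError("empty template")
    n = len(template)
    work = template + template[: min(n, max_product)] if circular else template
    fwd_sites = _site_matches(work, primers.forward, primers.max_mismatch)
    # reverse primer anneals to the plus strand as revcomp(reverse); its 3'
    # anchor is at the *left* end of the plus-strand footprint, so match the
    # reversed pattern on the reversed template to reuse the right-anchor rule
    rc = revcomp(primers.reverse)
    rev_sites_rev = _site_matches(
        work[::-1], rc[::-1], primers.max_mismatch
    )
    rev_sites = [(len(work) - i - len(rc), m) for i, m in rev_sites_rev]
    out = []
    for fs, fm in fwd_sites:
        if fs >= n:  # forward sites only in the first copy
            continue
        for rs, rm in rev_sites:
            end = rs + len(rc)
            length = end - fs
            if length < len(primers.forward) + len(primers.reverse):
                continue
            if length > max_product or (circular and length > n):
                continue
            out.append(
                Amplicon(
                    start=fs, end=end, length=length, fwd_mismatches=fm, rev_mismatches=rm
                )
            )
    out.sort(key=lambda a: (a.start, a.length))
    return out


def intron_presence(
    models_by_taxon: dict[str, list[GeneModel]],
    gene: str,
    reference_taxon: str,
) -> pd.DataFrame:
    """Intron presence/absence of one gene across taxa.

    Per taxon: the gene's cis intron count, and a call of ``intron_loss``
    when it is below the reference count, ``gene_loss`` when the gene is
    absent, ``none`` otherwise.
    """
    if reference_taxon not in models_by_taxon:
        raise KeyError(f"reference taxon {reference_taxon!r} missing")
    ref_models = {m.name: m for m in models_by_taxon[reference_taxon]}
    if gene not in ref_models:
        raise KeyError(f"gene {gene!r} absent from reference {reference_taxon!r}")
    ref_count = ref_models[gene].n_introns
    if ref_count < 1:
        raise ValueError(f"reference copy of {gene!r} has no intron")
    rows = []
    for taxon, models in models_by_taxon.items():
        named = {m.name: m for m in models}
        if gene not in named:
            rows.append({"taxon": taxon, "introns": 0, "call": "gene_loss"})
            continue
        count = named[gene].n_introns
        call = "intron_loss" if count < ref_count else "none"
        rows.append({"taxon": taxon, "introns": count, "call": call})
    return pd.DataFrame(rows)


def pairwise_global_align(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> tuple[str, str, float]:
    """Needleman-Wunsch global alignment with linear gap costs.

    Ties break deterministically: diagonal, then up (gap in ``b``), then
    left (gap in ``a``).  Returns the two aligned strings and the score.
    """
    if not a or not b:
        raise ValueError("pairwise_global_align requires non-empty strings")
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[:, 0] = gap * np.arange(n + 1)
    score[0, :] = gap * np.arange(m + 1)
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    sub = np.where(
        np.frombuffer(a.encode(), dtype=np.uint8)[:, None]
        == np.frombuffer(b.encode(), dtype=np.uint8)[None, :],
        match,
        mismatch,
    )
    for i in range(1, n + 1):
        diag = score[i - 1, :-1] + sub[i - 1]
        for j in range(1, m + 1):
            best = diag[j - 1]
            move = 0
            up = score[i - 1, j] + gap
            if up > best:
                best, move = up, 1
            left = score[i, j - 1] + gap
            if left > best:
                best, move = left, 2
            score[i, j] = best
            ptr[i, j] = move
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        move = ptr[i, j]
        if move == 0 and i > 0 and j > 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif move == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score[n, m])
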