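"""K-mer dot-plot comparison of two plastomes and inversion detection.

Shared k-mers (in both orientations) between the two sequences form anchor
points; chaining collinear anchors yields match segments, and inverted
segments above a size threshold are reported as structural rearrangements.
Because plastomes carry a genome-scale inverted repeat, anti-diagonal
anchors between the IR copies are expected even for perfectly collinear
genomes; segments lying inside the IRs on both genomes are therefore not
counted as inversions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import PlastomeRecord, RegionPartition, revcomp

__all__ = ["MatchSegment", "dotplot", "detect_rearrangements"]


@dataclass
class MatchSegment:
    a_interval: tuple[int, int]
    b_interval: tuple[int, int]
    orientation: str  # forward | inverted
    anchors: int

    @property
    def length(self) -> int:
        return self.a_interval[1] - self.a_interval[0]


def _kmer_counts(seq: str, k: int) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            out.setdefault(kmer, []).append(i)
    return out


def dotplot(
    a: PlastomeRecord | str, b: PlastomeRecord | str, k: int = 21
) -> pd.DataFrame:
    """All shared k-mer anchors between two sequences, both orientations.

    Only k-mers unique in each sequence (counting both orientations within
    that sequence) are used, which suppresses repeat-induced noise.  Returns
    a DataFrame with columns ``a_pos``, ``b_pos``, ``orientation``; for an
    inverted anchor ``b_pos`` is the plus-strand start of the reverse
    complement occurrence in ``b``.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    seq_a = a.sequence if isinstance(a, PlastomeRecord) else a
    seq_b = b.sequence if isinstance(b, PlastomeRecord) else b
    if len(seq_a) < k or len(seq_b) < k:
        raise ValueError("sequences must be at least k long")
    idx_a = _kmer_counts(seq_a, k)
    idx_b = _kmer_counts(seq_b, k)

    # a k-mer is usable when it occurs exactly once (plus strand) in each
    # sequence; forward and inverted co-occurrences are emitted separately,
    # so a quadripartite IR contributes its expected anti-diagonal anchors
    # while multi-copy repeat noise is suppressed
    rows = []
    for kmer, positions in idx_a.items():
        if len(positions) != 1:
            continue
        fwd_hits = idx_b.get(kmer, ())
        if len(fwd_hits) == 1:
            rows.append((positions[0], fwd_hits[0], "forward"))
        rc = revcomp(kmer)
        rev_hits = idx_b.get(rc, ()) if rc != kmer else ()
        if len(rev_hits) == 1:
            rows.append((positions[0], rev_hits[0], "inverted"))
    return pd.DataFrame(rows, columns=["a_pos", "b_pos", "orientation"]).sort_values(
        ["a_pos", "b_pos"]
    ).reset_index(drop=True)


def detect_rearrangements(
    anchors: pd.DataFrame,
    min_block: int = 5000,
    k: int = 21,
    min_chain: int = 5,
    max_gap: int | None = None,
    ir_a: RegionPartition | None = None,
    ir_b: RegionPartition | None = None,
) -> tuple[list[MatchSegment], str]:
    """Chain anchors into collinear segments and call large inversions.

    Chaining is single-linkage along each (anti-)diagonal with a positional
    gap tolerance of ``max_gap`` (default 200 bp: a single substitution
    destroys a full k-mer's worth of anchors, so the tolerance must span
    several nearby substitutions at percent-level divergence); segments need
    at least ``min_chain`` anchors.
    Returns the segments and a verdict: ``"collinear"`` when no inverted
    segment of at least ``min_block`` exists (segments lying within the
    quadripartite IRs of both genomes, when partitions are supplied, are
    exempt), otherwise ``"rearranged"``.
    """
    segments: list[MatchSegment] = []
    gap_tol = max_gap if max_gap is not None else max(2 * k, 200)
    for orientation, sub in anchors.groupby("orientation"):
        a_pos = sub["a_pos"].to_numpy()
        b_pos = sub["b_pos"].to_numpy()
        diag = b_pos - a_pos if orientation == "forward" else b_pos + a_pos
        order = np.lexsort((a_pos, diag))
        a_pos, b_pos, diag = a_pos[order], b_pos[order], diag[order]
        if len(a_pos) == 0:
            continue
        breaks = np.flatnonzero(
            (np.abs(np.diff(diag)) > gap_tol)
            | (np.abs(np.diff(a_pos)) > gap_tol)
        )
        starts = np.concatenate(([0], breaks + 1))
        stops = np.concatenate((breaks + 1, [len(a_pos)]))
        for lo, hi in zip(starts, stops):
            if hi - lo < min_chain:
                continue
            segments.append(
                MatchSegment(
                    (int(a_pos[lo:hi].min()), int(a_pos[lo:hi].max()) + k),
                    (int(b_pos[lo:hi].min()), int(b_pos[lo:hi].max()) + k),
                    str(orientation),
                    int(hi - lo),
                )
            )
    segments.sort(key=lambda s: s.a_interval)

    def in_ir(iv: tuple[int, int], part: RegionPartition | None) -> bool:
        if part is None:
            return False
        for region in (part.ira, part.irb):
            if region[0] <= iv[0] and iv[1] <= region[1]:
                return True
        return False

    inversions = [
        s
        for s in segments
        if s.orientation == "inverted"
        and s.length >= min_block
        and not (in_ir(s.a_interval, ir_a) and in_ir(s.b_interval, ir_b))
    ]
    verdict = "rearranged" if inversions else "collinear"
    return segments, verdict
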