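"""SSR scanning and long-repeat detection in the four REPuter classes.

SSRs are maximal perfect tandem runs of a primitive 1-6 bp motif, reported
when the copy number reaches a motif-length-specific cutoff (default 8 for
mononucleotide, 4 for dinucleotide, 3 for tri- through hexanucleotide
motifs).  Long repeats are maximal gapless pairings of two loci in one of
four relations -- forward (identical), reverse (reversed), complement
(base-complemented) or palindromic (reverse-complemented) -- of at least 30
bp with Hamming identity of at least 0.90.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import class_mask
from .records import PlastomeRecord, RegionPartition, complement, revcomp

__all__ = [
    "SSRHit",
    "RepeatHit",
    "DEFAULT_SSR_THRESHOLDS",
    "find_ssrs",
    "find_long_repeats",
    "repeat_summary",
    "ssr_summary",
]

DEFAULT_SSR_THRESHOLDS: dict[int, int] = {1: 8, 2: 4, 3: 3, 4: 3, 5: 3, 6: 3}

REPEAT_TYPES = ("forward", "reverse", "complement", "palindromic")


@dataclass
class SSRHit:
    motif: str
    copies: int
    start: int
    end: int
    region: str | None = None  # LSC | SSC | IR
    context: str | None = None  # coding | intron | intergenic

    @property
    def motif_length(self) -> int:
        return len(self.motif)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class RepeatHit:
    type: str  # forward | reverse | complement | palindromic
    pos1: tuple[int, int]
    pos2: tuple[int, int]
    length: int
    identity: float


def is_primitive(motif: str) -> bool:
    """True when the motif is not a repetition of a shorter motif."""
    m = len(motif)
    for p in range(1, m):
        if m % p == 0 and motif == motif[: p] * (m // p):
            return False
    return True


def _tandem_candidates(seq: str, m: int, min_copies: int) -> list[SSRHit]:
    """Maximal tandem runs of period m with >= min_copies whole copies."""
    n = len(seq)
    if n < m * min_copies:
        return []
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    eq = s[: n - m] == s[m:]
    hits = []
    # maximal True runs of eq
    padded = np.concatenate(([False], eq, [False]))
    changes = np.flatnonzero(padded[1:] != padded[:-1])
    for start, stop in zip(changes[::2], changes[1::2]):
        r = stop - start  # run of r positions where s[i] == s[i+m]
        copies = (r + m) // m
        if copies < min_copies:
            continue
        motif = seq[start : start + m]
        if "N" in motif or not is_primitive(motif):
            continue
        hits.append(
            SSRHit(motif=motif, copies=copies, start=start, end=start + copies * m)
        )
    return hits


def find_ssrs(
    record: PlastomeRecord | str,
    partition: RegionPartition | None = None,
    thresholds: dict[int, int] | None = None,
    collapse_ir: bool = False,
) -> list[SSRHit]:
    """Scan for simple sequence repeats meeting the copy-number cutoffs.

    Overlapping hits of different period (e.g. a homopolymer embedded in a
    longer dinucleotide run) are resolved by keeping the hit with the longer
    total span.  Compound SSRs are not merged: adjacent runs of distinct
    motifs stay separate hits.  With ``collapse_ir`` and a partition, hits
    at mirrored loci inside the two IRs are collapsed to one representative.
    """
    seq = record.sequence if isinstance(record, PlastomeRecord) else record
    thresholds = {**DEFAULT_SSR_THRESHOLDS, **(thresholds or {})}
    candidates: list[SSRHit] = []
    for m, min_copies in sorted(thresholds.items()):
        candidates.extend(_tandem_candidates(seq, m, min_copies))
    # overlap resolution: prefer longer span, then shorter motif, then start
    candidates.sort(key=lambda h: (-h.span, h.motif_length, h.start))
    kept: list[SSRHit] = []
    for hit in candidates:
        if all(hit.end <= o.start or o.end <= hit.start for o in kept):
            kept.append(hit)
    kept.sort(key=lambda h: h.start)

    if partition is not None and isinstance(record, PlastomeRecord):
        mask = class_mask(record)
        for hit in kept:
            hit.region = _majority_region_of_interval(hit.start, hit.end, partition)
            hit.context = _majority_context(mask, hit.start, hit.end)
        if collapse_ir:
            kept = _collapse_ir_ssrs(kept, partition)
    return kept


def _majority_region_of_interval(
    start: int, end: int, partition: RegionPartition
) -> str:
    counts = {"LSC": 0, "IR": 0, "SSC": 0}
    for region, iv in (
        ("LSC", partition.lsc),
        ("IR", partition.ira),
        ("SSC", partition.ssc),
        ("IR", partition.irb),
    ):
        lo, hi = max(start, iv[0]), min(end, iv[1])
        if hi > lo:
            counts[region] += hi - lo
    return max(counts, key=lambda r: (counts[r], r))


def _majority_context(mask: np.ndarray, start: int, end: int) -> str:
    window = mask[start:end]
    coding = int((window >= 2).sum())
    intron = int((window == 1).sum())
    intergenic = int((window == 0).sum())
    best = max(
        [("coding", coding), ("intron", intron), ("intergenic", intergenic)],
        key=lambda kv: kv[1],
    )
    return best[0]


def _collapse_ir_ssrs(
    hits: list[SSRHit], partition: RegionPartition
) -> list[SSRHit]:
    """Collapse mirrored duplicate SSRs inside the two IR copies."""
    ira, irb = partition.ira, partition.irb
    kept: list[SSRHit] = []
    seen_mirrors: set[tuple[int, int]] = set()
    for hit in sorted(hits, key=lambda h: h.start):
        if irb[0] <= hit.start and hit.end <= irb[1]:
            # mirrored interval in IRa
            m_end = ira[0] + (irb[1] - hit.start)
            m_start = ira[0] + (irb[1] - hit.end)
            if (m_start, m_end) in seen_mirrors:
                continue
        if ira[0] <= hit.start and hit.end <= ira[1]:
            seen_mirrors.add((hit.start, hit.end))
        kept.append(hit)
    return kept


# ---------------------------------------------------------------------------
# long repeats
# ---------------------------------------------------------------------------


MIN_TERMINAL_RUN = 8  # shortest exact run allowed at a hit's ends


def _maximal_windows(
    match: np.ndarray, min_len: int, min_identity: float
) -> list[tuple[int, int, int]]:
    """Qualifying repeat windows on one diagonal's match vector.

    A window qualifies when its length is at least ``min_len``, its Hamming
    identity at least ``min_identity``, and each of its terminal exact runs
    is at least ``MIN_TERMINAL_RUN`` long (so chance flank matches cannot
    drag a sub-threshold exact repeat over the length cutoff).  Windows
    contained in a longer qualifying window are dropped, and overlapping
    windows resolve to the longest (ties: fewest mismatches, then leftmost).
    Returns ``(start, end_exclusive, mismatches)`` triples.
    """
    total = len(match)
    if total < min_len:
        return []
    # fast rejection: any qualifying window (length >= min_len, identity >=
    # min_identity) contains a min_len subwindow whose mismatch count is at
    # most floor((1 - min_identity) * min_len), by an averaging argument
    cum = np.concatenate(([0], np.cumsum(match)))
    window_matches = cum[min_len:] - cum[:-min_len]
    if window_matches.max() < min_len - int((1 - min_identity) * min_len + 1e-9):
        return []
    mismatch_pos = np.flatnonzero(~match)
    bounds = list(mismatch_pos)
    qualifying: list[tuple[int, int, int]] = []
    m = len(bounds)
    max_mism = int((1 - min_identity) * total + 1e-9)
    edges = [-1] + bounds + [total]
    min_terminal = min(MIN_TERMINAL_RUN, min_len)
    for a in range(m + 1):
        start = edges[a] + 1
        if start >= total:
            continue
        for b in range(min(m, a + max_mism), a - 1, -1):
            end = edges[b + 1] - 1
            if end < start:
                continue
            length = end - start + 1
            mism = b - a
            if mism > 0:
                left_run = edges[a + 1] - edges[a] - 1
                right_run = edges[b + 1] - edges[b] - 1
                if left_run < min_terminal or right_run < min_terminal:
                    continue
            if length >= min_len and (length - mism) / length >= min_identity:
                qualifying.append((start, end + 1, mism))
    qualifying = sorted(set(qualifying))
    # drop windows contained in another qualifying window
    maximal = [
        w
        for w in qualifying
        if not any(o != w and o[0] <= w[0] and o[1] >= w[1] for o in qualifying)
    ]
    # resolve remaining overlaps: longest, then fewest mismatches, then left
    maximal.sort(key=lambda w: (-(w[1] - w[0]), w[2], w[0]))
    kept: list[tuple[int, int, int]] = []
    for w in maximal:
        if all(w[1] <= o[0] or o[1] <= w[0] for o in kept):
            kept.append(w)
    return sorted(kept)


def _seed_positions(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(i)
    return index


def _cluster(points: list[int], gap: int) -> list[list[int]]:
    clusters: list[list[int]] = []
    for p in sorted(set(points)):
        if clusters and p - clusters[-1][-1] <= gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters


def find_long_repeats(
    record: PlastomeRecord | str,
    min_len: int = 30,
    min_identity: float = 0.90,
    seed_len: int = 11,
    partition: RegionPartition | None = None,
) -> list[RepeatHit]:
    """Detect long repeats of the four classes by seed-and-extend.

    Exact ``seed_len``-mers shared between the two loci (under the class's
    transform) anchor candidate diagonals; around each seed cluster the
    maximal windows satisfying the length and identity thresholds are
    enumerated.  Nested hits (both intervals inside another hit's intervals)
    and low-complexity hits (an interval >= 90% one nucleotide) are removed.
    When a partition is supplied, the genome-scale IR pair itself is excluded
    and mirrored duplicates inside the IRs are collapsed to one
    representative.
    """
    seq = record.sequence if isinstance(record, PlastomeRecord) else record
    if min_len < 8:
        raise ValueError("min_len must be >= 8 (seed length bound)")
    seed_len = min(seed_len, min_len)
    n = len(seq)
    if n < min_len:
        return []
    s_bytes = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp_bytes = np.frombuffer(complement(seq).encode(), dtype=np.uint8)
    index = _seed_positions(seq, seed_len)

    hits: list[RepeatHit] = []
    margin = 2 * min_len

    def _diagonal_hits(rtype: str) -> None:
        """Forward/complement: pairing s[p] with t[p + delta]."""
        t_bytes = s_bytes if rtype == "forward" else comp_bytes
        pair_seeds: dict[int, list[int]] = {}
        for kmer, positions in index.items():
            target = kmer if rtype == "forward" else complement(kmer)
            tpos = index.get(target, ())
            for i in positions:
                for j in tpos:
                    if j > i:
                        pair_seeds.setdefault(j - i, []).append(i)
        for delta, starts in pair_seeds.items():
            limit = n - delta
            for cluster in _cluster(starts, margin):
                lo = max(0, cluster[0] - margin)
                hi = min(limit, cluster[-1] + seed_len + margin)
                match = s_bytes[lo:hi] == t_bytes[lo + delta : hi + delta]
                for ws, we, mism in _maximal_windows(match, min_len, min_identity):
                    p1 = (lo + ws, lo + we)
                    p2 = (lo + ws + delta, lo + we + delta)
                    if p1[1] > p2[0]:  # overlapping copies: tandem, not a pair
                        continue
                    length = we - ws
                    hits.append(
                        RepeatHit(rtype, p1, p2, length, (length - mism) / length)
                    )

    def _antidiagonal_hits(rtype: str) -> None:
        """Reverse/palindromic: pairing s[p] with t[d - p]."""
        t_bytes = s_bytes if rtype == "reverse" else comp_bytes
        pair_seeds: dict[int, list[int]] = {}
        for kmer, positions in index.items():
            target = kmer[::-1] if rtype == "reverse" else revcomp(kmer)
            tpos = index.get(target, ())
            for i in positions:
                for j in tpos:
                    if j >= i:
                        pair_seeds.setdefault(i + j + seed_len - 1, []).append(i)
        for d, starts in pair_seeds.items():
            for cluster in _cluster(starts, margin):
                lo = max(0, cluster[0] - margin, d - n + 1)
                hi = min((d - 1) // 2, cluster[-1] + seed_len - 1 + margin)
                if hi < lo:
                    continue
                ps = np.arange(lo, hi + 1)
                match = s_bytes[ps] == t_bytes[d - ps]
                for ws, we, mism in _maximal_windows(match, min_len, min_identity):
                    p1 = (lo + ws, lo + we)
                    p2 = (d - (lo + we) + 1, d - (lo + ws) + 1)
                    if p1[1] > p2[0]:
                        continue
                    length = we - ws
                    hits.append(
                        RepeatHit(rtype, p1, p2, length, (length - mism) / length)
                    )

    _diagonal_hits("forward")
    _diagonal_hits("complement")
    _antidiagonal_hits("palindromic")
    _antidiagonal_hits("reverse")

    # deduplicate identical hits found from different seeds
    uniq: dict[tuple, RepeatHit] = {}
    for h in hits:
        uniq.setdefault((h.type, h.pos1, h.pos2), h)
    hits = list(uniq.values())

    hits = [h for h in hits if not _low_complexity(seq, h)]
    hits = _remove_nested(hits)

    if partition is not None:
        hits = _exclude_ir_pair(hits, partition)
        hits = _collapse_ir_repeats(hits, partition)
    hits.sort(key=lambda h: (h.pos1, h.pos2, h.type))
    return hits


def _low_complexity(seq: str, hit: RepeatHit, frac: float = 0.90) -> bool:
    for s, e in (hit.pos1, hit.pos2):
        window = seq[s:e]
        if max(window.count(b) for b in "ACGT") >= frac * len(window):
            return True
    return False


def _remove_nested(hits: list[RepeatHit]) -> list[RepeatHit]:
    def contained(inner: tuple[int, int], outer: tuple[int, int]) -> bool:
        return outer[0] <= inner[0] and inner[1] <= outer[1]

    kept = []
    for h in hits:
        nested = False
        for g in hits:
            if g is h or g.length < h.length:
                continue
            if g.length == h.length and (g.pos1, g.pos2) == (h.pos1, h.pos2):
                continue
            if (contained(h.pos1, g.pos1) and contained(h.pos2, g.pos2)) or (
                contained(h.pos1, g.pos2) and contained(h.pos2, g.pos1)
            ):
                nested = True
                break
        if not nested:
            kept.append(h)
    return kept


def _exclude_ir_pair(
    hits: list[RepeatHit], partition: RegionPartition
) -> list[RepeatHit]:
    """Drop the palindromic hit that is the quadripartite IR pair itself."""
    ira, irb = partition.ira, partition.irb
    ir_len = ira[1] - ira[0]

    def is_the_ir(h: RepeatHit) -> bool:
        if h.type != "palindromic" or h.length < 0.5 * ir_len:
            return False
        o1 = min(h.pos1[1], ira[1]) - max(h.pos1[0], ira[0])
        o2 = min(h.pos2[1], irb[1]) - max(h.pos2[0], irb[0])
        return o1 >= 0.9 * h.length and o2 >= 0.9 * h.length

    return [h for h in hits if not is_the_ir(h)]


def _collapse_ir_repeats(
    hits: list[RepeatHit], partition: RegionPartition
) -> list[RepeatHit]:
    """Collapse hits whose intervals all lie inside the IRs and that are
    mirror images of an already-kept hit."""
    ira, irb = partition.ira, partition.irb

    def inside_ir(iv: tuple[int, int]) -> bool:
        return (ira[0] <= iv[0] and iv[1] <= ira[1]) or (
            irb[0] <= iv[0] and iv[1] <= irb[1]
        )

    def mirror(iv: tuple[int, int]) -> tuple[int, int]:
        if ira[0] <= iv[0] and iv[1] <= ira[1]:
            return (irb[1] - (iv[1] - ira[0]), irb[1] - (iv[0] - ira[0]))
        return (ira[0] + (irb[1] - iv[1]), ira[0] + (irb[1] - iv[0]))

    kept: list[RepeatHit] = []
    seen: set[tuple] = set()
    for h in sorted(hits, key=lambda x: (x.pos1, x.pos2, x.type)):
        if inside_ir(h.pos1) and inside_ir(h.pos2):
            key = (h.type, h.length, tuple(sorted([h.pos1, h.pos2])))
            m1, m2 = mirror(h.pos1), mirror(h.pos2)
            mirror_key = (h.type, h.length, tuple(sorted([m1, m2])))
            if mirror_key in seen:
                continue
            seen.add(key)
        kept.append(h)
    return kept


def repeat_summary(hits: list[RepeatHit], by: str = "type") -> pd.DataFrame:
    """Counts of long-repeat hits by ``type`` or ``length_bin``.

    Length bins are 10 bp wide starting at 30.  A ``total`` row is appended.
    """
    rows: dict[str, int]
    if by == "type":
        rows = {t: 0 for t in REPEAT_TYPES}
        for h in hits:
            rows[h.type] += 1
    elif by == "length_bin":
        rows = {}
        for h in hits:
            lo = 30 + 10 * ((h.length - 30) // 10) if h.length >= 30 else 0
            label = f"{lo}-{lo + 9}"
            rows[label] = rows.get(label, 0) + 1
    else:
        raise ValueError(f"unknown facet {by!r}")
    df = pd.DataFrame({"group": list(rows), "count": list(rows.values())})
    df.loc[len(df)] = {"group": "total", "count": sum(rows.values())}
    return df


def ssr_summary(hits: list[SSRHit], by: str = "motif_length") -> pd.DataFrame:
    """Counts of SSR hits by ``motif_length``, ``region`` or ``context``."""
    rows: dict = {}
    for h in hits:
        if by == "motif_length":
            key = h.motif_length
        elif by == "region":
            key = h.region
        elif by == "context":
            key = h.context
        else:
            raise ValueError(f"unknown facet {by!r}")
        rows[key] = rows.get(key, 0) + 1
    df = pd.DataFrame(
        {"group": list(rows), "count": list(rows.values())}
    ).sort_values("group", key=lambda s: s.astype(str)).reset_index(drop=True)
    df.loc[len(df)] = {"group": "total", "count": sum(rows.values())}
    return df
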