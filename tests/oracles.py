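"""Independent brute-force oracles used to cross-check the scanners.

These deliberately avoid the seeded/clustered code paths of the package:
SSRs are found by direct motif counting at every position, long repeats by
building complete per-diagonal match vectors, PCR sites by comparing every
substring, the inverted repeat by a quadratic anti-diagonal sweep, and
parsimony lengths by exhaustive enumeration of internal-node labelings.
"""

from __future__ import annotations

import itertools

import numpy as np

COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


def complement(s: str) -> str:
    return "".join(COMP[c] for c in s)


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------


def _primitive(motif: str) -> bool:
    for p in range(1, len(motif)):
        if len(motif) % p == 0 and motif == motif[:p] * (len(motif) // p):
            return False
    return True


def brute_ssrs(seq: str, thresholds: dict[int, int]) -> list[tuple[str, int, int, int]]:
    """(motif, copies, start, end) tuples under the same reporting policy:
    leftmost maximal whole-copy runs, primitive motifs, overlaps resolved to
    the longest span (ties: shorter motif, then start)."""
    candidates = []
    n = len(seq)
    for m, min_copies in thresholds.items():
        for i in range(n - m + 1):
            motif = seq[i : i + m]
            if "N" in motif or not _primitive(motif):
                continue
            if i >= m and seq[i - m : i] == motif:
                continue  # not leftmost
            copies = 1
            while seq[i + copies * m : i + (copies + 1) * m] == motif:
                copies += 1
            if copies >= min_copies:
                candidates.append((motif, copies, i, i + copies * m))
    candidates.sort(key=lambda c: (-(c[3] - c[2]), len(c[0]), c[2]))
    kept: list[tuple[str, int, int, int]] = []
    for c in candidates:
        if all(c[3] <= o[2] or o[3] <= c[2] for o in kept):
            kept.append(c)
    return sorted(kept, key=lambda c: c[2])


# ---------------------------------------------------------------------------
# long repeats
# ---------------------------------------------------------------------------


def _windows_from_match(match, min_len, min_identity, min_terminal=8):
    """Qualifying windows from one full diagonal match vector, by direct
    enumeration over match-position endpoint pairs."""
    match = np.asarray(match, dtype=bool)
    pos = np.flatnonzero(match)
    cum = np.concatenate(([0], np.cumsum(match)))
    wins = []
    for ai in range(len(pos)):
        for bi in range(len(pos) - 1, ai - 1, -1):
            i, j = int(pos[ai]), int(pos[bi])
            length = j - i + 1
            if length < min_len:
                break
            matches = int(cum[j + 1] - cum[i])
            mism = length - matches
            if matches / length < min_identity:
                continue
            if mism > 0:
                # terminal exact runs
                lt = 0
                while i + lt <= j and match[i + lt]:
                    lt += 1
                rt = 0
                while j - rt >= i and match[j - rt]:
                    rt += 1
                if lt < min_terminal or rt < min_terminal:
                    continue
            wins.append((i, j + 1, mism))
    # containment then overlap resolution (longest, fewest mism, leftmost)
    maximal = [
        w
        for w in wins
        if not any(o != w and o[0] <= w[0] and o[1] >= w[1] for o in wins)
    ]
    maximal.sort(key=lambda w: (-(w[1] - w[0]), w[2], w[0]))
    kept = []
    for w in maximal:
        if all(w[1] <= o[0] or o[1] <= w[0] for o in kept):
            kept.append(w)
    return sorted(kept)


def brute_long_repeats(seq: str, min_len: int = 30, min_identity: float = 0.90):
    """All qualifying repeat pairs by full-diagonal enumeration.

    Returns (type, pos1, pos2, length, identity) tuples before the nested /
    low-complexity post-filters (apply those separately when comparing).
    """
    n = len(seq)
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp_arr = np.frombuffer(complement(seq).encode(), dtype=np.uint8)
    hits = []
    for rtype in ("forward", "complement"):
        t = s if rtype == "forward" else comp_arr
        for delta in range(1, n - min_len + 1):
            match = s[: n - delta] == t[delta:]
            for ws, we, mism in _windows_from_match(match, min_len, min_identity):
                p1 = (ws, we)
                p2 = (ws + delta, we + delta)
                if p1[1] > p2[0]:
                    continue
                L = we - ws
                hits.append((rtype, p1, p2, L, (L - mism) / L))
    for rtype in ("reverse", "palindromic"):
        t = s if rtype == "reverse" else comp_arr
        for d in range(2 * min_len - 1, 2 * n - 2):
            lo = max(0, d - n + 1)
            hi = (d - 1) // 2
            if hi - lo + 1 < min_len:
                continue
            ps = np.arange(lo, hi + 1)
            match = s[ps] == t[d - ps]
            for ws, we, mism in _windows_from_match(match, min_len, min_identity):
                p1 = (lo + ws, lo + we)
                p2 = (d - (lo + we) + 1, d - (lo + ws) + 1)
                if p1[1] > p2[0]:
                    continue
                L = we - ws
                hits.append((rtype, p1, p2, L, (L - mism) / L))
    return hits


def low_complexity(seq: str, hit, frac: float = 0.90) -> bool:
    for s_, e_ in (hit[1], hit[2]):
        window = seq[s_:e_]
        if max(window.count(b) for b in "ACGT") >= frac * len(window):
            return True
    return False


def remove_nested(hits):
    def contained(inner, outer):
        return outer[0] <= inner[0] and inner[1] <= outer[1]

    kept = []
    for h in hits:
        nested = False
        for g in hits:
            if g is h or g[3] < h[3]:
                continue
            if g[3] == h[3] and (g[1], g[2]) == (h[1], h[2]):
                continue
            if (contained(h[1], g[1]) and contained(h[2], g[2])) or (
                contained(h[1], g[2]) and contained(h[2], g[1])
            ):
                nested = True
                break
        if not nested:
            kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------


def brute_pcr(
    template: str,
    fwd: str,
    rev: str,
    max_mismatch: int = 0,
    circular: bool = False,
    max_product: int = 10_000,
    anchor3: int = 3,
):
    """(start, end, length) products by comparing every substring."""
    n = len(template)
    work = template + (template[: min(n, max_product)] if circular else "")
    rc = revcomp(rev)

    def sites(pattern: str, anchor_left: bool) -> list[int]:
        L = len(pattern)
        out = []
        for i in range(len(work) - L + 1):
            window = work[i : i + L]
            mism = sum(1 for a, b in zip(window, pattern) if a != b)
            anchor = window[:anchor3] == pattern[:anchor3] if anchor_left else (
                window[L - anchor3 :] == pattern[L - anchor3 :]
            )
            if mism <= max_mismatch and (max_mismatch == 0 or anchor):
                out.append(i)
        return out

    products = []
    for fs in sites(fwd, anchor_left=False):
        if fs >= n:
            continue
        for rs in sites(rc, anchor_left=True):
            end = rs + len(rc)
            length = end - fs
            if length < len(fwd) + len(rev) or length > max_product:
                continue
            if circular and length > n:
                continue
            products.append((fs, end, length))
    return sorted(products)


# ---------------------------------------------------------------------------
# inverted repeat
# ---------------------------------------------------------------------------


def brute_ir(seq: str, min_len: int) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """Longest disjoint reverse-complement pair (zero mismatches) by a full
    anti-diagonal sweep; ties toward the smaller first-start."""
    n = len(seq)
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp_arr = np.frombuffer(complement(seq).encode(), dtype=np.uint8)
    best = None
    for d in range(2 * min_len - 1, 2 * n - 2):
        lo = max(0, d - n + 1)
        hi = (d - 1) // 2
        if hi < lo:
            continue
        ps = np.arange(lo, hi + 1)
        match = s[ps] == comp_arr[d - ps]
        padded = np.concatenate(([False], match, [False]))
        changes = np.flatnonzero(padded[1:] != padded[:-1])
        for a, b in zip(changes[::2], changes[1::2]):
            L = int(b - a)
            if L < min_len:
                continue
            p0 = lo + int(a)
            cand = (L, p0, d)
            if best is None or (cand[0], -cand[1]) > (best[0], -best[1]):
                best = cand
    if best is None:
        return None
    L, p0, d = best
    return ((p0, p0 + L), (d - (p0 + L) + 1, d - p0 + 1))


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------


def brute_fitch_column(states: dict[str, str], newick: str) -> int:
    """Minimum mutation count of one column on one topology, by exhaustive
    labeling of internal nodes (and of leaves with missing data)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    nodes = list(tree.preorder_node_iter())
    free = [
        node
        for node in nodes
        if not node.is_leaf() or states[node.taxon.label] not in "ACGT"
    ]
    fixed = {
        id(node): states[node.taxon.label]
        for node in nodes
        if node.is_leaf() and states[node.taxon.label] in "ACGT"
    }
    best = None
    for combo in itertools.product("ACGT", repeat=len(free)):
        labels = dict(fixed)
        for node, state in zip(free, combo):
            labels[id(node)] = state
        cost = 0
        for node in nodes:
            if node.parent_node is not None:
                cost += labels[id(node)] != labels[id(node.parent_node)]
        if best is None or cost < best:
            best = cost
    return int(best)
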