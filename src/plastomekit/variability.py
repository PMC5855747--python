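"""Per-gene alignment statistics and parsimony-based variability indices.

Given a multiple alignment of one gene across taxa and a tree topology, the
module computes conserved and parsimony-informative site counts, the
percentage of parsimony-informative sites (PI%), the consistency index (CI)
and retention index (RI) from Fitch small-parsimony step counts, and mean
pairwise sequence identity (SI).  Genes are then ranked by PI% to surface
the most variable markers.

Gap and ambiguity policy: ``-`` and ``N`` are missing data.  They are not
character states for site classification or parsimony (a missing leaf takes
the union of all four states in the Fitch pass), and positions where either
row is a gap are excluded from pairwise identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import dendropy
import numpy as np
import pandas as pd

from .composition import round_half_away

__all__ = [
    "Alignment",
    "VariabilityStats",
    "align_stats",
    "fitch_length",
    "ci_ri",
    "rank_genes",
    "pi_percent",
    "nj_tree",
    "per_column_fitch",
]

_STATE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_MISSING = 15  # union of all states


@dataclass
class Alignment:
    """A gap-aware multiple sequence alignment over {A,C,G,T,N,-}."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs >= 2 rows")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows differ in length")
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        self.rows = [r.upper() for r in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, path_or_handle) -> "Alignment":
        from Bio import SeqIO

        records = list(SeqIO.parse(path_or_handle, "fasta"))
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_bitmask(self) -> np.ndarray:
        """(n_taxa, n_cols) uint8 state bitmasks; gaps/N = all-states union."""
        out = np.full((len(self.rows), self.length), _MISSING, dtype=np.uint8)
        for i, row in enumerate(self.rows):
            arr = np.frombuffer(row.encode(), dtype=np.uint8)
            for base, bit in _STATE_BITS.items():
                out[i, arr == ord(base)] = bit
        return out


@dataclass
class VariabilityStats:
    gene: str
    unaligned_length_ref: int
    aligned_length: int
    conserved_sites: int
    parsimony_informative: int
    pi_percent: float
    ci: float | None = None
    ri: float | None = None
    seq_identity: float | None = None


def pi_percent(informative: int, aligned_length: int) -> float:
    """Percentage of parsimony-informative sites, to two decimals."""
    return round_half_away(100 * informative / aligned_length, 2)


def _column_state_counts(aln: Alignment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per column: counts of each base (4 x L), non-missing totals, and the
    number of distinct observed states."""
    L = aln.length
    counts = np.zeros((4, L), dtype=np.int64)
    for row in aln.rows:
        arr = np.frombuffer(row.encode(), dtype=np.uint8)
        for bi, base in enumerate("ACGT"):
            counts[bi] += arr == ord(base)
    non_missing = counts.sum(axis=0)
    n_states = (counts > 0).sum(axis=0)
    return counts, non_missing, n_states


def align_stats(aln: Alignment, gene: str = "", unaligned_length_ref: int | None = None) -> VariabilityStats:
    """Site classification and pairwise identity for one alignment.

    A column is conserved when all non-missing tokens are identical (columns
    that are entirely missing count as conserved); it is parsimony
    informative when at least two states each occur in at least two taxa.
    Identity is the mean over row pairs of the fraction of identical
    positions among positions where neither row is a gap.
    """
    counts, non_missing, n_states = _column_state_counts(aln)
    conserved = int((n_states <= 1).sum())
    informative = int(((counts >= 2).sum(axis=0) >= 2).sum())
    identities = []
    arrs = [np.frombuffer(r.encode(), dtype=np.uint8) for r in aln.rows]
    gap = ord("-")
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            both = (arrs[i] != gap) & (arrs[j] != gap)
            denom = int(both.sum())
            if denom:
                identities.append(int((arrs[i][both] == arrs[j][both]).sum()) / denom)
    return VariabilityStats(
        gene=gene,
        unaligned_length_ref=(
            unaligned_length_ref
            if unaligned_length_ref is not None
            else len(aln.rows[0].replace("-", ""))
        ),
        aligned_length=aln.length,
        conserved_sites=conserved,
        parsimony_informative=informative,
        pi_percent=pi_percent(informative, aln.length),
        seq_identity=float(np.mean(identities)) if identities else None,
    )


def _rooted_binary(tree: dendropy.Tree) -> dendropy.Tree:
    """A structurally binary rooted copy of a (possibly unrooted) tree."""
    t = tree.clone(depth=1)
    seed = t.seed_node
    if len(seed.child_nodes()) > 2:
        edge = seed.child_nodes()[0].edge
        t.reroot_at_edge(edge, update_bipartitions=False)
    for node in t.preorder_node_iter():
        if len(node.child_nodes()) > 2:
            raise ValueError("tree has polytomies; a binary topology is required")
    return t


def per_column_fitch(aln: Alignment, tree: dendropy.Tree | str) -> np.ndarray:
    """Fitch small-parsimony step counts for every column on one topology.

    Leaves carry their observed state's bitmask (gaps/N take the union of
    all states); at each internal node the children's sets are intersected,
    or, when disjoint, unioned at the cost of one step.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    tree = _rooted_binary(tree)
    leaf_names = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    aln_names = set(aln.taxa)
    if leaf_names != aln_names:
        raise ValueError(
            f"leaf/taxa mismatch: only in tree {sorted(leaf_names - aln_names)}, "
            f"only in alignment {sorted(aln_names - leaf_names)}"
        )
    masks = aln.to_bitmask()
    by_name = {name: masks[i] for i, name in enumerate(aln.taxa)}
    steps = np.zeros(aln.length, dtype=np.int64)
    sets: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[id(node)] = by_name[node.taxon.label]
            continue
        c1, c2 = node.child_nodes()
        a, b = sets[id(c1)], sets[id(c2)]
        inter = a & b
        empty = inter == 0
        steps += empty
        result = np.where(empty, a | b, inter)
        sets[id(node)] = result.astype(np.uint8)
    return steps


def fitch_length(aln: Alignment, tree: dendropy.Tree | str) -> int:
    """Total Fitch parsimony length of the alignment on the given topology."""
    return int(per_column_fitch(aln, tree).sum())


def ci_ri(aln: Alignment, tree: dendropy.Tree | str) -> tuple[float, float]:
    """Consistency and retention indices over the variable columns.

    Per column ``i``: ``s_i`` = Fitch steps, ``m_i`` = observed states - 1
    (the minimum conceivable steps), ``g_i`` = non-missing tokens minus the
    largest state frequency (the steps on a star/worst tree).  Then
    ``CI = sum(m)/sum(s)`` and ``RI = (sum(g)-sum(s))/(sum(g)-sum(m))``,
    both over variable columns; with no homoplasy potential
    (``sum(g) == sum(m)``) RI is defined as 1, and with no variable columns
    both indices are 1.
    """
    steps = per_column_fitch(aln, tree)
    counts, non_missing, n_states = _column_state_counts(aln)
    m = np.maximum(n_states - 1, 0)
    g = np.where(non_missing > 0, non_missing - counts.max(axis=0), 0)
    variable = m >= 1
    if not variable.any():
        return 1.0, 1.0
    S = int(steps[variable].sum())
    M = int(m[variable].sum())
    G = int(g[variable].sum())
    ci = M / S if S else 1.0
    ri = (G - S) / (G - M) if G != M else 1.0
    return float(ci), float(ri)


def nj_tree(aln: Alignment) -> dendropy.Tree:
    """Neighbor-joining topology from uncorrected pairwise p-distances.

    A fallback when no tree is supplied; full model-based inference is out
    of scope.
    """
    n = len(aln.taxa)
    arrs = [np.frombuffer(r.encode(), dtype=np.uint8) for r in aln.rows]
    gap = ord("-")
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (arrs[i] != gap) & (arrs[j] != gap)
            denom = int(both.sum())
            d = 1.0 - (int((arrs[i][both] == arrs[j][both]).sum()) / denom) if denom else 0.0
            dist[i, j] = dist[j, i] = d
    csv_rows = ["," + ",".join(aln.taxa)]
    for i, name in enumerate(aln.taxa):
        csv_rows.append(name + "," + ",".join(f"{x:.10f}" for x in dist[i]))
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        src=StringIO("\n".join(csv_rows)), delimiter=","
    )
    return pdm.nj_tree()


def rank_genes(
    stats: list[VariabilityStats], min_len: int = 200, filtered: bool = True
) -> pd.DataFrame:
    """Rank genes by PI% (descending).

    With ``filtered`` (the default) genes whose unaligned reference length
    is at most ``min_len`` are dropped; the unfiltered variant keeps every
    gene, since short but informative genes can still be useful markers.
    Ties break by aligned length (descending), then gene name.
    """
    rows = [
        {
            "gene": s.gene,
            "length_bp": s.unaligned_length_ref,
            "aligned_length": s.aligned_length,
            "conserved_sites": s.conserved_sites,
            "parsimony_informative": s.parsimony_informative,
            "pi_percent": s.pi_percent,
            "ci": None if s.ci is None else round_half_away(s.ci, 2),
            "ri": None if s.ri is None else round_half_away(s.ri, 1),
            "seq_identity": (
                None if s.seq_identity is None else round_half_away(s.seq_identity, 1)
            ),
        }
        for s in stats
        if not filtered or s.unaligned_length_ref > min_len
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return df.sort_values(
        ["pi_percent", "aligned_length", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
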