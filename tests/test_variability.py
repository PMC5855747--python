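import itertools

import numpy as np
import pytest

import oracles
from plastomekit import (
    Alignment,
    VariabilityStats,
    align_stats,
    ci_ri,
    fitch_length,
    nj_tree,
    per_column_fitch,
    pi_percent,
    rank_genes,
)
from plastomekit import refdata


def random_alignment(rng, n_taxa, n_cols, gap_frac=0.0):
    rows = []
    for _ in range(n_taxa):
        chars = rng.choice(list("ACGT"), n_cols)
        if gap_frac:
            mask = rng.random(n_cols) < gap_frac
            chars = np.where(mask, "-", chars)
        rows.append("".join(chars))
    return Alignment([f"t{i}" for i in range(n_taxa)], rows)


def random_binary_newick(rng, taxa):
    nodes = [name for name in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


class TestAlignStats:
    def test_identical_rows(self):
        aln = Alignment(list("abcd"), ["ACGT"] * 4)
        s = align_stats(aln)
        assert s.conserved_sites == 4
        assert s.parsimony_informative == 0
        assert s.pi_percent == 0.0
        assert s.seq_identity == 1.0

    def test_fully_informative_toy(self):
        aln = Alignment(list("abcd"), ["AA", "AA", "TT", "TT"])
        s = align_stats(aln)
        assert s.parsimony_informative == 2
        assert s.pi_percent == 100.0
        assert s.conserved_sites == 0

    def test_printed_counts_give_printed_percentages(self):
        """Informative-site counts over aligned lengths reproduce the printed
        PI percentages for every reference gene."""
        for row in refdata.VARIABILITY_ROWS:
            assert pi_percent(row["informative"], row["aligned"]) == row["pi_percent"]

    def test_gaps_are_missing_data(self):
        aln = Alignment(list("abcd"), ["A-", "AN", "A-", "AT"])
        s = align_stats(aln)
        # both columns have a single observed state (A; T) -> conserved
        assert s.conserved_sites == 2
        assert s.parsimony_informative == 0

    def test_singleton_not_informative(self):
        aln = Alignment(list("abcd"), ["A", "A", "A", "T"])
        assert align_stats(aln).parsimony_informative == 0


class TestFitch:
    def test_two_taxa_equals_hamming(self):
        aln = Alignment(["a", "b"], ["ACGTAC", "ACCTAA"])
        assert fitch_length(aln, "(a,b);") == 2

    def test_four_taxon_split_depends_on_topology(self):
        aln = Alignment(["1", "2", "3", "4"], ["A", "A", "T", "T"])
        assert fitch_length(aln, "((1,2),(3,4));") == 1
        assert fitch_length(aln, "((1,3),(2,4));") == 2

    def test_invariant_column_is_free(self):
        aln = Alignment(["1", "2", "3", "4"], ["G", "G", "G", "G"])
        for nwk in ("((1,2),(3,4));", "((1,3),(2,4));", "((1,4),(2,3));"):
            assert fitch_length(aln, nwk) == 0

    def test_leaf_mismatch_reported(self):
        aln = Alignment(["a", "b", "c"], ["A", "C", "G"])
        with pytest.raises(ValueError, match="mismatch"):
            fitch_length(aln, "((a,b),(c,d));")

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_enumeration(self, seed):
        """Fitch step counts equal the brute-force minimum over all internal
        labelings, for 4-6 taxa with occasional missing data."""
        rng = np.random.default_rng(seed)
        n_taxa = int(rng.integers(4, 7))
        taxa = [f"t{i}" for i in range(n_taxa)]
        newick = random_binary_newick(rng, taxa)
        aln = random_alignment(rng, n_taxa, 6, gap_frac=0.15)
        aln = Alignment(taxa, aln.rows)
        steps = per_column_fitch(aln, newick)
        for col in range(aln.length):
            states = {t: aln.rows[i][col] for i, t in enumerate(taxa)}
            assert steps[col] == oracles.brute_fitch_column(states, newick), (col, states)


class TestCiRi:
    def test_tree_compatible_data(self):
        aln = Alignment(["1", "2", "3", "4"], ["AAG", "AAG", "TTG", "TAG"])
        ci, ri = ci_ri(aln, "((1,2),(3,4));")
        assert ci == 1.0 and ri == 1.0

    def test_single_incongruent_column(self):
        """m=1, s=2, g=2 gives CI 0.5 and RI 0."""
        aln = Alignment(["1", "2", "3", "4"], ["A", "A", "T", "T"])
        ci, ri = ci_ri(aln, "((1,3),(2,4));")
        assert ci == pytest.approx(0.5)
        assert ri == pytest.approx(0.0)

    def test_mixed_columns(self):
        """One congruent 2+2 column (s=1) and one incongruent (s=2), each
        with m=1, g=2: CI = 2/3, RI = 1/2."""
        aln = Alignment(["1", "2", "3", "4"], ["AA", "AT", "TA", "TT"])
        ci, ri = ci_ri(aln, "((1,3),(2,4));")
        assert ci == pytest.approx(2 / 3)
        assert ri == pytest.approx(0.5)

    def test_no_variable_columns(self):
        aln = Alignment(["1", "2", "3", "4"], ["AAA"] * 4)
        assert ci_ri(aln, "((1,2),(3,4));") == (1.0, 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_m_le_s_le_g_per_column(self, seed):
        """The minimum, realized and worst-case step counts are ordered
        m <= s <= g on every column."""
        rng = np.random.default_rng(seed)
        n_taxa = int(rng.integers(4, 8))
        taxa = [f"t{i}" for i in range(n_taxa)]
        aln = Alignment(taxa, random_alignment(rng, n_taxa, 40, gap_frac=0.1).rows)
        newick = random_binary_newick(rng, taxa)
        steps = per_column_fitch(aln, newick)
        from plastomekit.variability import _column_state_counts

        counts, non_missing, n_states = _column_state_counts(aln)
        m = np.maximum(n_states - 1, 0)
        g = np.where(non_missing > 0, non_missing - counts.max(axis=0), 0)
        assert (m <= steps).all()
        assert (steps <= g + (non_missing == 0)).all()  # all-missing cols are 0

    def test_invariance_under_reordering(self):
        rng = np.random.default_rng(3)
        taxa = [f"t{i}" for i in range(5)]
        aln = Alignment(taxa, random_alignment(rng, 5, 30).rows)
        newick = random_binary_newick(rng, taxa)
        base = ci_ri(aln, newick)
        order = rng.permutation(5)
        shuffled_taxa = [aln.taxa[i] for i in order]
        shuffled_rows = [aln.rows[i] for i in order]
        assert ci_ri(Alignment(shuffled_taxa, shuffled_rows), newick) == base
        cols = rng.permutation(aln.length)
        permuted = ["".join(r[c] for c in cols) for r in aln.rows]
        assert ci_ri(Alignment(aln.taxa, permuted), newick) == base


class TestRankGenes:
    def make_stats(self):
        return [
            VariabilityStats(
                gene=r["gene"],
                unaligned_length_ref=r["length"],
                aligned_length=r["aligned"],
                conserved_sites=r["conserved"],
                parsimony_informative=r["informative"],
                pi_percent=pi_percent(r["informative"], r["aligned"]),
                ci=r["ci"],
                ri=r["ri"],
                seq_identity=r["si"],
            )
            for r in refdata.VARIABILITY_ROWS
        ]

    def test_reference_ordering(self):
        """Sorting the reference rows by PI% reproduces the published rank:
        matK, ycf1, ccsA, accD, rps3, ndhF, rps8, rpl22, petL, ndhD."""
        ranked = rank_genes(self.make_stats(), filtered=False)
        assert list(ranked["gene"]) == [
            "matK", "ycf1", "ccsA", "accD", "rps3",
            "ndhF", "rps8", "rpl22", "petL", "ndhD",
        ]

    def test_length_filter_drops_petL(self):
        ranked = rank_genes(self.make_stats(), min_len=200)
        assert "petL" not in set(ranked["gene"])
        assert len(ranked) == 9

    def test_single_gene(self):
        stats = self.make_stats()[:1]
        assert len(rank_genes(stats, filtered=False)) == 1

    def test_empty(self):
        assert rank_genes([]).empty


def test_nj_tree_leafset_and_ladder():
    rng = np.random.default_rng(6)
    taxa = ["a", "b", "c", "d", "e"]
    rows = []
    base = "".join(rng.choice(list("ACGT"), 200))
    for i in range(5):
        row = list(base)
        for pos in rng.choice(200, size=5 * (i + 1), replace=False):
            row[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[row[pos]]
        rows.append("".join(row))
    tree = nj_tree(Alignment(taxa, rows))
    assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == set(taxa)
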