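import numpy as np
import pytest

import oracles
from plastomekit import (
    RepeatHit,
    SSRHit,
    find_long_repeats,
    find_ssrs,
    repeat_summary,
    ssr_summary,
)
from plastomekit.repeats import DEFAULT_SSR_THRESHOLDS, is_primitive
from plastomekit.simulate import PlastomeSpec, generate_plastome
from conftest import random_seq


class TestSSRScan:
    def test_mononucleotide_cutoff(self):
        assert [(h.motif, h.copies) for h in find_ssrs("G" + "A" * 8 + "C")] == [("A", 8)]
        assert find_ssrs("G" + "A" * 7 + "C") == []

    def test_dinucleotide_primitive_motif(self):
        hits = find_ssrs("GGC" + "AT" * 4 + "CGG")
        assert [(h.motif, h.copies, h.end - h.start) for h in hits] == [("AT", 4, 8)]
        # never reported as a tetranucleotide (ATAT)x2
        assert all(h.motif_length == 2 for h in hits)

    def test_primitivity_rule(self):
        assert is_primitive("AT")
        assert not is_primitive("ATAT")
        assert not is_primitive("AAA")
        assert is_primitive("AAT")

    def test_homopolymer_inside_dinucleotide_run_reported_once(self):
        """Overlap policy keeps the longer total span only."""
        seq = "GC" + "A" * 9 + "TA" * 6 + "GC"
        hits = find_ssrs(seq)
        assert len(hits) == 1
        assert hits[0].span >= 12

    def test_compound_ssrs_stay_separate(self):
        seq = "GG" + "A" * 8 + "CT" * 5 + "GG"
        motifs = {h.motif for h in find_ssrs(seq)}
        assert motifs == {"A", "CT"}

    def test_empty_sequence(self):
        assert find_ssrs("") == []

    def test_maximality(self):
        """No reported run can be extended by one motif copy on either side."""
        seq = random_seq(np.random.default_rng(8), 3000)
        for h in find_ssrs(seq, thresholds={1: 5, 2: 3, 3: 2, 4: 2, 5: 2, 6: 2}):
            m = len(h.motif)
            assert seq[h.start - m : h.start] != seq[h.start : h.start + m]
            assert seq[h.end : h.end + m] != seq[h.end - m : h.end]

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bruteforce_on_random_sequences(self, seed):
        seq = random_seq(np.random.default_rng(seed), 2000)
        got = [(h.motif, int(h.copies), int(h.start), int(h.end)) for h in find_ssrs(seq)]
        assert got == oracles.brute_ssrs(seq, DEFAULT_SSR_THRESHOLDS)


def _flanked(bg: str, pieces: list[tuple[int, str]]) -> str:
    """Insert pieces at offsets, separated so flanks cannot pair by design
    of the calling test."""
    out = list(bg)
    for offset, piece in pieces:
        out[offset : offset + len(piece)] = piece
    return "".join(out)


class TestLongRepeats:
    def setup_method(self):
        self.rng = np.random.default_rng(42)
        self.bg = random_seq(self.rng, 3000)

    def test_planted_forward_repeat(self):
        seg = random_seq(self.rng, 35)
        seq = _flanked(self.bg, [(300, "T" + seg + "G"), (1800, "A" + seg + "C")])
        hits = find_long_repeats(seq, seed_len=11)
        fw = [h for h in hits if h.type == "forward"]
        assert len(fw) == 1
        assert fw[0].length == 35 and fw[0].identity == 1.0
        assert fw[0].pos1 == (301, 336) and fw[0].pos2 == (1801, 1836)

    def test_planted_palindromic_repeat(self):
        seg = random_seq(self.rng, 40)
        seq = _flanked(
            self.bg, [(300, "T" + seg + "G"), (1800, "T" + oracles.revcomp(seg) + "G")]
        )
        hits = [h for h in find_long_repeats(seq, seed_len=11) if h.type == "palindromic"]
        assert len(hits) == 1 and hits[0].length == 40 and hits[0].identity == 1.0

    def test_planted_reverse_and_complement(self):
        seg = random_seq(self.rng, 36)
        for rtype, partner in (
            ("reverse", seg[::-1]),
            ("complement", oracles.complement(seg)),
        ):
            seq = _flanked(self.bg, [(300, "T" + seg + "G"), (1800, "T" + partner + "G")])
            hits = [h for h in find_long_repeats(seq, seed_len=11) if h.type == rtype]
            assert len(hits) == 1 and hits[0].length == 36, rtype

    def test_29bp_duplicate_below_cutoff(self):
        seg = random_seq(self.rng, 29)
        # flanks are chosen to mismatch so the exact run stays 29 bp
        seq = _flanked(self.bg, [(300, "A" + seg + "A"), (1800, "C" + seg + "C")])
        assert find_long_repeats(seq, seed_len=11) == []

    def test_identity_threshold(self):
        """3 substitutions in 35 bp (0.914) qualify; 4 (0.886) do not."""
        seg = random_seq(self.rng, 35)
        comp = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for n_mut, expected in ((3, 1), (4, 0)):
            mutated = list(seg)
            for pos in np.linspace(9, 25, n_mut).astype(int):
                mutated[pos] = comp[mutated[pos]]
            seq = _flanked(
                self.bg, [(300, "A" + seg + "A"), (1800, "C" + "".join(mutated) + "C")]
            )
            hits = find_long_repeats(seq, seed_len=7)
            assert len(hits) == expected, n_mut
            if hits:
                assert hits[0].identity >= 0.9

    def test_min_len_bound(self):
        with pytest.raises(ValueError):
            find_long_repeats("ACGT" * 100, min_len=7)

    def test_low_complexity_filtered(self):
        seq = _flanked(self.bg, [(300, "A" * 40), (1800, "A" * 40)])
        hits = find_long_repeats(seq, seed_len=11)
        assert all(h.type != "forward" or h.pos1[0] != 300 for h in hits)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_with_planted_repeats(self, seed):
        """Seed-and-extend equals full-diagonal enumeration, including the
        nested and low-complexity post-filters."""
        rng = np.random.default_rng(seed + 100)
        bg = random_seq(rng, 400)
        seg = random_seq(rng, 32)
        seq = _flanked(bg, [(50, "A" + seg + "A"), (300, "C" + seg + "C")])
        got = sorted(
            (h.type, tuple(map(int, h.pos1)), tuple(map(int, h.pos2)), int(h.length))
            for h in find_long_repeats(seq, seed_len=8)
        )
        brute = oracles.brute_long_repeats(seq)
        brute = [h for h in brute if not oracles.low_complexity(seq, h)]
        brute = oracles.remove_nested(brute)
        want = sorted((t, p1, p2, L) for t, p1, p2, L, _ in brute)
        assert got == want


class TestIRAwarePostprocessing:
    def test_genome_scale_ir_pair_excluded(self, small_genome):
        record, truth = small_genome
        hits = find_long_repeats(record, partition=truth.partition)
        ir_len = truth.partition.ir_length
        assert all(h.length < 0.5 * ir_len for h in hits)

    def test_ir_mirrored_hits_collapse(self):
        spec = PlastomeSpec.minimal(seed=21, planted_repeats=[("forward", 34, 1.0)])
        record, truth = generate_plastome(spec)
        hits = find_long_repeats(record, partition=truth.partition)
        want = truth.repeats[0]
        assert [(h.type, tuple(map(int, h.pos1)), tuple(map(int, h.pos2))) for h in hits] == [
            (want["type"], tuple(want["pos1"]), tuple(want["pos2"]))
        ]


class TestSummaries:
    def test_repeat_type_totals(self):
        """14 palindromic + 19 forward + 8 reverse recombine to 41."""
        hits = (
            [RepeatHit("palindromic", (0, 30), (50, 80), 30, 1.0)] * 14
            + [RepeatHit("forward", (0, 30), (50, 80), 30, 1.0)] * 19
            + [RepeatHit("reverse", (0, 30), (50, 80), 30, 1.0)] * 8
        )
        df = repeat_summary(hits, by="type")
        counts = dict(zip(df["group"], df["count"]))
        assert counts["palindromic"] == 14 and counts["forward"] == 19
        assert counts["reverse"] == 8 and counts["total"] == 41

    def test_ssr_context_totals(self):
        """89 coding + 34 intron + 155 intergenic recombine to 278."""
        hits = (
            [SSRHit("A", 8, 0, 8, context="coding")] * 89
            + [SSRHit("A", 8, 0, 8, context="intron")] * 34
            + [SSRHit("A", 8, 0, 8, context="intergenic")] * 155
        )
        df = ssr_summary(hits, by="context")
        counts = dict(zip(df["group"], df["count"]))
        assert counts == {"coding": 89, "intron": 34, "intergenic": 155, "total": 278}

    def test_empty_hits(self):
        df = repeat_summary([], by="type")
        assert int(df[df["group"] == "total"]["count"].iloc[0]) == 0

    def test_length_bins(self):
        hits = [
            RepeatHit("forward", (0, L), (100, 100 + L), L, 1.0) for L in (30, 35, 41, 95)
        ]
        df = repeat_summary(hits, by="length_bin")
        counts = dict(zip(df["group"], df["count"]))
        assert counts["30-39"] == 2 and counts["40-49"] == 1 and counts["90-99"] == 1

    def test_count_conservation_on_generated_genome(self):
        spec = PlastomeSpec.minimal(
            seed=9,
            planted_ssrs=[("A", 9, "LSC"), ("AT", 5, "SSC"), ("CAT", 4, "LSC")],
            planted_repeats=[("forward", 33, 1.0), ("palindromic", 40, 1.0)],
        )
        record, truth = generate_plastome(spec)
        ssrs = find_ssrs(record, partition=truth.partition, collapse_ir=True)
        for facet in ("motif_length", "region", "context"):
            df = ssr_summary(ssrs, by=facet)
            assert int(df[df["group"] == "total"]["count"].iloc[0]) == len(ssrs)


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", range(5))
    def test_full_recall_and_precision(self, seed):
        """Every planted feature is recovered, and nothing else, on a
        screened background."""
        spec = PlastomeSpec.minimal(
            seed=seed,
            planted_ssrs=[
                ("A", 10, "LSC"),
                ("T", 8, "SSC"),
                ("AG", 4, "LSC"),
                ("AAT", 3, "IR"),
                ("ACGT", 3, "LSC"),
                ("ACGTC", 3, "SSC"),
                ("ACGTCA", 3, "LSC"),
            ],
            planted_repeats=[
                ("forward", 35, 1.0),
                ("palindromic", 40, 1.0),
                ("reverse", 31, 1.0),
                ("complement", 33, 1.0),
            ],
        )
        record, truth = generate_plastome(spec)
        assert truth.residual_features == []
        ssrs = find_ssrs(record, partition=truth.partition, collapse_ir=True)
        got = {(h.motif, int(h.copies), int(h.start)) for h in ssrs}
        want = {(s["motif"], s["copies"], s["start"]) for s in truth.ssrs}
        assert got == want
        reps = find_long_repeats(record, partition=truth.partition)
        got_r = {(h.type, tuple(map(int, h.pos1)), tuple(map(int, h.pos2))) for h in reps}
        want_r = {(r["type"], tuple(r["pos1"]), tuple(r["pos2"])) for r in truth.repeats}
        assert got_r == want_r
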