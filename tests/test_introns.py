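import numpy as np
import pytest

import oracles
from plastomekit import (
    GeneModel,
    PrimerPair,
    in_silico_pcr,
    intron_presence,
    intron_table,
    pairwise_global_align,
    revcomp,
)
from plastomekit import refdata
from conftest import random_seq


def reference_models() -> list[GeneModel]:
    return [
        GeneModel(name, region, seg, trans_spliced=(name == "rps12"))
        for name, _cat, region, seg, _strand in refdata.GENE_INVENTORY
        if len(seg) > 1
    ]


class TestIntronTable:
    def test_reference_inventory(self):
        """The deposited intron models: 17 intron-bearing genes, the longest
        intron 2,495 bp inside trnK-UUU, two cis two-intron genes."""
        table = intron_table(reference_models())
        assert len(table) == 17
        top = table.loc[table["longest_intron_bp"].idxmax()]
        assert top["gene"] == "trnK-UUU" and top["longest_intron_bp"] == 2495
        assert sorted(table[table["n_introns"] == 2]["gene"]) == ["clpP", "ycf3"]

    def test_ycf3_two_introns(self):
        row = intron_table([GeneModel("ycf3", "LSC", (153, 727, 228, 731, 126))]).iloc[0]
        assert row["n_introns"] == 2
        assert row["intron_total_bp"] == 1458
        assert row["longest_intron_bp"] == 731

    def test_single_exon_gene(self):
        row = intron_table([GeneModel("rbcL", "LSC", (1428,))]).iloc[0]
        assert row["n_introns"] == 0
        assert row["intron_total_bp"] == 0
        assert row["longest_intron_bp"] is None

    def test_trans_spliced_counts_cis_only(self):
        row = intron_table(
            [GeneModel("rps12", "IR", (114, None, 27, 546, 231), trans_spliced=True)]
        ).iloc[0]
        assert row["n_introns"] == 1
        assert row["intron_total_bp"] == 546

    @pytest.mark.parametrize("segments", [(100, 200), (0, 10, 20), (-5,)])
    def test_alternation_violations_rejected(self, segments):
        with pytest.raises(ValueError):
            GeneModel("bad", "LSC", segments)


class TestInSilicoPCR:
    F = "ACTTCGTTTGAGACGGTGTG"
    R = "AAAAACCCCGATTTCTTTGA"

    def test_constructed_product_length(self):
        rng = np.random.default_rng(4)
        template = self.F + random_seq(rng, 100) + revcomp(self.R)
        amps = in_silico_pcr(template, PrimerPair(self.F, self.R))
        assert [(a.start, a.length) for a in amps] == [(0, 140)]

    def test_missing_reverse_site(self):
        rng = np.random.default_rng(4)
        template = self.F + random_seq(rng, 200)
        assert in_silico_pcr(template, PrimerPair(self.F, self.R)) == []

    def test_circular_origin_spanning_product(self):
        rng = np.random.default_rng(4)
        mid = random_seq(rng, 300)
        # forward site near the end; reverse site after the origin
        template = random_seq(rng, 50) + revcomp(self.R) + mid + self.F + random_seq(rng, 30)
        assert in_silico_pcr(template, PrimerPair(self.F, self.R), circular=False) == []
        amps = in_silico_pcr(template, PrimerPair(self.F, self.R), circular=True)
        assert len(amps) == 1
        assert amps[0].length == 30 + 50 + 40

    def test_three_prime_anchor(self):
        rng = np.random.default_rng(4)
        fwd_bad_anchor = self.F[:-1] + ("A" if self.F[-1] != "A" else "C")
        template = self.F + random_seq(rng, 100) + revcomp(self.R)
        primers = PrimerPair(fwd_bad_anchor, self.R, max_mismatch=2)
        assert in_silico_pcr(template, primers) == []
        fwd_mid_mismatch = self.F[:5] + ("A" if self.F[5] != "A" else "C") + self.F[6:]
        primers = PrimerPair(fwd_mid_mismatch, self.R, max_mismatch=2)
        amps = in_silico_pcr(template, primers)
        assert len(amps) == 1 and amps[0].fwd_mismatches == 1

    def test_primer_validation(self):
        with pytest.raises(ValueError):
            PrimerPair("ACGTACGTACGT", self.R)  # too short
        with pytest.raises(ValueError):
            PrimerPair(self.F, "AAAAACCCCGAUUUCUUUGA")  # non-ACGT

    def test_empty_template_rejected(self):
        with pytest.raises(ValueError):
            in_silico_pcr("", PrimerPair(self.F, self.R))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        template = random_seq(rng, 400)
        # plant one or two site pairs
        template = (
            template[:40] + self.F + template[60:200] + revcomp(self.R) + template[220:]
        )
        got = [(a.start, a.end, a.length) for a in in_silico_pcr(
            template, PrimerPair(self.F, self.R), circular=bool(seed % 2)
        )]
        want = oracles.brute_pcr(template, self.F, self.R, circular=bool(seed % 2))
        assert got == want


class TestIntronPresence:
    def models(self, introns_by_taxon: dict[str, int | None]) -> dict:
        out = {}
        for taxon, n in introns_by_taxon.items():
            models = [GeneModel("matK", "LSC", (1500,))]
            if n is not None:
                seg = [40] + [860, 227][: 2 * n - 1] if n else [267]
                if n == 1:
                    seg = (40, 860, 227)
                else:
                    seg = (267,)
                models.append(GeneModel("rps16", "LSC", tuple(seg)))
            out[taxon] = models
        return out

    def test_intron_loss_called(self):
        models = self.models({"ref": 1, "q1": 0, "q2": 1})
        df = intron_presence(models, "rps16", "ref").set_index("taxon")
        assert df.loc["q1", "call"] == "intron_loss"
        assert df.loc["q2", "call"] == "none"

    def test_gene_loss_called(self):
        models = self.models({"ref": 1, "q1": None})
        df = intron_presence(models, "rps16", "ref").set_index("taxon")
        assert df.loc["q1", "call"] == "gene_loss"

    def test_reference_without_gene_rejected(self):
        models = self.models({"ref": None, "q": 1})
        with pytest.raises(KeyError):
            intron_presence(models, "rps16", "ref")

    def test_intronless_reference_rejected(self):
        models = self.models({"ref": 0})
        with pytest.raises(ValueError):
            intron_presence(models, "rps16", "ref")


class TestGlobalAlignment:
    def test_identical(self):
        a, b, score = pairwise_global_align("ACGT", "ACGT", 1, -1, -2)
        assert (a, b, score) == ("ACGT", "ACGT", 4.0)

    def test_single_gap(self):
        a, b, score = pairwise_global_align("ACGT", "AGT", 1, -1, -2)
        assert score == 1.0
        assert a == "ACGT" and b.count("-") == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_global_align("", "ACGT")

    @pytest.mark.parametrize("seed", range(15))
    def test_optimal_score_vs_exhaustive(self, seed):
        """The DP score equals the brute-force optimum over all alignments."""
        rng = np.random.default_rng(seed)
        a = random_seq(rng, int(rng.integers(2, 7)))
        b = random_seq(rng, int(rng.integers(2, 7)))

        def brute(i, j):
            if i == len(a) and j == len(b):
                return 0.0
            best = -1e9
            if i < len(a) and j < len(b):
                best = max(best, (1 if a[i] == b[j] else -1) + brute(i + 1, j + 1))
            if i < len(a):
                best = max(best, -2 + brute(i + 1, j))
            if j < len(b):
                best = max(best, -2 + brute(i, j + 1))
            return best

        _, _, score = pairwise_global_align(a, b, 1, -1, -2)
        assert score == pytest.approx(brute(0, 0))
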