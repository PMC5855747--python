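import numpy as np
import pytest

from plastomekit import (
    GenePlan,
    detect_ir,
    find_long_repeats,
    find_ssrs,
    fitch_length,
    gc_content,
    intron_presence,
    partition_from_ir,
    revcomp,
)
from plastomekit.simulate import (
    CapacityError,
    PlastomeSpec,
    evolve_taxa,
    generate_plastome,
)

EIGHT_TAXON_TREE = (
    "(((A:0.02,B:0.02):0.01,(C:0.02,D:0.02):0.01):0.01,"
    "((E:0.02,F:0.02):0.01,(G:0.02,H:0.02):0.01):0.01):0.0;"
)

SMALL_GENES = [
    GenePlan("matK", "protein", "LSC", (900,), "+"),
    GenePlan("rps16", "protein", "LSC", (40, 860, 227), "+"),
    GenePlan("rrn16", "rRNA", "IR", (700,), "+"),
    GenePlan("ndhF", "protein", "SSC", (800,), "-"),
]


def small_annotated_spec(seed=0, **kw):
    return PlastomeSpec.minimal(
        lsc_len=6000, ssc_len=2000, ir_len=2000, seed=seed,
        gene_inventory=list(SMALL_GENES), **kw
    )


class TestGeneratePlastome:
    def test_reference_scale_total_length(self, full_genome):
        record, truth = full_genome
        assert len(record) == 157960
        assert truth.partition.lsc == (0, 86315)
        assert truth.partition.ir_length == 26577

    def test_irb_is_reverse_complement_of_ira(self, small_genome):
        record, truth = small_genome
        part = truth.partition
        ira = record.sequence[slice(*part.ira)]
        irb = record.sequence[slice(*part.irb)]
        assert irb == revcomp(ira)

    def test_gc_targets_hit(self, small_genome):
        record, truth = small_genome
        part = truth.partition
        spec_targets = {"LSC": 0.351, "SSC": 0.318, "IR": 0.427}
        for region, iv in (("LSC", part.lsc), ("SSC", part.ssc), ("IR", part.ira)):
            assert abs(gc_content(record.sequence[slice(*iv)]) - spec_targets[region]) <= 0.005

    def test_screened_background_is_feature_free(self, small_genome):
        record, truth = small_genome
        assert truth.residual_features == []
        assert find_ssrs(record, partition=truth.partition) == []
        assert find_long_repeats(record, partition=truth.partition) == []

    def test_determinism(self):
        spec = PlastomeSpec.minimal(seed=13, planted_ssrs=[("A", 9, "LSC")])
        rec1, _ = generate_plastome(spec)
        rec2, _ = generate_plastome(spec)
        assert rec1.sequence == rec2.sequence
        rec3, _ = generate_plastome(spec, seed=14)
        assert rec3.sequence != rec1.sequence

    def test_capacity_error(self):
        spec = PlastomeSpec.minimal(
            lsc_len=500, ssc_len=200, ir_len=300,
            gene_inventory=[GenePlan("big", "protein", "LSC", (2000,), "+")],
        )
        with pytest.raises(CapacityError):
            generate_plastome(spec)

    def test_annotations_validate_and_mirror(self, full_genome):
        record, truth = full_genome
        record.validate()
        by_name = record.annotations_by_name()
        ann_a, ann_b = sorted(by_name["rrn16"], key=lambda a: a.start)
        assert (ann_a.copy_tag, ann_b.copy_tag) == ("IR_A", "IR_B")
        seq_a = record.sequence[slice(*ann_a.exons[0])]
        seq_b = record.sequence[slice(*ann_b.exons[0])]
        assert seq_b == revcomp(seq_a)

    def test_primer_construct_amplifies_at_spec_length(self):
        from plastomekit import PrimerPair, in_silico_pcr
        from plastomekit.refdata import (
            RPS16_AMPLICON_LENGTH,
            RPS16_PRIMER_FORWARD,
            RPS16_PRIMER_REVERSE,
        )

        spec = PlastomeSpec.minimal(
            seed=2,
            primer_constructs=[
                (RPS16_PRIMER_FORWARD, RPS16_PRIMER_REVERSE, RPS16_AMPLICON_LENGTH)
            ],
        )
        record, truth = generate_plastome(spec)
        amps = in_silico_pcr(
            record.sequence,
            PrimerPair(RPS16_PRIMER_FORWARD, RPS16_PRIMER_REVERSE),
            circular=True,
        )
        assert [(a.start, a.length) for a in amps] == [
            (truth.amplicons[0]["start"], 550)
        ]


class TestEvolveTaxa:
    def test_zero_rate_keeps_everything_identical(self):
        record, _ = generate_plastome(small_annotated_spec(seed=4))
        ev = evolve_taxa(record, EIGHT_TAXON_TREE, sub_rate=0.0, seed=1)
        for taxon, rec in ev.records.items():
            assert rec.sequence == record.sequence, taxon
        from plastomekit import align_stats

        for gene, aln in ev.alignments.items():
            assert align_stats(aln).pi_percent == 0.0

    def test_intron_loss_recovered_on_exact_clade(self):
        record, _ = generate_plastome(small_annotated_spec(seed=4))
        ev = evolve_taxa(
            record,
            EIGHT_TAXON_TREE,
            sub_rate=0.5,
            events=[(["E", "F", "G", "H"], "intron_loss", "rps16")],
            seed=2,
        )
        df = intron_presence(ev.models_by_taxon, "rps16", "A").set_index("taxon")
        lost = set(df[df["call"] == "intron_loss"].index)
        assert lost == {"E", "F", "G", "H"}

    def test_gene_loss_recovered(self):
        record, _ = generate_plastome(small_annotated_spec(seed=4))
        ev = evolve_taxa(
            record,
            EIGHT_TAXON_TREE,
            sub_rate=0.5,
            events=[(["G", "H"], "gene_loss", "matK")],
            seed=2,
        )
        df = intron_presence(ev.models_by_taxon, "rps16", "A")  # unrelated gene intact
        assert set(df["call"]) == {"none"}
        for taxon in ("G", "H"):
            assert "matK" not in {m.name for m in ev.models_by_taxon[taxon]}
            aln = ev.alignments["matK"]
            row = aln.rows[aln.taxa.index(taxon)]
            assert set(row) == {"-"}

    def test_unknown_gene_event_rejected(self):
        record, _ = generate_plastome(small_annotated_spec(seed=4))
        with pytest.raises(KeyError):
            evolve_taxa(record, EIGHT_TAXON_TREE, events=[(["A"], "intron_loss", "nope")])

    def test_identity_decreases_with_rate(self):
        """Mean pairwise identity is monotone decreasing on a rate grid,
        averaged over replicates."""
        from plastomekit import align_stats

        record, _ = generate_plastome(small_annotated_spec(seed=6))
        means = []
        for rate in (0.25, 1.25, 2.5):
            vals = []
            for rep in range(5):
                ev = evolve_taxa(record, EIGHT_TAXON_TREE, sub_rate=rate, seed=100 + rep)
                vals.append(align_stats(ev.alignments["matK"]).seq_identity)
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_pi_percent_monotone_in_rate(self):
        from plastomekit import align_stats

        record, _ = generate_plastome(small_annotated_spec(seed=6))
        means = []
        for rate in (0.25, 1.25, 2.5):
            vals = []
            for rep in range(5):
                ev = evolve_taxa(record, EIGHT_TAXON_TREE, sub_rate=rate, seed=200 + rep)
                vals.append(align_stats(ev.alignments["matK"]).pi_percent)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_true_tree_shorter_than_alternative(self):
        """Fitch length on the generating topology is no longer than on a
        scrambled topology, on average."""
        record, _ = generate_plastome(small_annotated_spec(seed=8))
        wrong_tree = (
            "(((A,G),(C,F)),((E,B),(D,H)));"
        )
        true_wins = 0
        for rep in range(6):
            ev = evolve_taxa(record, EIGHT_TAXON_TREE, sub_rate=1.0, seed=300 + rep)
            aln = ev.alignments["matK"]
            if fitch_length(aln, EIGHT_TAXON_TREE) <= fitch_length(aln, wrong_tree):
                true_wins += 1
        assert true_wins == 6
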