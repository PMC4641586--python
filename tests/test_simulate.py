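"""Synthetic generators: determinism, planted structure, count models."""

import numpy as np
import pytest

from promloop.core import DatasetMeta, GenomicInterval, overlaps
from promloop.simulate import (
    make_toy_gene_model,
    nb_counts,
    plant_motifs,
    simulate_chip_experiment,
    simulate_methylation,
    simulate_pets,
    simulate_variant_reads,
    TruthBundle,
)


class TestToyGeneModel:
    def test_deterministic_under_seed(self):
        m1, s1 = make_toy_gene_model(300_000, 5, seed=3)
        m2, s2 = make_toy_gene_model(300_000, 5, seed=3)
        assert m1 == m2 and s1 == s2

    def test_exon_cardinality_and_names(self):
        model, _ = make_toy_gene_model(300_000, 7, seed=0)
        assert [e.name for e in model.start_exons] == [f"{i}u" for i in range(1, 8)]

    def test_promoter_span_179_up_25_down(self):
        model, _ = make_toy_gene_model(300_000, 7, seed=0)
        tss = model.exon("5u").tss
        assert (model.promoter.start, model.promoter.end) == (tss - 179, tss + 25)
        assert len(model.promoter) == 204

    def test_genome_too_short_rejected(self):
        with pytest.raises(ValueError, match="genome too short"):
            make_toy_gene_model(5_000, 5, seed=0)

    def test_exon_sizes_in_range(self):
        model, seq = make_toy_gene_model(300_000, 9, seed=1)
        for e in model.start_exons:
            assert 80 <= len(e.interval) <= 300
        assert set(seq) <= set("ACGT")


class TestNBCounts:
    def test_zero_dispersion_is_poisson(self):
        # Poisson(1000): central 99% mass well inside [900, 1100]
        rng = np.random.default_rng(0)
        draws = nb_counts(rng, 1000.0, 0.0, size=500)
        assert np.mean((draws >= 900) & (draws <= 1100)) >= 0.99

    def test_dispersion_inflates_variance(self):
        rng = np.random.default_rng(0)
        d = nb_counts(rng, 200.0, 0.2, size=4000)
        # var = m + phi m^2 = 200 + 8000 = 8200
        assert 5000 < d.var() < 12000

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_counts(np.random.default_rng(0), 10, -0.1)


class TestVariantReads:
    def test_zero_means_zero_background_zero_reads(self, toy_model):
        model, _ = toy_model
        aln, metas, _ = simulate_variant_reads(
            model, [("s1", "c")], {"c": {}}, background_reads=0, seed=0
        )
        assert aln["s1"] == []

    def test_reads_land_inside_their_exon(self, toy_model):
        model, _ = toy_model
        aln, metas, _ = simulate_variant_reads(
            model, [("s1", "c")], {"c": {"5u": 200}}, dispersion=0.0,
            background_reads=0, seed=1,
        )
        exon = model.exon("5u").interval
        for read in aln["s1"]:
            assert exon.start <= read.start and read.end <= exon.end
            assert read.strand == model.strand
        assert metas[0].total_mapped_reads == len(aln["s1"])

    def test_deterministic(self, toy_model):
        model, _ = toy_model
        a1 = simulate_variant_reads(model, [("s", "c")], {"c": {"5u": 100}}, seed=9)
        a2 = simulate_variant_reads(model, [("s", "c")], {"c": {"5u": 100}}, seed=9)
        assert a1[0] == a2[0]

    def test_read_length_longer_than_exon_rejected(self, toy_model):
        model, _ = toy_model
        with pytest.raises(ValueError, match="read_length"):
            simulate_variant_reads(
                model, [("s", "c")], {"c": {"5u": 10}}, read_length=5000,
                background_reads=0, seed=0,
            )


class TestChipExperiment:
    def test_planted_window_rate_arithmetic(self):
        # enrichment 8 over background 2 -> expected 16 per planted window
        peak = (GenomicInterval("chrS", 1000, 1200), 8.0)
        counts = []
        for seed in range(40):
            treat, _, _ = simulate_chip_experiment(
                10_000, 2.0, [peak], seed=seed
            )
            counts.append(
                sum(1 for r in treat if 1000 <= r.start < 1200) / 4.0
            )
        assert abs(np.mean(counts) - 16.0) < 1.5

    def test_no_peaks_treatment_matches_input_rate(self):
        treat, ctrl, _ = simulate_chip_experiment(100_000, 2.0, [], seed=5)
        ratio = len(treat) / len(ctrl)
        assert 0.9 < ratio < 1.1

    def test_deterministic(self):
        r1 = simulate_chip_experiment(10_000, 2.0, [], seed=3)
        r2 = simulate_chip_experiment(10_000, 2.0, [], seed=3)
        assert r1[0] == r2[0] and r1[1] == r2[1]

    def test_peak_outside_genome_rejected(self):
        with pytest.raises(ValueError, match="outside genome"):
            simulate_chip_experiment(
                1_000, 2.0, [(GenomicInterval("chrS", 900, 1100), 8.0)], seed=0
            )


class TestPets:
    PROM = GenomicInterval("chrS", 100_000, 100_204)
    REGIONS = [GenomicInterval("chrS", 300_000 + 20_000 * i, 301_000 + 20_000 * i)
               for i in range(5)]

    def test_true_pair_cardinality(self):
        pets, truth = simulate_pets(self.PROM, self.REGIONS, 3, 0, seed=0)
        assert len(pets) == 15
        assert all(t for _, t in truth.planted_pets)

    def test_every_true_pair_promoter_anchored(self):
        pets, _ = simulate_pets(self.PROM, self.REGIONS, 4, 0, seed=2)
        for p in pets:
            on = overlaps(p.anchor1, self.PROM) + overlaps(p.anchor2, self.PROM)
            assert on == 1

    def test_region_overlapping_promoter_rejected(self):
        with pytest.raises(ValueError, match="overlaps the promoter"):
            simulate_pets(self.PROM, [GenomicInterval("chrS", 100_100, 101_000)], 1, 0)


class TestPlantMotifs:
    def test_plus_strand_written_verbatim_consensus(self):
        seq, truth = plant_motifs("A" * 30, [("RCGTG", 10, "+")], seed=1)
        window = seq[10:15]
        assert window[0] in "AG" and window[1:] == "CGTG"
        assert len(seq) == 30

    def test_minus_strand_written_as_reverse_complement(self):
        seq, _ = plant_motifs("A" * 30, [("RCGTG", 10, "-")], seed=1)
        from promloop.simulate import reverse_complement

        rc = reverse_complement(seq[10:15])
        assert rc[0] in "AG" and rc[1:] == "CGTG"

    def test_overlapping_instances_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            plant_motifs("A" * 30, [("RCGTG", 10, "+"), ("RCGTG", 12, "+")])

    def test_empty_instances_identity(self):
        assert plant_motifs("ACGTACGT", [], seed=0)[0] == "ACGTACGT"


class TestMethylation:
    def test_perfect_conversion_gives_pure_fractions(self):
        records, _ = simulate_methylation(
            [10, 20], {10: "methylated", 20: "unmethylated"},
            coverage=200, conversion_rate=1.0, dropout=0.0, seed=0,
        )
        by_pos = {r.pos: r for r in records}
        assert by_pos[10].unmethylated == 0 and by_pos[10].methylated > 0
        assert by_pos[20].methylated == 0 and by_pos[20].unmethylated > 0

    def test_zero_coverage_mean_gives_zero_counts(self):
        records, _ = simulate_methylation(
            [5], {5: "methylated"}, coverage=0.0, dropout=0.0, seed=0
        )
        assert all(r.coverage == 0 for r in records)

    def test_dropout_removes_sites(self):
        positions = list(range(0, 4000, 2))
        records, _ = simulate_methylation(
            positions, {p: "methylated" for p in positions},
            coverage=5, dropout=0.3, seed=1,
        )
        frac = 1 - len(records) / len(positions)
        assert 0.25 < frac < 0.35

    def test_invalid_conversion_rate(self):
        with pytest.raises(ValueError):
            simulate_methylation([1], {1: "methylated"}, conversion_rate=0.0)


def test_truth_bundle_round_trip(tmp_path, toy_model):
    model, _ = toy_model
    tb = TruthBundle(gene_model=model,
                     variant_abundance={"c": {"5u": 10.0}},
                     planted_motifs=[("HRE", 123, "+")],
                     planted_methylation={55: "methylated"})
    path = tmp_path / "truth.json"
    tb.to_json(str(path))
    back = TruthBundle.from_json(str(path))
    assert back.gene_model == model
    assert back.variant_abundance == tb.variant_abundance
    assert back.planted_motifs == [("HRE", 123, "+")]
    assert back.planted_methylation == {55: "methylated"}
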