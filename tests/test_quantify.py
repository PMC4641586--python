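"""Start-exon counting, RPKM, TSS-window signal, ANOVA and Tukey-Kramer."""

import numpy as np
import pytest
from scipy import stats

from promloop.core import AlignedRead, DatasetMeta, GeneModel, GenomicInterval, StartExon
from promloop.quantify import (
    ExpressionRecord,
    compute_rpkm,
    condition_fold_changes,
    count_start_exon_reads,
    groseq_tss_rpkm,
    groseq_tss_window,
    one_way_anova,
    studentized_range_critical,
    tukey_kramer,
)


def small_model():
    e1 = StartExon("5u", GenomicInterval("chrS", 120, 220, "+"), 120)
    e2 = StartExon("9u", GenomicInterval("chrS", 200, 320, "+"), 200)  # overlaps 5u
    prom = GenomicInterval("chrS", 0, 204)
    return GeneModel("g", "+", (e1, e2), prom)


def read(start, end, strand="+", sample="s"):
    return AlignedRead("chrS", start, end, strand, sample)


class TestCounting:
    def test_one_bp_overlap_counts(self):
        counts = count_start_exon_reads([read(100, 150)], small_model())
        assert counts == {"5u": 1, "9u": 0}

    def test_no_overlap_counted_nowhere(self):
        counts = count_start_exon_reads([read(0, 50)], small_model())
        assert counts == {"5u": 0, "9u": 0}

    def test_multi_exon_read_counts_in_each(self):
        counts = count_start_exon_reads([read(190, 230)], small_model())
        assert counts == {"5u": 1, "9u": 1}

    def test_best_overlap_assigns_once(self):
        # [190,230) overlaps 5u by 30 bp, 9u by 30 bp -> tie to leftmost (5u)
        counts = count_start_exon_reads([read(190, 230)], small_model(),
                                        assignment="best-overlap")
        assert counts == {"5u": 1, "9u": 0}
        counts = count_start_exon_reads([read(195, 230)], small_model(),
                                        assignment="best-overlap")
        assert counts == {"5u": 0, "9u": 1}  # 25 vs 30 bp

    def test_stranded_mode_drops_antisense(self):
        counts = count_start_exon_reads([read(130, 150, strand="-")],
                                        small_model(), stranded=True)
        assert counts == {"5u": 0, "9u": 0}


class TestRpkm:
    @pytest.mark.parametrize(
        "count,length,total,expected",
        [(0, 200, 10**6, 0.0), (100, 1000, 10**6, 100.0), (300, 600, 2 * 10**6, 250.0)],
    )
    def test_hand_arithmetic(self, count, length, total, expected):
        assert compute_rpkm(count, length, total) == pytest.approx(expected)

    def test_joint_scaling_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c = int(rng.integers(0, 10_000))
            L = int(rng.integers(50, 5_000))
            T = int(rng.integers(10**5, 10**8))
            k = int(rng.integers(2, 10))
            assert compute_rpkm(c * k, L, T * k) == pytest.approx(compute_rpkm(c, L, T))

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            compute_rpkm(1, 0, 10**6)
        with pytest.raises(ValueError):
            compute_rpkm(1, 100, 0)


class TestGroseq:
    def meta(self):
        return DatasetMeta("s", "c", 10**6)

    def test_plus_strand_window(self):
        w = groseq_tss_window(1000, "+", "chrS")
        assert (w.start, w.end) == (900, 1500)

    def test_window_read_rule_and_rpkm(self):
        model = small_model()
        # 5u TSS at 120: window [20, 620); 6 reads with 5' end inside
        reads = [read(s, s + 30) for s in (25, 100, 200, 300, 400, 600)]
        records = groseq_tss_rpkm(reads, model, self.meta())
        r5u = next(r for r in records if r.unit_name == "5u")
        assert r5u.raw_count == 6
        assert r5u.rpkm == pytest.approx(6 / 0.6)  # 10.0 at 1M mapped reads

    def test_five_prime_rule_not_any_overlap(self):
        model = small_model()
        # read overlaps the window but its 5' end (start, + strand) is outside
        records = groseq_tss_rpkm([read(625, 660)], model, self.meta())
        assert next(r for r in records if r.unit_name == "5u").raw_count == 0

    def test_minus_strand_mirror_symmetry(self):
        L = 10_000
        plus_exon = StartExon("5u", GenomicInterval("chrS", 1000, 1200, "+"), 1000)
        plus = GeneModel("g", "+", (plus_exon,), GenomicInterval("chrS", 900, 1000))
        m_iv = GenomicInterval("chrS", L - 1200, L - 1000, "-")
        minus_exon = StartExon("5u", m_iv, L - 1 - 1000)
        minus = GeneModel("g", "-", (minus_exon,), GenomicInterval("chrS", L - 1000, L - 900))
        rng = np.random.default_rng(4)
        starts = rng.integers(600, 1800, size=200)
        plus_reads = [read(int(s), int(s) + 40) for s in starts]
        minus_reads = [read(L - int(s) - 40, L - int(s), strand="-") for s in starts]
        a = groseq_tss_rpkm(plus_reads, plus, self.meta())[0]
        b = groseq_tss_rpkm(minus_reads, minus, self.meta())[0]
        assert a.raw_count == b.raw_count and a.rpkm == pytest.approx(b.rpkm)

    def test_matches_brute_force_window_check(self):
        model = small_model()
        rng = np.random.default_rng(7)
        reads = [read(int(s), int(s) + 30, strand=str(st))
                 for s, st in zip(rng.integers(0, 2000, 300),
                                  rng.choice(["+", "-"], 300))]
        records = groseq_tss_rpkm(reads, model, self.meta())
        for exon in model.start_exons:
            lo, hi = exon.tss - 100, exon.tss + 500
            expected = sum(1 for r in reads if r.strand == "+" and lo <= r.start < hi)
            got = next(r for r in records if r.unit_name == exon.name).raw_count
            assert got == expected


class TestAnova:
    def test_equal_groups(self):
        F, p = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert F == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_textbook_fixture_f_15000(self):
        # SSB = 15000 (df 1), MSW = 1 (df 4) -> F = 15000
        F, p = one_way_anova([[1, 2, 3], [101, 102, 103]])
        assert F == pytest.approx(15000.0)
        assert p < 1e-6

    def test_permutation_invariance(self):
        F1, _ = one_way_anova([[3, 1, 2], [9, 4, 6]])
        F2, _ = one_way_anova([[1, 2, 3], [4, 6, 9]])
        assert F1 == pytest.approx(F2)

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            one_way_anova([[1, 2], [3]])
        with pytest.raises(ValueError):
            one_way_anova([[1, 2]])


class TestTukeyKramer:
    def test_identical_groups_not_significant(self):
        flags = tukey_kramer([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert flags == {(0, 1): False}

    def test_q_critical_value_3_12(self):
        assert studentized_range_critical(3, 12, 0.05) == pytest.approx(3.773, abs=0.01)

    def test_k2_matches_pooled_t_test(self):
        # q = sqrt(2) * |t| identity: decisions must coincide at equal alpha
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = rng.normal(0, 1, size=int(rng.integers(3, 8)))
            b = rng.normal(rng.uniform(-2, 2), 1, size=int(rng.integers(3, 8)))
            tk = tukey_kramer([list(a), list(b)], alpha=0.05)[(0, 1)]
            t = stats.ttest_ind(a, b, equal_var=True)
            assert tk == (t.pvalue < 0.05)

    def test_matches_scipy_tukey_hsd(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            groups = [list(rng.normal(rng.uniform(-1, 1), 1, size=int(rng.integers(3, 9))))
                      for _ in range(int(rng.integers(3, 5)))]
            ours = tukey_kramer(groups, alpha=0.05)
            ref = stats.tukey_hsd(*groups)
            for (i, j), sig in ours.items():
                assert sig == (ref.pvalue[i, j] < 0.05)


class TestFoldChanges:
    def records(self, rpkms_by_cond, unit="5u"):
        out = []
        for cond, values in rpkms_by_cond.items():
            for i, v in enumerate(values):
                out.append(ExpressionRecord(f"{cond}{i}", cond, unit, 0, 100, v))
        return out

    def test_fold_4_3_from_means(self):
        recs = self.records({"hypoxia": [80, 86, 92], "normoxia": [19, 20, 21]})
        [r] = condition_fold_changes(recs, "hypoxia", "normoxia")
        assert r.fold_change == pytest.approx(86 / 20)

    def test_identical_groups_fold_1_f_0(self):
        recs = self.records({"a": [5, 6, 7], "b": [5, 6, 7]})
        [r] = condition_fold_changes(recs, "a", "b")
        assert r.fold_change == pytest.approx(1.0)
        assert r.anova_F == pytest.approx(0.0)

    def test_zero_control_reported_undefined(self):
        recs = self.records({"a": [5, 6, 7], "b": [0, 0, 0]})
        [r] = condition_fold_changes(recs, "a", "b")
        assert r.fold_change is None

    def test_decrease_reported_as_fraction_of_control(self):
        recs = self.records({"E2": [3.8, 4.0, 4.2], "control": [9.9, 10.0, 10.1]})
        [r] = condition_fold_changes(recs, "E2", "control")
        assert r.fold_change == pytest.approx(0.40)
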