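"""Window counting, the Poisson minimum-read threshold, peak calling,
and NB exact-test differential enrichment."""

import numpy as np
import pytest
from scipy import stats

from promloop.core import AlignedRead, GenomicInterval
from promloop.peaks import (
    DifferentialResult,
    WindowCounts,
    call_peaks,
    differential_regions,
    poisson_min_reads,
    region_counts,
    window_counts,
)


def read(start, end=None, strand="+"):
    return AlignedRead("chrS", start, end or start + 36, strand)


class TestWindowCounts:
    def test_hand_assignment(self):
        wc = window_counts([read(10), read(60), read(62)], 200, 50)
        assert wc.counts == (1, 2, 0, 0)

    def test_no_reads_all_zero(self):
        wc = window_counts([], 130, 50)
        assert wc.counts == (0, 0, 0)  # ceil(130/50) windows

    def test_count_conservation(self):
        rng = np.random.default_rng(3)
        reads = [read(int(s)) for s in rng.integers(0, 5000, 300)]
        wc = window_counts(reads, 6000, 50)
        assert sum(wc.counts) == 300

    def test_minus_strand_uses_5prime_end(self):
        # minus-strand read [10, 60): 5' base is 59 -> window 1
        wc = window_counts([read(10, 60, strand="-")], 100, 50)
        assert wc.counts == (0, 1)


class TestPoissonMinReads:
    def test_threshold_lambda1_20000_windows(self):
        k = poisson_min_reads(1.0, 20_000, alpha=0.05)
        assert k == 9
        # direct survival-function verification of minimality
        bound = 0.05 / 20_000
        assert stats.poisson.sf(8, 1.0) <= bound < stats.poisson.sf(7, 1.0)

    def test_vanishing_background_one_window(self):
        assert poisson_min_reads(1e-12, 1, alpha=0.05) == 1

    @pytest.mark.parametrize("pair", [(0.5, 1), (1, 2), (2, 5)])
    def test_monotone_in_rate(self, pair):
        lo, hi = pair
        assert poisson_min_reads(lo, 1000) <= poisson_min_reads(hi, 1000)


class TestCallPeaks:
    def test_single_hot_window(self):
        wc = WindowCounts("chrS", 50, (1, 0, 9, 1))
        # global mean lambda = 11/4; k from Bonferroni at alpha=0.05 over 4 windows
        [peak] = call_peaks(wc, alpha=0.05)
        assert peak.interval == GenomicInterval("chrS", 100, 150)
        assert peak.read_count == 9

    def test_adjacent_significant_windows_merge(self):
        counts = [0] * 40 + [20, 22] + [0] * 40
        wc = WindowCounts("chrS", 50, tuple(counts))
        [peak] = call_peaks(wc, alpha=0.05)
        assert peak.interval.start == 40 * 50 and peak.interval.end == 42 * 50
        assert peak.read_count == 42

    def test_all_zero_no_peaks(self):
        assert call_peaks(WindowCounts("chrS", 50, (0,) * 100)) == []

    def test_grid_mismatch_rejected(self):
        t = WindowCounts("chrS", 50, (0, 0))
        c = WindowCounts("chrS", 25, (0, 0))
        with pytest.raises(ValueError, match="grids differ"):
            call_peaks(t, c)

    def test_equals_brute_force_threshold_and_merge(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(2.0, size=400)
        counts[100:104] += 40
        counts[250] += 30
        wc = WindowCounts("chrS", 50, tuple(int(c) for c in counts))
        peaks = call_peaks(wc, alpha=0.05)
        # oracle: per-window Poisson tail at the global mean, Bonferroni, then merge
        lam = counts.mean()
        sig = stats.poisson.sf(counts - 1, lam) <= 0.05 / len(counts)
        blocks = []
        for w in np.flatnonzero(sig):
            if blocks and w == blocks[-1][1]:
                blocks[-1][1] = w + 1
            else:
                blocks.append([w, w + 1])
        assert [(p.interval.start // 50, p.interval.end // 50) for p in peaks] == [
            tuple(b) for b in blocks
        ]

    def test_input_control_suppresses_copycat_enrichment(self):
        # a region hot in both treatment and input is not a peak
        counts = np.full(200, 2)
        counts[50:54] = 30
        treat = WindowCounts("chrS", 50, tuple(int(c) for c in counts))
        ctrl = WindowCounts("chrS", 50, tuple(int(c) for c in counts))
        assert call_peaks(treat, ctrl, alpha=0.05) == []
        flat = WindowCounts("chrS", 50, tuple([2] * 200))
        peaks = call_peaks(treat, flat, alpha=0.05)
        assert len(peaks) == 1 and peaks[0].interval.start == 50 * 50


class TestDifferentialRegions:
    REGION = [GenomicInterval("chrS", 0, 100)]

    def test_spec_fixture_log2fc_2_enriched(self):
        [res] = differential_regions(self.REGION, [[100, 120]], [[25, 30]],
                                     [1e6, 1e6], [1e6, 1e6])
        assert res.log2_fold_change == pytest.approx(2.0)
        assert res.klass == "enriched"
        # oracle: conditional binomial on the per-side totals (dispersion ~ 0)
        expected_p = stats.binomtest(220, 275, 0.5).pvalue
        assert res.p_value == pytest.approx(expected_p, rel=1e-6)

    def test_equal_counts_unchanged(self):
        [res] = differential_regions(self.REGION, [[50, 60]], [[50, 60]],
                                     [1e6, 1e6], [1e6, 1e6])
        assert res.log2_fold_change == pytest.approx(0.0)
        assert res.klass == "unchanged"

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(5)
        regions = [GenomicInterval("chrS", i * 200, i * 200 + 100) for i in range(20)]
        a = rng.poisson(80, size=(20, 2)).tolist()
        b = rng.poisson(30, size=(20, 2)).tolist()
        libs = [1e6, 1e6]
        fwd = differential_regions(regions, a, b, libs, libs)
        rev = differential_regions(regions, b, a, libs, libs)
        for f, r in zip(fwd, rev):
            assert f.log2_fold_change == pytest.approx(-r.log2_fold_change)
            assert f.p_value == pytest.approx(r.p_value, rel=1e-9)
            swap = {"enriched": "depleted", "depleted": "enriched",
                    "unchanged": "unchanged"}
            assert swap[f.klass] == r.klass

    def test_double_zero_region_unchanged_p1(self):
        [res] = differential_regions(self.REGION, [[0, 0]], [[0, 0]],
                                     [1e6, 1e6], [1e6, 1e6])
        assert res.klass == "unchanged" and res.p_value == 1.0

    def test_library_size_normalisation(self):
        # same rates, 2x library depth difference: no enrichment
        [res] = differential_regions(self.REGION, [[200, 200]], [[100, 100]],
                                     [2e6, 2e6], [1e6, 1e6])
        assert abs(res.log2_fold_change) < 0.05
        assert res.klass == "unchanged"

    def test_class_thresholds_honoured(self):
        for res in differential_regions(
            [GenomicInterval("chrS", 0, 100)] * 2,
            [[100, 120], [40, 44]], [[25, 30], [25, 27]],
            [1e6, 1e6], [1e6, 1e6],
        ):
            if res.klass == "enriched":
                assert res.log2_fold_change >= 1 and res.p_value < 0.05
            else:
                assert res.log2_fold_change < 1 or res.p_value >= 0.05


def test_region_counts_by_five_prime():
    regions = [GenomicInterval("chrS", 0, 100), GenomicInterval("chrS", 100, 200)]
    reads = [read(10), read(95, 140), read(150)]
    assert region_counts(reads, regions) == [2, 1]
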