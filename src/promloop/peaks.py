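"""Window-based ChIP-seq peak calling and differential enrichment.

The chromosome is tiled with non-overlapping 50 bp windows; each read is
assigned to one window by its 5'-most aligned base. The minimum read
count that makes a window significant is derived from the Poisson upper
tail with a Bonferroni correction across windows — the reproducible
formalisation of an "automatically calculated" threshold. Adjacent
significant windows merge into peaks. Differential enrichment between
conditions uses a negative-binomial exact test with a common
method-of-moments dispersion and classifies regions at p < 0.05 with
|log2 fold change| >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import AlignedRead, GenomicInterval


@dataclass(frozen=True)
class WindowCounts:
    chrom: str
    window_size: int
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if any(c < 0 for c in self.counts):
            raise ValueError("window counts must be non-negative")

    def window_interval(self, index: int) -> GenomicInterval:
        lo = index * self.window_size
        return GenomicInterval(self.chrom, lo, lo + self.window_size)


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    read_count: int
    expected: float
    p_value: float
    fold_over_input: float | None = None


@dataclass(frozen=True)
class DifferentialResult:
    region: GenomicInterval
    counts_a: tuple[int, ...]
    counts_b: tuple[int, ...]
    log2_fold_change: float
    p_value: float
    klass: str  # enriched | depleted | unchanged


def window_counts(
    alignments: Sequence[AlignedRead],
    chrom_length: int,
    window_size: int = 50,
    chrom: str | None = None,
) -> WindowCounts:
    """Tile ``[0, chrom_length)`` and count reads by 5'-most aligned base."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if chrom is None:
        chroms = {r.chrom for r in alignments}
        if len(chroms) > 1:
            raise ValueError(f"alignments span several chromosomes {sorted(chroms)}; pass chrom=")
        chrom = chroms.pop() if chroms else "chrS"
    n = -(-chrom_length // window_size)
    counts = np.zeros(n, dtype=int)
    for read in alignments:
        if read.chrom != chrom:
            continue
        w = read.five_prime // window_size
        if 0 <= w < n:
            counts[w] += 1
    return WindowCounts(chrom, window_size, tuple(int(c) for c in counts))


def poisson_min_reads(background_rate: float, n_windows: int, alpha: float = 0.05) -> int:
    """Smallest k with P(X >= k | Poisson(rate)) <= alpha / n_windows.

    The Bonferroni correction across windows makes k the minimum read
    count per window at family-wise error alpha.
    """
    if background_rate <= 0:
        raise ValueError("background_rate must be positive")
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    bound = alpha / n_windows
    k = 1
    while stats.poisson.sf(k - 1, background_rate) > bound:
        k += 1
    return k


def call_peaks(
    treatment: WindowCounts,
    control: WindowCounts | None = None,
    alpha: float = 0.05,
    local_span: int = 5000,
) -> list[Peak]:
    """Call enriched windows against an input-derived Poisson background.

    With an input control the per-window background is the local input
    mean over ``local_span`` bp (floored at the global input mean), scaled
    to the treatment library size; without one it is the global treatment
    mean. A window is significant when the Poisson upper tail of its count
    is <= alpha/n_windows; runs of adjacent significant windows merge into
    one peak carrying the summed count and the minimum member p-value.
    """
    t = np.asarray(treatment.counts, dtype=float)
    n = len(t)
    if n == 0:
        return []
    if control is not None:
        if (control.window_size != treatment.window_size
                or len(control.counts) != n or control.chrom != treatment.chrom):
            raise ValueError("treatment and control window grids differ")
        c = np.asarray(control.counts, dtype=float)
        scale = t.sum() / c.sum() if c.sum() > 0 else 1.0

        def local_mean(span_bp: int) -> np.ndarray:
            half = max(span_bp // (2 * treatment.window_size), 1)
            kernel = np.ones(2 * half + 1)
            return np.convolve(c, kernel, mode="same") / np.convolve(
                np.ones(n), kernel, mode="same"
            )

        # max over scales: genome-wide mean, a wide and a narrow local mean,
        # so focal input enrichment is not smoothed away
        lam = np.maximum.reduce(
            [np.full(n, c.mean()), local_mean(local_span), local_mean(local_span // 20)]
        ) * scale
    else:
        lam = np.full(n, t.mean() if t.mean() > 0 else 1e-9)
    lam = np.maximum(lam, 1e-9)
    pvals = stats.poisson.sf(t - 1, lam)
    significant = pvals <= alpha / n

    peaks: list[Peak] = []
    i = 0
    while i < n:
        if not significant[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and significant[j + 1]:
            j += 1
        iv = GenomicInterval(
            treatment.chrom,
            i * treatment.window_size,
            (j + 1) * treatment.window_size,
        )
        count = int(t[i:j + 1].sum())
        expected = float(lam[i:j + 1].sum())
        fold = None
        if control is not None:
            fold = count / expected if expected > 0 else None
        peaks.append(
            Peak(iv, count, expected, float(pvals[i:j + 1].min()), fold)
        )
        i = j + 1
    return peaks


def region_counts(
    alignments: Sequence[AlignedRead], regions: Sequence[GenomicInterval]
) -> list[int]:
    """Reads per region by 5'-end containment."""
    out = []
    for region in regions:
        out.append(
            sum(1 for r in alignments if region.contains(r.chrom, r.five_prime))
        )
    return out


def _moments_dispersion(counts: np.ndarray) -> float:
    """Common NB dispersion across regions by method of moments.

    ``counts`` is regions x replicates, already library-size normalised.
    phi solves var = m + phi*m^2 per region; the average over informative
    regions, floored at 0, is returned.
    """
    phis = []
    for row in counts:
        if len(row) < 2:
            continue
        m = row.mean()
        if m <= 0:
            continue
        v = row.var(ddof=1)
        phis.append((v - m) / (m * m))
    if not phis:
        return 0.0
    return max(float(np.mean(phis)), 0.0)


def _nb_exact_pvalue(a: float, b: float, phi: float) -> float:
    """Exact two-sided test that two NB totals share a common mean.

    Conditions on the total s = a + b: the p-value is the probability mass
    of all splits (x, s - x) no more likely than the observed one, under
    independent NB(mu, phi) margins with the null mean mu = s / 2.
    phi = 0 reduces to the conditional binomial test with p = 1/2.
    """
    s = int(round(a + b))
    if s == 0:
        return 1.0
    mu = s / 2.0
    x = np.arange(s + 1)
    if phi <= 0:
        logp = stats.binom.logpmf(x, s, 0.5)
        probs = np.exp(logp)
    else:
        r = 1.0 / phi
        p = r / (r + mu)
        lp = stats.nbinom.logpmf(x, r, p)
        joint = lp + lp[::-1]
        joint -= joint.max()
        probs = np.exp(joint)
        probs /= probs.sum()
    obs = probs[int(round(a))]
    return float(min(probs[probs <= obs * (1 + 1e-12)].sum(), 1.0))


def differential_regions(
    regions: Sequence[GenomicInterval],
    counts_a: Sequence[Sequence[int]],
    counts_b: Sequence[Sequence[int]],
    lib_sizes_a: Sequence[float],
    lib_sizes_b: Sequence[float],
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    pseudocount: float = 0.5,
) -> list[DifferentialResult]:
    """Classify regions as enriched/depleted/unchanged between two conditions.

    Counts are total-count scaled to the geometric mean library size;
    log2FC falls back to a pseudocount per side only when one side's mean
    is zero, so finite ratios are reported exactly. The p-value is an exact NB test on
    the normalised per-side totals with a common method-of-moments
    dispersion (Poisson/binomial when the dispersion estimate is zero).
    Enriched means log2FC >= ``lfc_threshold`` and p < alpha; depleted is
    the mirror image.
    """
    if min(len(counts_a[0]) if counts_a else 0, len(counts_b[0]) if counts_b else 0) < 1:
        raise ValueError("need at least one replicate per side")
    la = np.asarray(lib_sizes_a, dtype=float)
    lb = np.asarray(lib_sizes_b, dtype=float)
    if (la <= 0).any() or (lb <= 0).any():
        raise ValueError("library sizes must be positive")
    ref = float(np.exp(np.mean(np.log(np.concatenate([la, lb])))))
    norm_a = np.asarray(counts_a, dtype=float) * (ref / la)
    norm_b = np.asarray(counts_b, dtype=float) * (ref / lb)
    phi = _moments_dispersion(np.vstack([norm_a, norm_b]))

    na, nb = norm_a.shape[1], norm_b.shape[1]
    results = []
    for idx, region in enumerate(regions):
        ma = norm_a[idx].mean()
        mb = norm_b[idx].mean()
        if ma == 0 and mb == 0:
            results.append(
                DifferentialResult(region, tuple(int(c) for c in counts_a[idx]),
                                   tuple(int(c) for c in counts_b[idx]), 0.0, 1.0,
                                   "unchanged")
            )
            continue
        if ma == 0 or mb == 0:  # pseudocount only where a zero would blow up
            lfc = float(np.log2((ma + pseudocount) / (mb + pseudocount)))
        else:
            lfc = float(np.log2(ma / mb))
        # per-replicate dispersion phi gives total dispersion phi/n for the
        # normalised per-side mean totals used in the exact test
        tot_a = norm_a[idx].sum() / na * min(na, nb)
        tot_b = norm_b[idx].sum() / nb * min(na, nb)
        phi_tot = phi / min(na, nb)
        p = _nb_exact_pvalue(tot_a, tot_b, phi_tot)
        if lfc >= lfc_threshold and p < alpha:
            klass = "enriched"
        elif lfc <= -lfc_threshold and p < alpha:
            klass = "depleted"
        else:
            klass = "unchanged"
        results.append(
            DifferentialResult(region, tuple(int(c) for c in counts_a[idx]),
                               tuple(int(c) for c in counts_b[idx]), lfc, float(p), klass)
        )
    return results
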