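"""Start-exon-specific transcript quantification and condition statistics.

RNA-seq reads are assigned to alternative start exons by >= 1 bp overlap
(a read overlapping k exons counts once toward each) and normalised to
RPKM: reads per exon length in kb per million mapped reads. GRO-seq
nascent-transcription signal is quantified in a strand-oriented window
from 100 bp upstream to 500 bp downstream of each TSS, normalised to the
fixed 0.6 kb window. Condition contrasts use treated/control RPKM-mean
ratios with one-way ANOVA across conditions followed by Tukey-Kramer
pairwise tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import AlignedRead, DatasetMeta, GeneModel, GenomicInterval, overlaps


@dataclass(frozen=True)
class ExpressionRecord:
    sample_id: str
    condition: str
    unit_name: str
    raw_count: int
    feature_length: int
    rpkm: float


@dataclass
class FoldChangeResult:
    unit_name: str
    condition_a: str
    condition_b: str
    mean_rpkm_a: float
    mean_rpkm_b: float
    fold_change: float | None          # None when the control mean is zero
    anova_F: float | None = None
    anova_p: float | None = None
    pairwise_flags: dict = field(default_factory=dict)  # (cond_i, cond_j) -> bool


def count_start_exon_reads(
    alignments: list[AlignedRead],
    gene_model: GeneModel,
    stranded: bool = False,
    assignment: str = "any-overlap",
) -> dict[str, int]:
    """Count reads per start exon by genomic-footprint overlap.

    ``any-overlap`` (default): a read contributes 1 to every exon it
    overlaps by >= 1 bp. ``best-overlap``: only to the exon with the
    largest overlap (ties to the leftmost exon).
    """
    if assignment not in ("any-overlap", "best-overlap"):
        raise ValueError(f"unknown assignment mode {assignment!r}")
    counts = {e.name: 0 for e in gene_model.start_exons}
    for read in alignments:
        if stranded and read.strand != gene_model.strand:
            continue
        riv = GenomicInterval(read.chrom, read.start, read.end)
        hits = [
            (min(read.end, e.interval.end) - max(read.start, e.interval.start), e.name)
            for e in gene_model.start_exons
            if overlaps(riv, e.interval)
        ]
        if not hits:
            continue
        if assignment == "any-overlap":
            for _, name in hits:
                counts[name] += 1
        else:
            counts[max(hits, key=lambda h: (h[0], -gene_model.exon(h[1]).interval.start))[1]] += 1
    return counts


def compute_rpkm(count: int, feature_length: int, total_mapped_reads: int) -> float:
    """Reads per feature length in kb per million mapped reads."""
    if feature_length <= 0:
        raise ValueError("feature_length must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    return count / (feature_length / 1000.0) / (total_mapped_reads / 1e6)


def quantify_sample(
    alignments: list[AlignedRead],
    gene_model: GeneModel,
    meta: DatasetMeta,
    stranded: bool = False,
    assignment: str = "any-overlap",
) -> list[ExpressionRecord]:
    counts = count_start_exon_reads(alignments, gene_model, stranded, assignment)
    records = []
    for exon in gene_model.start_exons:
        length = len(exon.interval)
        c = counts[exon.name]
        records.append(
            ExpressionRecord(meta.sample_id, meta.condition, exon.name, c, length,
                             compute_rpkm(c, length, meta.total_mapped_reads))
        )
    return records


GROSEQ_UPSTREAM = 100
GROSEQ_DOWNSTREAM = 500
GROSEQ_WINDOW = GROSEQ_UPSTREAM + GROSEQ_DOWNSTREAM  # the fixed 0.6 kb fragment


def groseq_tss_window(tss: int, strand: str, chrom: str,
                      chrom_length: int | None = None) -> GenomicInterval:
    """Strand-oriented window 100 bp upstream through 500 bp downstream of a TSS."""
    if strand == "-":
        lo, hi = tss - GROSEQ_DOWNSTREAM + 1, tss + GROSEQ_UPSTREAM + 1
    else:
        lo, hi = tss - GROSEQ_UPSTREAM, tss + GROSEQ_DOWNSTREAM
    if lo < 0 or (chrom_length is not None and hi > chrom_length):
        import warnings

        warnings.warn(f"TSS window [{lo},{hi}) clipped to chromosome bounds")
        lo = max(lo, 0)
        if chrom_length is not None:
            hi = min(hi, chrom_length)
    return GenomicInterval(chrom, lo, hi)


def groseq_tss_rpkm(
    alignments: list[AlignedRead],
    gene_model: GeneModel,
    meta: DatasetMeta,
    stranded: bool = True,
    chrom_length: int | None = None,
) -> list[ExpressionRecord]:
    """RPKM of nascent transcription in each TSS-proximal window.

    A read is in a window when its 5'-most aligned base falls inside; only
    reads on the gene strand count in stranded mode (nascent run-on signal
    is strand-specific). The RPKM feature length is fixed at the 600 bp
    window regardless of clipping.
    """
    records = []
    for exon in gene_model.start_exons:
        window = groseq_tss_window(exon.tss, gene_model.strand, exon.interval.chrom,
                                   chrom_length)
        count = 0
        for read in alignments:
            if stranded and read.strand != gene_model.strand:
                continue
            if window.contains(read.chrom, read.five_prime):
                count += 1
        records.append(
            ExpressionRecord(meta.sample_id, meta.condition, exon.name, count,
                             GROSEQ_WINDOW,
                             compute_rpkm(count, GROSEQ_WINDOW, meta.total_mapped_reads))
        )
    return records


def one_way_anova(groups: list[list[float]]) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA (F statistic, upper-tail p)."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each ANOVA group needs at least two values")
        if not all(np.isfinite(g)):
            raise ValueError("ANOVA values must be finite")
    f, p = stats.f_oneway(*groups)
    if np.isnan(f):  # all values identical across groups
        return 0.0, 1.0
    return float(f), float(p)


def tukey_kramer(
    groups: list[list[float]], alpha: float = 0.05
) -> dict[tuple[int, int], bool]:
    """Tukey-Kramer pairwise comparisons after one-way ANOVA.

    For groups i < j the studentized-range statistic is
    ``q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))`` with MSW the
    within-group mean square on N - k df; a pair is significant when q
    exceeds the studentized-range critical value at (k, N - k, alpha),
    which controls the family-wise error at alpha (Kramer's adjustment
    handles unequal group sizes).
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs at least two values")
    ns = [len(g) for g in groups]
    means = [float(np.mean(g)) for g in groups]
    N = sum(ns)
    ssw = sum(float(np.sum((np.asarray(g) - m) ** 2)) for g, m in zip(groups, means))
    df = N - k
    msw = ssw / df
    qcrit = studentized_range_critical(k, df, alpha)
    out = {}
    for i, j in itertools.combinations(range(k), 2):
        if msw == 0:
            out[(i, j)] = means[i] != means[j]
            continue
        se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        q = abs(means[i] - means[j]) / se
        out[(i, j)] = bool(q > qcrit)
    return out


def studentized_range_critical(k: int, df: int, alpha: float = 0.05) -> float:
    """Upper critical value of the studentized range with k groups, df error df."""
    return float(stats.studentized_range.ppf(1 - alpha, k, df))


def condition_fold_changes(
    records: list[ExpressionRecord],
    condition_a: str,
    condition_b: str,
    alpha: float = 0.05,
) -> list[FoldChangeResult]:
    """Treated/control fold change per start exon with ANOVA across conditions.

    ``condition_a`` is the treated group and ``condition_b`` the control;
    decreases come out as fractions of control (0.64 means 64% of control).
    A zero control mean gives ``fold_change=None`` rather than an error.
    ANOVA spans every condition present in ``records``; Tukey-Kramer flags
    are attached when >= 3 conditions have replication or the ANOVA is
    significant.
    """
    units = sorted({r.unit_name for r in records})
    conditions = sorted({r.condition for r in records})
    results = []
    for unit in units:
        by_cond = {
            c: [r.rpkm for r in records if r.unit_name == unit and r.condition == c]
            for c in conditions
        }
        if not by_cond.get(condition_a) or not by_cond.get(condition_b):
            raise ValueError(f"unit {unit}: missing replicates for contrast conditions")
        mean_a = float(np.mean(by_cond[condition_a]))
        mean_b = float(np.mean(by_cond[condition_b]))
        fold = mean_a / mean_b if mean_b > 0 else None
        res = FoldChangeResult(unit, condition_a, condition_b, mean_a, mean_b, fold)
        replicated = [c for c in conditions if len(by_cond[c]) >= 2]
        if len(replicated) >= 2:
            F, p = one_way_anova([by_cond[c] for c in replicated])
            res.anova_F, res.anova_p = F, p
            if len(replicated) >= 3 or p < alpha:
                flags = tukey_kramer([by_cond[c] for c in replicated], alpha)
                res.pairwise_flags = {
                    (replicated[i], replicated[j]): sig for (i, j), sig in flags.items()
                }
        results.append(res)
    return results
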