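"""Domain types and interval arithmetic shared by every pipeline stage.

All coordinates are 0-based half-open (``[start, end)``), the BED
convention. Conversions from 1-based formats (GTF, SAM) happen only at
format boundaries in :mod:`promloop.io`. Chromosome names are compared by
exact string equality; no "chr" prefix normalisation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class StartExon:
    """An alternative first exon; ``tss`` is its first transcribed base."""

    name: str
    interval: GenomicInterval
    tss: int

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.tss < self.interval.end):
            raise ValueError(
                f"tss {self.tss} outside exon {self.name} "
                f"[{self.interval.start},{self.interval.end})"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene with several mutually exclusive start exons.

    Each start exon marks an alternative promoter; ``promoter`` is the
    regulatory interval of the promoter of interest (for the myoglobin
    architecture this spans 179 bp upstream to 25 bp downstream of the
    cancer-associated first exon's first base).
    """

    gene_id: str
    strand: str
    start_exons: tuple[StartExon, ...]
    promoter: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be '+' or '-'")
        if not self.start_exons:
            raise ValueError("gene model needs at least one start exon")
        names = [e.name for e in self.start_exons]
        if len(set(names)) != len(names):
            raise ValueError("start exon names must be unique")
        for e in self.start_exons:
            if e.interval.strand not in (".", self.strand):
                raise ValueError(f"start exon {e.name} not on gene strand")

    @property
    def chrom(self) -> str:
        return self.start_exons[0].interval.chrom

    def exon(self, name: str) -> StartExon:
        for e in self.start_exons:
            if e.name == name:
                return e
        raise KeyError(name)


@dataclass(frozen=True)
class AlignedRead:
    """A mapped read reduced to its genomic footprint."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    sample_id: str = ""
    read_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("read end must exceed start")

    @property
    def five_prime(self) -> int:
        """5'-most aligned base (strand-aware; end-1 on the minus strand)."""
        return self.start if self.strand != "-" else self.end - 1


@dataclass(frozen=True)
class DatasetMeta:
    sample_id: str
    condition: str
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.total_mapped_reads <= 0:
            raise ValueError("total_mapped_reads must be positive")


@dataclass(frozen=True)
class PETPair:
    """One ChIA-PET interaction: two anchors held in proximity by a factor."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    pet_count: int = 1
    factor: str = "PolII"
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if self.pet_count < 1:
            raise ValueError("pet_count must be >= 1")


@dataclass(frozen=True)
class AssayTrack:
    """A peak set from one assay in one condition (one dataset)."""

    assay: str
    condition: str
    peaks: tuple[GenomicInterval, ...]
    dataset_id: str = ""

    def __post_init__(self) -> None:
        starts = [(p.chrom, p.start) for p in self.peaks]
        if starts != sorted(starts):
            object.__setattr__(self, "peaks", tuple(sorted(self.peaks)))


@dataclass(frozen=True)
class CpGRecord:
    """Bisulfite evidence at one CpG: counts of reads calling each state."""

    chrom: str
    pos: int
    methylated: int
    unmethylated: int

    def __post_init__(self) -> None:
        if self.methylated < 0 or self.unmethylated < 0:
            raise ValueError("counts must be non-negative")

    @property
    def coverage(self) -> int:
        return self.methylated + self.unmethylated


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share >= 1 bp on the same chromosome."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals separated by at most ``gap`` bp into disjoint blocks.

    Returns the minimal sorted set of disjoint intervals covering the input;
    strand information is dropped (merged blocks are unstranded).
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    pool = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in pool:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end + gap:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """bp separating two intervals on the same chromosome; 0 if they overlap."""
    if a.chrom != b.chrom:
        raise ValueError("intervals on different chromosomes")
    if overlaps(a, b):
        return 0
    return b.start - a.end if b.start >= a.end else a.start - b.end
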