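"""Read trimming, quality filtering, and end-masking before mapping.

Three named profiles reproduce the preprocessing regimes of the analyses:

* ``rnaseq`` — trim 12 bp from the 5' end and 5 bp from the 3' end,
  quality-trim at error-probability limit 0.05, keep reads >= 15 bp with
  at most two ambiguous bases;
* ``groseq`` — trim 12 bp from the 5' end, quality limit 0.01, keep reads
  >= 10 bp with at most two ambiguous bases;
* ``chip_bisulfite`` — reject reads with mean Phred < 30, then mask the
  first 15 bp and last 5 bp with N.

Quality trimming follows the modified-Mott rule: with per-base error
probability p (from Phred), keep the contiguous segment maximising
sum(limit - p). The commercial tool behind the published parameters does
not document its algorithm; this is the standard published variant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence


@dataclass(frozen=True)
class RawRead:
    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quals must have equal length")


@dataclass(frozen=True)
class PreprocessProfile:
    trim5: int = 0
    trim3: int = 0
    min_length: int = 0
    max_ambiguous: int = 2
    quality_limit: float | None = None   # error-probability threshold
    mode: str = "trim"                   # trim | mask | reject

    def __post_init__(self) -> None:
        if min(self.trim5, self.trim3, self.min_length, self.max_ambiguous) < 0:
            raise ValueError("profile fields must be non-negative")
        if self.quality_limit is not None and not 0 < self.quality_limit < 1:
            raise ValueError("quality_limit must be in (0, 1)")


PROFILES: dict[str, PreprocessProfile] = {
    "rnaseq": PreprocessProfile(trim5=12, trim3=5, min_length=15,
                                max_ambiguous=2, quality_limit=0.05),
    "groseq": PreprocessProfile(trim5=12, trim3=0, min_length=10,
                                max_ambiguous=2, quality_limit=0.01),
    "chip_bisulfite": PreprocessProfile(mode="mask"),
}


def phred_to_error(q: int) -> float:
    return 10.0 ** (-q / 10.0)


def mott_trim(read: RawRead, limit: float) -> RawRead | None:
    """Keep the maximal-scoring contiguous segment under score sum(limit - p).

    Returns None when every base scores below the limit.
    """
    scores = [limit - phred_to_error(q) for q in read.quals]
    best_sum = cur_sum = 0.0
    best = (0, 0)
    cur_start = 0
    for i, s in enumerate(scores):
        cur_sum += s
        if cur_sum <= 0:
            cur_sum = 0.0
            cur_start = i + 1
        elif cur_sum > best_sum:
            best_sum = cur_sum
            best = (cur_start, i + 1)
    if best == (0, 0):
        return None
    lo, hi = best
    return RawRead(read.id, read.bases[lo:hi], read.quals[lo:hi])


def trim_and_filter(
    reads: Iterable[RawRead], profile: PreprocessProfile
) -> list[RawRead]:
    """Apply fixed end-trimming, quality trimming, and length/N filters.

    Order preserved; reads failing the minimum length or the ambiguous-base
    cap are dropped.
    """
    if profile.mode != "trim":
        raise ValueError(f"trim_and_filter needs a trim-mode profile, got {profile.mode!r}")
    kept = []
    for read in reads:
        end = len(read.bases) - profile.trim3
        if end <= profile.trim5:
            continue
        trimmed = RawRead(read.id, read.bases[profile.trim5:end],
                          read.quals[profile.trim5:end])
        if profile.quality_limit is not None:
            trimmed = mott_trim(trimmed, profile.quality_limit)
            if trimmed is None:
                continue
        if len(trimmed.bases) < profile.min_length:
            continue
        if trimmed.bases.count("N") > profile.max_ambiguous:
            continue
        kept.append(trimmed)
    return kept


def phred_filter_and_mask(
    reads: Iterable[RawRead],
    min_phred: float = 30,
    mask5: int = 15,
    mask3: int = 5,
) -> tuple[list[RawRead], dict[str, int]]:
    """Reject reads with mean Phred below ``min_phred``; N-mask survivors' ends.

    The first ``mask5`` and last ``mask3`` bases become N (length unchanged).
    Reads too short to carry both masks are rejected and counted. Returns
    (surviving reads, counter dict with 'rejected_quality' and
    'rejected_short').
    """
    kept = []
    counts = {"input": 0, "rejected_quality": 0, "rejected_short": 0}
    for read in reads:
        counts["input"] += 1
        if len(read.bases) <= mask5 + mask3:
            counts["rejected_short"] += 1
            continue
        if sum(read.quals) / len(read.quals) < min_phred:
            counts["rejected_quality"] += 1
            continue
        n = len(read.bases)
        core = read.bases[mask5:n - mask3] if mask3 else read.bases[mask5:]
        masked = "N" * mask5 + core + "N" * mask3
        kept.append(replace(read, bases=masked))
    return kept, counts


def trim_adapters(
    reads: Iterable[RawRead], adapters: Sequence[str]
) -> list[RawRead]:
    """Strip exact adapter prefixes/suffixes (no error-tolerant alignment)."""
    out = []
    for read in reads:
        bases, quals = read.bases, read.quals
        changed = True
        while changed:
            changed = False
            for adapter in adapters:
                if bases.startswith(adapter):
                    bases, quals = bases[len(adapter):], quals[len(adapter):]
                    changed = True
                if adapter and bases.endswith(adapter):
                    bases, quals = bases[:-len(adapter)], quals[:-len(adapter)]
                    changed = True
        if bases:
            out.append(RawRead(read.id, bases, tuple(quals)))
    return out


def reads_from_fastq_tuples(tuples) -> list[RawRead]:
    return [RawRead(rid, bases, tuple(quals)) for rid, bases, quals in tuples]


def reads_to_fastq_tuples(reads: Iterable[RawRead]):
    return [(r.id, r.bases, list(r.quals)) for r in reads]
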