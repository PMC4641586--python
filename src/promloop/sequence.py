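"""IUPAC consensus motif scanning and per-CpG methylation calling.

The default motif set covers the regulatory elements relevant to a
hormone- and hypoxia-responsive promoter network: the HIF-bound hypoxia
response element core (HRE, RCGTG), estrogen-response-element half site
(RGGTCA), androgen-response elements (full palindromic GGWACANNNTGTTCT
and AGAACA half site), the RUNX1 core (TGTGGT) and the SP1 box (GGGCGG).
These are literature-standard cores, user-overridable via a motif
definition TSV; matching is exact IUPAC containment, not position-weight
scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import CpGRecord, GenomicInterval
from .simulate import IUPAC, reverse_complement


@dataclass(frozen=True)
class MotifDef:
    name: str
    consensus: str
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("consensus must be non-empty")
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in {self.consensus!r}")


@dataclass(frozen=True)
class MotifHit:
    motif: str
    chrom: str
    position: int          # 0-based start of the matched window (+ coordinates)
    strand: str
    matched_sequence: str  # the window as written on the + strand


@dataclass(frozen=True)
class MethylationCall:
    record: CpGRecord
    fraction: float | None
    call: str  # methylated | unmethylated | intermediate | no_call


DEFAULT_MOTIFS = (
    MotifDef("HRE", "RCGTG"),
    MotifDef("ERE_half", "RGGTCA"),
    MotifDef("ARE", "GGWACANNNTGTTCT"),
    MotifDef("ARE_half", "AGAACA"),
    MotifDef("RUNX1", "TGTGGT"),
    MotifDef("SP1", "GGGCGG"),
)


def _matches(window: str, consensus: str) -> bool:
    # N in the sequence never satisfies a code (not even N in the consensus)
    return all(b != "N" and b in IUPAC[c] for b, c in zip(window, consensus.upper()))


def scan_motifs(
    sequence: str,
    motifs: Iterable[MotifDef] = DEFAULT_MOTIFS,
    offset: int = 0,
    chrom: str = "chrS",
) -> list[MotifHit]:
    """Report every exact IUPAC consensus match in the sequence.

    Plus-strand matches are direct; for ``both_strands`` motifs a window
    whose reverse complement matches is reported on the minus strand at
    the window's plus-strand coordinates. Positions are shifted by
    ``offset`` (the genomic start of the sequence).
    """
    seq = sequence.upper()
    hits = []
    for motif in motifs:
        m = len(motif.consensus)
        rc = reverse_complement(motif.consensus)
        for i in range(len(seq) - m + 1):
            window = seq[i:i + m]
            if _matches(window, motif.consensus):
                hits.append(MotifHit(motif.name, chrom, offset + i, "+", window))
            if motif.both_strands and _matches(window, rc):
                hits.append(MotifHit(motif.name, chrom, offset + i, "-", window))
    hits.sort(key=lambda h: (h.position, h.motif, h.strand))
    return hits


def read_motif_tsv(path: str) -> list[MotifDef]:
    """Motif definition TSV: name, consensus, both_strands (true/false)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "name\t")):
                continue
            f = line.split("\t")
            both = len(f) < 3 or f[2].strip().lower() in ("1", "true", "yes")
            out.append(MotifDef(f[0], f[1], both))
    return out


def methylation_fraction_and_call(
    records: Iterable[CpGRecord],
    min_coverage: int = 4,
    unmeth_max: float = 0.2,
    meth_min: float = 0.8,
) -> list[MethylationCall]:
    """Call each CpG methylated/unmethylated/intermediate from its counts.

    Sites with coverage below ``min_coverage`` are no_call (uneven
    sequencing depth leaves such CpGs unreported); otherwise the
    methylated fraction is thresholded at ``unmeth_max`` / ``meth_min``.
    """
    if not 0 <= unmeth_max < meth_min <= 1:
        raise ValueError("need 0 <= unmeth_max < meth_min <= 1")
    calls = []
    for rec in records:
        cov = rec.coverage
        if cov < min_coverage:
            calls.append(MethylationCall(rec, rec.methylated / cov if cov else None, "no_call"))
            continue
        frac = rec.methylated / cov
        if frac <= unmeth_max:
            call = "unmethylated"
        elif frac >= meth_min:
            call = "methylated"
        else:
            call = "intermediate"
        calls.append(MethylationCall(rec, frac, call))
    return calls


def filter_chromosome(records: Sequence, chrom_name: str) -> list:
    """Keep records on one chromosome (exact name match), order preserved."""
    return [r for r in records if r.chrom == chrom_name]


def annotate_regions(
    regions: Sequence[tuple[str, GenomicInterval]],
    motif_hits: Sequence[MotifHit],
    methylation_calls: Sequence[MethylationCall],
) -> tuple[dict[str, dict], dict[str, int]]:
    """Per-region report of contained motif hits and CpG calls.

    A feature belongs to a region when its span (motif window, or the CpG
    base) overlaps the region by >= 1 bp. Returns ({region_id: {"motifs":
    [...], "cpgs": [...]}}, counters of features outside all regions).
    """
    report = {rid: {"motifs": [], "cpgs": []} for rid, _ in regions}
    orphans = {"motifs": 0, "cpgs": 0}
    for hit in motif_hits:
        span = GenomicInterval(hit.chrom, hit.position, hit.position + len(hit.matched_sequence))
        placed = False
        for rid, iv in regions:
            if iv.chrom == span.chrom and span.start < iv.end and iv.start < span.end:
                report[rid]["motifs"].append(hit)
                placed = True
        if not placed:
            orphans["motifs"] += 1
    for call in methylation_calls:
        placed = False
        for rid, iv in regions:
            if iv.contains(call.record.chrom, call.record.pos):
                report[rid]["cpgs"].append(call)
                placed = True
        if not placed:
            orphans["cpgs"] += 1
    return report, orphans
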