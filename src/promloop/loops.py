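"""Promoter-anchored chromatin-loop integration and the evidence matrix.

ChIA-PET pairs with exactly one anchor on the promoter identify distal
candidate regulatory regions; overlapping distal anchors merge into named
candidate regions (A, B, C... in genomic order, A1/A2-style sub-letters
when a merge gap splits a cluster). Each region is then crossed against
every (assay, condition) peak track to build the presence/absence
evidence matrix, and per-assay condition responses (treatment-gained,
treatment-lost, constitutive, closed) are derived from it.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

from .core import (
    AssayTrack,
    GenomicInterval,
    PETPair,
    interval_distance,
    merge_intervals,
    overlaps,
)

PRESENT, ABSENT, NO_DATA = "present", "absent", "no_data"


@dataclass
class CandidateRegion:
    region_id: str
    interval: GenomicInterval
    supporting_pets: list[PETPair]
    datasets: set[str]
    distance_to_promoter: int = 0


@dataclass
class EvidenceMatrix:
    """Region x (assay, condition) presence calls with an audit trail."""

    row_ids: list[str]
    columns: list[tuple[str, str]]               # (assay, condition)
    cells: dict[tuple[str, str, str], str]       # (row, assay, condition) -> call
    audit: dict[tuple[str, str, str], list] = field(default_factory=dict)

    def cell(self, row: str, assay: str, condition: str) -> str:
        return self.cells.get((row, assay, condition), NO_DATA)


def promoter_anchored_pets(
    pets: list[PETPair], promoter: GenomicInterval
) -> tuple[list[tuple[PETPair, GenomicInterval]], dict[str, int]]:
    """Select pairs with exactly one promoter-overlapping anchor.

    Returns (pair, distal anchor) for each, plus counters of excluded
    pairs: both anchors on the promoter, or neither.
    """
    kept = []
    counts = {"both_on_promoter": 0, "neither_on_promoter": 0}
    for pet in pets:
        on1 = overlaps(pet.anchor1, promoter)
        on2 = overlaps(pet.anchor2, promoter)
        if on1 and on2:
            counts["both_on_promoter"] += 1
        elif on1:
            kept.append((pet, pet.anchor2))
        elif on2:
            kept.append((pet, pet.anchor1))
        else:
            counts["neither_on_promoter"] += 1
    return kept, counts


def _region_ids(n: int) -> list[str]:
    letters = string.ascii_uppercase
    if n <= len(letters):
        return list(letters[:n])
    ids = []
    for i in range(n):
        ids.append(letters[i % 26] + str(i // 26 + 1))
    return ids


def define_candidate_regions(
    anchored: list[tuple[PETPair, GenomicInterval]],
    promoter: GenomicInterval,
    merge_gap: int = 1000,
    min_support: int = 1,
) -> list[CandidateRegion]:
    """Merge distal anchors into named candidate regions.

    Anchors within ``merge_gap`` bp merge; regions with fewer than
    ``min_support`` supporting pairs are dropped; ids run alphabetically
    by genomic position; each region reports its distance to the promoter.
    """
    anchors = [a for _, a in anchored]
    merged = merge_intervals(anchors, gap=merge_gap)
    regions: list[CandidateRegion] = []
    for iv in merged:
        support = [pet for pet, anchor in anchored if overlaps(anchor, iv)]
        if len(support) < min_support:
            continue
        regions.append(
            CandidateRegion(
                region_id="",
                interval=iv,
                supporting_pets=support,
                datasets={p.dataset_id for p in support if p.dataset_id},
                distance_to_promoter=interval_distance(iv, promoter),
            )
        )
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    for rid, region in zip(_region_ids(len(regions)), regions):
        region.region_id = rid
    return regions


def build_evidence_matrix(
    regions: list[CandidateRegion],
    promoter: GenomicInterval,
    tracks: list[AssayTrack],
) -> EvidenceMatrix:
    """Cross regions (plus the promoter) against every assay/condition track.

    A cell is present iff any peak of any matching track overlaps the
    region by >= 1 bp; absent iff at least one matching track exists but
    none overlaps; no_data iff no matching track. Conflicting datasets
    resolve to present, and every present call is traceable to concrete
    (dataset_id, peak) pairs in the audit log.
    """
    rows = [("promoter", promoter)] + [(r.region_id, r.interval) for r in regions]
    columns = sorted({(t.assay, t.condition) for t in tracks})
    cells: dict[tuple[str, str, str], str] = {}
    audit: dict[tuple[str, str, str], list] = {}
    for row_id, interval in rows:
        for assay, condition in columns:
            matching = [t for t in tracks if t.assay == assay and t.condition == condition]
            hits = [
                (t.dataset_id, p)
                for t in matching
                for p in t.peaks
                if overlaps(p, interval)
            ]
            key = (row_id, assay, condition)
            if not matching:
                cells[key] = NO_DATA
            elif hits:
                cells[key] = PRESENT
                audit[key] = hits
            else:
                cells[key] = ABSENT
    return EvidenceMatrix([r for r, _ in rows], columns, cells, audit)


def classify_condition_response(
    matrix: EvidenceMatrix,
    assay: str,
    control_condition: str,
    treated_condition: str,
) -> dict[str, str]:
    """Label each region's chromatin response of one assay to a treatment.

    treatment-gained: present only under treatment (the androgen-gained
    DNase pattern of a hormone-responsive enhancer); treatment-lost is
    the converse; constitutive: present in both; closed: absent in both;
    no_data whenever either condition lacks a track.
    """
    labels = {}
    for row in matrix.row_ids:
        ctrl = matrix.cell(row, assay, control_condition)
        trt = matrix.cell(row, assay, treated_condition)
        if NO_DATA in (ctrl, trt):
            labels[row] = NO_DATA
        elif trt == PRESENT and ctrl == ABSENT:
            labels[row] = "treatment-gained"
        elif trt == ABSENT and ctrl == PRESENT:
            labels[row] = "treatment-lost"
        elif trt == PRESENT and ctrl == PRESENT:
            labels[row] = "constitutive"
        else:
            labels[row] = "closed"
    return labels
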