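"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; GTF and SAM
(1-based) are converted at this boundary. BED/bedGraph coordinates pass
through unchanged. A simplified 6-column alignment TSV
(chrom, start, end, strand, sample, read_id) is accepted alongside SAM so
synthetic data and tests need no binary formats.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    AlignedRead,
    CpGRecord,
    DatasetMeta,
    GeneModel,
    GenomicInterval,
    PETPair,
    StartExon,
)


class FormatError(ValueError):
    """A malformed line in a standard-format file."""

    def __init__(self, path: str, lineno: int, field: str, message: str):
        self.path, self.lineno, self.field = path, lineno, field
        super().__init__(f"{path}:{lineno}: bad {field}: {message}")


def _int_field(path: str, lineno: int, name: str, raw: str) -> int:
    try:
        return int(raw)
    except ValueError:
        raise FormatError(path, lineno, name, f"not an integer: {raw!r}") from None


# ---------------------------------------------------------------- BED / bedGraph

def read_bed(path: str) -> list[GenomicInterval]:
    """BED3/BED6+; strand taken from column 6 when present."""
    return [iv for _, iv in read_named_bed(path)]


def read_named_bed(path: str) -> list[tuple[str, GenomicInterval]]:
    out: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(path, lineno, "columns", "BED needs >= 3 columns")
            start = _int_field(path, lineno, "start", f[1])
            end = _int_field(path, lineno, "end", f[2])
            strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else "."
            name = f[3] if len(f) >= 4 else ""
            try:
                out.append((name, GenomicInterval(f[0], start, end, strand)))
            except ValueError as e:
                raise FormatError(path, lineno, "interval", str(e)) from None
    return out


def write_bed(
    records: Sequence[GenomicInterval] | Sequence[tuple[str, GenomicInterval]],
    path: str,
    *,
    scores: Sequence[float] | None = None,
) -> None:
    named = [r if isinstance(r, tuple) else ("", r) for r in records]
    with open(path, "w") as fh:
        for i, (name, iv) in enumerate(named):
            score = scores[i] if scores is not None else 0
            if name or iv.strand != "." or scores is not None:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name or '.'}\t{score:g}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bedpe(path: str) -> list[PETPair]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(path, lineno, "columns", "BEDPE needs >= 6 columns")
            a1 = GenomicInterval(
                f[0],
                _int_field(path, lineno, "start1", f[1]),
                _int_field(path, lineno, "end1", f[2]),
            )
            a2 = GenomicInterval(
                f[3],
                _int_field(path, lineno, "start2", f[4]),
                _int_field(path, lineno, "end2", f[5]),
            )
            count = _int_field(path, lineno, "score", f[7]) if len(f) >= 8 and f[7] not in (".", "") else 1
            factor = f[6] if len(f) >= 7 and f[6] != "." else "PolII"
            dataset = f[10] if len(f) >= 11 else ""
            out.append(PETPair(a1, a2, pet_count=count, factor=factor, dataset_id=dataset))
    return out


def write_bedpe(pets: Sequence[PETPair], path: str) -> None:
    with open(path, "w") as fh:
        for p in pets:
            fh.write(
                "\t".join(
                    [
                        p.anchor1.chrom, str(p.anchor1.start), str(p.anchor1.end),
                        p.anchor2.chrom, str(p.anchor2.start), str(p.anchor2.end),
                        p.factor, str(p.pet_count), ".", ".", p.dataset_id,
                    ]
                )
                + "\n"
            )


# -------------------------------------------------------------------------- GTF

def read_gtf(path: str) -> list[tuple[str, GenomicInterval, dict]]:
    """Return (feature, interval, attributes) per line, 0-based half-open."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise FormatError(path, lineno, "columns", "GTF needs 9 columns")
            start1 = _int_field(path, lineno, "start", f[3])
            end1 = _int_field(path, lineno, "end", f[4])
            strand = f[6] if f[6] in ("+", "-") else "."
            attrs: dict[str, str] = {}
            for chunk in f[8].split(";"):
                chunk = chunk.strip()
                if not chunk:
                    continue
                key, _, val = chunk.partition(" ")
                attrs[key] = val.strip().strip('"')
            out.append((f[2], GenomicInterval(f[0], start1 - 1, end1, strand), attrs))
    return out


def write_gene_model_gtf(model: GeneModel, path: str, source: str = "promloop") -> None:
    def line(feature: str, iv: GenomicInterval, attrs: str) -> str:
        return "\t".join(
            [iv.chrom, source, feature, str(iv.start + 1), str(iv.end), ".",
             model.strand, ".", attrs]
        ) + "\n"

    with open(path, "w") as fh:
        gid = f'gene_id "{model.gene_id}"'
        for exon in model.start_exons:
            fh.write(
                line("start_exon", exon.interval, f'{gid}; exon_label "{exon.name}"; tss "{exon.tss}"')
            )
        fh.write(line("promoter", model.promoter, gid))


def read_gene_model_gtf(path: str) -> GeneModel:
    exons: list[StartExon] = []
    promoter = None
    gene_id, strand = "gene", "+"
    for feature, iv, attrs in read_gtf(path):
        gene_id = attrs.get("gene_id", gene_id)
        if feature == "start_exon":
            strand = iv.strand
            tss = int(attrs.get("tss", iv.start if iv.strand == "+" else iv.end - 1))
            exons.append(StartExon(attrs.get("exon_label", f"exon{len(exons)+1}"), iv, tss))
        elif feature == "promoter":
            promoter = GenomicInterval(iv.chrom, iv.start, iv.end)
    if promoter is None:
        raise ValueError(f"{path}: gene model GTF lacks a promoter feature")
    return GeneModel(gene_id, strand, tuple(exons), promoter)


# ----------------------------------------------------------------- alignments

def read_sam(path: str, sample_id: str = "") -> list[AlignedRead]:
    """Parse plain-text SAM; spliced alignments yield one record per block.

    Only chrom, position, CIGAR span and flag-derived strand are used;
    quality, mate and tag fields are ignored.
    """
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            strand = "-" if aln.is_reverse else "+"
            for bstart, bend in aln.get_blocks():
                reads.append(
                    AlignedRead(aln.reference_name, bstart, bend, strand,
                                sample_id=sample_id, read_id=aln.query_name)
                )
    return reads


def write_sam(reads: Sequence[AlignedRead], chrom_lengths: dict[str, int], path: str) -> None:
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": c, "LN": n} for c, n in chrom_lengths.items()]}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id or f"read{i}"
            a.reference_name = r.chrom
            a.reference_start = r.start
            a.flag = 16 if r.strand == "-" else 0
            span = r.end - r.start
            a.cigarstring = f"{span}M"
            a.query_sequence = "N" * span
            a.mapping_quality = 60
            out.write(a)


def read_alignment_tsv(path: str) -> list[AlignedRead]:
    """Simplified 6-column alignment table: chrom start end strand sample read_id."""
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(path, lineno, "columns", "alignment TSV needs 6 columns")
            reads.append(
                AlignedRead(
                    f[0],
                    _int_field(path, lineno, "start", f[1]),
                    _int_field(path, lineno, "end", f[2]),
                    f[3], f[4], f[5],
                )
            )
    return reads


def write_alignment_tsv(reads: Sequence[AlignedRead], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t{r.sample_id}\t{r.read_id}\n")


def read_alignments(path: str, sample_id: str = "") -> list[AlignedRead]:
    """Dispatch on extension: .sam via SAM parsing, anything else as TSV."""
    if path.endswith(".sam"):
        return read_sam(path, sample_id=sample_id)
    return read_alignment_tsv(path)


# ------------------------------------------------------------- FASTA / FASTQ

def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fastq(path: str) -> list[tuple[str, str, list[int]]]:
    """Return (id, bases, phred quality list) per read."""
    out = []
    for rec in SeqIO.parse(path, "fastq"):
        out.append((rec.id, str(rec.seq).upper(), list(rec.letter_annotations["phred_quality"])))
    return out


def write_fastq(reads: Iterable[tuple[str, str, Sequence[int]]], path: str) -> None:
    records = []
    for rid, bases, quals in reads:
        rec = SeqRecord(Seq(bases), id=rid, description="")
        rec.letter_annotations["phred_quality"] = list(quals)
        records.append(rec)
    SeqIO.write(records, path, "fastq")


# ------------------------------------------------------------------ CpG table

def read_cpg_tsv(path: str) -> list[CpGRecord]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "chrom\t")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise FormatError(path, lineno, "columns", "CpG TSV needs 4 columns")
            out.append(
                CpGRecord(
                    f[0],
                    _int_field(path, lineno, "pos", f[1]),
                    _int_field(path, lineno, "methylated", f[2]),
                    _int_field(path, lineno, "unmethylated", f[3]),
                )
            )
    return out


def write_cpg_tsv(records: Sequence[CpGRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tmethylated_count\tunmethylated_count\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.methylated}\t{r.unmethylated}\n")


# ------------------------------------------------------------- sample sheets

def read_sample_sheet(path: str) -> list[tuple[DatasetMeta, str]]:
    """TSV: sample_id, condition, total_mapped_reads, alignment path."""
    out = []
    base = os.path.dirname(os.path.abspath(path))
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "sample_id\t")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise FormatError(path, lineno, "columns", "sample sheet needs 4 columns")
            rel = f[3]
            apath = rel if os.path.isabs(rel) else os.path.join(base, rel)
            out.append(
                (DatasetMeta(f[0], f[1], _int_field(path, lineno, "total_mapped_reads", f[2])), apath)
            )
    return out


def read_track_manifest(path: str) -> list[tuple[str, str, str, str]]:
    """TSV: path, assay, condition, dataset_id; paths resolved next to the manifest."""
    out = []
    base = os.path.dirname(os.path.abspath(path))
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "path\t")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise FormatError(path, lineno, "columns", "track manifest needs 4 columns")
            rel = f[0]
            out.append((rel if os.path.isabs(rel) else os.path.join(base, rel), f[1], f[2], f[3]))
    return out


# ------------------------------------------------------- UCSC custom tracks

def write_custom_track(records, track_name: str, path: str) -> None:
    """Emit a browser-loadable custom track.

    ``records`` is either a sequence of intervals (BED track) or of
    (interval, value) pairs (bedGraph track); mixing the two is an error.
    Output is deterministically sorted by chromosome then start.
    """
    records = list(records)
    is_pair = [isinstance(r, tuple) for r in records]
    if any(is_pair) and not all(is_pair):
        raise ValueError("custom track records must be all intervals or all (interval, value)")
    with open(path, "w") as fh:
        if records and all(is_pair):
            fh.write(f'track type=bedGraph name="{track_name}"\n')
            for iv, val in sorted(records, key=lambda r: (r[0].chrom, r[0].start)):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{val:g}\n")
        else:
            fh.write(f'track name="{track_name}"\n')
            for iv in sorted(records, key=lambda r: (r.chrom, r.start)):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ------------------------------------------------------------------ dispatch

_READERS = {
    "BED": read_bed,
    "BEDPE": read_bedpe,
    "GTF": read_gtf,
    "SAM": read_sam,
    "FASTA": read_fasta,
    "FASTQ": read_fastq,
    "CPG-TSV": read_cpg_tsv,
    "ALIGN-TSV": read_alignment_tsv,
}


def parse_records(path: str, fmt: str):
    """Parse ``path`` as the named standard format into typed records."""
    try:
        reader = _READERS[fmt.upper()]
    except KeyError:
        raise ValueError(
            f"unknown format {fmt!r}; expected one of {sorted(_READERS)}"
        ) from None
    return reader(path)
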