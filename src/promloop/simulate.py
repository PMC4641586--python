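"""Synthetic-data generators with planted ground truth.

Every generator is a pure function of its parameters and a seed: calling it
twice with the same arguments yields identical output. The generated data
mirror the statistical structure the downstream analyses assume — a gene
with several alternative start exons whose usage shifts with hypoxia and
hormone treatment, Poisson ChIP-seq background with enriched windows,
promoter-anchored interaction pairs plus noise, planted IUPAC motifs, and
per-CpG bisulfite counts with imperfect conversion.

Negative-binomial counts use the (mean ``m``, dispersion ``phi``)
parameterisation with variance ``m + phi * m**2``; ``phi = 0`` degenerates
smoothly to Poisson(m).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import (
    AlignedRead,
    CpGRecord,
    DatasetMeta,
    GeneModel,
    GenomicInterval,
    PETPair,
    StartExon,
)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TruthBundle:
    """Planted ground truth for recovery tests of every downstream stage."""

    gene_model: GeneModel | None = None
    variant_abundance: dict = field(default_factory=dict)   # condition -> exon -> mean
    planted_peaks: list = field(default_factory=list)       # (GenomicInterval, enrichment)
    planted_pets: list = field(default_factory=list)        # (PETPair, is_true)
    planted_motifs: list = field(default_factory=list)      # (name, position, strand)
    planted_methylation: dict = field(default_factory=dict) # pos -> "methylated"/"unmethylated"

    def to_json(self, path: str) -> None:
        def iv(x: GenomicInterval):
            return [x.chrom, x.start, x.end, x.strand]

        doc = {
            "variant_abundance": self.variant_abundance,
            "planted_peaks": [[iv(p), e] for p, e in self.planted_peaks],
            "planted_pets": [
                [iv(p.anchor1), iv(p.anchor2), p.pet_count, p.factor, bool(t)]
                for p, t in self.planted_pets
            ],
            "planted_motifs": [[n, int(pos), s] for n, pos, s in self.planted_motifs],
            "planted_methylation": {str(k): v for k, v in self.planted_methylation.items()},
        }
        if self.gene_model is not None:
            m = self.gene_model
            doc["gene_model"] = {
                "gene_id": m.gene_id,
                "strand": m.strand,
                "promoter": iv(m.promoter),
                "start_exons": [[e.name, iv(e.interval), e.tss] for e in m.start_exons],
            }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "TruthBundle":
        with open(path) as fh:
            doc = json.load(fh)
        def iv(x):
            return GenomicInterval(x[0], x[1], x[2], x[3])
        tb = cls()
        tb.variant_abundance = doc.get("variant_abundance", {})
        tb.planted_peaks = [(iv(p), e) for p, e in doc.get("planted_peaks", [])]
        tb.planted_pets = [
            (PETPair(iv(a1), iv(a2), pet_count=c, factor=f), t)
            for a1, a2, c, f, t in doc.get("planted_pets", [])
        ]
        tb.planted_motifs = [(n, pos, s) for n, pos, s in doc.get("planted_motifs", [])]
        tb.planted_methylation = {int(k): v for k, v in doc.get("planted_methylation", {}).items()}
        if "gene_model" in doc:
            g = doc["gene_model"]
            tb.gene_model = GeneModel(
                g["gene_id"], g["strand"],
                tuple(StartExon(n, iv(i), t) for n, i, t in g["start_exons"]),
                iv(g["promoter"]),
            )
        return tb


def nb_counts(rng: np.random.Generator, mean, dispersion: float, size=None):
    """Counts with variance m + phi*m^2 (gamma-Poisson mixture); phi=0 is Poisson."""
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.maximum(mean, 1e-300) * dispersion, size=size)
    lam = np.where(mean > 0, lam, 0.0)
    return rng.poisson(lam)


def designations(n_start_exons: int) -> tuple[str, str]:
    """(cancer-promoter exon label, muscle exon label) for an n-exon toy gene.

    Mirrors the myoglobin naming: the cancer-associated promoter drives the
    "5u" exon and the muscle promoter the "9u" exon whenever those labels
    exist; smaller toy genes fall back to the middle and last exon.
    """
    labels = [f"{i + 1}u" for i in range(n_start_exons)]
    cancer = "5u" if n_start_exons >= 5 else labels[n_start_exons // 2]
    muscle = "9u" if n_start_exons >= 9 else labels[-1]
    return cancer, muscle


def make_toy_gene_model(
    genome_length: int = 1_000_000,
    n_start_exons: int = 7,
    seed: int = 0,
    chrom: str = "chrS",
) -> tuple[GeneModel, str]:
    """Build a single-chromosome toy gene with alternative start exons.

    Exons (80-300 bp) are labelled 1u..Nu in genomic order on the plus
    strand. The promoter spans 179 bp upstream to 25 bp downstream of the
    cancer-promoter exon's first base. The genome is uniform random A/C/G/T.
    """
    if n_start_exons < 3:
        raise ValueError("need at least 3 start exons")
    rng = np.random.default_rng(seed)
    sizes = rng.integers(80, 301, size=n_start_exons)
    gaps = rng.integers(300, 2001, size=n_start_exons - 1)
    span = int(sizes.sum() + gaps.sum())
    if genome_length < 10 * span:
        raise ValueError(
            f"genome_length {genome_length} < 10x gene span {span}; genome too short"
        )
    gene_start = genome_length // 10
    exons = []
    pos = gene_start
    for i in range(n_start_exons):
        iv = GenomicInterval(chrom, pos, pos + int(sizes[i]), "+")
        exons.append(StartExon(f"{i + 1}u", iv, tss=iv.start))
        if i < n_start_exons - 1:
            pos = iv.end + int(gaps[i])
    cancer_label, _ = designations(n_start_exons)
    cancer_tss = next(e.tss for e in exons if e.name == cancer_label)
    promoter = GenomicInterval(chrom, cancer_tss - 179, cancer_tss + 25)
    model = GeneModel("toygene", "+", tuple(exons), promoter)
    sequence = "".join(rng.choice(list("ACGT"), size=genome_length))
    return model, sequence


def simulate_variant_reads(
    model: GeneModel,
    samples: list[tuple[str, str]] | list[DatasetMeta],
    abundance: dict[str, dict[str, float]],
    dispersion: float = 0.05,
    read_length: int = 50,
    background_reads: int = 50_000,
    genome_length: int | None = None,
    seed: int = 0,
) -> tuple[dict[str, list[AlignedRead]], list[DatasetMeta], TruthBundle]:
    """Simulate RNA-seq alignments with per-start-exon replicate counts.

    For each sample the count per start exon is negative-binomial
    (mean from ``abundance[condition][exon]``, shared dispersion); that many
    reads are placed uniformly within the exon on the gene strand.
    ``background_reads`` further reads per sample are scattered genome-wide
    so the total mapped count dwarfs the gene signal, as the
    reads-per-million normalisation assumes. Returned metadata records the
    realised ``total_mapped_reads``.
    """
    pairs = [
        (s.sample_id, s.condition) if isinstance(s, DatasetMeta) else tuple(s)
        for s in samples
    ]
    if genome_length is None:
        genome_length = max(e.interval.end for e in model.start_exons) * 2
    rng = np.random.default_rng(seed)
    alignments: dict[str, list[AlignedRead]] = {}
    metas: list[DatasetMeta] = []
    for sample_id, condition in pairs:
        reads: list[AlignedRead] = []
        cond_means = abundance.get(condition, {})
        n_gene = 0
        for exon in model.start_exons:
            mean = float(cond_means.get(exon.name, 0.0))
            if mean < 0:
                raise ValueError("abundance means must be >= 0")
            exon_len = len(exon.interval)
            count = int(nb_counts(rng, mean, dispersion)) if mean > 0 else 0
            if count > 0 and read_length > exon_len:
                raise ValueError(
                    f"read_length {read_length} exceeds exon {exon.name} length {exon_len}"
                )
            starts = rng.integers(
                exon.interval.start, exon.interval.end - read_length + 1, size=count
            )
            for s in starts:
                reads.append(
                    AlignedRead(exon.interval.chrom, int(s), int(s) + read_length,
                                model.strand, sample_id)
                )
            n_gene += count
        bg_starts = rng.integers(0, max(genome_length - read_length, 1), size=background_reads)
        bg_strands = rng.choice(["+", "-"], size=background_reads)
        for s, st in zip(bg_starts, bg_strands):
            reads.append(AlignedRead(model.chrom, int(s), int(s) + read_length, str(st), sample_id))
        alignments[sample_id] = reads
        metas.append(DatasetMeta(sample_id, condition, max(n_gene + background_reads, 1)))
    truth = TruthBundle(gene_model=model, variant_abundance=abundance)
    return alignments, metas, truth


def simulate_chip_experiment(
    genome_length: int,
    background_rate: float = 2.0,
    peaks: list[tuple[GenomicInterval, float]] | None = None,
    n_reads_input: int | None = None,
    window_size: int = 50,
    read_length: int = 36,
    chrom: str = "chrS",
    seed: int = 0,
) -> tuple[list[AlignedRead], list[AlignedRead], TruthBundle]:
    """Simulate a ChIP experiment with planted enriched windows plus input.

    The input control is homogeneous Poisson per window; the treatment
    multiplies the window rate by the planted enrichment factor wherever a
    window overlaps a planted peak. ``background_rate`` is the expected
    treatment reads per window outside peaks; ``n_reads_input`` is the
    expected input total (defaults to matching the background).
    """
    peaks = peaks or []
    n_windows = -(-genome_length // window_size)
    for iv, enr in peaks:
        if iv.end > genome_length or iv.chrom != chrom:
            raise ValueError(f"planted peak {iv} outside genome of length {genome_length}")
        if enr <= 1:
            raise ValueError("enrichment factor must exceed 1")
    if background_rate <= 0:
        raise ValueError("background_rate must be positive")
    rng = np.random.default_rng(seed)

    rates = np.full(n_windows, background_rate)
    for iv, enr in peaks:
        w0, w1 = iv.start // window_size, -(-iv.end // window_size)
        rates[w0:w1] = background_rate * enr

    def place(counts: np.ndarray, sample_id: str) -> list[AlignedRead]:
        reads = []
        for w, c in enumerate(counts):
            if c == 0:
                continue
            lo = w * window_size
            hi = min(lo + window_size, genome_length)
            starts = rng.integers(lo, hi, size=c)
            for s in sorted(int(x) for x in starts):
                reads.append(AlignedRead(chrom, s, s + read_length, "+", sample_id))
        return reads

    treatment = place(rng.poisson(rates), "treatment")
    input_rate = (n_reads_input / n_windows) if n_reads_input else background_rate
    control = place(rng.poisson(np.full(n_windows, input_rate)), "input")
    truth = TruthBundle(planted_peaks=list(peaks))
    return treatment, control, truth


def simulate_pets(
    promoter: GenomicInterval,
    distal_regions: list[GenomicInterval],
    n_true_per_region: int = 3,
    n_noise: int = 10,
    genome_length: int = 1_000_000,
    factor: str = "PolII",
    seed: int = 0,
) -> tuple[list[PETPair], TruthBundle]:
    """Simulate ChIA-PET pairs: promoter-anchored true loops plus noise.

    True pairs place one anchor overlapping the promoter and the other
    inside a distal region (anchor widths 100-500 bp, jittered); noise
    pairs have both anchors uniform on the genome.
    """
    from .core import overlaps

    for r in distal_regions:
        if overlaps(r, promoter):
            raise ValueError(f"distal region {r} overlaps the promoter")
    rng = np.random.default_rng(seed)
    pets: list[tuple[PETPair, bool]] = []

    def anchor_over(target: GenomicInterval) -> GenomicInterval:
        width = int(rng.integers(100, 501))
        center = int(rng.integers(target.start, target.end))
        start = max(0, center - width // 2)
        return GenomicInterval(target.chrom, start, start + width)

    for region in distal_regions:
        for _ in range(n_true_per_region):
            a1 = anchor_over(promoter)
            a2 = anchor_over(region)
            pets.append((PETPair(a1, a2, pet_count=int(rng.integers(1, 5)), factor=factor), True))
    for _ in range(n_noise):
        def uniform_anchor() -> GenomicInterval:
            width = int(rng.integers(100, 501))
            start = int(rng.integers(0, max(genome_length - width, 1)))
            return GenomicInterval(promoter.chrom, start, start + width)
        pets.append((PETPair(uniform_anchor(), uniform_anchor(), factor=factor), False))
    truth = TruthBundle(planted_pets=list(pets))
    return [p for p, _ in pets], truth


def plant_motifs(
    sequence: str,
    instances: list[tuple[str, int, str]],
    seed: int = 0,
) -> tuple[str, TruthBundle]:
    """Overwrite the sequence with concrete realisations of IUPAC consensi.

    Each instance is (consensus, position, strand); ambiguity codes resolve
    uniformly at random under the seed, and minus-strand instances are
    written as the reverse complement of the realisation. Instances must
    not overlap.
    """
    rng = np.random.default_rng(seed)
    spans = sorted((pos, pos + len(cons)) for cons, pos, _ in instances)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"planted motifs overlap at [{s2},{e1})")
    seq = list(sequence)
    planted = []
    for cons, pos, strand in instances:
        if pos < 0 or pos + len(cons) > len(sequence):
            raise ValueError(f"motif at {pos} outside sequence of length {len(sequence)}")
        realised = "".join(rng.choice(list(IUPAC[c.upper()])) for c in cons)
        written = realised if strand == "+" else reverse_complement(realised)
        seq[pos:pos + len(cons)] = written
        planted.append((cons, pos, strand))
    truth = TruthBundle(planted_motifs=planted)
    return "".join(seq), truth


def simulate_methylation(
    cpg_positions: list[int],
    states: dict[int, str],
    coverage: float = 20.0,
    conversion_rate: float = 0.99,
    dropout: float = 0.1,
    chrom: str = "chrS",
    seed: int = 0,
) -> tuple[list[CpGRecord], TruthBundle]:
    """Simulate per-CpG bisulfite counts with imperfect conversion.

    Coverage per site is Poisson(``coverage``); each read reports the true
    state with probability ``conversion_rate``. A ``dropout`` fraction of
    sites is omitted entirely, emulating uneven sequencing depth.
    """
    if not 0 < conversion_rate <= 1:
        raise ValueError("conversion_rate must be in (0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for pos in cpg_positions:
        if rng.random() < dropout:
            continue
        state = states[pos]
        cov = int(rng.poisson(coverage))
        correct = int(rng.binomial(cov, conversion_rate)) if cov else 0
        wrong = cov - correct
        if state == "methylated":
            records.append(CpGRecord(chrom, pos, correct, wrong))
        else:
            records.append(CpGRecord(chrom, pos, wrong, correct))
    truth = TruthBundle(planted_methylation=dict(states))
    return records, truth
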