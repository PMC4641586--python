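# Methods

This note documents the models, conventions and numerical choices behind
each pipeline stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Coordinate and format conventions

All internal coordinates are 0-based half-open (`[start, end)`); GTF and SAM
(1-based) are converted only at the format boundary. A simplified 6-column
alignment TSV (chrom, start, end, strand, sample, read_id) is accepted
alongside plain-text SAM so that synthetic data needs no binary formats.
Spliced SAM alignments (N in CIGAR) contribute each aligned block as an
independent span, since counting concerns genomic footprint. Chromosome
names are compared by exact string equality; mixed naming schemes must be
harmonised upstream.

## Read preprocessing

Three named profiles fix the published parameter sets: `rnaseq` (trim 12 bp
at 5′ and 5 bp at 3′, quality limit 0.05, minimum length 15, ≤ 2 ambiguous
bases), `groseq` (trim 12 bp at 5′, limit 0.01, minimum 10) and
`chip_bisulfite` (reject mean Phred < 30, mask 15 bp at 5′ and 5 bp at 3′
with N). Two interpretation choices were genuinely open and are fixed here:

* the "quality limit" is implemented as modified-Mott trimming — keep the
  contiguous segment maximising Σ(limit − p) over per-base error
  probabilities p — because the tool that defined the parameter does not
  publish its algorithm;
* the Phred-30 rejection uses the read's **mean** quality (minimum- or
  windowed-score readings are equally defensible; mean is the least
  aggressive).

Adapter handling is exact prefix/suffix matching only; synthetic reads carry
no adapters.

## Start-exon quantification

Reads are assigned to alternative start exons by ≥ 1 bp overlap and
multi-counted when exons overlap (a `best-overlap` unique-assignment mode
exists for sensitivity analysis). RPKM is
`count / (length/1000) / (total_mapped/1e6)`; the denominator is the
genome-wide mapped-read count, so the one simulated gene must be a
negligible fraction of each library (the generator guarantees this by
scattering background reads genome-wide). RNA-seq counting is unstranded by
default; GRO-seq counting keeps only reads on the annotated gene strand,
because run-on signal is strand-specific, and a read is in a TSS window when
its 5′-most aligned base lies in the strand-oriented −100/+500 bp interval.
The window length is fixed at 600 bp in the RPKM denominator even when
clipped at a chromosome end (a warning is emitted).

Condition contrasts report treated/control ratios of mean RPKM; decreases
are therefore fractions of control (0.64 ≡ "64% of control"). A zero control
mean yields an explicit undefined fold, never an exception. One-way ANOVA
(fixed effects) spans all conditions present; Tukey–Kramer pairwise tests
use the studentized-range distribution with Kramer's unequal-n standard
error `sqrt(MSW/2 · (1/n_i + 1/n_j))`. Note that ANOVA on raw RPKM is
heteroscedastic under the count model (variance grows with the mean), which
makes post-hoc comparisons conservative for strongly induced exons — this
mirrors the analysis style being reproduced rather than a recommended
modern practice.

## Peak calling

Non-overlapping 50 bp windows tile the chromosome from 0 (the window size is
the published parameter; the tiling step is a choice). Each read belongs to
exactly one window via its 5′ base. The "automatically calculated" minimum
read count is formalised as the smallest k with
`P(X ≥ k | Poisson(λ)) ≤ α/n_windows` (Bonferroni at α = 0.05), i.e. a
reproducible stand-in for an unpublished heuristic. With an input control
the per-window λ is the maximum of the genome-wide input mean, a 5 kb local
mean and a 250 bp local mean, scaled by the treatment/input library ratio —
the multi-scale maximum prevents focal input enrichment from being smoothed
away. Adjacent significant windows merge; the merged peak carries the summed
count and the minimum member p-value.

Differential enrichment normalises counts by total-count scaling to the
geometric-mean library size, estimates one common NB dispersion across
regions by method of moments (variance = m + φm²; the estimate is floored at
0, where the test reduces to an exact conditional binomial), and tests the
per-side totals by summing the probabilities of all splits of the grand
total no more likely than the observed one. The log2 fold change is exact
for positive means; a 0.5 pseudocount enters only when one side is zero.
Classification: enriched iff log2FC ≥ 1 and p < 0.05, depleted mirrored,
otherwise unchanged.

## Loop integration

A pair is promoter-anchored when exactly one anchor overlaps the promoter
(pairs with both anchors on the promoter are excluded and counted). Distal
anchors merge within 1 kb (default) into candidate regions, dropped below
`min_support` supporting pairs, and named A, B, C… by genomic position —
the merge rule is a declared convention replacing manual boundary drawing
across browser tracks. Cross-dataset confirmation is reported as a
per-region dataset count, not used as a filter. Evidence-matrix cells are a
pure function of (regions, tracks): present iff any matching track has an
overlapping peak (with an audit trail naming the dataset and peak), absent
iff a matching track exists without overlap, no-data otherwise; conflicting
datasets resolve to present and are logged. Condition-response labels
(treatment-gained/lost, constitutive, closed) require data on both sides;
anything else is no-data, never guessed.

## Sequence features

Motif matching is exact IUPAC containment (an N in the sequence satisfies no
code), scanning both strands; minus-strand hits are reported at plus-strand
coordinates. The default consensus set — HRE RCGTG, ERE half site RGGTCA,
ARE GGWACANNNTGTTCT and AGAACA half site, RUNX1 TGTGGT, SP1 GGGCGG — uses
literature-standard cores as declared substitutes for an unnamed prediction
tool, and is overridable via a motif TSV. Note the HRE core is short enough
to occur by chance roughly every 500 bp of random sequence; hits are
evidence only in conjunction with the chromatin/binding matrix. In the
orchestrated pipeline, scanning covers each recovered region padded by
500 bp (the maximum interaction-anchor width) so elements at region edges
are not missed.

Methylation calls per CpG: no-call below 4× coverage, unmethylated at
fraction ≤ 0.2, methylated at ≥ 0.8, intermediate between — binary
published statuses come without thresholds, so these are explicit
conventions.

## Synthetic data

Every generator is a pure function of (parameters, seed). Negative-binomial
counts use mean m and dispersion φ with variance m + φm² (gamma–Poisson
mixture; φ = 0 degenerates smoothly to Poisson). The default scenario
encodes the emulated study conditions: ten start exons with exon 5u dominant
(mean 500 counts/replicate) and exon 9u planted so the control 5u:9u RPKM
ratio is 214; hypoxia multiplies 5u by 4.3 and 4u by 1.2; estrogen scales
5u/4u to 0.40/0.55 of control and androgen to 0.64/0.82; three replicates
per condition at dispersion 0.05 (no replicate dispersion is published for
the emulated data; 0.05 is a typical cell-line RNA-seq value). ChIP
treatment is Poisson with 8× rate inside planted peaks over background 2
reads/window; the input is homogeneous Poisson. True interaction pairs have
one anchor jittered over the promoter and one inside a distal region
(widths 100–500 bp); noise pairs are uniform. Methylation coverage is
Poisson(20) with 0.99 bisulfite conversion and 10% site dropout.

Not emulated: sequencing errors, adapters in synthetic reads, duplicate and
fragment-length structure, spliced reads across start exons, mappability
biases, copy-number or GC effects. Passing recovery tests therefore shows
the analysis logic is correct under the stated count models, not that the
pipeline is robust to every artefact of real libraries.

## Problem sizes and determinism

The default end-to-end scenario (1 Mb genome, 12 RNA-seq + 6 GRO-seq
samples, 10 ChIP tracks, ~6×10⁵ reads total) runs in ~15 s on one CPU and
is byte-identical across reruns at a fixed seed; all stage seeds derive from
the single config seed via crc32-keyed seed sequences. Monte-Carlo checks
use 50–200 dataset replicates, sized so each completes in seconds to a
couple of minutes. The acceptance script averages fold-change recovery over
60 independent datasets (ratio of grand means — the minimum-variance
unbiased aggregation, with relative sd ≈ 2.5% for the 5u contrasts).

## Known limitations

* The fold-change sampling noise floor at n = 3 replicates and φ = 0.05 is
  sd(log fold) ≈ √(2φ/3) ≈ 0.19 irrespective of sequencing depth; single-
  dataset fold estimates routinely deviate ±20% from the planted effect.
* The NB exact test conditions on normalised totals and treats the common
  dispersion as known; with few regions the method-of-moments estimate is
  noisy (its null type-I error is verified ≤ 7% at the defaults).
* Tukey–Kramer on raw RPKM inherits the heteroscedasticity noted above.
* BAM/CRAM, tabix and liftover are out of scope; alignments arrive as
  plain-text SAM or TSV.
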