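"""End-to-end orchestration: scenario simulation, staged analysis, report.

``default_config`` encodes the study conditions the synthetic scenario
emulates: a ten-start-exon gene whose cancer-promoter exon (5u) responds
to hypoxia (mean induction 4.3x) and is repressed by estrogen (to 40% of
control) and androgen (to 64%), a near-silent muscle exon (9u, 214-fold
below 5u), negative-binomial replicate counts (n = 3, dispersion 0.05),
Poisson ChIP background with enriched windows at the hormone/hypoxia-
responsive candidate regions, promoter-anchored interaction pairs plus
noise, planted response-element motifs, and bisulfite CpG counts.

``simulate_scenario`` writes every pipeline input to disk in standard
formats; ``run_pipeline`` reads them back through the format layer and
executes the analysis stages; ``summarize_report`` renders the result
surfaces (fold-change table, evidence crossmark table, condition-response
labels, per-region motif/CpG annotation).
"""

from __future__ import annotations

import copy
import json
import os
import time
from dataclasses import asdict

import numpy as np
import yaml

from . import io as pio
from .core import AssayTrack, DatasetMeta, GenomicInterval
from .loops import (
    build_evidence_matrix,
    classify_condition_response,
    define_candidate_regions,
    promoter_anchored_pets,
)
from .peaks import call_peaks, window_counts
from .preprocess import PROFILES, reads_from_fastq_tuples, reads_to_fastq_tuples, trim_and_filter
from .quantify import condition_fold_changes, groseq_tss_rpkm, quantify_sample
from .sequence import (
    DEFAULT_MOTIFS,
    annotate_regions,
    filter_chromosome,
    methylation_fraction_and_call,
    scan_motifs,
)
from .simulate import (
    TruthBundle,
    designations,
    make_toy_gene_model,
    plant_motifs,
    simulate_chip_experiment,
    simulate_methylation,
    simulate_pets,
    simulate_variant_reads,
)


class ConfigError(ValueError):
    pass


def default_config(seed: int = 1, outdir: str = "promloop_out") -> dict:
    """Scenario parameters mirroring the emulated study conditions."""
    # exon lengths depend only on the seed, so the planted 5u:9u RPKM ratio
    # (214-fold, the muscle exon near-silent) is exact at any genome size
    model, _ = make_toy_gene_model(300_000, 10, seed=seed)
    len5u = len(model.exon("5u").interval)
    len9u = len(model.exon("9u").interval)
    control = {
        "1u": 20, "2u": 20, "3u": 5, "4u": 200, "5u": 500,
        "6u": 5, "7u": 5, "8u": 10, "9u": 500.0 * (len9u / len5u) / 214.0,
        "10u": 10,
    }
    hypoxia = dict(control, **{"5u": 500 * 4.3, "4u": 200 * 1.2})
    e2 = dict(control, **{"5u": 500 * 0.40, "4u": 200 * 0.55})
    r1881 = dict(control, **{"5u": 500 * 0.64, "4u": 200 * 0.82})
    return {
        "seed": seed,
        "outdir": outdir,
        "genome": {"length": 1_000_000, "chrom": "chrS", "n_start_exons": 10},
        "rnaseq": {
            "abundance": {
                "control": control, "hypoxia": hypoxia, "E2": e2, "R1881": r1881,
            },
            "replicates": 3,
            "dispersion": 0.05,
            "read_length": 50,
            "background_reads": 50_000,
            "contrasts": [["hypoxia", "control"], ["E2", "control"], ["R1881", "control"]],
        },
        "groseq": {"conditions": ["control", "E2"], "replicates": 3},
        "chip": {
            "window_size": 50,
            "alpha": 0.05,
            "background_rate": 2.0,
            "enrichment": 8.0,
            # assay/condition -> candidate-region indices carrying a planted peak
            # (regions indexed in genomic order; "P" marks the promoter itself)
            "experiments": {
                "DNase/control": ["P", 0, 1, 2, 5, 6],
                "DNase/DHT": ["P", 0, 1, 2, 3, 5, 6],
                "FAIRE/normoxia": ["P", 0, 1, 2, 5, 6],
                "FAIRE/hypoxia": ["P", 0, 1, 2, 5, 6],
                "HIF1a/normoxia": [],
                "HIF1a/hypoxia": [2],
                "ERa/control": [],
                "ERa/E2": [2],
                "AR/control": [],
                "AR/DHT": [3],
            },
            "responses": [
                ["DNase", "control", "DHT"],
                ["HIF1a", "normoxia", "hypoxia"],
                ["ERa", "control", "E2"],
                ["AR", "control", "DHT"],
            ],
        },
        "pets": {
            # distal region offsets relative to the promoter start (bp)
            "offsets": [-40_000, -20_000, 30_000, 80_000, 150_000, 200_000, 250_000],
            "region_width": 1_000,
            "n_true_per_region": 3,
            "n_noise": 10,
            "merge_gap": 1_000,
            "min_support": 1,
        },
        "motifs": {
            # motif consensus plantings per candidate-region index
            "plant": [
                ["RCGTG", 2, "HRE"], ["RGGTCA", 2, "ERE_half"], ["RGGTCA", 2, "ERE_half"],
                ["RGGTCA", 2, "ERE_half"], ["RGGTCA", 2, "ERE_half"],
                ["TGTGGT", 2, "RUNX1"], ["TGTGGT", 2, "RUNX1"],
                ["GGWACANNNTGTTCT", 3, "ARE"], ["AGAACA", 3, "ARE_half"],
                ["AGAACA", 3, "ARE_half"], ["GGGCGG", "P", "SP1"],
            ],
        },
        "methylation": {
            "coverage": 20.0,
            "conversion_rate": 0.99,
            "dropout": 0.1,
            "n_cpgs_per_region": 6,
            # regions whose CpGs are planted unmethylated (others methylated)
            "unmethylated_regions": ["P", 2],
            "min_coverage": 4,
        },
        "preprocess": {"profile": "rnaseq", "n_reads": 2000, "read_length": 60},
    }


def validate_config(config: dict) -> None:
    if "seed" not in config:
        raise ConfigError("config must set an explicit seed")
    for key in ("outdir", "genome"):
        if key not in config:
            raise ConfigError(f"config missing required key {key!r}")


def load_config(path: str) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    validate_config(config)
    return config


def _child_seed(seed: int, label: str) -> int:
    # stable per-stage substream, kept below 2**31 (crc32 is process-stable)
    import zlib

    h = np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    return int(h.generate_state(1)[0] % (2**31))


def _planted_regions(config: dict) -> tuple[GenomicInterval, list[GenomicInterval]]:
    """Promoter and planted distal regions implied by the config geometry."""
    g = config["genome"]
    model, _ = make_toy_gene_model(
        g["length"], g["n_start_exons"], seed=config["seed"], chrom=g["chrom"]
    )
    width = config["pets"]["region_width"]
    regions = []
    for off in config["pets"]["offsets"]:
        start = model.promoter.start + off
        regions.append(GenomicInterval(g["chrom"], start, start + width))
    return model.promoter, sorted(regions, key=lambda r: r.start)


def simulate_scenario(config: dict, outdir: str | None = None) -> dict:
    """Generate every pipeline input on disk; returns a path manifest."""
    validate_config(config)
    outdir = outdir or config["outdir"]
    os.makedirs(outdir, exist_ok=True)
    seed = config["seed"]
    g = config["genome"]
    chrom, genome_length = g["chrom"], g["length"]

    model, genome_seq = make_toy_gene_model(
        genome_length, g["n_start_exons"], seed=seed, chrom=chrom
    )
    promoter, distal = _planted_regions(config)

    truth = TruthBundle(gene_model=model)
    paths: dict[str, object] = {"outdir": outdir}

    # --- gene model -------------------------------------------------------
    gm_path = os.path.join(outdir, "gene_model.gtf")
    pio.write_gene_model_gtf(model, gm_path)
    paths["gene_model"] = gm_path

    # --- RNA-seq replicates ----------------------------------------------
    rcfg = config["rnaseq"]
    samples = [
        (f"{cond}_rep{i + 1}", cond)
        for cond in rcfg["abundance"]
        for i in range(rcfg["replicates"])
    ]
    alignments, metas, rna_truth = simulate_variant_reads(
        model, samples, rcfg["abundance"], rcfg["dispersion"], rcfg["read_length"],
        rcfg["background_reads"], genome_length, seed=_child_seed(seed, "rnaseq"),
    )
    truth.variant_abundance = rna_truth.variant_abundance
    sheet_rows = []
    for meta in metas:
        apath = os.path.join(outdir, f"rnaseq_{meta.sample_id}.tsv")
        pio.write_alignment_tsv(alignments[meta.sample_id], apath)
        sheet_rows.append(
            f"{meta.sample_id}\t{meta.condition}\t{meta.total_mapped_reads}\t"
            f"{os.path.basename(apath)}\n"
        )
    sheet_path = os.path.join(outdir, "samples_rnaseq.tsv")
    with open(sheet_path, "w") as fh:
        fh.write("sample_id\tcondition\ttotal_mapped_reads\tpath\n")
        fh.writelines(sheet_rows)
    paths["sample_sheet"] = sheet_path

    # --- GRO-seq replicates (nascent signal at the same exons) -----------
    gcfg = config["groseq"]
    gsamples = [
        (f"gro_{cond}_rep{i + 1}", cond)
        for cond in gcfg["conditions"]
        for i in range(gcfg["replicates"])
    ]
    gro_abundance = {c: rcfg["abundance"][c] for c in gcfg["conditions"]}
    galn, gmetas, _ = simulate_variant_reads(
        model, gsamples, gro_abundance, rcfg["dispersion"], rcfg["read_length"],
        rcfg["background_reads"], genome_length, seed=_child_seed(seed, "groseq"),
    )
    gsheet_rows = []
    for meta in gmetas:
        apath = os.path.join(outdir, f"groseq_{meta.sample_id}.tsv")
        pio.write_alignment_tsv(galn[meta.sample_id], apath)
        gsheet_rows.append(
            f"{meta.sample_id}\t{meta.condition}\t{meta.total_mapped_reads}\t"
            f"{os.path.basename(apath)}\n"
        )
    gsheet_path = os.path.join(outdir, "samples_groseq.tsv")
    with open(gsheet_path, "w") as fh:
        fh.write("sample_id\tcondition\ttotal_mapped_reads\tpath\n")
        fh.writelines(gsheet_rows)
    paths["groseq_sample_sheet"] = gsheet_path

    # --- ChIP experiments -------------------------------------------------
    ccfg = config["chip"]
    chip_manifest = []
    for label, targets in ccfg["experiments"].items():
        assay, condition = label.split("/")
        planted = []
        for t in targets:
            iv = promoter if t == "P" else distal[int(t)]
            planted.append((iv, ccfg["enrichment"]))
        treat, ctrl_reads, chip_truth = simulate_chip_experiment(
            genome_length, ccfg["background_rate"], planted,
            window_size=ccfg["window_size"], chrom=chrom,
            seed=_child_seed(seed, f"chip:{label}"),
        )
        tag = label.replace("/", "_")
        tpath = os.path.join(outdir, f"chip_{tag}_treat.tsv")
        ipath = os.path.join(outdir, f"chip_{tag}_input.tsv")
        pio.write_alignment_tsv(treat, tpath)
        pio.write_alignment_tsv(ctrl_reads, ipath)
        chip_manifest.append((tag, assay, condition, tpath, ipath))
        truth.planted_peaks.extend(chip_truth.planted_peaks)
    chip_sheet = os.path.join(outdir, "chip_experiments.tsv")
    with open(chip_sheet, "w") as fh:
        fh.write("dataset_id\tassay\tcondition\ttreatment\tinput\n")
        for tag, assay, condition, tpath, ipath in chip_manifest:
            fh.write(
                f"{tag}\t{assay}\t{condition}\t{os.path.basename(tpath)}\t"
                f"{os.path.basename(ipath)}\n"
            )
    paths["chip_sheet"] = chip_sheet

    # --- ChIA-PET pairs ---------------------------------------------------
    pcfg = config["pets"]
    pets, pet_truth = simulate_pets(
        promoter, distal, pcfg["n_true_per_region"], pcfg["n_noise"],
        genome_length, seed=_child_seed(seed, "pets"),
    )
    truth.planted_pets = pet_truth.planted_pets
    pets_path = os.path.join(outdir, "pets.bedpe")
    pio.write_bedpe(pets, pets_path)
    paths["pets"] = pets_path

    # --- motifs planted into the genome ----------------------------------
    mcfg = config["motifs"]
    rng = np.random.default_rng(_child_seed(seed, "motif-positions"))
    instances = []
    used: list[tuple[int, int]] = []
    planted_names = []
    for consensus, where, name in mcfg["plant"]:
        target = promoter if where == "P" else distal[int(where)]
        for _ in range(100):
            pos = int(rng.integers(target.start, target.end - len(consensus)))
            if all(pos + len(consensus) <= s or pos >= e for s, e in used):
                break
        else:
            raise RuntimeError("could not place a non-overlapping motif instance")
        used.append((pos, pos + len(consensus)))
        strand = "+" if rng.random() < 0.5 else "-"
        instances.append((consensus, pos, strand))
        planted_names.append(name)
    genome_seq, _motif_truth = plant_motifs(
        genome_seq, instances, seed=_child_seed(seed, "motif-bases")
    )
    truth.planted_motifs = [
        (name, pos, strand)
        for name, (_, pos, strand) in zip(planted_names, instances)
    ]
    fasta_path = os.path.join(outdir, "genome.fa")
    pio.write_fasta({chrom: genome_seq}, fasta_path)
    paths["genome_fasta"] = fasta_path

    # --- methylation ------------------------------------------------------
    mecfg = config["methylation"]
    rng = np.random.default_rng(_child_seed(seed, "cpg-positions"))
    states: dict[int, str] = {}
    for idx, region in enumerate([promoter] + distal):
        where = "P" if idx == 0 else idx - 1
        state = (
            "unmethylated"
            if where in mecfg["unmethylated_regions"]
            else "methylated"
        )
        pos_pool = rng.choice(
            np.arange(region.start, region.end), size=mecfg["n_cpgs_per_region"],
            replace=False,
        )
        for p in sorted(int(x) for x in pos_pool):
            states[p] = state
    records, meth_truth = simulate_methylation(
        sorted(states), states, mecfg["coverage"], mecfg["conversion_rate"],
        mecfg["dropout"], chrom=chrom, seed=_child_seed(seed, "cpg-reads"),
    )
    truth.planted_methylation = meth_truth.planted_methylation
    cpg_path = os.path.join(outdir, "cpgs.tsv")
    pio.write_cpg_tsv(records, cpg_path)
    paths["cpg_table"] = cpg_path

    # --- raw reads for the preprocessing stage ----------------------------
    prcfg = config["preprocess"]
    rng = np.random.default_rng(_child_seed(seed, "fastq"))
    raw = []
    L = prcfg["read_length"]
    for i in range(prcfg["n_reads"]):
        start = int(rng.integers(0, genome_length - L))
        bases = genome_seq[start:start + L]
        quals = np.clip(rng.normal(35, 4, size=L).round(), 2, 40).astype(int)
        raw.append((f"synthread{i}", bases, [int(q) for q in quals]))
    fastq_path = os.path.join(outdir, "raw_reads.fastq")
    pio.write_fastq(raw, fastq_path)
    paths["raw_fastq"] = fastq_path

    truth_path = os.path.join(outdir, "truth.json")
    truth.to_json(truth_path)
    paths["truth"] = truth_path

    manifest_path = os.path.join(outdir, "inputs.json")
    with open(manifest_path, "w") as fh:
        json.dump({k: v for k, v in paths.items()}, fh, indent=1, sort_keys=True)
    return paths


def run_pipeline(config: dict, inputs: dict | None = None) -> dict:
    """Execute all analysis stages against on-disk inputs.

    ``inputs`` is the path manifest from :func:`simulate_scenario` (or an
    equivalent dict for real data). Returns the report bundle; every table
    is also persisted under ``<outdir>/results``.
    """
    validate_config(config)
    outdir = config["outdir"]
    if inputs is None:
        with open(os.path.join(outdir, "inputs.json")) as fh:
            inputs = json.load(fh)
    resdir = os.path.join(outdir, "results")
    os.makedirs(resdir, exist_ok=True)
    log: list[str] = []
    t_start = time.time()

    def stage(name):
        log.append(f"{name}\t{time.time() - t_start:.2f}s")

    bundle: dict = {"config": copy.deepcopy(config)}

    model = pio.read_gene_model_gtf(inputs["gene_model"])
    bundle["gene_model"] = model

    # preprocess -----------------------------------------------------------
    if "raw_fastq" in inputs:
        raw = reads_from_fastq_tuples(pio.read_fastq(inputs["raw_fastq"]))
        profile = PROFILES[config["preprocess"]["profile"]]
        kept = trim_and_filter(raw, profile)
        pio.write_fastq(
            reads_to_fastq_tuples(kept), os.path.join(resdir, "preprocessed.fastq")
        )
        bundle["preprocess"] = {"input": len(raw), "kept": len(kept)}
        stage("preprocess")

    # RNA-seq quantification ----------------------------------------------
    records = []
    for meta, path in pio.read_sample_sheet(inputs["sample_sheet"]):
        aln = pio.read_alignments(path, sample_id=meta.sample_id)
        records.extend(quantify_sample(aln, model, meta))
    bundle["expression"] = records
    with open(os.path.join(resdir, "expression.tsv"), "w") as fh:
        fh.write("sample_id\tcondition\tunit_name\traw_count\tfeature_length\trpkm\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.condition}\t{r.unit_name}\t{r.raw_count}\t"
                f"{r.feature_length}\t{r.rpkm:.6g}\n"
            )
    stage("quantify")

    # fold changes ---------------------------------------------------------
    fold_rows = []
    bundle["fold_changes"] = {}
    for treated, control in config["rnaseq"]["contrasts"]:
        results = condition_fold_changes(records, treated, control)
        bundle["fold_changes"][(treated, control)] = results
        for r in results:
            fold = "NA" if r.fold_change is None else f"{r.fold_change:.4g}"
            anova_p = "NA" if r.anova_p is None else f"{r.anova_p:.4g}"
            sig = r.pairwise_flags.get((control, treated), r.pairwise_flags.get((treated, control), ""))
            fold_rows.append(
                f"{r.unit_name}\t{treated}\t{control}\t{r.mean_rpkm_a:.6g}\t"
                f"{r.mean_rpkm_b:.6g}\t{fold}\t{anova_p}\t{sig}\n"
            )
    with open(os.path.join(resdir, "fold_changes.tsv"), "w") as fh:
        fh.write(
            "unit\ttreated\tcontrol\tmean_rpkm_treated\tmean_rpkm_control\t"
            "fold_change\tanova_p\ttukey_treated_vs_control\n"
        )
        fh.writelines(fold_rows)
    stage("foldchange")

    # GRO-seq --------------------------------------------------------------
    if "groseq_sample_sheet" in inputs:
        grecords = []
        for meta, path in pio.read_sample_sheet(inputs["groseq_sample_sheet"]):
            aln = pio.read_alignments(path, sample_id=meta.sample_id)
            grecords.extend(
                groseq_tss_rpkm(aln, model, meta, chrom_length=config["genome"]["length"])
            )
        bundle["groseq"] = grecords
        with open(os.path.join(resdir, "groseq.tsv"), "w") as fh:
            fh.write("sample_id\tcondition\tunit_name\traw_count\tfeature_length\trpkm\n")
            for r in grecords:
                fh.write(
                    f"{r.sample_id}\t{r.condition}\t{r.unit_name}\t{r.raw_count}\t"
                    f"{r.feature_length}\t{r.rpkm:.6g}\n"
                )
        stage("groseq")

    # ChIP peak calling ----------------------------------------------------
    tracks: list[AssayTrack] = []
    if "chip_sheet" in inputs:
        base = os.path.dirname(os.path.abspath(inputs["chip_sheet"]))
        ccfg = config["chip"]
        with open(inputs["chip_sheet"]) as fh:
            rows = [
                line.rstrip("\n").split("\t")
                for line in fh
                if line.strip() and not line.startswith("dataset_id")
            ]
        for tag, assay, condition, tpath, ipath in rows:
            treat = pio.read_alignment_tsv(os.path.join(base, tpath))
            ctrl = pio.read_alignment_tsv(os.path.join(base, ipath))
            wc_t = window_counts(treat, config["genome"]["length"],
                                 ccfg["window_size"], chrom=config["genome"]["chrom"])
            wc_i = window_counts(ctrl, config["genome"]["length"],
                                 ccfg["window_size"], chrom=config["genome"]["chrom"])
            called = call_peaks(wc_t, wc_i, alpha=ccfg["alpha"])
            peak_bed = os.path.join(resdir, f"peaks_{tag}.bed")
            pio.write_bed(
                [(f"peak{i+1}", p.interval) for i, p in enumerate(called)],
                peak_bed,
                scores=[min(-np.log10(max(p.p_value, 1e-300)), 1000) for p in called],
            )
            pio.write_custom_track(
                [p.interval for p in called], f"{assay} {condition} peaks",
                os.path.join(resdir, f"peaks_{tag}.track.bed"),
            )
            tracks.append(
                AssayTrack(assay, condition, tuple(p.interval for p in called), tag)
            )
        bundle["tracks"] = tracks
        stage("callpeaks")

    # ChIA-PET integration -------------------------------------------------
    pets = pio.read_bedpe(inputs["pets"])
    anchored, pet_counts = promoter_anchored_pets(pets, model.promoter)
    regions = define_candidate_regions(
        anchored, model.promoter,
        merge_gap=config["pets"]["merge_gap"],
        min_support=config["pets"]["min_support"],
    )
    bundle["regions"] = regions
    bundle["pet_counts"] = pet_counts
    pio.write_bed(
        [(r.region_id, r.interval) for r in regions],
        os.path.join(resdir, "candidate_regions.bed"),
    )
    stage("chiapet")

    # evidence matrix ------------------------------------------------------
    matrix = build_evidence_matrix(regions, model.promoter, tracks)
    bundle["evidence"] = matrix
    with open(os.path.join(resdir, "evidence_matrix.tsv"), "w") as fh:
        cols = matrix.columns
        fh.write("region\t" + "\t".join(f"{a}:{c}" for a, c in cols) + "\n")
        for row in matrix.row_ids:
            marks = []
            for a, c in cols:
                cell = matrix.cell(row, a, c)
                marks.append({"present": "X", "absent": "-", "no_data": "?"}[cell])
            fh.write(row + "\t" + "\t".join(marks) + "\n")
    responses = {}
    for assay, control, treated in config["chip"]["responses"]:
        responses[(assay, control, treated)] = classify_condition_response(
            matrix, assay, control, treated
        )
    bundle["responses"] = responses
    with open(os.path.join(resdir, "condition_responses.tsv"), "w") as fh:
        fh.write("assay\tcontrol\ttreated\tregion\tlabel\n")
        for (assay, control, treated), labels in responses.items():
            for row, label in labels.items():
                fh.write(f"{assay}\t{control}\t{treated}\t{row}\t{label}\n")
    stage("evidence")

    # motifs and methylation -----------------------------------------------
    genome = pio.read_fasta(inputs["genome_fasta"])
    chrom = config["genome"]["chrom"]
    seq = genome[chrom]
    named_regions = [("promoter", model.promoter)] + [
        (r.region_id, r.interval) for r in regions
    ]
    # pad by the maximum interaction-anchor width so elements at the edge
    # of a recovered region are still scanned
    flank = 500
    hits = []
    for _, iv in named_regions:
        lo = max(iv.start - flank, 0)
        hi = min(iv.end + flank, len(seq))
        hits.extend(scan_motifs(seq[lo:hi], DEFAULT_MOTIFS, offset=lo, chrom=chrom))
    # deduplicate hits found through overlapping regions
    hits = sorted(set(hits), key=lambda h: (h.position, h.motif, h.strand))
    bundle["motif_hits"] = hits
    with open(os.path.join(resdir, "motif_hits.bed"), "w") as fh:
        for h in hits:
            fh.write(
                f"{h.chrom}\t{h.position}\t{h.position + len(h.matched_sequence)}\t"
                f"{h.motif}\t0\t{h.strand}\n"
            )
    cpgs = filter_chromosome(pio.read_cpg_tsv(inputs["cpg_table"]), chrom)
    calls = methylation_fraction_and_call(
        cpgs, min_coverage=config["methylation"]["min_coverage"]
    )
    bundle["methylation"] = calls
    with open(os.path.join(resdir, "methylation.tsv"), "w") as fh:
        fh.write("chrom\tpos\tmethylated\tunmethylated\tfraction\tcall\n")
        for c in calls:
            frac = "NA" if c.fraction is None else f"{c.fraction:.4g}"
            fh.write(
                f"{c.record.chrom}\t{c.record.pos}\t{c.record.methylated}\t"
                f"{c.record.unmethylated}\t{frac}\t{c.call}\n"
            )
    report, orphans = annotate_regions(named_regions, hits, calls)
    bundle["annotation"] = report
    with open(os.path.join(resdir, "region_annotation.tsv"), "w") as fh:
        fh.write("region\tfeature_type\tposition\tdetail\n")
        for rid, _ in named_regions:
            for h in report[rid]["motifs"]:
                fh.write(f"{rid}\tmotif\t{h.position}\t{h.motif}({h.strand})\n")
            for c in report[rid]["cpgs"]:
                fh.write(f"{rid}\tCpG\t{c.record.pos}\t{c.call}\n")
    stage("annotate")

    with open(os.path.join(outdir, "run.log"), "w") as fh:
        fh.write("\n".join(log) + "\n")
    bundle["resdir"] = resdir
    return bundle


def summarize_report(bundle: dict, path: str | None = None) -> str:
    """One-page summary of the pipeline's result surfaces."""
    required = ["expression", "fold_changes", "regions", "evidence", "responses"]
    missing = [k for k in required if k not in bundle]
    if missing:
        raise ValueError(f"incomplete bundle; missing stages: {missing}")
    lines = ["# Pipeline summary", "", "## Start-exon fold changes (treated vs control)", ""]
    lines.append("| exon | contrast | fold change | ANOVA p |")
    lines.append("|---|---|---|---|")
    for (treated, control), results in bundle["fold_changes"].items():
        for r in results:
            fold = "undefined" if r.fold_change is None else f"{r.fold_change:.2f}"
            p = "NA" if r.anova_p is None else f"{r.anova_p:.3g}"
            lines.append(f"| {r.unit_name} | {treated}/{control} | {fold} | {p} |")
    lines += ["", "## Candidate regions and evidence", ""]
    matrix = bundle["evidence"]
    header = "| region | " + " | ".join(f"{a}:{c}" for a, c in matrix.columns) + " |"
    lines.append(header)
    lines.append("|" + "---|" * (len(matrix.columns) + 1))
    for row in matrix.row_ids:
        marks = [
            {"present": "X", "absent": "", "no_data": "?"}[matrix.cell(row, a, c)]
            for a, c in matrix.columns
        ]
        lines.append("| " + row + " | " + " | ".join(marks) + " |")
    lines += ["", "## Condition responses", ""]
    for (assay, control, treated), labels in bundle["responses"].items():
        for row, label in labels.items():
            if label not in ("no_data",):
                lines.append(f"- {assay} {treated} vs {control}: {row} -> {label}")
    if "annotation" in bundle:
        lines += ["", "## Region annotation (motifs and CpG calls)", ""]
        for rid, feats in bundle["annotation"].items():
            motifs = ", ".join(sorted({h.motif for h in feats["motifs"]})) or "none"
            cpg_calls = [c.call for c in feats["cpgs"] if c.call != "no_call"]
            meth = (
                f"{cpg_calls.count('unmethylated')}/{len(cpg_calls)} CpGs unmethylated"
                if cpg_calls else "no called CpGs"
            )
            lines.append(f"- {rid}: motifs [{motifs}]; {meth}")
    text = "\n".join(lines) + "\n"
    if path:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def run_full(seed: int = 1, outdir: str = "promloop_out", config: dict | None = None) -> dict:
    """Simulate the default scenario, run every stage, write the summary."""
    config = config or default_config(seed=seed, outdir=outdir)
    inputs = simulate_scenario(config)
    bundle = run_pipeline(config, inputs)
    summarize_report(bundle, os.path.join(bundle["resdir"], "summary.md"))
    return bundle
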