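"""End-to-end demo pipeline on synthetic data.

Runs, in order: chimera assembly -> profile building -> scanning ->
background -> enrichment -> overlap classification -> annotation ->
signal matrices -> super-enhancer calling/comparison -> screen ranking,
writing TSV/BED/FASTA artifacts, a resolved-config manifest and a log
with stage timings.  Defaults follow the published analysis settings
(two-mismatch thresholds, 0-8 bp spacers, 500 bp merge gap, +/-1 kb TSS
window, slope cutoff 1, 25 bp proximity window).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .enrichment import motif_enrichment, proximity_coenrichment, rank_profiles
from .intervals import GeneModel, PeakSet, Transcript, classify_overlap, signal_matrix
from .motifs import ConsensusMotif, assemble_chimeras, assemble_palindrome, build_profile, scan
from .screen import gene_scores, guide_ratios
from .simulate import (
    knockout_track,
    plant_peakset,
    simulate_genome,
    simulate_screen_counts,
    simulate_signal_track,
)
from .superenhancer import compare_super_sets, rank_and_call, stitch_peaks, super_enhancer_frame

logger = logging.getLogger("neocistrome")

# Library of common regulatory consensus elements used by the demo
# enrichment stage alongside the composite motif.  The AR half-site and
# full ARE are field-standard; the forkhead element here is the test
# stand-in (the user supplies real partner matrices as motif files).
DEMO_LIBRARY = {
    "AR_half": "AGAACA",
    "FKH": "TGTTTAC",
    "ETS": "GGAAGT",
    "HOX": "TTTATGG",
    "Ebox": "CACGTG",
    "AP1": "TGACTCA",
    "CRE": "TGACGTCA",
    "NFY": "CCAAT",
    "SP1": "GGGCGG",
}


@dataclass
class RunConfig:
    """Resolved parameters for one pipeline run."""

    outdir: str = "neocistrome_run"
    seed: int = 1
    # motif parameters (defaults follow the published analysis)
    mismatch_tolerance: int = 2
    spacer_min: int = 0
    spacer_max: int = 8
    half_site: str = "AGAACA"
    partner_element: str = "TGTTTAC"
    partner_name: str = "FKH"
    are_spacer: int = 3
    chimera_spacer: int = 0
    # cistrome parameters
    merge_gap: int = 500
    tss_window: int = 1000
    proximity_window: int = 25
    # synthetic-data parameters (the study conditions)
    genome_length: int = 2_000_000
    gc: float = 0.5
    n_target_peaks: int = 500
    n_background_peaks: int = 5000
    peak_width: int = 200
    target_fraction: float = 0.40
    background_fraction: float = 0.05
    # super-enhancer parameters
    se_chrom_len: int = 3_000_000
    n_typical_enhancers: int = 90
    n_super_clusters: int = 10
    cluster_span: int = 20_000
    amplification: float = 20.0
    stitch_distance: int = 12_500
    slope_threshold: float = 1.0
    se_lost_fraction: float = 0.75
    heatmap_flank: int = 1500
    heatmap_bin: int = 50
    # screen parameters
    run_screen: bool = True
    n_genes: int = 100
    guides_per_gene: int = 4
    planted_gene_delta: float = 2.0
    screen_mean_count: float = 500.0
    screen_dispersion: float = 0.1
    pseudocount: float = 0.5

    def validate(self) -> None:
        if self.mismatch_tolerance < 0:
            raise ValueError("mismatch_tolerance must be >= 0")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")
        if not (0 <= self.spacer_min <= self.spacer_max):
            raise ValueError("invalid spacer range")
        if self.slope_threshold <= 0:
            raise ValueError("slope_threshold must be > 0")
        if not (0 < self.gc < 1):
            raise ValueError("gc must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage(name):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception:
                logger.exception("stage %s: FAILED", name)
                raise
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return result
        return wrapper
    return decorator


def demo_profiles(config: RunConfig):
    """The demo motif library: composite + ARE + single elements."""
    half = ConsensusMotif("AR_half", config.half_site)
    partner = ConsensusMotif(config.partner_name, config.partner_element)
    are = assemble_palindrome(half, config.are_spacer)
    chimera = ConsensusMotif(
        f"{config.partner_name}_AR_half",
        config.partner_element + "N" * config.chimera_spacer + config.half_site,
    )
    k = config.mismatch_tolerance
    profiles = [build_profile(chimera, k), build_profile(are, k)]
    for name, iupac in DEMO_LIBRARY.items():
        profiles.append(build_profile(ConsensusMotif(name, iupac), k))
    return profiles, half, partner, chimera


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full synthetic demo; returns the output directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        _run_stages(config, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outdir


def _run_stages(config: RunConfig, outdir: Path) -> None:
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
    rng_seed = config.seed

    # --- motifs -----------------------------------------------------------
    profiles, half, partner, chimera = _motif_stage(config, outdir)

    # --- synthetic peaks + enrichment ------------------------------------
    genome, target, background, truth_t = _peaks_stage(config, outdir, chimera)
    results = _enrichment_stage(config, outdir, profiles, target, background, genome)

    # --- proximity co-occurrence -----------------------------------------
    _proximity_stage(config, outdir, half, partner, target, genome)

    # --- overlap classification + annotation -----------------------------
    _overlap_stage(config, outdir, target, truth_t, genome)

    # --- super-enhancers --------------------------------------------------
    _rose_stage(config, outdir)

    # --- screen -----------------------------------------------------------
    if config.run_screen:
        _screen_stage(config, outdir)

    summary = {"stages": "complete", "seed": rng_seed,
               "top_profile": results[0].profile_name}
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


@_stage("motif")
def _motif_stage(config: RunConfig, outdir: Path):
    profiles, half, partner, chimera = demo_profiles(config)
    chimera_family = assemble_chimeras(
        partner, half, (config.spacer_min, config.spacer_max)
    )
    nio.write_motif_file(profiles, outdir / "profiles.motif")
    with open(outdir / "chimera_configurations.txt", "w") as fh:
        for m in chimera_family:
            fh.write(f"{m.name}\t{m.iupac}\n")
    return profiles, half, partner, chimera


@_stage("simulate-peaks")
def _peaks_stage(config: RunConfig, outdir: Path, chimera: ConsensusMotif):
    seq_t = simulate_genome(config.genome_length, config.gc, config.seed)
    seq_b = simulate_genome(
        config.genome_length * max(1, config.n_background_peaks // max(config.n_target_peaks, 1)),
        config.gc, config.seed + 1,
    )
    seq_t, target, truth_t = plant_peakset(
        seq_t, config.n_target_peaks, config.peak_width, chimera,
        config.target_fraction, seed=config.seed + 2, chrom="chrT", label="target",
    )
    seq_b, background, truth_b = plant_peakset(
        seq_b, config.n_background_peaks, config.peak_width, chimera,
        config.background_fraction, seed=config.seed + 3, chrom="chrB",
        label="background",
    )
    genome = {"chrT": seq_t, "chrB": seq_b}
    nio.write_fasta(genome, outdir / "genome.fa")
    nio.write_bed(target, outdir / "target_peaks.bed")
    nio.write_bed(background, outdir / "background_peaks.bed")
    nio.write_tsv(truth_t, outdir / "target_truth.tsv")
    nio.write_tsv(truth_b, outdir / "background_truth.tsv")
    return genome, target, background, truth_t


@_stage("enrich")
def _enrichment_stage(config: RunConfig, outdir: Path, profiles, target,
                      background, genome):
    results = [
        motif_enrichment(p, target, background, genome) for p in profiles
    ]
    ranked = rank_profiles(results)
    frame = pd.DataFrame([vars(r) for r in ranked])
    nio.write_tsv(frame, outdir / "enrichment.tsv")
    return ranked


@_stage("proximity")
def _proximity_stage(config: RunConfig, outdir: Path, half, partner, target, genome):
    half_profile = build_profile(half, 0)
    partner_profile = build_profile(partner, 0)
    anchors = scan(half_profile, genome, both_strands=True, peaks=target)
    prox = proximity_coenrichment(anchors, partner_profile, target, genome,
                                  window=config.proximity_window)
    nio.write_tsv(pd.DataFrame([vars(prox) | {"fraction": prox.fraction}]),
                  outdir / "proximity.tsv")


@_stage("overlap-annotate")
def _overlap_stage(config: RunConfig, outdir: Path, target, truth, genome):
    # KO cistrome: sites whose composite motif was planted are lost.
    retained_names = set(truth.loc[~truth["planted"], "peak"])
    ko = PeakSet([iv for iv in target if iv.name in retained_names], "ko")
    venn = classify_overlap(target, ko, merge_gap=config.merge_gap)
    with open(outdir / "overlap_counts.json", "w") as fh:
        json.dump(venn.counts, fh, indent=2)

    gene_model = _synthetic_gene_model(config)
    from .intervals import annotate_peaks
    cats, fractions, _ = annotate_peaks(target, gene_model, config.tss_window)
    nio.write_tsv(
        pd.DataFrame({"peak": [iv.name for iv in target], "category": cats}),
        outdir / "annotation.tsv",
    )
    with open(outdir / "annotation_fractions.json", "w") as fh:
        json.dump(fractions, fh, indent=2)


def _synthetic_gene_model(config: RunConfig) -> GeneModel:
    """Regularly spaced two-exon transcripts along the target chromosome."""
    transcripts = []
    span, step = 20_000, 100_000
    for i, start in enumerate(range(50_000, config.genome_length - span, step)):
        exons = ((start, start + 2_000), (start + span - 2_000, start + span))
        transcripts.append(Transcript(f"tx_{i}", "chrT", start, start + span,
                                      "+" if i % 2 == 0 else "-", exons))
    return GeneModel(transcripts)


@_stage("rose")
def _rose_stage(config: RunConfig, outdir: Path):
    peaks, frame, truth = simulate_signal_track(
        config.se_chrom_len, config.n_typical_enhancers, config.n_super_clusters,
        config.cluster_span, config.amplification, seed=config.seed + 4,
    )
    from .intervals import Coverage
    wt_cov = Coverage(frame)
    stitched = stitch_peaks(peaks, config.stitch_distance)
    wt_called = rank_and_call(stitched, wt_cov, config.slope_threshold)
    nio.write_tsv(super_enhancer_frame(wt_called), outdir / "superenhancers_wt.tsv")
    nio.write_bedgraph(frame, outdir / "signal_wt.bedGraph")

    ko_frame, ko_truth = knockout_track(frame, truth, config.se_lost_fraction,
                                        seed=config.seed + 5)
    ko_called = rank_and_call(stitched, Coverage(ko_frame), config.slope_threshold)
    nio.write_tsv(super_enhancer_frame(ko_called), outdir / "superenhancers_ko.tsv")
    comparison = compare_super_sets(wt_called, ko_called)
    comparison.pop("paired_scores")
    with open(outdir / "superenhancer_comparison.json", "w") as fh:
        json.dump(comparison, fh, indent=2)

    se_peaks = PeakSet([d.interval for d in wt_called if d.is_super], "supers")
    if len(se_peaks):
        mat, offsets, _ = signal_matrix(se_peaks, wt_cov,
                                        flank=config.heatmap_flank,
                                        bin_size=config.heatmap_bin)
        pd.DataFrame(mat, columns=offsets).to_csv(
            outdir / "signal_matrix.tsv", sep="\t", index=False
        )


@_stage("screen")
def _screen_stage(config: RunConfig, outdir: Path):
    effects = {"gene0000": config.planted_gene_delta}
    table, truth = simulate_screen_counts(
        config.n_genes, config.guides_per_gene, effects,
        config.screen_mean_count, config.screen_dispersion, seed=config.seed + 6,
    )
    ratios = guide_ratios(table, config.pseudocount)
    genes = gene_scores(ratios)
    nio.write_tsv(table.frame, outdir / "screen_counts.tsv")
    nio.write_tsv(ratios, outdir / "guide_ratios.tsv")
    nio.write_tsv(genes, outdir / "gene_scores.tsv")
    nio.write_tsv(truth, outdir / "screen_truth.tsv")
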