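"""One-shot orchestration: simulation/input -> reads -> pileup -> report.

``run_pipeline`` ties the stages together behind a single config so a run
is reproducible from one file: identical config + seed gives an identical
summary.  Each stage writes its artifact (FASTQ, SAM, profile TSV,
combined TSV, spectrum TSV, summary JSON) into the output directory, and
a plain-text log echoes versions, seed and every parameter.
"""

from __future__ import annotations

import datetime
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .guides import GuideDesign, ReferenceAmplicon, read_guides_tsv
from .profiling import (
    MutationProfile,
    PassageRecord,
    combine_profiles,
    estimate_window_extent,
    generations_from_passages,
    per_generation_rate,
    per_read_count_summary,
    spectrum,
    subtract_background,
    window_average,
)
from .readproc import (
    align_read,
    build_pileup,
    merge_readset,
    read_fasta,
    read_fastq,
    read_fastq_pair,
    read_pileup_text,
    read_sam,
    substitutions_per_read,
    write_fastq,
    write_per_read_counts_tsv,
    write_sam,
)
from .simulate import (
    GenomePool,
    SimulationConfig,
    sample_reads,
    simulate_mutagenesis,
    write_config_yaml,
    write_truth_tsv,
)

MODES = ("simulate", "fastq", "sam", "pileup")


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    mode: str
    output_dir: str
    reference: str                       # FASTA path
    guides: str                          # guide TSV path
    seed: int = 0
    log_level: str = "INFO"
    plots: bool = False
    paths: dict = field(default_factory=dict)      # mode-specific inputs
    analysis: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise StageError(f"stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


def _now() -> str:
    return datetime.datetime.now().isoformat(timespec="seconds")


def _reads_to_profile(readset, ref, analysis, outdir, log, tag=""):
    min_overlap = int(analysis.get("min_overlap", 10))
    max_mm = float(analysis.get("max_mismatch_frac", 0.1))
    merged, unmerged = merge_readset(readset, min_overlap, max_mm)
    log(f"merge{tag}: {len(merged.singles)} merged, {unmerged} unmerged (dropped)")
    alignments = [align_read(r, ref) for r in merged.singles]
    n_unaligned = sum(1 for a in alignments if not a.aligned)
    log(f"align{tag}: {len(alignments)} reads, {n_unaligned} below identity threshold")
    aligned = [a for a in alignments if a.aligned]
    write_sam(aligned, ref, outdir / f"alignments{tag}.sam")
    cols = build_pileup(aligned, ref)
    profile = MutationProfile.from_pileup(cols, ref.id)
    counts = [substitutions_per_read(a) for a in aligned]
    write_per_read_counts_tsv(aligned, outdir / f"per_read_counts{tag}.tsv")
    return profile, counts, unmerged


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the machine-readable summary."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(f"{_now()} {msg}")

    log(f"dbeprof {__version__} python {platform.python_version()} numpy {np.__version__}")
    log(f"mode={config.mode} seed={config.seed}")
    log(f"analysis parameters: {json.dumps(config.analysis, sort_keys=True)}")
    log(f"simulation parameters: {json.dumps(config.simulation, sort_keys=True)}")

    ref = _load_reference(config)
    guides = _load_guides(config, ref)
    analysis = dict(config.analysis)
    center = int(analysis.get("window_center", guides[0].pam3_pos if guides else len(ref) // 2))
    halfwidth = int(analysis.get("window_halfwidth", 50))
    combine_hw = int(analysis.get("combine_halfwidth", halfwidth + 10))
    coverage_frac = float(analysis.get("coverage_frac", 0.99))

    counts: list[int] = []
    unmerged = 0
    truth_mutations = None
    if config.mode == "simulate":
        profile, counts, unmerged, truth_mutations = _run_simulate(
            config, ref, guides, analysis, outdir, log
        )
    elif config.mode == "fastq":
        readset = _load_fastq(config.paths)
        profile, counts, unmerged = _reads_to_profile(readset, ref, analysis, outdir, log)
    elif config.mode == "sam":
        alignments = read_sam(config.paths["sam"], ref)
        cols = build_pileup(alignments, ref)
        profile = MutationProfile.from_pileup(cols, ref.id)
        counts = [substitutions_per_read(a) for a in alignments]
        log(f"sam: {len(alignments)} alignments")
    else:  # pileup
        cols = read_pileup_text(config.paths["pileup"])
        profile = MutationProfile.from_pileup(cols, ref.id)
        log(f"pileup: {len(cols)} columns")

    background = _load_background(config, ref, analysis, outdir, log)
    if background is not None:
        profile = subtract_background(profile, background)
        log("background subtracted (rates clamped at zero)")

    profile.to_tsv(outdir / "profile.tsv")

    summary: dict = {
        "mode": config.mode,
        "seed": config.seed,
        "n_unmerged_pairs": unmerged,
        "window_center": center,
        "window_halfwidth": halfwidth,
    }
    if truth_mutations is not None:
        summary["true_mutation_count"] = truth_mutations

    mean_rate = window_average(profile, center, halfwidth)
    summary["window_mean_substitution_rate"] = mean_rate

    generations = _resolve_generations(config, log)
    summary["generations"] = generations
    summary["substitutions_per_bp_per_generation"] = per_generation_rate(mean_rate, generations)

    spec = spectrum(profile, center, halfwidth)
    spec.to_frame().to_csv(outdir / "spectrum.tsv", sep="\t")
    summary["at_fraction"] = spec.at_fraction

    if guides:
        combined = combine_profiles([profile] * len(guides), guides, combine_hw)
        pd.DataFrame(
            {"rel_position": combined.rel_positions, "mean_rate": combined.mean_rate,
             **{name: vec for name, vec in combined.per_guide.items()}}
        ).to_csv(outdir / "combined.tsv", sep="\t", index=False, float_format="%.8g")
        try:
            left, right, width = estimate_window_extent(combined, coverage_frac)
            summary["window_extent"] = {"left": left, "right": right, "width_bp": width}
        except ValueError:
            summary["window_extent"] = None
            log("window extent unavailable: no substitution signal")

    if counts:
        rc = per_read_count_summary(counts)
        summary["per_read"] = {"frac_ge1": rc.frac_ge1, "frac_ge2": rc.frac_ge2,
                               "n_reads": rc.n_reads}

    if config.plots:
        from .plots import plot_profile, plot_spectrum_heatmap

        plot_profile(profile, outdir / "profile.svg", center=center, halfwidth=halfwidth)
        plot_spectrum_heatmap(spec, outdir / "spectrum.svg")
        log("plots written")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=2)
        fh.write("\n")
    log("summary written")
    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return summary


@_stage("reference")
def _load_reference(config: RunConfig) -> ReferenceAmplicon:
    return read_fasta(config.reference)


@_stage("guides")
def _load_guides(config: RunConfig, ref: ReferenceAmplicon) -> list[GuideDesign]:
    guides = read_guides_tsv(config.guides)
    for g in guides:
        g.validate_against(ref)
    return guides


@_stage("fastq")
def _load_fastq(paths: dict):
    if "reads2" in paths and paths["reads2"]:
        return read_fastq_pair(paths["reads"], paths["reads2"])
    return read_fastq(paths["reads"])


@_stage("simulate")
def _run_simulate(config: RunConfig, ref, guides, analysis, outdir, log):
    sim = dict(config.simulation)
    n_reads = int(sim.pop("n_reads", 1000))
    sim_config = SimulationConfig(reference=ref, guides=guides, seed=config.seed, **sim)
    write_config_yaml(sim_config, outdir / "simulation_config.yaml")
    pool: GenomePool = simulate_mutagenesis(sim_config)
    write_truth_tsv(pool, outdir / "truth.tsv")
    log(f"simulate: {sim_config.n_genomes} genomes, {pool.total_mutations()} true mutations")
    readset = sample_reads(
        pool, n_reads, sim_config.read_length, sim_config.paired,
        sim_config.seq_error_rate, config.seed,
    )
    if readset.pairs:
        write_fastq(readset, outdir / "reads_R1.fastq", outdir / "reads_R2.fastq")
    else:
        write_fastq(readset, outdir / "reads.fastq")
    profile, counts, unmerged = _reads_to_profile(readset, ref, analysis, outdir, log)
    return profile, counts, unmerged, pool.total_mutations()


@_stage("background")
def _load_background(config: RunConfig, ref, analysis, outdir, log):
    paths = config.paths
    if paths.get("background_profile"):
        return MutationProfile.from_tsv(paths["background_profile"], ref.id)
    if paths.get("background_reads"):
        if paths.get("background_reads2"):
            rs = read_fastq_pair(paths["background_reads"], paths["background_reads2"])
        else:
            rs = read_fastq(paths["background_reads"])
        profile, _, _ = _reads_to_profile(rs, ref, analysis, outdir, log, tag="_background")
        return profile
    return None


@_stage("generations")
def _resolve_generations(config: RunConfig, log) -> float:
    paths = config.paths
    if paths.get("passages"):
        df = pd.read_csv(paths["passages"])
        record = PassageRecord(list(zip(df["od_start"], df["od_end"])))
        g = generations_from_passages(record)
        log(f"generations from passages: {g:.3f}")
        return g
    g = float(config.analysis.get("generations",
                                  config.simulation.get("generations", 20.5)))
    return g
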