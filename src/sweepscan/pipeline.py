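"""End-to-end orchestration: simulate/load -> filter -> scan -> outliers -> annotate.

The pipeline is a pure function of its configuration and seed: running the
same :class:`RunConfig` twice yields byte-identical outputs. Each stage
logs machine-readable ``key=value`` lines (no timestamps, so logs are
reproducible too) and writes tab-separated tables into the output
directory.
"""

from __future__ import annotations

import contextlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .annotate import genes_in_windows, summarize_run
from .errors import ConfigError, SweepScanError
from .filtering import FilterParams, FilterResult, apply_filters
from .fst import breed_mean_fst, pair_fst_tracks
from .hp import HP_MODES, breed_hp_track
from .io import CountsTable, GeneFeature
from .outliers import classify_shared, select_outliers, z_transform
from .simulate import (
    BreedModel,
    SweepTruth,
    emit_toy_annotation,
    implant_sweep,
    sample_pool_reads,
    simulate_frequencies,
    write_sweep_truth,
)
from .windows import MIN_SNPS, STEP, WINDOW_SIZE, make_windows

logger = logging.getLogger("sweepscan")

STAGES = ("simulate", "filter", "scan", "outliers", "annotate")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from YAML."""

    breeds: list[BreedModel]
    chrom_lengths: dict[str, int]
    out_dir: str = "sweepscan_out"
    seed: int = 0
    # simulation (used when counts_path is not given)
    snp_per_kb: float = 2.5
    error_rate: float = 0.01
    mean_qual: float = 35.0
    sweeps: list[SweepTruth] = field(default_factory=list)
    n_toy_genes: int = 100
    # inputs (optional: simulated when absent)
    counts_path: str | None = None
    gff3_path: str | None = None
    # filtering and scan parameters
    filters: FilterParams = field(default_factory=FilterParams)
    window_size: int = WINDOW_SIZE
    step: int = STEP
    min_snps: int = MIN_SNPS
    q: float = 0.005
    hp_mode: str = "per_snp_mean"

    def __post_init__(self) -> None:
        if len(self.breeds) < 2:
            raise ConfigError(f"need at least 2 breeds, got {len(self.breeds)}")
        names = [b.name for b in self.breeds]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate breed names in {names}")
        if not (0.0 < self.q < 0.5):
            raise ConfigError(f"q must be in (0, 0.5), got {self.q}")
        if self.hp_mode not in HP_MODES:
            raise ConfigError(f"hp_mode must be one of {HP_MODES}")
        if self.window_size % self.step != 0:
            raise ConfigError("window_size must be a multiple of step")
        if not self.chrom_lengths:
            raise ConfigError("chrom_lengths must name at least one chromosome")
        for s in self.sweeps:
            if s.breed not in names:
                raise ConfigError(f"sweep names unknown breed {s.breed!r}")

    @property
    def breed_names(self) -> list[str]:
        return [b.name for b in self.breeds]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        breeds = [BreedModel(**b) for b in raw.pop("breeds", [])]
        sweeps = [SweepTruth(**s) for s in raw.pop("sweeps", [])]
        filters = FilterParams(**raw.pop("filters", {}))
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(breeds=breeds, sweeps=sweeps, filters=filters, **raw)


@dataclass
class ScanResult:
    """In-memory results of filter -> scan -> outliers -> annotate."""

    counts: CountsTable
    filt: FilterResult
    windows: pd.DataFrame
    window_stats: pd.DataFrame
    calls: pd.DataFrame
    overlap_matrix: pd.DataFrame
    gene_table: pd.DataFrame
    window_annotations: pd.DataFrame
    report: pd.DataFrame


@contextlib.contextmanager
def _stage(name: str):
    """Re-raise stage errors with the stage name prepended."""
    try:
        yield
    except SweepScanError as exc:
        raise type(exc)(f"stage={name}: {exc}") from exc


def simulate_counts(config: RunConfig) -> tuple[CountsTable, list[SweepTruth]]:
    """Simulate pooled counts (drift background plus configured sweeps)."""
    sim = simulate_frequencies(
        config.chrom_lengths,
        config.breeds,
        snp_per_kb=config.snp_per_kb,
        seed=config.seed,
    )
    for sweep in config.sweeps:
        sim = implant_sweep(sim, sweep)
    counts = sample_pool_reads(
        sim,
        config.breeds,
        error_rate=config.error_rate,
        mean_qual=config.mean_qual,
        seed=config.seed + 1,
    )
    return counts, list(config.sweeps)


def scan_counts(
    counts: CountsTable,
    config: RunConfig,
    genes: Sequence[GeneFeature] = (),
) -> ScanResult:
    """Run filter -> window scans -> outlier calls -> annotation in memory."""
    with _stage("filter"):
        filt = apply_filters(counts, config.filters)
        for breed, n in filt.n_retained().items():
            logger.info("stage=filter breed=%s n_retained=%d", breed, n)

    with _stage("scan"):
        windows = make_windows(config.chrom_lengths, config.window_size, config.step)
        pair_tracks = pair_fst_tracks(
            counts, filt, windows, config.window_size, config.step, config.min_snps
        )
        per_breed = []
        for breed in counts.breeds:
            fst_track = breed_mean_fst(pair_tracks, breed, counts.breeds)
            hp_track = breed_hp_track(
                counts, filt, breed, windows,
                config.window_size, config.step, config.min_snps, config.hp_mode,
            )
            track = fst_track.rename(columns={"n_snps": "n_snps_fst"})
            track["breed"] = breed
            track["n_snps"] = hp_track["n_snps"]
            track["hp"] = hp_track["hp"]
            track["zfst"] = z_transform(track["fst"].to_numpy()).z
            track["zhp"] = z_transform(track["hp"].to_numpy()).z
            per_breed.append(track)
            logger.info(
                "stage=scan breed=%s n_windows=%d n_unmasked_fst=%d n_unmasked_hp=%d",
                breed, len(track),
                int(track["fst"].notna().sum()), int(track["hp"].notna().sum()),
            )
        window_stats = pd.concat(per_breed, ignore_index=True)

    with _stage("outliers"):
        calls = pd.concat(
            [
                select_outliers(track, config.q)
                for track in per_breed
            ],
            ignore_index=True,
        )
        calls, overlap_matrix = classify_shared(calls)
        logger.info(
            "stage=outliers n_calls=%d n_putative=%d",
            len(calls), int((calls["status"] == "putative_selection").sum()),
        )

    with _stage("annotate"):
        gene_table, window_annotations = genes_in_windows(calls, genes)
        report = summarize_run(counts, filt, calls, gene_table, config.chrom_lengths)
        logger.info("stage=annotate n_gene_hits=%d", len(gene_table))

    return ScanResult(
        counts=counts,
        filt=filt,
        windows=windows,
        window_stats=window_stats,
        calls=calls,
        overlap_matrix=overlap_matrix,
        gene_table=gene_table,
        window_annotations=window_annotations,
        report=report,
    )


def run_pipeline(config: RunConfig, stop_after: str | None = None) -> ScanResult | None:
    """Execute the full pipeline and write all outputs under ``out_dir``.

    ``stop_after`` truncates the run after a named stage (one of
    ``simulate``, ``filter``, ``scan``, ``outliers``, ``annotate``); the
    later stages are cheap recomputations from the counts table, so the
    subcommand-style partial runs always agree with a full run.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ConfigError(f"stop_after must be one of {STAGES}, got {stop_after!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_file_log(out / "run.log")

    with _stage("simulate"):
        if config.counts_path:
            counts = sio.read_pooled_counts(config.counts_path, config.breed_names)
            logger.info("stage=load counts=%s n_sites=%d", config.counts_path, len(counts))
        else:
            counts, sweeps = simulate_counts(config)
            sio.write_pooled_counts(counts, out / "counts.tsv")
            write_sweep_truth(sweeps, out / "sweep_truth.tsv")
            logger.info(
                "stage=simulate n_sites=%d n_sweeps=%d seed=%d",
                len(counts), len(sweeps), config.seed,
            )
        if config.gff3_path:
            genes = sio.read_gff3_genes(config.gff3_path)
        else:
            genes = emit_toy_annotation(
                config.chrom_lengths, config.n_toy_genes,
                seed=config.seed + 2, path=out / "genes.gff3",
            )
        logger.info("stage=simulate n_genes=%d", len(genes))
    if stop_after == "simulate":
        return None

    result = scan_counts(counts, config, genes)

    filt_report = result.filt.report
    filt_report.to_csv(out / "filter_report.tsv", sep="\t", index=False)
    if stop_after == "filter":
        return result
    sio.write_window_stats(result.window_stats, out / "window_stats.tsv")
    if stop_after == "scan":
        return result
    result.calls.to_csv(
        out / "selection_calls.tsv", sep="\t", index=False,
        float_format="%.12g", na_rep="NA",
    )
    putative = result.calls[result.calls["status"] == "putative_selection"]
    sio.write_outlier_bed(putative, out / "putative_windows.bed")
    result.overlap_matrix.to_csv(out / "overlap_matrix.tsv", sep="\t")
    if stop_after == "outliers":
        return result
    result.gene_table.to_csv(out / "gene_annotations.tsv", sep="\t", index=False)
    result.report.to_csv(
        out / "run_report.tsv", sep="\t", index=False, float_format="%.12g"
    )
    return result


def _setup_file_log(path: Path) -> None:
    """Log key=value lines to the run directory (no timestamps: reproducible)."""
    for h in list(logger.handlers):
        if isinstance(h, logging.FileHandler):
            logger.removeHandler(h)
            h.close()
    handler = logging.FileHandler(path, mode="w")
    handler.setFormatter(logging.Formatter("%(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
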