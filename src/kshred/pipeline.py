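"""End-to-end orchestration: simulate (optional) -> census -> binning ->
target selection, with a machine-readable run report.

A run is driven by one configuration (YAML on disk or a PipelineConfig);
every stage writes its table next to the others in ``output_dir`` and the
report echoes the full parameter set, so runs are self-describing.  Two
runs with identical configuration produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .binning import BinningParams, process_long_reads, stats_to_tsv, xsi_filter
from .census import CensusParams, ClassThresholds, census_to_tsv, count_kmers, merge_census
from .demo import demo_genome_spec, demo_longread_params, demo_read_params
from .simulate import (
    GenomeSpec,
    LongReadSimParams,
    ReadSimParams,
    RepeatClusterSpec,
    build_genome,
    simulate_long_reads,
    simulate_short_reads,
)
from .targets import BackgroundIndex, SelectionParams, percentile_filter, rank_targets

log = logging.getLogger("kshred")


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and offending input."""


@dataclass
class PipelineConfig:
    output_dir: str = "kshred_out"
    # either simulate a dataset ...
    genome: Optional[GenomeSpec] = None
    male_reads_sim: Optional[ReadSimParams] = None
    female_reads_sim: Optional[ReadSimParams] = None
    long_reads_sim: Optional[LongReadSimParams] = None
    # ... or point at existing libraries
    male_fastq: Optional[str] = None
    female_fastq: Optional[str] = None
    long_reads: Optional[str] = None
    mito_fasta: Optional[str] = None
    census: CensusParams = field(default_factory=CensusParams)
    thresholds: ClassThresholds = field(default_factory=ClassThresholds)
    binning: BinningParams = field(default_factory=BinningParams)
    selection: SelectionParams = field(default_factory=SelectionParams)
    seed: int = 0

    @property
    def simulate(self) -> bool:
        return self.genome is not None


def validate_config(cfg: PipelineConfig) -> list:
    """Return every violation found, not just the first."""
    errs = []
    errs += cfg.census.validate()
    errs += cfg.thresholds.validate()
    errs += cfg.binning.validate()
    errs += cfg.selection.validate()
    if cfg.simulate:
        errs += cfg.genome.validate()
        for p in (cfg.male_reads_sim, cfg.female_reads_sim):
            if p is None:
                errs.append("config: simulation requires male and female read params")
            else:
                errs += p.validate()
        if cfg.long_reads_sim is None:
            errs.append("config: simulation requires long-read params")
        else:
            errs += cfg.long_reads_sim.validate()
    else:
        for name in ("male_fastq", "female_fastq", "long_reads", "mito_fasta"):
            path = getattr(cfg, name)
            if path is None:
                errs.append(f"config: {name} is required when not simulating")
            elif not Path(path).exists():
                errs.append(f"config: {name} path does not exist: {path}")
    return errs


def demo_config(output_dir: str, seed: int = 0) -> PipelineConfig:
    """The packaged full-size synthetic demonstration configuration."""
    ss = np.random.SeedSequence(seed)
    s_gen, s_m, s_f, s_lr = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    return PipelineConfig(
        output_dir=output_dir,
        genome=demo_genome_spec(seed=s_gen),
        male_reads_sim=demo_read_params("male", seed=s_m),
        female_reads_sim=demo_read_params("female", seed=s_f),
        long_reads_sim=demo_longread_params(seed=s_lr),
        seed=seed,
    )


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    for key in ("output_dir", "male_fastq", "female_fastq", "long_reads", "mito_fasta", "seed"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "genome" in raw:
        g = dict(raw["genome"])
        g["clusters"] = [RepeatClusterSpec(**c) for c in g.get("clusters", [])]
        cfg.genome = GenomeSpec(**g)
    if "male_reads_sim" in raw:
        cfg.male_reads_sim = ReadSimParams(**raw["male_reads_sim"])
    if "female_reads_sim" in raw:
        cfg.female_reads_sim = ReadSimParams(**raw["female_reads_sim"])
    if "long_reads_sim" in raw:
        cfg.long_reads_sim = LongReadSimParams(**raw["long_reads_sim"])
    for key, cls in (
        ("census", CensusParams),
        ("thresholds", ClassThresholds),
        ("binning", BinningParams),
        ("selection", SelectionParams),
    ):
        if key in raw:
            setattr(cfg, key, cls(**raw[key]))
    return cfg


def _echo_params(cfg: PipelineConfig) -> dict:
    def conv(obj):
        if obj is None:
            return None
        d = asdict(obj)
        return d

    return {
        "seed": cfg.seed,
        "census": conv(cfg.census),
        "thresholds": conv(cfg.thresholds),
        "binning": conv(cfg.binning),
        "selection": conv(cfg.selection),
        "genome": conv(cfg.genome) if cfg.simulate else None,
        "male_reads_sim": conv(cfg.male_reads_sim),
        "female_reads_sim": conv(cfg.female_reads_sim),
        "long_reads_sim": conv(cfg.long_reads_sim),
    }


def run_pipeline(cfg: PipelineConfig, keep_in_memory: bool = False):
    """Execute census -> binning -> selection (plus optional simulation).

    Writes census.tsv, read_bins.tsv, kmer_stats.tsv, candidates.tsv,
    targets.tsv and report.json under ``cfg.output_dir``; returns the run
    report dict (and, with ``keep_in_memory``, the intermediate frames).
    """
    errs = validate_config(cfg)
    if errs:
        raise PipelineError("invalid configuration: " + "; ".join(errs))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"stages": [], "parameters": _echo_params(cfg)}
    mem = {}

    truth = None
    if cfg.simulate:
        log.info("[simulate] building genome and libraries")
        genome, truth = build_genome(cfg.genome)
        _io.write_fasta(out / "genome.fasta", sorted(genome.items()))
        _io.write_fasta(out / "mito.fasta", [("MT", genome["MT"])])
        cfg = PipelineConfig(**{**cfg.__dict__})  # shallow copy; fill paths
        cfg.male_fastq = str(out / "male.fastq")
        cfg.female_fastq = str(out / "female.fastq")
        cfg.long_reads = str(out / "long_reads.fasta")
        cfg.mito_fasta = str(out / "mito.fasta")
        n_m = simulate_short_reads(genome, cfg.male_reads_sim, cfg.male_fastq)
        n_f = simulate_short_reads(genome, cfg.female_reads_sim, cfg.female_fastq)
        n_lr = simulate_long_reads(genome, cfg.long_reads_sim, cfg.long_reads)
        report["stages"].append(
            {"stage": "simulate", "male_reads": n_m, "female_reads": n_f, "long_reads": n_lr}
        )
        mem["genome"], mem["truth"] = genome, truth

    # census ---------------------------------------------------------------
    log.info("[census] counting male library")
    census_m = count_kmers(cfg.male_fastq, cfg.census)
    log.info("[census] counting female library")
    census_f = count_kmers(cfg.female_fastq, cfg.census)
    if census_m.total_valid == 0 or census_f.total_valid == 0:
        raise PipelineError(
            "census: empty short-read library "
            f"(male valid windows: {census_m.total_valid}, female: {census_f.total_valid})"
        )
    census = merge_census(census_m, census_f, cfg.census, cfg.thresholds)
    census_to_tsv(census, out / "census.tsv")
    class_counts = census["kmer_class"].value_counts().to_dict()
    report["stages"].append(
        {
            "stage": "census",
            "male_valid_windows": census_m.total_valid,
            "female_valid_windows": census_f.total_valid,
            "male_invalid_windows": census_m.n_invalid,
            "female_invalid_windows": census_f.n_invalid,
            "kmers_counted": int(np.union1d(census_m.codes, census_f.codes).size),
            "kmers_after_noise_floor": int(len(census)),
            "class_counts": {str(k): int(v) for k, v in class_counts.items()},
        }
    )

    # long-read binning ------------------------------------------------------
    log.info("[bin-reads] filtering and binning long reads")
    mito_seq = "".join(s for _n, s in _io.read_fasta(cfg.mito_fasta))
    result = process_long_reads(cfg.long_reads, census, mito_seq, cfg.binning)
    result.read_table.to_csv(out / "read_bins.tsv", sep="\t", index=False)
    stats_to_tsv(result.kmer_stats, out / "kmer_stats.tsv")
    status_counts = result.read_table["status"].value_counts().to_dict()
    bin_counts = result.read_table.loc[
        result.read_table["status"] == "kept", "bin"
    ].value_counts().to_dict()
    report["stages"].append(
        {
            "stage": "bin-reads",
            "reads_in": int(len(result.read_table)),
            "reads_kept": int(result.n_kept),
            "status_counts": {str(k): int(v) for k, v in status_counts.items()},
            "bin_counts": {str(k): int(v) for k, v in bin_counts.items()},
        }
    )

    # selection --------------------------------------------------------------
    log.info("[select] XSI/LSum filtering and ranking")
    candidates = xsi_filter(
        result.kmer_stats, census, xsi_min=cfg.selection.xsi_min, lsum=cfg.census.lsum
    )
    stats_to_tsv(candidates, out / "candidates.tsv")
    flagged = percentile_filter(candidates, cfg.selection)
    kept = result.read_table["status"] == "kept"
    bg_ids = set(
        result.read_table.loc[kept & result.read_table["bin"].isin(["A", "Y"]), "read_id"]
    )
    background = [seq for name, seq in _io.read_seqs(cfg.long_reads) if name in bg_ids]
    bg_index = BackgroundIndex(background)
    del background
    table = rank_targets(flagged, bg_index, cfg.selection)
    table.to_csv(out / "targets.tsv", sep="\t", index=False, float_format="%.6g")
    report["stages"].append(
        {
            "stage": "select",
            "candidates_after_xsi_lsum": int(len(candidates)),
            "flagged": int(len(flagged)),
            "selected_kmers": int(table["kmer"].nunique()) if len(table) else 0,
            "target_rows": int(len(table)),
        }
    )

    report["outputs"] = {
        "census": str(out / "census.tsv"),
        "read_bins": str(out / "read_bins.tsv"),
        "kmer_stats": str(out / "kmer_stats.tsv"),
        "candidates": str(out / "candidates.tsv"),
        "targets": str(out / "targets.tsv"),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    if keep_in_memory:
        mem.update(
            census=census,
            read_table=result.read_table,
            kmer_stats=result.kmer_stats,
            candidates=candidates,
            flagged=flagged,
            targets=table,
        )
        return report, mem
    return report
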