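"""End-to-end runs: genome avoidance scans and assay reports with manifests.

A run reads inputs, executes the configured analyses, and writes TSV/JSON
outputs plus a manifest recording the configuration, the seed, the package
version and a content hash of every output file.  Identical configuration
and inputs yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assay_stats import (
    endpoint_biomass_comparison,
    fitness_inference,
    fitness_per_replicate,
    read_cfu_table,
    read_growth_table,
)
from .cell_fate import fate_fractions, lysis_time_comparison, read_fate_table, survival_curve
from .cohort_analysis import assign_cohorts, cohort_summary
from .genome_io import filter_genomes, join_metadata, read_fasta
from .motif_stats import motif_table
from .shuffle_null import shuffle_table

logger = logging.getLogger(__name__)

DEFAULT_MOTIFS = ("ACA", "GCU", "ACG", "ACU")


@dataclass
class RunConfig:
    """Configuration of a reproducible run."""

    seed: int
    fasta: str | None = None
    metadata: str | None = None
    cfu: str | None = None
    growth: str | None = None
    fate: str | None = None
    motifs: tuple[str, ...] = DEFAULT_MOTIFS
    n_shuffles: int = 10_000
    min_length: int = 1000
    host_filter: str = "Escherichia"
    outdir: str = "taphage_out"
    alpha: float = 0.05
    t_eval: float | None = None

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("motifs must be non-empty")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "motifs" in raw:
            raw["motifs"] = tuple(raw["motifs"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["motifs"] = list(self.motifs)
        return d


def _write_tsv(frame: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# taphage {__version__} seed={seed}\n")
        frame.to_csv(fh, sep="\t", index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, config: RunConfig, files: list[Path]) -> Path:
    manifest = {
        "package": "taphage",
        "version": __version__,
        "config": config.to_dict(),
        "files": {p.name: _sha256(p) for p in files},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def run_avoidance(config: RunConfig) -> dict[str, Path]:
    """Read -> filter -> per-motif stats -> shuffle null -> cohort summaries."""
    if config.fasta is None:
        raise ValueError("run_avoidance requires a FASTA input")
    fasta = Path(config.fasta)
    if not fasta.exists():
        raise FileNotFoundError(fasta)
    if config.metadata is not None and not Path(config.metadata).exists():
        raise FileNotFoundError(config.metadata)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = read_fasta(fasta)
    if config.metadata is not None:
        records = join_metadata(records, config.metadata)
    records = filter_genomes(records, min_length=config.min_length)
    logger.info("analysing %d genomes after filtering", len(records))

    stats = motif_table(records, config.motifs)
    stats_path = outdir / "genome_stats.tsv"
    _write_tsv(stats, stats_path, config.seed)

    null = shuffle_table(records, config.motifs, n_shuffles=config.n_shuffles, seed=config.seed)
    null_path = outdir / "shuffle_null.tsv"
    _write_tsv(null, null_path, config.seed)

    cohorts = assign_cohorts(records, host_filter=config.host_filter)
    report = {}
    for name, members in cohorts.items():
        ids = {m.id for m in members}
        report[name] = {}
        for motif in config.motifs:
            values = stats.loc[
                (stats["motif"] == motif) & stats["genome_id"].isin(ids),
                "relative_frequency",
            ].dropna()
            if values.empty:
                continue
            summ = cohort_summary(values.tolist(), cohort=name, motif=motif)
            report[name][motif] = {
                "n_genomes": summ.n_genomes,
                "mean": summ.mean,
                "min": summ.min,
                "max": summ.max,
                "p_vs_1": summ.p_vs_1,
            }
    cohort_path = outdir / "cohort_summary.json"
    cohort_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    files = [stats_path, null_path, cohort_path]
    manifest = _write_manifest(outdir, config, files)
    return {
        "genome_stats": stats_path,
        "shuffle_null": null_path,
        "cohort_summary": cohort_path,
        "manifest": manifest,
    }


def run_assays(config: RunConfig) -> dict[str, Path]:
    """Fitness, growth-endpoint and cell-fate reports from assay tables."""
    if config.cfu is None and config.growth is None and config.fate is None:
        raise ValueError("run_assays requires at least one assay table")
    for path in (config.cfu, config.growth, config.fate):
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(path)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    out: dict[str, Path] = {}

    if config.cfu is not None:
        table = read_cfu_table(config.cfu)
        rows = []
        for (phage, moi), group in table.groupby(["phage", "moi"]):
            w = fitness_per_replicate(group)
            res = fitness_inference(w.tolist())
            rows.append(
                {
                    "phage": phage,
                    "moi": moi,
                    "n": res.n,
                    "mean_w": res.mean_w,
                    "ci95_low": res.ci95_low,
                    "ci95_high": res.ci95_high,
                    "p_vs_1": res.p_vs_1,
                    "significant": res.p_vs_1 < config.alpha,
                }
            )
        path = outdir / "fitness.tsv"
        _write_tsv(pd.DataFrame(rows), path, config.seed)
        files.append(path)
        out["fitness"] = path

    if config.growth is not None:
        curves = read_growth_table(config.growth)
        conditions = sorted(curves["condition"].unique())
        if len(conditions) != 2:
            raise ValueError("growth endpoint comparison requires exactly 2 conditions")
        t_eval = config.t_eval if config.t_eval is not None else curves["t_min"].max()
        comp = endpoint_biomass_comparison(curves, t_eval, conditions[0], conditions[1])
        path = outdir / "growth_endpoint.json"
        path.write_text(json.dumps(dataclasses.asdict(comp), indent=2) + "\n")
        files.append(path)
        out["growth"] = path

    if config.fate is not None:
        table = read_fate_table(config.fate)
        report: dict = {}
        for condition, group in table.groupby("condition"):
            fractions = fate_fractions(group)
            curve = survival_curve(group)
            report[str(condition)] = {
                "n_cells": int(len(group)),
                "fractions": fractions.set_index("fate")["percent"].to_dict(),
                "survival_final": curve.pooled[-1],
            }
        conditions = sorted(table["condition"].unique())
        if len(conditions) == 2:
            t_a = table.loc[
                (table["condition"] == conditions[0]) & (table["fate"] == "lysed"),
                "t_lysis_min",
            ]
            t_b = table.loc[
                (table["condition"] == conditions[1]) & (table["fate"] == "lysed"),
                "t_lysis_min",
            ]
            if len(t_a) >= 2 and len(t_b) >= 2:
                comp = lysis_time_comparison(t_a.tolist(), t_b.tolist())
                report["lysis_time_comparison"] = dataclasses.asdict(comp)
        path = outdir / "cell_fate.json"
        path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        files.append(path)
        out["fate"] = path

    out["manifest"] = _write_manifest(outdir, config, files)
    return out
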