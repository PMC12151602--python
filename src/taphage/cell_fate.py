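"""Single-cell infection outcomes: fate fractions, survival curves, lysis times.

Inputs are per-cell event tables (one row per cell observed from the start
of phage exposure): a categorical fate, the time of lysis for lysed cells,
and optional pre/post exposure cell lengths.  Cells that do not lyse are
treated as surviving through the end of observation; there is no censoring
model beyond the endpoint truncation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

FATES = ("lysed", "survived", "growth_arrested", "filamented", "arrested_and_filamented")

FATE_COLUMNS = (
    "cell_id", "condition", "fate", "t_lysis_min",
    "length_pre_um", "length_post_um", "observation_end_min",
)


def read_fate_table(path) -> pd.DataFrame:
    """Read and validate a per-cell fate table (TSV)."""
    table = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in FATE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"fate table {path} is missing columns: {missing}")
    return validate_fate_table(table)


def validate_fate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check fate labels, lysis times and id uniqueness within condition."""
    bad = set(table["fate"]) - set(FATES)
    if bad:
        raise ValueError(f"unknown fate labels: {sorted(bad)}")
    lysed = table[table["fate"] == "lysed"]
    if lysed["t_lysis_min"].isna().any():
        raise ValueError("lysed cells must carry a t_lysis_min value")
    late = lysed["t_lysis_min"] > lysed["observation_end_min"]
    if late.any():
        raise ValueError("t_lysis_min exceeds observation_end_min for some cells")
    dup = table.duplicated(subset=["condition", "cell_id"])
    if dup.any():
        raise ValueError("cell ids must be unique within a condition")
    return table


def fate_fractions(table: pd.DataFrame) -> pd.DataFrame:
    """Per-fate counts and percentages over the full fate partition.

    Percentages are 100 * count / total and sum to 100 up to rounding; all
    five fate categories appear, zero-filled where unobserved.
    """
    if len(table) < 1:
        raise ValueError("fate table is empty")
    counts = table["fate"].value_counts().reindex(FATES, fill_value=0)
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "fate": FATES,
            "count": counts.to_numpy(dtype=int),
            "percent": 100.0 * counts.to_numpy() / total,
            "total": total,
        }
    )


@dataclass(frozen=True)
class SurvivalCurve:
    """Fraction of cells surviving (not yet lysed) as a function of time."""

    times: tuple[float, ...]
    pooled: tuple[float, ...]
    by_replicate: Mapping[str, tuple[float, ...]]

    def at(self, t: float) -> float:
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        if idx < 0:
            return 1.0
        return self.pooled[idx]


def _surviving_fraction(
    t_lysis: np.ndarray, n_cells: int, grid: np.ndarray
) -> np.ndarray:
    # fraction of cells with no lysis event at or before each grid time
    lysed_by_t = np.searchsorted(np.sort(t_lysis), grid, side="right")
    return 1.0 - lysed_by_t / n_cells


def survival_curve(
    table: pd.DataFrame,
    grid: Sequence[float] | None = None,
    grid_step: float = 5.0,
    replicate_column: str | None = None,
) -> SurvivalCurve:
    """Population survival versus time from a per-cell fate table.

    At each grid time t the surviving fraction is the share of cells with no
    lysis event at or before t; non-lysed cells survive through the end of
    observation.  With ``replicate_column`` set, per-replicate curves are
    computed alongside the pooled curve (each replicate weighted by its own
    cell count in its curve; the pooled curve uses all cells).
    """
    if len(table) < 1:
        raise ValueError("fate table is empty")
    end = float(table["observation_end_min"].max())
    if grid is None:
        grid = np.arange(0.0, end + grid_step / 2, grid_step)
    grid = np.asarray(grid, dtype=float)
    if grid.size and (grid.min() < 0 or grid.max() > end + 1e-9):
        raise ValueError("grid must lie within [0, observation_end]")
    lysis_times = table.loc[table["fate"] == "lysed", "t_lysis_min"].to_numpy(float)
    pooled = _surviving_fraction(lysis_times, len(table), grid)
    by_replicate: dict[str, tuple[float, ...]] = {}
    if replicate_column is not None:
        for rep, sub in table.groupby(replicate_column):
            t_rep = sub.loc[sub["fate"] == "lysed", "t_lysis_min"].to_numpy(float)
            by_replicate[str(rep)] = tuple(_surviving_fraction(t_rep, len(sub), grid))
    return SurvivalCurve(
        times=tuple(float(t) for t in grid),
        pooled=tuple(float(f) for f in pooled),
        by_replicate=by_replicate,
    )


@dataclass(frozen=True)
class LysisComparison:
    """Mann-Whitney comparison of two lysis-time samples."""

    u_statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    percent_difference: float  # 100 * (mean_a - mean_b) / mean_b
    method: str


def lysis_time_comparison(
    times_a: Sequence[float], times_b: Sequence[float]
) -> LysisComparison:
    """Two-sided Mann-Whitney test on lysis times plus mean difference.

    Uses exact enumeration when both samples have at most 8 untied
    observations, otherwise the tie-corrected normal approximation.  The
    percent difference is relative to sample b.
    """
    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    if a.size < 2 or b.size < 2:
        raise ValueError("the test requires at least 2 observations per sample")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    # no continuity correction, so balanced samples give p = 1 exactly
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    mean_a, mean_b = float(a.mean()), float(b.mean())
    return LysisComparison(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_a=mean_a,
        mean_b=mean_b,
        percent_difference=100.0 * (mean_a - mean_b) / mean_b,
        method=method,
    )


@dataclass(frozen=True)
class LengthChange:
    """Relative change in mean cell length across phage exposure."""

    percent_change: float  # 100 * (mean_post - mean_pre) / mean_pre
    p_value: float
    mean_pre: float
    mean_post: float
    paired: bool


def length_change(
    lengths_pre: Sequence[float],
    lengths_post: Sequence[float],
    paired: bool = False,
) -> LengthChange:
    """Percent change of mean cell length with a rank-based test.

    Paired mode uses the Wilcoxon signed-rank test (requires equal-length,
    matched samples); unpaired mode uses the Mann-Whitney test.
    """
    pre = np.asarray(lengths_pre, dtype=float)
    post = np.asarray(lengths_post, dtype=float)
    if pre.size < 2 or post.size < 2:
        raise ValueError("need at least 2 measurements per group")
    if paired:
        if pre.size != post.size:
            raise ValueError("paired mode requires samples of equal length")
        diffs = post - pre
        if np.all(diffs == 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(diffs).pvalue)
    else:
        p = float(stats.mannwhitneyu(post, pre, alternative="two-sided").pvalue)
    mean_pre, mean_post = float(pre.mean()), float(post.mean())
    return LengthChange(
        percent_change=100.0 * (mean_post - mean_pre) / mean_pre,
        p_value=p,
        mean_pre=mean_pre,
        mean_post=mean_post,
        paired=paired,
    )
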