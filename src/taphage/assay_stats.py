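"""Competition-assay fitness and population-growth statistics.

The central quantity is the Wrightian relative fitness of a focal strain
against a reference strain over one incubation interval,

    w = (CFU_focal_t / CFU_focal_0) / (CFU_ref_t / CFU_ref_0),

the ratio of the two strains' fold-changes in colony-forming units.  Under
neutrality w = 1; w > 1 means the focal strain (e.g. one carrying an intact
toxin-antitoxin locus) out-survived the reference during phage exposure.

Inference on a set of replicate w values fits an intercept-only linear
model and tests the intercept against 1 (equivalent to a one-sample t-test
on w - 1), with a t-based 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

CFU_COLUMNS = (
    "replicate", "phage", "moi", "t_min",
    "cfu_focal_0", "cfu_focal_t", "cfu_ref_0", "cfu_ref_t",
)

GROWTH_COLUMNS = ("condition", "replicate", "t_min", "a600")


def read_cfu_table(path) -> pd.DataFrame:
    """Read a CFU competition table (TSV) and validate its columns."""
    table = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in CFU_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"CFU table {path} is missing columns: {missing}")
    return table


def read_growth_table(path) -> pd.DataFrame:
    """Read a long-format growth-curve table (TSV) and validate its columns."""
    table = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in GROWTH_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"growth table {path} is missing columns: {missing}")
    return table


def wrightian_fitness(
    cfu_focal_0: float, cfu_focal_t: float, cfu_ref_0: float, cfu_ref_t: float
) -> float:
    """Wrightian relative fitness of the focal strain over one interval.

    All four CFU values must be strictly positive; a zero or negative value
    raises ``ValueError`` naming the offending field.
    """
    fields = {
        "cfu_focal_0": cfu_focal_0,
        "cfu_focal_t": cfu_focal_t,
        "cfu_ref_0": cfu_ref_0,
        "cfu_ref_t": cfu_ref_t,
    }
    for name, value in fields.items():
        if not value > 0:
            raise ValueError(f"{name} must be > 0 for a computable fitness, got {value}")
    return (cfu_focal_t / cfu_focal_0) / (cfu_ref_t / cfu_ref_0)


def fitness_per_replicate(table: pd.DataFrame) -> pd.Series:
    """Per-replicate w for every row of a CFU table."""
    return table.apply(
        lambda row: wrightian_fitness(
            row["cfu_focal_0"], row["cfu_focal_t"], row["cfu_ref_0"], row["cfu_ref_t"]
        ),
        axis=1,
    )


@dataclass(frozen=True)
class FitnessResult:
    """Replicate fitness values with the test of the neutral null w = 1."""

    w: tuple[float, ...]
    mean_w: float
    ci95_low: float
    ci95_high: float
    t_statistic: float
    p_vs_1: float

    @property
    def n(self) -> int:
        return len(self.w)


def fitness_inference(values: Sequence[float]) -> FitnessResult:
    """Intercept-only regression of w with the null hypothesis intercept = 1.

    Equivalent to a one-sample t-test on w - 1.  The 95% confidence interval
    comes from the t distribution.  With zero variance the test degenerates:
    p = 1 when the common value is exactly 1, else p = 0, and the interval
    collapses to a point.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("fitness_inference requires at least 2 replicates")
    mean = float(arr.mean())
    if np.ptp(arr) == 0.0:
        p = 1.0 if mean == 1.0 else 0.0
        t_stat = 0.0 if mean == 1.0 else np.inf * np.sign(mean - 1.0)
        return FitnessResult(tuple(arr), mean, mean, mean, float(t_stat), p)
    model = sm.OLS(arr, np.ones_like(arr)).fit()
    test = model.t_test("const = 1")
    ci_low, ci_high = model.conf_int(alpha=0.05)[0]
    return FitnessResult(
        w=tuple(float(v) for v in arr),
        mean_w=mean,
        ci95_low=float(ci_low),
        ci95_high=float(ci_high),
        t_statistic=float(np.squeeze(test.tvalue)),
        p_vs_1=float(np.squeeze(test.pvalue)),
    )


@dataclass(frozen=True)
class BiomassComparison:
    """Endpoint biomass difference between two growth conditions."""

    percent_difference: float  # 100 * (mean_a - mean_b) / mean_b
    p_value: float
    mean_a: float
    mean_b: float
    t_eval: float  # grid time actually used
    n_a: int
    n_b: int


def endpoint_biomass_comparison(
    curves: pd.DataFrame,
    t_eval: float,
    condition_a: str,
    condition_b: str,
) -> BiomassComparison:
    """Compare mean absorbance of two conditions at one time point.

    ``curves`` is a long table (condition, replicate, t_min, a600).  The
    requested time snaps to the nearest recorded grid point within half the
    median sampling interval; outside that it is an error.  The p-value is a
    two-sample two-sided t-test across replicates.
    """
    times = np.sort(curves["t_min"].unique())
    if times.size == 0:
        raise ValueError("growth table has no time points")
    step = float(np.median(np.diff(times))) if times.size > 1 else np.inf
    nearest = float(times[np.argmin(np.abs(times - t_eval))])
    if abs(nearest - t_eval) > step / 2 + 1e-9:
        raise ValueError(
            f"t_eval={t_eval} is outside the recorded grid (nearest point {nearest})"
        )
    at_t = curves[curves["t_min"] == nearest]
    a = at_t.loc[at_t["condition"] == condition_a, "a600"].to_numpy(dtype=float)
    b = at_t.loc[at_t["condition"] == condition_b, "a600"].to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both conditions need >= 2 replicates at the evaluation time")
    percent = 100.0 * (a.mean() - b.mean()) / b.mean()
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b).pvalue)
    return BiomassComparison(
        percent_difference=float(percent),
        p_value=p,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_eval=nearest,
        n_a=int(a.size),
        n_b=int(b.size),
    )


@dataclass(frozen=True)
class FoldProtection:
    """Ratio of mean CFU with vs without the defence system."""

    fold: float
    ci95_low: float
    ci95_high: float
    n_boot: int


def cfu_fold_protection(
    cfu_with_system: Sequence[float],
    cfu_without_system: Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
) -> FoldProtection:
    """Fold increase in surviving CFU conferred by the defence system.

    Ratio of group means with a seeded percentile bootstrap 95% interval.
    """
    a = np.asarray(cfu_with_system, dtype=float)
    b = np.asarray(cfu_without_system, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups need at least one count")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("CFU counts must be strictly positive")
    fold = float(a.mean() / b.mean())
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, a.size, size=(n_boot, a.size))
    idx_b = rng.integers(0, b.size, size=(n_boot, b.size))
    ratios = a[idx_a].mean(axis=1) / b[idx_b].mean(axis=1)
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return FoldProtection(fold, float(lo), float(hi), n_boot)
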