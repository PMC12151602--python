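"""Cohort-level summaries of motif avoidance across genome classes.

Genomes are partitioned into three biologically motivated cohorts:

* ``ssRNA_phage_host`` — (+)ssRNA phages infecting the focal host genus
  (default *Escherichia*, where the MazF toxin cleaves ACA sites),
* ``non_ssRNA_phage`` — phages of bacterial hosts whose genomes are not
  (+)ssRNA,
* ``ssRNA_nonbacterial`` — (+)ssRNA viruses of non-bacterial hosts.

Per-genome relative motif frequencies are then summarized per cohort and
tested for departure from 1 (no bias).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .genome_io import GenomeRecord

logger = logging.getLogger(__name__)

COHORTS = ("ssRNA_phage_host", "non_ssRNA_phage", "ssRNA_nonbacterial", "unclassified")

#: Host strings that rule a genome out of any host-based cohort.
_NON_HOSTS = {"unknown", "unclassified", ""}


def assign_cohorts(
    records: Sequence[GenomeRecord], host_filter: str = "Escherichia"
) -> dict[str, list[GenomeRecord]]:
    """Partition records into the three cohorts plus an unclassified bin.

    Host matching is a case-insensitive prefix match on the genus string, so
    ``"Escherichia"`` matches ``"Escherichia coli"`` and broad-host entries
    such as ``"Escherichia; Pseudomonas"``.  Records whose host is
    ``"unclassified"`` or unknown, and (+)ssRNA phages of bacterial hosts
    other than the focal genus, land in the unclassified bin.  Every record
    lands in exactly one bin.
    """
    out: dict[str, list[GenomeRecord]] = {c: [] for c in COHORTS}
    prefix = host_filter.strip().lower()
    for rec in records:
        host = rec.host.strip().lower()
        is_ssrna = rec.moltype == "ssRNA+"
        if host in _NON_HOSTS or rec.moltype == "unknown":
            out["unclassified"].append(rec)
        elif host == "non-bacterial":
            if is_ssrna:
                out["ssRNA_nonbacterial"].append(rec)
            else:
                out["unclassified"].append(rec)
        elif is_ssrna:
            if host.startswith(prefix):
                out["ssRNA_phage_host"].append(rec)
            else:
                out["unclassified"].append(rec)
        else:
            out["non_ssRNA_phage"].append(rec)
    return out


@dataclass(frozen=True)
class DepartureTest:
    """One-sample test of mean relative frequency against 1."""

    statistic: float
    p_value: float
    direction: str  # "under", "over" or "none"
    method: str


def test_departure_from_1(
    values: Sequence[float], method: str = "wilcoxon"
) -> DepartureTest:
    """Two-sided one-sample test of relative frequency = 1.

    ``method`` is ``"wilcoxon"`` (signed-rank, default: robust to the skewed,
    bounded values) or ``"ttest"``.  Values all exactly 1 give p = 1 by
    convention.  Direction reports the side of the departure of the mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values to test departure from 1")
    mean = arr.mean()
    direction = "under" if mean < 1 else ("over" if mean > 1 else "none")
    diffs = arr - 1.0
    if np.all(diffs == 0):
        return DepartureTest(0.0, 1.0, "none", method)
    if method == "wilcoxon":
        stat, p = stats.wilcoxon(diffs)
    elif method == "ttest":
        res = stats.ttest_1samp(arr, popmean=1.0)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return DepartureTest(float(stat), float(p), direction, method)


# not a pytest test, despite the statistical naming convention
test_departure_from_1.__test__ = False  # type: ignore[attr-defined]


@dataclass(frozen=True)
class CohortSummary:
    """Summary of relative motif frequencies within one cohort."""

    cohort: str
    motif: str
    n_genomes: int
    values: tuple[float, ...]
    mean: float
    min: float
    max: float
    hist_edges: tuple[float, ...]
    hist_counts: tuple[int, ...]
    test: DepartureTest | None

    @property
    def p_vs_1(self) -> float | None:
        return None if self.test is None else self.test.p_value


def cohort_summary(
    values: Sequence[float],
    cohort: str = "custom",
    motif: str = "ACA",
    bin_width: float = 0.05,
    bin_range: tuple[float, float] = (0.0, 2.0),
    method: str = "wilcoxon",
) -> CohortSummary:
    """Summarize a cohort's relative frequencies.

    The histogram uses fixed-width bins over ``bin_range`` with an open-topped
    last bin (values above the range are counted in the final bin), mirroring
    the usual presentation with a dashed reference line at 1.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise ValueError("cohort_summary requires at least one value")
    lo, hi = bin_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    clipped = np.clip(arr, lo, np.nextafter(hi, lo))
    counts, _ = np.histogram(clipped, bins=edges)
    test = test_departure_from_1(arr, method=method) if arr.size >= 2 else None
    return CohortSummary(
        cohort=cohort,
        motif=motif,
        n_genomes=int(arr.size),
        values=tuple(float(v) for v in arr),
        mean=float(arr.mean()),
        min=float(arr.min()),
        max=float(arr.max()),
        hist_edges=tuple(float(e) for e in edges),
        hist_counts=tuple(int(c) for c in counts),
        test=test,
    )


def plot_cohorts(
    summaries: Mapping[str, CohortSummary], path: str, title: str | None = None
) -> None:
    """Histogram per cohort with a dashed reference line at relative frequency 1."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, max(len(summaries), 1), figsize=(4 * len(summaries), 3))
    if len(summaries) == 1:
        axes = [axes]
    for ax, (name, summ) in zip(np.atleast_1d(axes), summaries.items()):
        edges = np.asarray(summ.hist_edges)
        ax.bar(edges[:-1], summ.hist_counts, width=np.diff(edges), align="edge")
        ax.axvline(1.0, linestyle="--", color="grey")
        ax.set_title(f"{name} ({summ.motif}, n={summ.n_genomes})")
        ax.set_xlabel("relative frequency")
        ax.set_ylabel("genomes")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
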