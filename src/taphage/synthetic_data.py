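"""Generators for synthetic inputs with controlled ground truth.

Every stage of the analysis can be exercised without downloads: genomes of
given length and base composition with a tunable motif-avoidance factor,
CFU competition tables with a known survival-probability ratio between
strains, logistic growth curves with a known final-yield ratio, and
per-cell fate tables with known lysis fraction and lysis-time distribution.
All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeRecord, RNA_BASES
from .motif_stats import (
    IUPAC_EXPAND,
    _BASE_CODE,
    _count_encoded,
    _motif_masks,
    base_fractions,
    expected_count,
)

_CODE_BASE = {i: b for b, i in _BASE_CODE.items()}


@dataclass(frozen=True)
class GenomeSimSpec:
    """Recipe for one synthetic genome.

    ``avoidance`` is the target relative motif frequency: 1 means a plain
    i.i.d. draw from the composition, values below 1 are enforced by
    disrupting motif occurrences, values above 1 by creating them.
    """

    length: int
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif: str = "ACA"
    avoidance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        comp = np.asarray(self.composition, dtype=float)
        if comp.size != 4 or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("composition must be 4 non-negative fractions summing to 1")
        if self.length < len(self.motif):
            raise ValueError("length must be at least the motif length")
        if self.avoidance < 0:
            raise ValueError("avoidance must be >= 0")


def _draw_iid(spec: GenomeSimSpec, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(4, size=spec.length, p=np.asarray(spec.composition)).astype(np.int8)


def simulate_genome(spec: GenomeSimSpec, record_id: str = "sim") -> GenomeRecord:
    """Generate one genome with the requested motif avoidance.

    For ``avoidance == 1`` the sequence is an i.i.d. draw from the
    composition.  For ``avoidance < 1`` motif occurrences are disrupted one
    at a time — a uniformly chosen occurrence has its centre base replaced by
    a random base that breaks the match, rescanning after each edit — until
    the observed count first falls to or below ``avoidance`` times the
    expected count under the *current* composition.  For ``avoidance > 1``
    near-miss windows are completed the same way until the count first
    reaches the target; an unreachable target raises ``ValueError``.

    The realized count and composition are recorded in the description.
    The record is marked as a complete ssRNA+ genome of host "synthetic".
    """
    rng = np.random.default_rng(spec.seed)
    codes = _draw_iid(spec, rng)
    masks = _motif_masks(spec.motif)
    k = len(spec.motif)
    center = k // 2
    center_bases = set(IUPAC_EXPAND[spec.motif[center]])
    breaking = [_BASE_CODE[b] for b in RNA_BASES if b not in center_bases]
    completing = [_BASE_CODE[b] for b in center_bases]

    def occurrences() -> np.ndarray:
        n_windows = codes.size - k + 1
        hit = masks[0][codes[:n_windows]]
        for j in range(1, k):
            hit &= masks[j][codes[j : j + n_windows]]
        return np.flatnonzero(hit)

    def target() -> float:
        return spec.avoidance * expected_count(base_fractions(codes), spec.motif)

    max_edits = 10 * spec.length  # safety against pathological cycles
    if spec.avoidance < 1.0:
        if not breaking:
            raise ValueError("motif centre admits every base; avoidance is unreachable")
        edits = 0
        while True:
            occ = occurrences()
            if occ.size <= target():
                break
            if edits >= max_edits:
                raise ValueError(f"could not reach avoidance {spec.avoidance}")
            pos = int(rng.choice(occ))
            codes[pos + center] = rng.choice(breaking)
            edits += 1
    elif spec.avoidance > 1.0:
        edits = 0
        while True:
            occ = occurrences()
            if occ.size >= target():
                break
            if edits >= max_edits:
                raise ValueError(f"could not reach avoidance {spec.avoidance}")
            edits += 1
            n_windows = codes.size - k + 1
            near = np.ones(n_windows, dtype=bool)
            for j in range(k):
                if j == center:
                    continue
                near &= masks[j][codes[j : j + n_windows]]
            near &= ~masks[center][codes[center : center + n_windows]]
            candidates = np.flatnonzero(near)
            if candidates.size == 0:
                raise ValueError(
                    f"avoidance {spec.avoidance} is unreachable: no window can be "
                    "converted into a motif occurrence"
                )
            pos = int(rng.choice(candidates))
            codes[pos + center] = rng.choice(completing)

    sequence = "".join(_CODE_BASE[int(c)] for c in codes)
    realized = _count_encoded(codes, masks)
    comp = base_fractions(codes)
    description = (
        f"synthetic genome motif={spec.motif} avoidance={spec.avoidance} "
        f"count={realized} "
        f"comp=A:{comp.fraction_a:.4f},C:{comp.fraction_c:.4f},"
        f"G:{comp.fraction_g:.4f},U:{comp.fraction_u:.4f}"
    )
    return GenomeRecord(
        id=record_id,
        description=description,
        sequence=sequence,
        moltype="ssRNA+",
        host="synthetic",
        complete=True,
    )


def simulate_genomes(spec: GenomeSimSpec, n: int, id_prefix: str = "sim") -> list[GenomeRecord]:
    """Generate ``n`` independent genomes by spawning substreams of the seed."""
    children = np.random.SeedSequence(spec.seed).spawn(n)
    records = []
    for i, child in enumerate(children):
        sub = GenomeSimSpec(
            length=spec.length,
            composition=spec.composition,
            motif=spec.motif,
            avoidance=spec.avoidance,
            seed=int(child.generate_state(1, dtype=np.uint32)[0]),
        )
        records.append(simulate_genome(sub, record_id=f"{id_prefix}{i:04d}"))
    return records


@dataclass(frozen=True)
class AssaySimSpec:
    """Recipe for a synthetic competition assay.

    Each strain starts at ``initial_cfu`` cells; phage exposure thins each
    strain binomially by its survival probability, after which both strains
    grow by the same deterministic fold.  The expected relative fitness is
    therefore survival_prob_focal / survival_prob_ref — the growth cancels.
    """

    n_replicates: int = 6
    initial_cfu: int = 100_000
    survival_prob_focal: float = 0.575
    survival_prob_ref: float = 0.5
    growth_fold: float = 10.0
    phage: str = "synthetic"
    moi: float = 0.1
    t_min: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("survival_prob_focal", "survival_prob_ref"):
            p = getattr(self, name)
            if not 0 < p <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {p}")
        if self.initial_cfu < 1:
            raise ValueError("initial_cfu must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def simulate_competition(spec: AssaySimSpec) -> pd.DataFrame:
    """Synthetic CFU table with the schema used by the fitness statistics."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for rep in range(spec.n_replicates):
        survivors_focal = rng.binomial(spec.initial_cfu, spec.survival_prob_focal)
        survivors_ref = rng.binomial(spec.initial_cfu, spec.survival_prob_ref)
        rows.append(
            {
                "replicate": f"r{rep:03d}",
                "phage": spec.phage,
                "moi": spec.moi,
                "t_min": spec.t_min,
                "cfu_focal_0": spec.initial_cfu,
                "cfu_focal_t": survivors_focal * spec.growth_fold,
                "cfu_ref_0": spec.initial_cfu,
                "cfu_ref_t": survivors_ref * spec.growth_fold,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FateSimSpec:
    """Recipe for a synthetic per-cell fate table.

    Fates are drawn from a categorical distribution; lysed cells receive a
    lysis time from a right-skewed positive distribution (lognormal by
    default) truncated at the end of observation.  ``shift`` multiplies the
    time scale (e.g. 1.23 for a 23% longer mean time to lysis).
    """

    n_cells: int = 200
    lysis_fraction: float = 0.4
    arrest_fraction: float = 0.02
    filament_fraction: float = 0.01
    arrest_and_filament_fraction: float = 0.005
    family: str = "lognormal"  # or "gamma"
    median_minutes: float = 150.0
    sigma_log: float = 0.4
    shift: float = 1.0
    mean_length_um: float = 3.0
    length_cv: float = 0.15
    length_shift: float = 1.0  # multiplies post-exposure lengths
    observation_end: float = 650.0
    condition: str = "wt"
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = (
            self.lysis_fraction,
            self.arrest_fraction,
            self.filament_fraction,
            self.arrest_and_filament_fraction,
        )
        if any(not 0 <= f <= 1 for f in fractions) or sum(fractions) > 1:
            raise ValueError("fate fractions must lie in [0,1] and jointly sum to <= 1")
        if self.observation_end <= 0:
            raise ValueError("observation_end must be positive")
        if self.shift <= 0:
            raise ValueError("shift must be positive")


def _draw_lysis_times(spec: FateSimSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    scale = spec.median_minutes * spec.shift
    times = np.empty(0)
    while times.size < n:
        if spec.family == "lognormal":
            draw = scale * np.exp(spec.sigma_log * rng.standard_normal(2 * n))
        elif spec.family == "gamma":
            shape = 1.0 / spec.sigma_log**2
            draw = rng.gamma(shape, scale / shape, size=2 * n)
        else:
            raise ValueError(f"unknown lysis-time family {spec.family!r}")
        times = np.concatenate([times, draw[draw <= spec.observation_end]])
    return times[:n]


def simulate_cell_fates(spec: FateSimSpec) -> pd.DataFrame:
    """Synthetic per-cell fate table with the schema used by the fate statistics."""
    rng = np.random.default_rng(spec.seed)
    probs = np.array(
        [
            spec.lysis_fraction,
            spec.arrest_fraction,
            spec.filament_fraction,
            spec.arrest_and_filament_fraction,
        ]
    )
    probs = np.append(probs, 1.0 - probs.sum())
    labels = ["lysed", "growth_arrested", "filamented", "arrested_and_filamented", "survived"]
    fates = rng.choice(labels, size=spec.n_cells, p=probs)
    n_lysed = int(np.sum(fates == "lysed"))
    lysis_times = _draw_lysis_times(spec, n_lysed, rng)
    pre = spec.mean_length_um * (1.0 + spec.length_cv * rng.standard_normal(spec.n_cells))
    pre = np.clip(pre, 0.5, None)
    post = pre * spec.length_shift * (1.0 + 0.02 * rng.standard_normal(spec.n_cells))
    rows = []
    lysed_seen = 0
    for i, fate in enumerate(fates):
        t_lysis = np.nan
        if fate == "lysed":
            t_lysis = float(lysis_times[lysed_seen])
            lysed_seen += 1
        rows.append(
            {
                "cell_id": f"c{i:05d}",
                "condition": spec.condition,
                "fate": fate,
                "t_lysis_min": t_lysis,
                "length_pre_um": float(pre[i]),
                "length_post_um": float(post[i]),
                "observation_end_min": spec.observation_end,
            }
        )
    return pd.DataFrame(rows)


def simulate_growth_curves(
    final_yields: dict[str, float],
    n_replicates: int = 5,
    noise_cv: float = 0.05,
    a0: float = 0.02,
    rate: float = 0.02,
    t_max: float = 600.0,
    dt: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Logistic growth curves per condition with replicate-level yield noise.

    Each replicate follows A(t) = K / (1 + (K/A0 - 1) e^(-rt)) with its
    carrying capacity K drawn around the condition's final yield with the
    given coefficient of variation.  Output is a long table
    (condition, replicate, t_min, a600) on a uniform 5-minute-style grid.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_max + dt / 2, dt)
    rows = []
    for condition, yield_ in final_yields.items():
        for rep in range(n_replicates):
            K = yield_ * (1.0 + noise_cv * rng.standard_normal())
            K = max(K, 2 * a0)
            curve = K / (1.0 + (K / a0 - 1.0) * np.exp(-rate * times))
            for t, a in zip(times, curve):
                rows.append(
                    {
                        "condition": condition,
                        "replicate": f"r{rep:02d}",
                        "t_min": float(t),
                        "a600": float(a),
                    }
                )
    return pd.DataFrame(rows)
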