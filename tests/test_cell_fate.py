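import itertools
import math

import numpy as np
import pandas as pd
import pytest

from taphage.cell_fate import (
    FATES,
    fate_fractions,
    length_change,
    lysis_time_comparison,
    survival_curve,
    validate_fate_table,
)
from taphage.synthetic_data import FateSimSpec, simulate_cell_fates


def make_table(fates, t_lysis=None, end=650.0, condition="wt"):
    t_lysis = t_lysis or {}
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(len(fates))],
            "condition": condition,
            "fate": fates,
            "t_lysis_min": [t_lysis.get(i, np.nan) for i in range(len(fates))],
            "length_pre_um": 3.0,
            "length_post_um": 3.0,
            "observation_end_min": end,
        }
    )


def test_fate_fractions_pooled_percentage():
    # 103 of 289 lysed -> 35.6% at one decimal
    fates = ["lysed"] * 103 + ["survived"] * 186
    table = make_table(fates, {i: 100.0 for i in range(103)})
    frac = fate_fractions(table)
    lysed = frac.set_index("fate").loc["lysed"]
    assert lysed["count"] == 103
    assert round(lysed["percent"], 1) == 35.6
    assert frac["percent"].sum() == pytest.approx(100.0)


def test_fate_fractions_edge_cases():
    all_survived = fate_fractions(make_table(["survived"] * 5))
    assert all_survived.set_index("fate").loc["lysed", "percent"] == 0.0
    one_lysed = fate_fractions(make_table(["lysed"], {0: 10.0}))
    assert one_lysed.set_index("fate").loc["lysed", "percent"] == 100.0


def test_fate_validation():
    bad = make_table(["exploded"])
    with pytest.raises(ValueError, match="unknown fate"):
        validate_fate_table(bad)
    missing_time = make_table(["lysed"])
    with pytest.raises(ValueError, match="t_lysis"):
        validate_fate_table(missing_time)
    late = make_table(["lysed"], {0: 9000.0})
    with pytest.raises(ValueError, match="observation_end"):
        validate_fate_table(late)


def test_survival_no_lysis_is_constant_one():
    curve = survival_curve(make_table(["survived"] * 10))
    assert all(f == 1.0 for f in curve.pooled)


def test_survival_steps_at_common_lysis_time():
    table = make_table(["lysed"] * 4, {i: 10.0 for i in range(4)})
    curve = survival_curve(table, grid=[0, 5, 10, 15])
    assert curve.pooled == (1.0, 1.0, 0.0, 0.0)


def test_survival_matches_empirical_cdf_oracle():
    rng = np.random.default_rng(19)
    times = rng.uniform(0, 600, size=80)
    fates = ["lysed"] * 80 + ["survived"] * 20
    table = make_table(fates, dict(enumerate(times)))
    grid = np.arange(0, 651, 5.0)
    curve = survival_curve(table, grid=grid)
    for t, frac in zip(curve.times, curve.pooled):
        ecdf = np.mean(times <= t) * 80 / 100  # brute-force fraction lysed by t
        assert frac == pytest.approx(1.0 - ecdf, abs=1e-12)


def test_survival_end_equals_one_minus_lysed_fraction():
    spec = FateSimSpec(n_cells=300, lysis_fraction=0.4, seed=5)
    table = simulate_cell_fates(spec)
    curve = survival_curve(table)
    lysed_fraction = (table["fate"] == "lysed").mean()
    assert curve.pooled[-1] == pytest.approx(1.0 - lysed_fraction, abs=1e-12)


def test_survival_per_replicate_curves():
    table = pd.concat(
        [
            make_table(["lysed"] * 2, {0: 10.0, 1: 20.0}).assign(rep="r1"),
            make_table(["survived"] * 2).assign(rep="r2"),
        ],
        ignore_index=True,
    )
    table["cell_id"] = [f"c{i}" for i in range(len(table))]
    curve = survival_curve(table, grid=[0, 30], replicate_column="rep")
    assert curve.by_replicate["r1"][-1] == 0.0
    assert curve.by_replicate["r2"][-1] == 1.0
    assert curve.pooled[-1] == 0.5


def test_lysis_comparison_identical_samples():
    res = lysis_time_comparison([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
    assert res.p_value == pytest.approx(1.0)
    assert res.percent_difference == pytest.approx(0.0)


def test_lysis_comparison_exact_small_sample():
    res = lysis_time_comparison([1, 2, 3], [4, 5, 6])
    assert res.u_statistic == 0.0
    assert res.method == "exact"
    assert res.p_value == pytest.approx(0.1)


def test_lysis_comparison_rejects_tiny_samples():
    with pytest.raises(ValueError):
        lysis_time_comparison([1.0], [2.0, 3.0])


def brute_force_mannwhitney(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all group labellings."""
    a, b = list(a), list(b)
    combined = a + b
    n1 = len(a)
    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    us = []
    for idx in itertools.combinations(range(len(combined)), n1):
        grp = [combined[i] for i in idx]
        rest = [combined[i] for i in range(len(combined)) if i not in idx]
        us.append(
            sum(1 for x in grp for y in rest if x > y)
            + 0.5 * sum(1 for x in grp for y in rest if x == y)
        )
    us = np.array(us)
    p = 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return min(p, 1.0)


def test_mannwhitney_matches_enumeration_small_samples():
    rng = np.random.default_rng(40)
    for n1 in range(2, 7):
        for n2 in range(2, 7):
            draw = rng.permutation(100)[: n1 + n2].astype(float)  # distinct values
            a, b = draw[:n1], draw[n1:]
            res = lysis_time_comparison(a, b)
            assert res.p_value == pytest.approx(brute_force_mannwhitney(a, b), abs=1e-12)


def test_lysis_shift_power():
    """A 23% scale shift at n = 100 per group is detected at alpha = 0.001 in
    at least 90% of simulations (lognormal times, sigma 0.25)."""
    rng = np.random.default_rng(91)
    hits = 0
    n_sim = 500
    for _ in range(n_sim):
        a = 150 * 1.23 * np.exp(0.25 * rng.standard_normal(100))
        b = 150 * np.exp(0.25 * rng.standard_normal(100))
        if lysis_time_comparison(a, b).p_value < 0.001:
            hits += 1
    assert hits / n_sim >= 0.90


def test_length_change_elementwise_shift():
    pre = np.array([2.0, 3.0, 4.0, 2.5])
    res = length_change(pre, 1.07 * pre, paired=True)
    assert res.percent_change == pytest.approx(7.0)
    assert res.p_value < 0.2  # consistently positive shift


def test_length_change_identical_distributions():
    pre = np.array([2.0, 3.0, 4.0, 2.5, 3.1])
    res = length_change(pre, pre, paired=True)
    assert res.percent_change == pytest.approx(0.0)
    assert res.p_value == 1.0


def test_length_change_mismatched_pairs_rejected():
    with pytest.raises(ValueError, match="equal length"):
        length_change([1.0, 2.0], [1.0, 2.0, 3.0], paired=True)


def test_length_change_recovery_from_simulated_cells():
    """Simulated 4% elongation recovered within [2%, 6%] in >= 90% of runs."""
    hits = 0
    n_sim = 200
    for i in range(n_sim):
        table = simulate_cell_fates(
            FateSimSpec(n_cells=250, lysis_fraction=0.3, length_shift=1.04, seed=1000 + i)
        )
        res = length_change(
            table["length_pre_um"], table["length_post_um"], paired=True
        )
        if 2.0 <= res.percent_change <= 6.0:
            hits += 1
    assert hits / n_sim >= 0.90
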