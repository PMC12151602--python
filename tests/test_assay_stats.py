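import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from taphage.assay_stats import (
    cfu_fold_protection,
    endpoint_biomass_comparison,
    fitness_inference,
    wrightian_fitness,
)
from taphage.synthetic_data import simulate_growth_curves

positive = st.floats(min_value=1e-3, max_value=1e9, allow_nan=False, allow_infinity=False)


def test_wrightian_fitness_examples():
    assert wrightian_fitness(100, 200, 100, 100) == pytest.approx(2.0)
    assert wrightian_fitness(50, 500, 80, 800) == pytest.approx(1.0)


@pytest.mark.parametrize("field", ["cfu_focal_0", "cfu_focal_t", "cfu_ref_0", "cfu_ref_t"])
def test_zero_cfu_rejected_naming_field(field):
    kwargs = dict(cfu_focal_0=10, cfu_focal_t=10, cfu_ref_0=10, cfu_ref_t=10)
    kwargs[field] = 0
    with pytest.raises(ValueError, match=field):
        wrightian_fitness(**kwargs)


@given(positive, positive, positive, positive, st.floats(min_value=1e-3, max_value=1e3))
@settings(deadline=None, max_examples=100)
def test_fitness_scale_invariance(f0, ft, r0, rt, c):
    w = wrightian_fitness(f0, ft, r0, rt)
    scaled = wrightian_fitness(c * f0, c * ft, c * r0, c * rt)
    assert scaled == pytest.approx(w, rel=1e-9)


@given(positive, positive, positive, positive)
@settings(deadline=None, max_examples=100)
def test_strain_swap_inverts_fitness(f0, ft, r0, rt):
    w = wrightian_fitness(f0, ft, r0, rt)
    assert wrightian_fitness(r0, rt, f0, ft) == pytest.approx(1.0 / w, rel=1e-9)


def test_fitness_inference_degenerate_neutral():
    res = fitness_inference([1.0, 1.0, 1.0])
    assert res.p_vs_1 == 1.0
    assert res.ci95_low == res.ci95_high == 1.0


def test_fitness_inference_matches_closed_form_t():
    values = [1.2, 1.3, 1.4]
    res = fitness_inference(values)
    assert res.mean_w == pytest.approx(1.3)
    # closed-form one-sample t with df = 2
    arr = np.array(values)
    t = (arr.mean() - 1.0) / (arr.std(ddof=1) / math.sqrt(3))
    p = 2 * sps.t.sf(abs(t), df=2)
    assert res.t_statistic == pytest.approx(t, abs=1e-10)
    assert res.p_vs_1 == pytest.approx(p, abs=1e-10)
    ref = sps.ttest_1samp(arr, popmean=1.0)
    assert res.p_vs_1 == pytest.approx(float(ref.pvalue), abs=1e-10)
    # t-based 95% CI
    half = sps.t.ppf(0.975, df=2) * arr.std(ddof=1) / math.sqrt(3)
    assert res.ci95_low == pytest.approx(arr.mean() - half, abs=1e-10)
    assert res.ci95_high == pytest.approx(arr.mean() + half, abs=1e-10)


def test_fitness_inference_requires_replicates():
    with pytest.raises(ValueError):
        fitness_inference([1.1])


def test_binomial_thinning_recovers_fitness_ratio():
    """Survival probabilities 0.6 vs 0.465 give mean w near their ratio 1.29."""
    rng = np.random.default_rng(31)
    n0 = 100_000
    w = []
    for _ in range(200):
        focal = rng.binomial(n0, 0.6)
        ref = rng.binomial(n0, 0.465)
        w.append(wrightian_fitness(n0, focal, n0, ref))
    w = np.array(w)
    se = w.std(ddof=1) / math.sqrt(len(w))
    assert abs(w.mean() - 0.6 / 0.465) <= 3 * se


def _flat_curves(levels, times=(0.0, 5.0, 10.0)):
    rows = []
    for condition, values in levels.items():
        for rep, value in enumerate(values):
            for t in times:
                rows.append(
                    {"condition": condition, "replicate": f"r{rep}", "t_min": t, "a600": value}
                )
    return pd.DataFrame(rows)


def test_endpoint_identical_conditions():
    curves = _flat_curves({"a": [1.0, 1.1, 0.9], "b": [1.0, 1.1, 0.9]})
    res = endpoint_biomass_comparison(curves, 10.0, "a", "b")
    assert res.percent_difference == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_endpoint_22_percent_definition():
    curves = _flat_curves({"a": [1.22, 1.22], "b": [1.0, 1.0]})
    res = endpoint_biomass_comparison(curves, 10.0, "a", "b")
    assert res.percent_difference == pytest.approx(22.0)


def test_endpoint_time_outside_grid_rejected():
    curves = _flat_curves({"a": [1.0, 1.0], "b": [1.0, 1.0]})
    with pytest.raises(ValueError, match="grid"):
        endpoint_biomass_comparison(curves, 1000.0, "a", "b")


def test_endpoint_snaps_to_nearest_grid_point():
    curves = _flat_curves({"a": [1.5, 1.4], "b": [1.0, 1.1]})
    res = endpoint_biomass_comparison(curves, 9.0, "a", "b")
    assert res.t_eval == 10.0


def test_logistic_yield_ratio_recovered():
    """Logistic growth with a 22% final-yield ratio and 5% replicate noise:
    the estimated endpoint difference stays within [12%, 32%] in at least
    95% of simulations."""
    rng = np.random.default_rng(52)
    hits = 0
    n_sim = 200
    for i in range(n_sim):
        curves = simulate_growth_curves(
            {"wt": 1.22, "delta": 1.0},
            n_replicates=5,
            noise_cv=0.05,
            seed=int(rng.integers(2**31)),
        )
        res = endpoint_biomass_comparison(curves, 600.0, "wt", "delta")
        if 12.0 <= res.percent_difference <= 32.0:
            hits += 1
    assert hits / n_sim >= 0.95


def test_fold_protection_examples():
    res = cfu_fold_protection([170, 170], [100, 100], n_boot=100, seed=1)
    assert res.fold == pytest.approx(1.7)
    same = cfu_fold_protection([5, 6, 7], [5, 6, 7], n_boot=100, seed=1)
    assert same.fold == pytest.approx(1.0)


def test_fold_protection_zero_rejected():
    with pytest.raises(ValueError):
        cfu_fold_protection([0, 10], [10, 10])


def test_fold_protection_bootstrap_coverage():
    """The bootstrap interval covers the true 2.5-fold ratio in roughly 95%
    of simulated Poisson-count datasets (n = 6 per group)."""
    rng = np.random.default_rng(63)
    true_ratio = 2.5
    covered = 0
    n_sim = 300
    for _ in range(n_sim):
        with_sys = rng.poisson(250, size=6) + 1
        without = rng.poisson(100, size=6) + 1
        res = cfu_fold_protection(with_sys, without, n_boot=600, seed=int(rng.integers(2**31)))
        if res.ci95_low <= true_ratio <= res.ci95_high:
            covered += 1
    assert 0.85 <= covered / n_sim <= 0.995
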