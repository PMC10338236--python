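"""Empirical indicator estimators and the composite combination."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ewsbif import (CompositeWeights, ConfigurationError, DomainError,
                    EstimatorError, IndicatorSeries, NoiseSpec, autocatalytic,
                    composite, estimate, estimate_sweep, sweep)
from ewsbif.theory import entropy_gaussian, stationary_variance


def test_mean_and_variance_use_n_minus_1():
    assert estimate([0.0, 2.0], "mean") == 1.0
    assert estimate([0.0, 2.0], "var") == 2.0


def test_uniform_histogram_entropy_is_log_bins():
    # 4 equal-mass bins on explicit edges -> HS = log 4
    samples = np.repeat([0.5, 1.5, 2.5, 3.5], 25)
    hs = estimate(samples, "hs", edges=np.arange(5.0))
    assert hs == pytest.approx(math.log(4), abs=1e-12)


def test_autocorrelation_time_definition():
    # a series whose lag-1 autocorrelation is exactly e^-1 gives ACT = 1
    x = np.array([1.0, -1.0] * 50, dtype=float)
    with pytest.raises(EstimatorError):
        estimate(x, "act")  # ac1 = -1 is outside (0, 1)
    rng = np.random.default_rng(0)
    y = np.empty(20000)
    y[0] = 0.0
    rho = math.exp(-1.0)
    eps = rng.standard_normal(len(y))
    for i in range(1, len(y)):
        y[i] = rho * y[i - 1] + eps[i]
    r = estimate(y, "ac1")
    assert r == pytest.approx(rho, abs=0.02)
    assert estimate(y, "act") == pytest.approx(-1.0 / math.log(r), abs=1e-12)


def test_estimator_errors():
    with pytest.raises(EstimatorError):
        estimate([1.0, 1.0, 1.0], "ac1")  # constant series
    with pytest.raises(EstimatorError):
        estimate([1.0], "var")
    with pytest.raises(ConfigurationError):
        estimate([1.0, 2.0], "nope")


def test_variance_on_standard_normal_draws():
    n = 4000
    x = np.random.default_rng(5).standard_normal(n)
    assert abs(estimate(x, "var") - 1.0) < 4 / math.sqrt(n)


def test_gaussian_plugin_entropy_matches_closed_form():
    x = np.random.default_rng(1).normal(2.0, 0.3, size=500)
    assert estimate(x, "hs", hs_method="gaussian") == pytest.approx(
        entropy_gaussian(float(np.var(x, ddof=1))), abs=1e-14)


@pytest.fixture(scope="module")
def additive_sweep_series():
    model = autocatalytic(2.4)
    sw = sweep(model, NoiseSpec(0.1), [2.4, 2.1, 1.95, 1.85], n_traj=40,
               n_samples=30, dt_sample=5.0, seed=8)
    # exclude escaped trajectories: the comparison target is the
    # linearized on-branch theory
    return sw, estimate_sweep(sw, ("var", "ac1", "hs"), B=50, seed=8,
                              exclude_tipped=True)


def test_sweep_variance_tracks_theory(additive_sweep_series):
    from ewsbif import decay_rate
    sw, series = additive_sweep_series
    for i, c in enumerate(sw.c_grid):
        k = decay_rate(autocatalytic(float(c)))
        target = stationary_variance(k, 0.1**2)
        boot_se = series.boot["var"][i].std(ddof=1)
        assert abs(series.point["var"][i] - target) < 3.5 * max(boot_se, 1e-4)


def test_noise_free_sweep_has_flat_zero_variance():
    sw = sweep(autocatalytic(2.3), NoiseSpec(0.0), [2.3, 2.1], n_traj=5,
               n_samples=20, dt_sample=5.0, seed=0)
    series = estimate_sweep(sw, ("var",), B=10, seed=0)
    assert np.all(series.point["var"] < 1e-12)


def test_ac1_insensitive_to_noise_functional():
    """Lag autocorrelation depends only on the decay rate, not on whether
    the noise is additive or multiplicative."""
    model = autocatalytic(2.2)
    kw = dict(n_traj=40, n_samples=60, dt_sample=1.0, seed=14)
    sw_add = sweep(model, NoiseSpec(0.05, alpha=1.0), [2.2, 2.0], **kw)
    sw_mult = sweep(model, NoiseSpec(0.05, alpha=0.0, h_kind="x"),
                    [2.2, 2.0], **kw)
    s_add = estimate_sweep(sw_add, ("ac1",), B=50, seed=14)
    s_mult = estimate_sweep(sw_mult, ("ac1",), B=50, seed=15)
    for i in range(2):
        a, b = s_add.boot["ac1"][i], s_mult.boot["ac1"][i]
        se = np.hypot(a.std(ddof=1), b.std(ddof=1))
        assert abs(a.mean() - b.mean()) < 4 * se


def test_composite_weight_validation():
    with pytest.raises(ConfigurationError):
        CompositeWeights(("var", "hs"), (0.5, 0.6))
    with pytest.raises(ConfigurationError):
        CompositeWeights(("var", "hs"), (1.5, -0.5))


def test_composite_single_weight_is_standardized_component(additive_sweep_series):
    _, series = additive_sweep_series
    comp = composite(series, CompositeWeights(("var", "ac1", "hs"), (1.0, 0.0, 0.0)))
    arr = series.boot["var"]
    mu, sd = arr[0].mean(), arr[0].std(ddof=1)
    np.testing.assert_allclose(comp.boot["composite"], (arr - mu) / sd)
    # baseline level is centred at ~0 by construction
    assert abs(comp.boot["composite"][0].mean()) < 1e-12


def test_composite_increases_toward_bifurcation(additive_sweep_series):
    _, series = additive_sweep_series
    comp = composite(series, CompositeWeights(("var", "ac1", "hs"),
                                              (0.5, 0.0, 0.5)))
    means = comp.boot["composite"].mean(axis=1)
    assert means[-1] > means[0] + 3.0  # strong standardized increase


def test_composite_degenerate_baseline():
    levels = np.array([0.0, 1.0])
    boot = {"var": np.array([[1.0, 1.0, 1.0], [2.0, 3.0, 4.0]])}
    series = IndicatorSeries(levels, boot, {"var": np.array([1.0, 3.0])})
    with pytest.raises(DomainError):
        composite(series, CompositeWeights(("var",), (1.0,)))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(w1=st.floats(0.0, 1.0), split=st.floats(0.0, 1.0))
def test_composite_is_linear_in_weights(w1, split):
    rng = np.random.default_rng(42)
    levels = np.arange(3.0)
    boot = {"var": rng.normal(1.0, 0.2, (3, 20)),
            "hs": rng.normal(0.5, 0.1, (3, 20))}
    point = {k: v.mean(axis=1) for k, v in boot.items()}
    series = IndicatorSeries(levels, boot, point)
    w2 = 1.0 - w1
    full = composite(series, CompositeWeights(("var", "hs"), (w1, w2)))
    # decompose: w1*(split applied)... additivity per replicate
    a = composite(series, CompositeWeights(("var", "hs"), (1.0, 0.0)))
    b = composite(series, CompositeWeights(("var", "hs"), (0.0, 1.0)))
    np.testing.assert_allclose(
        full.boot["composite"],
        w1 * a.boot["composite"] + w2 * b.boot["composite"], atol=1e-10)
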