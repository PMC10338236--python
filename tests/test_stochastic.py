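"""Milstein integrator, ensembles, ramps and tipping counts."""

import numpy as np
import pytest

from ewsbif import (DomainError, ModelSpec, NoiseSpec, autocatalytic,
                    count_tipping, milstein_step, simulate_ensemble,
                    simulate_ramp, sweep)
from ewsbif.theory import ramping_moments, stationary_variance


def test_milstein_equals_euler_maruyama_for_constant_diffusion():
    rng = np.random.default_rng(0)
    x = rng.normal(size=200)
    dW = rng.normal(scale=0.1, size=200)
    f = lambda s: -0.7 * s  # noqa: E731
    g = lambda s: 0.3 * np.ones_like(s)  # noqa: E731
    mil = milstein_step(x, f, g, 0.01, dW, lambda s: np.zeros_like(s))
    em = x + f(x) * 0.01 + 0.3 * dW
    np.testing.assert_array_equal(mil, em)  # bit-identical


def test_milstein_multiplicative_correction():
    # f = 0, g(x) = x at x = 1: x' = 1 + dW + (dW^2 - dt)/2
    dW, dt = 0.3, 0.01
    out = milstein_step(1.0, lambda s: 0.0 * s, lambda s: s, dt, dW,
                        lambda s: np.ones_like(s))
    assert out == pytest.approx(1 + dW + 0.5 * (dW**2 - dt), abs=1e-15)
    # finite-difference fallback for the diffusion derivative agrees
    out_fd = milstein_step(1.0, lambda s: 0.0 * s, lambda s: s, dt, dW)
    assert out_fd == pytest.approx(out, abs=1e-8)


def test_ou_ensemble_matches_stationary_variance():
    # pure linear decay (ramp with a = 0) is the OU process
    k, sigma = 1.0, 0.2
    t, y = simulate_ramp(k, 0.0, NoiseSpec(sigma), n_traj=200, t_end=60.0,
                         seed=4, y0=0.0)
    tail = y[:, t > 10.0]
    var_hat = tail.var(ddof=1)
    target = stationary_variance(k, sigma**2)  # 0.02
    # MC standard error from per-trajectory variance spread
    se = tail.var(axis=1, ddof=1).std(ddof=1) / np.sqrt(tail.shape[0])
    assert abs(var_hat - target) < 3 * se


def test_deterministic_and_reproducible():
    m = autocatalytic(2.2)
    ens0 = simulate_ensemble(m, NoiseSpec(0.0), n_traj=3, n_samples=50, seed=1)
    x_eq = ens0.x0
    np.testing.assert_allclose(ens0.samples, x_eq, atol=1e-9)
    a = simulate_ensemble(m, NoiseSpec(0.1), n_traj=5, n_samples=40, seed=7)
    b = simulate_ensemble(m, NoiseSpec(0.1), n_traj=5, n_samples=40, seed=7)
    np.testing.assert_array_equal(a.samples, b.samples)


def test_strong_order_one_on_refined_brownian_path():
    # halving dt should roughly halve the pathwise error vs a dt/8 reference
    m = autocatalytic(2.1)
    noise = NoiseSpec(0.2, alpha=0.0, h_kind="x")
    x_eq = [e.x for e in __import__("ewsbif").equilibria(m).stable()][-1]
    rng = np.random.default_rng(12)
    T, dt0 = 2.0, 0.02
    n_fine = int(T / (dt0 / 8))
    errs = {1: [], 2: []}
    for _ in range(40):
        dW_fine = rng.normal(scale=np.sqrt(dt0 / 8), size=n_fine)

        def integrate(factor):
            step = dt0 / factor
            dWs = dW_fine.reshape(-1, 8 // (8 // factor) if False else 8)
            # aggregate fine increments into blocks of size 8/factor
            block = 8 // factor
            dWs = dW_fine.reshape(-1, block).sum(axis=1)
            x = x_eq
            for dW in dWs:
                x = milstein_step(x, m.drift, lambda s: noise.amplitude(s, m),
                                  step, dW,
                                  lambda s: noise.amplitude_dx(s, m))
            return x

        ref = integrate(8)
        errs[1].append(abs(integrate(1) - ref))
        errs[2].append(abs(integrate(2) - ref))
    ratio = np.mean(errs[1]) / np.mean(errs[2])
    assert 1.4 < ratio < 3.2  # strong order ~1


def test_ramp_moments_match_theory():
    k0, a, sigma = 1.0, 1.0, 0.2
    t, y = simulate_ramp(k0, a, NoiseSpec(sigma), n_traj=500, seed=3)
    i = np.searchsorted(t, 0.5)
    mean_th, var_th = ramping_moments(k0, a, sigma, t[i])
    se_mean = y[:, i].std(ddof=1) / np.sqrt(y.shape[0])
    assert abs(y[:, i].mean() - mean_th) < 3 * se_mean
    v = y[:, i].var(ddof=1)
    se_var = v * np.sqrt(2.0 / (y.shape[0] - 1))
    assert abs(v - var_th) < 3 * se_var
    with pytest.raises(DomainError):
        simulate_ramp(1.0, -0.5, NoiseSpec(0.1))
    with pytest.raises(DomainError):
        simulate_ramp(1.0, 0.0, NoiseSpec(0.1))  # a=0 needs t_end


def test_ramp_a_zero_is_stationary_ou():
    t, y = simulate_ramp(1.0, 0.0, NoiseSpec(0.2), n_traj=300, t_end=30.0,
                         seed=5, y0=0.0)
    tail = y[:, t > 10.0]
    target = stationary_variance(1.0, 0.04)
    se = tail.var(axis=1, ddof=1).std(ddof=1) / np.sqrt(tail.shape[0])
    assert abs(tail.var(ddof=1) - target) < 3 * se


def test_tipping_classification():
    m = autocatalytic(2.2)  # unstable root at x ~ 0.39
    ens = simulate_ensemble(m, NoiseSpec(0.05), n_traj=10, n_samples=100, seed=2)
    assert count_tipping(ens, m).fraction == 0.0
    # deterministic start below the separatrix falls to the lower state
    ens_low = simulate_ensemble(m, NoiseSpec(0.0), n_traj=4, n_samples=100,
                                seed=2, x0=0.3)
    assert count_tipping(ens_low, m).fraction == 1.0


def test_tipping_fraction_increases_with_noise_near_fold():
    m = autocatalytic(1.83)
    fracs = []
    for sigma in (0.1, 0.2, 0.35):
        ens = simulate_ensemble(m, NoiseSpec(sigma), n_traj=40,
                                n_samples=200, seed=9)
        fracs.append(count_tipping(ens, m).fraction)
    assert fracs[0] <= fracs[1] <= fracs[2] + 0.05
    assert fracs[2] > 0.0


def test_sweep_bookkeeping():
    m = autocatalytic(2.2)
    sw = sweep(m, NoiseSpec(0.05), [2.2, 2.0, 1.9], n_traj=10,
               n_samples=30, seed=1)
    assert sw.n_levels == 3
    assert sw.c0 == pytest.approx(1.7872, abs=1e-3)
    df = sw.to_frame()
    assert len(df) == 3 * 10 * 30
    assert set(df.columns) == {"c", "trajectory_id", "sample_index", "x",
                               "tipped"}
    assert sw.tipping_fractions().max() <= 1.0
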