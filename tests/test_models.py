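"""Drift catalog: equilibria, folds, decay rates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from ewsbif import (ConfigurationError, DomainError, ModelSpec, autocatalytic,
                    bistable_K_bound, decay_rate, equilibria,
                    saddle_node_point)


@pytest.mark.parametrize(
    "family,params,x,expected",
    [
        ("autocatalytic", {"K": 0.1, "c": 2.0, "n_h": 2}, 0.0, 0.1),
        ("autocatalytic", {"K": 0.1, "c": 5.0, "n_h": 2}, 0.0, 0.1),
        ("transcritical", {"p": 0.7}, 0.0, 0.0),
        ("transcritical", {"p": -3.0}, 0.0, 0.0),
        ("saddle_node", {"p": -1.0}, 0.0, 1.0),
    ],
)
def test_drift_values(family, params, x, expected):
    assert ModelSpec(family, params).drift(x) == pytest.approx(expected)


def test_drift_errors():
    with pytest.raises(ConfigurationError):
        ModelSpec("nope", {})
    with pytest.raises(ConfigurationError):
        ModelSpec("saddle_node", {}).drift(0.0)  # missing p


def test_saddle_node_equilibria():
    eq = equilibria(ModelSpec("saddle_node", {"p": -1.0}))
    assert [(round(e.x, 12), e.stability) for e in eq] == [
        (-1.0, "unstable"), (1.0, "stable")]
    assert eq.stable()[0].decay_rate == pytest.approx(2.0)
    assert len(equilibria(ModelSpec("saddle_node", {"p": 1.0}))) == 0


def _sign_scan_roots(f, lo, hi, step=1e-4):
    """Independent equilibrium oracle: dense sign scan + bisection."""
    xs = np.arange(lo, hi, step)
    fx = np.array([f(x) for x in xs])
    roots = []
    for i in range(len(xs) - 1):
        if fx[i] == 0.0:
            roots.append(xs[i])
        elif fx[i] * fx[i + 1] < 0:
            roots.append(brentq(f, xs[i], xs[i + 1], xtol=1e-12))
    return roots


def test_autocatalytic_three_equilibria_vs_scan_oracle():
    m = autocatalytic(2.2)
    eq = equilibria(m)
    assert [e.stability for e in eq] == ["stable", "unstable", "stable"]
    oracle = _sign_scan_roots(lambda x: m.drift(x), 0.0, 3.0)
    assert len(oracle) == 3
    np.testing.assert_allclose([e.x for e in eq], oracle, atol=1e-8)


def test_fold_points_against_reduced_cubic():
    # for n_h=2 the fold abscissae are roots of x^3 - x + 2K = 0
    K = 0.1
    cubic = np.roots([1.0, 0.0, -1.0, 2 * K])
    pos = np.sort(cubic[(np.abs(cubic.imag) < 1e-12) & (cubic.real > 0)].real)
    x_lo, c_lo = saddle_node_point(K, 2, "lower")
    x_up, c_up = saddle_node_point(K, 2, "upper")
    assert x_lo == pytest.approx(pos[0], abs=1e-8)
    assert x_up == pytest.approx(pos[1], abs=1e-8)
    assert (x_up, c_up) == (pytest.approx(0.879, abs=2e-3),
                            pytest.approx(1.787, abs=2e-3))
    assert (x_lo, c_lo) == (pytest.approx(0.209, abs=2e-3),
                            pytest.approx(2.605, abs=2e-3))
    assert c_up < c_lo  # high branch vanishes at the smaller c
    # c0 formula is self-consistent with the tangency condition
    for x0, c0 in [(x_lo, c_lo), (x_up, c_up)]:
        m = autocatalytic(c0, K=K)
        assert m.drift(x0) == pytest.approx(0.0, abs=1e-10)
        assert m.drift_dx(x0) == pytest.approx(0.0, abs=1e-8)


def test_bistable_K_bound():
    assert bistable_K_bound(2) == pytest.approx(1.0 / (3 * np.sqrt(3)), abs=1e-12)
    with pytest.raises(DomainError):
        bistable_K_bound(1)
    with pytest.raises(DomainError):
        saddle_node_point(0.25, 2)  # above the bound

    # bisection oracle on fold existence recovers the same bound
    def has_folds(K):
        try:
            saddle_node_point(K, 2)
            return True
        except DomainError:
            return False

    lo, hi = 0.05, 0.3
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        lo, hi = (mid, hi) if has_folds(mid) else (lo, mid)
    assert 0.5 * (lo + hi) == pytest.approx(bistable_K_bound(2), abs=1e-9)
    # folds merge as K approaches the bound
    _, ca = saddle_node_point(bistable_K_bound(2) - 1e-6, 2, "upper")
    _, cb = saddle_node_point(bistable_K_bound(2) - 1e-6, 2, "lower")
    assert abs(ca - cb) < 0.02


def test_decay_rates():
    assert decay_rate(ModelSpec("pitchfork_super", {"p": 1.0})) == pytest.approx(2.0)
    assert decay_rate(ModelSpec("saddle_node", {"p": -1.0})) == pytest.approx(2.0)
    with pytest.raises(DomainError):
        decay_rate(ModelSpec("saddle_node", {"p": 1.0}))


def test_decay_rate_differentiation_methods_agree():
    m = autocatalytic(2.2)
    assert decay_rate(m, method="analytic") == pytest.approx(
        decay_rate(m, method="fd"), abs=1e-6)


def test_decay_rate_vanishes_at_upper_fold():
    _, c0 = saddle_node_point(0.1, 2, "upper")
    ks = [decay_rate(autocatalytic(c0 + dc)) for dc in
          (0.5, 0.2, 0.1, 0.05, 0.01, 0.002)]
    assert all(a > b for a, b in zip(ks, ks[1:]))
    assert ks[-1] < 0.1


def test_unfolded_pitchfork_branch_is_smooth():
    # q = 0.01 unfolds the pitchfork: the branch tracked from p = -1 to 1
    # moves continuously, with no fold-induced jump
    prev = None
    for p in np.linspace(-1.0, 1.0, 201):
        eq = equilibria(ModelSpec("pitchfork_unfolded", {"p": p, "q": 0.01}))
        xs = [e.x for e in eq.stable()]
        assert xs, f"no stable equilibrium at p={p}"
        x = min(xs, key=lambda v: abs(v - prev)) if prev is not None else xs[0]
        if prev is not None:
            assert abs(x - prev) < 0.05
        prev = x


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    family=st.sampled_from(["saddle_node", "transcritical", "pitchfork_super",
                            "pitchfork_sub", "cusp", "autocatalytic"]),
    data=st.data(),
)
def test_stability_classification_matches_finite_differences(family, data):
    if family == "autocatalytic":
        params = {"K": data.draw(st.floats(0.01, 0.18)),
                  "c": data.draw(st.floats(0.5, 4.0)), "n_h": 2}
    elif family == "cusp":
        params = {"a": data.draw(st.floats(-1.0, 1.0)),
                  "b": data.draw(st.floats(-1.0, 1.0))}
    else:
        params = {"p": data.draw(st.floats(-2.0, 2.0))}
    m = ModelSpec(family, params)
    h = 1e-6
    for e in equilibria(m):
        d = (m.drift(e.x + h) - m.drift(e.x - h)) / (2 * h)
        if abs(d) < 1e-4:
            continue  # too close to a fold for the sign to be meaningful
        if e.stability == "stable":
            assert d < 0
            assert e.decay_rate == pytest.approx(abs(d), abs=1e-4)
        else:
            assert d > 0
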