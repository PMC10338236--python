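"""Catalog of one-dimensional drift fields with noisy-bifurcation structure.

Normal forms of the codimension-1 bifurcations (fold/saddle-node,
transcritical, super- and subcritical pitchfork, unfolded pitchfork, cusp)
plus the autocatalytic positive-feedback loop obtained from a genetic
toggle switch under slow-fast reduction,

    f(x, c) = K + c x^n / (1 + x^n) - x,        x >= 0,

with basal rate ``K``, maximum production rate ``c`` and Hill coefficient
``n_h`` (the literature writes the Hill coefficient as ``k``; this package
reserves ``k`` for the local decay rate |d f/d x| at a stable equilibrium
and uses ``n_h`` for the Hill exponent).

Sign conventions follow the geometry of a fold approached from above:
``saddle_node`` is f = -p - x^2 (stable branch at x = +sqrt(-p) for p < 0),
``transcritical`` is f = p x - x^2, pitchforks are f = p x -/+ x^3.
Equilibria and decay rates are always derived from the drift itself.
"""

from __future__ import annotations

import json

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError, DomainError

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "Equilibrium",
    "EquilibriumSet",
    "drift",
    "drift_dx",
    "equilibria",
    "saddle_node_point",
    "bistable_K_bound",
    "decay_rate",
    "autocatalytic",
]

FAMILIES = (
    "saddle_node",
    "transcritical",
    "pitchfork_super",
    "pitchfork_sub",
    "pitchfork_unfolded",
    "cusp",
    "autocatalytic",
)

# required parameter names per family
_REQUIRED = {
    "saddle_node": ("p",),
    "transcritical": ("p",),
    "pitchfork_super": ("p",),
    "pitchfork_sub": ("p",),
    "pitchfork_unfolded": ("p", "q"),
    "cusp": ("a", "b"),
    "autocatalytic": ("K", "c", "n_h"),
}

_STABILITY_TOL = 1e-10


@dataclass(frozen=True)
class ModelSpec:
    """A one-dimensional drift family with fixed parameters.

    Parameters
    ----------
    family
        One of :data:`FAMILIES`.
    params
        Mapping of named real parameters; see :data:`_REQUIRED` per family.
    """

    family: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown model family {self.family!r}")
        object.__setattr__(self, "params", dict(self.params))

    # -- parameter plumbing -------------------------------------------------
    def _p(self, overrides=None):
        merged = dict(self.params)
        if overrides:
            merged.update(overrides)
        missing = [k for k in _REQUIRED[self.family] if k not in merged]
        if missing:
            raise ConfigurationError(
                f"{self.family}: missing parameter(s) {missing}"
            )
        if self.family == "autocatalytic":
            if merged["K"] < 0 or merged["c"] < 0 or merged["n_h"] < 1:
                raise ConfigurationError(
                    "autocatalytic requires K >= 0, c >= 0, n_h >= 1"
                )
        return merged

    def with_params(self, **overrides) -> "ModelSpec":
        return replace(self, params={**self.params, **overrides})

    # -- drift and derivative ----------------------------------------------
    def drift(self, x, **overrides):
        """Evaluate f(x) for this family (vectorized over ``x``)."""
        pr = self._p(overrides)
        x = np.asarray(x, dtype=float)
        fam = self.family
        if fam == "saddle_node":
            out = -pr["p"] - x**2
        elif fam == "transcritical":
            out = pr["p"] * x - x**2
        elif fam == "pitchfork_super":
            out = pr["p"] * x - x**3
        elif fam == "pitchfork_sub":
            out = pr["p"] * x + x**3
        elif fam == "pitchfork_unfolded":
            u = x - 1.0
            out = pr["q"] + pr["p"] * u - u**3
        elif fam == "cusp":
            out = pr["a"] + pr["b"] * x - x**3
        else:  # autocatalytic
            n = pr["n_h"]
            xn = np.abs(x) ** n  # x >= 0 by contract; abs guards round-off
            out = pr["K"] + pr["c"] * xn / (1.0 + xn) - x
        return out if out.ndim else float(out)

    def drift_dx(self, x, **overrides):
        """Analytic d f/d x (vectorized over ``x``)."""
        pr = self._p(overrides)
        x = np.asarray(x, dtype=float)
        fam = self.family
        if fam == "saddle_node":
            out = -2.0 * x
        elif fam == "transcritical":
            out = pr["p"] - 2.0 * x
        elif fam == "pitchfork_super":
            out = pr["p"] - 3.0 * x**2
        elif fam == "pitchfork_sub":
            out = pr["p"] + 3.0 * x**2
        elif fam == "pitchfork_unfolded":
            out = pr["p"] - 3.0 * (x - 1.0) ** 2 + 0.0 * x
        elif fam == "cusp":
            out = pr["b"] - 3.0 * x**2
        else:
            n = pr["n_h"]
            xn = np.abs(x) ** n
            out = pr["c"] * n * np.abs(x) ** (n - 1) / (1.0 + xn) ** 2 - 1.0
        return out if out.ndim else float(out)


def _compiled(model: "ModelSpec"):
    """Parameter-bound (f, f') closures; avoids per-call dict merging in
    simulation inner loops."""
    pr = model._p()
    fam = model.family
    if fam == "saddle_node":
        p = pr["p"]
        return (lambda x: -p - x * x), (lambda x: -2.0 * x)
    if fam == "transcritical":
        p = pr["p"]
        return (lambda x: p * x - x * x), (lambda x: p - 2.0 * x)
    if fam == "pitchfork_super":
        p = pr["p"]
        return (lambda x: p * x - x**3), (lambda x: p - 3.0 * x * x)
    if fam == "pitchfork_sub":
        p = pr["p"]
        return (lambda x: p * x + x**3), (lambda x: p + 3.0 * x * x)
    if fam == "pitchfork_unfolded":
        p, q = pr["p"], pr["q"]
        return (lambda x: q + p * (x - 1.0) - (x - 1.0) ** 3), \
               (lambda x: p - 3.0 * (x - 1.0) ** 2)
    if fam == "cusp":
        a, b = pr["a"], pr["b"]
        return (lambda x: a + b * x - x**3), (lambda x: b - 3.0 * x * x)
    K, c, n = pr["K"], pr["c"], pr["n_h"]

    def f(x):
        xn = np.abs(x) ** n
        return K + c * xn / (1.0 + xn) - x

    def fdx(x):
        xn = np.abs(x) ** n
        return c * n * np.abs(x) ** (n - 1) / (1.0 + xn) ** 2 - 1.0

    return f, fdx


@dataclass(frozen=True)
class Equilibrium:
    x: float
    stability: str  # "stable" | "unstable"
    decay_rate: float | None = None  # |df/dx|, attached to stable points


@dataclass(frozen=True)
class EquilibriumSet:
    points: tuple[Equilibrium, ...]

    def __iter__(self):
        return iter(self.points)

    def __len__(self):
        return len(self.points)

    def stable(self):
        return [e for e in self.points if e.stability == "stable"]

    def unstable(self):
        return [e for e in self.points if e.stability == "unstable"]

    def to_json(self) -> str:
        return json.dumps(
            [
                {"x": e.x, "stability": e.stability, "decay_rate": e.decay_rate}
                for e in self.points
            ]
        )


def drift(model: ModelSpec, x, overrides=None):
    """Module-level alias for :meth:`ModelSpec.drift`."""
    return model.drift(x, **(overrides or {}))


def drift_dx(model: ModelSpec, x, overrides=None):
    return model.drift_dx(x, **(overrides or {}))


def _poly_coeffs(model: ModelSpec):
    """Coefficients (highest degree first) of the polynomial whose real
    roots are the equilibria, for every family (autocatalytic is cleared
    of its Hill denominator; n_h must be a positive integer)."""
    pr = model._p()
    fam = model.family
    if fam == "saddle_node":
        return [-1.0, 0.0, -pr["p"]], 0.0
    if fam == "transcritical":
        return [-1.0, pr["p"], 0.0], 0.0
    if fam == "pitchfork_super":
        return [-1.0, 0.0, pr["p"], 0.0], 0.0
    if fam == "pitchfork_sub":
        return [1.0, 0.0, pr["p"], 0.0], 0.0
    if fam == "pitchfork_unfolded":
        # roots in u = x - 1, shifted back by +1
        return [-1.0, 0.0, pr["p"], pr["q"]], 1.0
    if fam == "cusp":
        return [-1.0, 0.0, pr["b"], pr["a"]], 0.0
    # autocatalytic: (K + c x^n/(1+x^n) - x)(1 + x^n) = 0
    n = int(round(pr["n_h"]))
    if abs(n - pr["n_h"]) > 1e-12 or n < 1:
        raise ConfigurationError("autocatalytic root finding needs integer n_h >= 1")
    # K(1 + x^n) + c x^n - x(1 + x^n)
    coeffs = np.zeros(n + 2)
    coeffs[0] = -1.0  # degree n+1
    coeffs[1] = pr["K"] + pr["c"]  # degree n
    coeffs[-2] += -1.0  # degree 1
    coeffs[-1] = pr["K"]  # degree 0
    return list(coeffs), 0.0


def equilibria(model: ModelSpec) -> EquilibriumSet:
    """All real equilibria in the declared state domain, classified by the
    sign of d f/d x and sorted in increasing x; decay rate |df/dx| is
    attached to stable points."""
    coeffs, shift = _poly_coeffs(model)
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-8].real + shift
    # dedupe near-equal roots (folds) and filter state domain
    real = np.sort(real)
    kept: list[float] = []
    for r in real:
        if model.family == "autocatalytic" and r < -1e-10:
            continue
        if kept and abs(r - kept[-1]) < 1e-9:
            continue
        kept.append(float(r))
    pts = []
    for r in kept:
        d = model.drift_dx(r)
        if d < -_STABILITY_TOL:
            pts.append(Equilibrium(r, "stable", abs(d)))
        else:
            pts.append(Equilibrium(r, "unstable"))
    return EquilibriumSet(tuple(pts))


def bistable_K_bound(n_h: int) -> float:
    """Supremum of the basal rate K for which the autocatalytic loop has
    two distinct folds (bistability window in c).

    Eliminating c between f = 0 and df/dx = 0 gives
    K = x (n - 1 - x^n) / n on the fold locus; the bound is the maximum of
    the right-hand side over x > 0, attained at x^n = (n-1)/(n+1).
    For n_h = 2 this equals 1/(3*sqrt(3)).
    """
    if n_h < 2:
        raise DomainError("no bistability for n_h < 2")
    n = float(n_h)
    xstar = ((n - 1.0) / (n + 1.0)) ** (1.0 / n)
    return xstar * (n - 1.0 - xstar**n) / n


def saddle_node_point(K: float, n_h: int, branch: str = "upper"):
    """Fold (x0, c0) of the autocatalytic loop: simultaneous solution of
    f = 0 and df/dx = 0, with c0 = (x0^n + 1)^2 / (n x0^(n-1)).

    ``branch='upper'`` returns the fold at which the high branch vanishes
    (the smaller c0, larger x0); ``'lower'`` the other fold.
    """
    if branch not in ("upper", "lower"):
        raise ConfigurationError(f"unknown branch {branch!r}")
    bound = bistable_K_bound(n_h)
    if not 0.0 < K < bound:
        raise DomainError(
            f"K={K} outside the bistable range (0, {bound:.6g}) for n_h={n_h}"
        )
    n = float(n_h)

    def g(x):
        # f = 0 with c eliminated via the tangency condition
        return K + x * (x**n + 1.0 - n) / n

    xstar = ((n - 1.0) / (n + 1.0)) ** (1.0 / n)
    # g(0) = K > 0, g(xstar) < 0 inside the bistable window, g -> +inf
    x_lo = brentq(g, 1e-12, xstar, xtol=1e-14, rtol=8.9e-16)
    hi = 2.0 * xstar
    while g(hi) < 0:
        hi *= 2.0
    x_hi = brentq(g, xstar, hi, xtol=1e-14, rtol=8.9e-16)
    x0 = x_hi if branch == "upper" else x_lo
    c0 = (x0**n + 1.0) ** 2 / (n * x0 ** (n - 1.0))
    return float(x0), float(c0)


def decay_rate(model: ModelSpec, branch: str = "upper", method: str = "analytic") -> float:
    """Local decay rate k = |df/dx| at a stable equilibrium.

    ``branch`` selects among several stable points: ``'upper'`` the largest
    x, ``'lower'`` the smallest. ``method='fd'`` uses a central difference
    (step 1e-6) instead of the analytic derivative.
    """
    stable = equilibria(model).stable()
    if not stable:
        raise DomainError(f"{model.family}: no stable equilibrium")
    eq = stable[-1] if branch == "upper" else stable[0]
    if method == "analytic":
        return abs(model.drift_dx(eq.x))
    if method == "fd":
        h = 1e-6
        return abs((model.drift(eq.x + h) - model.drift(eq.x - h)) / (2 * h))
    raise ConfigurationError(f"unknown differentiation method {method!r}")


def autocatalytic(c: float, K: float = 0.1, n_h: int = 2) -> ModelSpec:
    """Convenience constructor for the toggle-switch reduction."""
    return ModelSpec("autocatalytic", {"K": K, "c": c, "n_h": n_h})
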