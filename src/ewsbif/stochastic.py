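"""Milstein integration of noisy bifurcation models and ensemble sweeps.

The stochastic differential equation is the Ito form

    dx = f(x) dt + g(x) dW,      g(x) = sigma * [alpha + (1 - alpha) h(x)],

mixing an additive component (weight ``alpha``) with a state-dependent
(multiplicative) one through the functional ``h``. Supported functionals:
``one`` (purely additive regardless of alpha), ``x``, ``x_squared``,
``f`` (proportional to the drift) and ``sqrt_f`` (square root of the
positive part of the drift, as used for birth-death-like intrinsic noise).

The integrator is the Milstein scheme,

    x_{i+1} = x_i + f(x_i) dt + g(x_i) dW_i
              + (1/2) g(x_i) g'(x_i) (dW_i^2 - dt),

which reduces bit-exactly to Euler-Maruyama when g is constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, IntegrationBlowupError
from .models import ModelSpec, equilibria, saddle_node_point

__all__ = [
    "NoiseSpec",
    "Ensemble",
    "ParameterSweep",
    "TippingCount",
    "milstein_step",
    "simulate_ensemble",
    "simulate_ramp",
    "sweep",
    "count_tipping",
]

_H_KINDS = ("one", "x", "x_squared", "sqrt_f", "f")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise intensity and additive/multiplicative mixing.

    ``alpha = 1`` is purely additive Gaussian noise; ``alpha = 0`` purely
    multiplicative through ``h_kind``.
    """

    sigma: float
    alpha: float = 1.0
    h_kind: str = "one"

    def __post_init__(self):
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError("alpha must lie in [0, 1]")
        if self.h_kind not in _H_KINDS:
            raise ConfigurationError(f"unknown h_kind {self.h_kind!r}")

    def _h(self, x, model: ModelSpec | None):
        kind = self.h_kind
        if kind == "one":
            return np.ones_like(np.asarray(x, dtype=float))
        if kind == "x":
            return np.asarray(x, dtype=float)
        if kind == "x_squared":
            return np.asarray(x, dtype=float) ** 2
        if model is None:
            raise ConfigurationError(f"h_kind {kind!r} needs a model")
        f = np.asarray(model.drift(x), dtype=float)
        if kind == "f":
            return f
        return np.sqrt(np.maximum(f, 0.0))  # sqrt_f; negative drift clipped

    def _h_dx(self, x, model: ModelSpec | None):
        kind = self.h_kind
        x = np.asarray(x, dtype=float)
        if kind == "one":
            return np.zeros_like(x)
        if kind == "x":
            return np.ones_like(x)
        if kind == "x_squared":
            return 2.0 * x
        if model is None:
            raise ConfigurationError(f"h_kind {kind!r} needs a model")
        df = np.asarray(model.drift_dx(x), dtype=float)
        if kind == "f":
            return df
        f = np.asarray(model.drift(x), dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(f > 0, df / (2.0 * np.sqrt(np.maximum(f, 1e-300))), 0.0)
        return out

    def amplitude(self, x, model: ModelSpec | None = None):
        """g(x) = sigma [alpha + (1 - alpha) h(x)]."""
        return self.sigma * (self.alpha + (1.0 - self.alpha) * self._h(x, model))

    def amplitude_dx(self, x, model: ModelSpec | None = None):
        """g'(x), analytic; zero for additive noise."""
        return self.sigma * (1.0 - self.alpha) * self._h_dx(x, model)


def milstein_step(x, drift_fn: Callable, diffusion_fn: Callable, dt: float, dW,
                  diffusion_dx_fn: Callable | None = None):
    """One Ito-Taylor second-order (Milstein) update.

    When ``diffusion_dx_fn`` is omitted the derivative is taken by central
    difference with step 1e-6.
    """
    if dt <= 0:
        raise DomainError("dt must be > 0")
    x = np.asarray(x, dtype=float)
    g = np.asarray(diffusion_fn(x), dtype=float)
    if diffusion_dx_fn is None:
        h = 1e-6
        g_dx = (np.asarray(diffusion_fn(x + h)) - np.asarray(diffusion_fn(x - h))) / (2 * h)
    else:
        g_dx = np.asarray(diffusion_dx_fn(x), dtype=float)
    dW = np.asarray(dW, dtype=float)
    out = x + np.asarray(drift_fn(x), dtype=float) * dt + g * dW \
        + 0.5 * g * g_dx * (dW**2 - dt)
    if not np.all(np.isfinite(out)):
        raise IntegrationBlowupError("non-finite state after Milstein step")
    return out if out.ndim else float(out)


@dataclass
class Ensemble:
    """Stationary trajectory segments of one parameter level.

    ``samples`` has shape (n_traj, L), recorded every ``dt_sample`` time
    units after the transient. ``tipped`` is filled by
    :func:`count_tipping`.
    """

    samples: np.ndarray
    c: float | None
    x0: float
    dt_sample: float
    model: ModelSpec
    noise: NoiseSpec
    seed: int
    tipped: np.ndarray | None = None

    @property
    def n_traj(self) -> int:
        return self.samples.shape[0]


def _dW_matrix(seed, n_traj, n_steps, dt):
    """Per-trajectory counter-based Wiener increments: trajectory j always
    receives the stream spawned as child j of the root seed, so results do
    not depend on execution order or ensemble chunking."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_traj)
    sq = np.sqrt(dt)
    rows = [np.random.default_rng(ch).standard_normal(n_steps) * sq for ch in children]
    return np.vstack(rows) if rows else np.empty((0, n_steps))


def _start_point(model: ModelSpec, branch: str, x0):
    if x0 is not None:
        return float(x0)
    stable = equilibria(model).stable()
    if not stable:
        raise DomainError(f"{model.family}: no stable equilibrium to start from")
    return stable[-1].x if branch == "upper" else stable[0].x


def simulate_ensemble(model: ModelSpec, noise: NoiseSpec, c: float | None = None,
                      n_traj: int = 50, dt: float = 0.01, transient: float = 50.0,
                      n_samples: int = 1000, dt_sample: float = 0.1,
                      seed: int = 0, branch: str = "upper", x0=None) -> Ensemble:
    """Independent stationary trajectories started on a stable branch.

    ``c`` overrides the control parameter ``c`` of an autocatalytic model;
    the transient is discarded and ``n_samples`` points per trajectory are
    recorded at interval ``dt_sample``. Bit-reproducible given ``seed``.
    """
    if c is not None:
        model = model.with_params(c=c)
    x_start = _start_point(model, branch, x0)
    stride = int(round(dt_sample / dt))
    if stride < 1 or abs(stride * dt - dt_sample) > 1e-9:
        raise ConfigurationError("dt_sample must be a positive multiple of dt")
    n_tr = int(round(transient / dt))
    n_steps = n_tr + n_samples * stride
    dW = _dW_matrix(seed, n_traj, n_steps, dt)

    x = np.full(n_traj, x_start, dtype=float)
    out = np.empty((n_traj, n_samples))
    # parameter-bound closures keep the inner loop cheap
    from .models import _compiled
    f, fdx = _compiled(model)
    sigma, alpha, kind = noise.sigma, noise.alpha, noise.h_kind
    j = 0
    for i in range(n_steps):
        dWi = dW[:, i]
        fx = f(x)
        if kind == "one" or alpha == 1.0:
            g = sigma if kind == "one" else sigma * (alpha + (1.0 - alpha))
            x = x + fx * dt + g * dWi
        else:
            if kind == "x":
                h, h_dx = x, 1.0
            elif kind == "x_squared":
                h, h_dx = x * x, 2.0 * x
            elif kind == "f":
                h, h_dx = fx, fdx(x)
            else:  # sqrt_f
                pos = fx > 0
                h = np.sqrt(np.where(pos, fx, 0.0))
                h_dx = np.where(pos, fdx(x) / (2.0 * np.maximum(h, 1e-300)), 0.0)
            g = sigma * (alpha + (1.0 - alpha) * h)
            g_dx = sigma * (1.0 - alpha) * h_dx
            x = x + fx * dt + g * dWi + 0.5 * g * g_dx * (dWi * dWi - dt)
        if not np.all(np.isfinite(x)):
            raise IntegrationBlowupError("non-finite state during ensemble "
                                         "integration", step=i)
        if i >= n_tr and (i - n_tr + 1) % stride == 0:
            out[:, j] = x
            j += 1
    cc = model.params.get("c") if model.family == "autocatalytic" else None
    return Ensemble(out, cc, x_start, dt_sample, model, noise, seed)


def simulate_ramp(k0: float, a: float, noise: NoiseSpec, n_traj: int = 500,
                  dt: float = 0.01, y0: float = 1.0, t_end: float | None = None,
                  seed: int = 0):
    """Linearized process with a linearly ramped decay rate,
    dy = -(k0 - a t) y dt + sigma dW, integrated until k reaches 0
    (or ``t_end``). Gaussian noise only (alpha = 1); ``a = 0`` recovers the
    stationary Ornstein-Uhlenbeck process and requires an explicit t_end.
    """
    if a < 0:
        raise DomainError("ramp rate a must be >= 0")
    if noise.alpha != 1.0 or noise.h_kind != "one":
        raise DomainError("ramped runs are restricted to additive Gaussian noise")
    if a == 0:
        if t_end is None:
            raise DomainError("a = 0 needs an explicit t_end")
    else:
        t_stop = k0 / a
        t_end = t_stop if t_end is None else min(t_end, t_stop)
    n_steps = int(round(t_end / dt))
    dW = _dW_matrix(seed, n_traj, n_steps, dt)
    y = np.full(n_traj, float(y0))
    out = np.empty((n_traj, n_steps + 1))
    out[:, 0] = y
    sigma = noise.sigma
    for i in range(n_steps):
        k_t = k0 - a * (i * dt)
        y = y + (-k_t * y) * dt + sigma * dW[:, i]
        out[:, i + 1] = y
    t = np.arange(n_steps + 1) * dt
    return t, out


@dataclass(frozen=True)
class TippingCount:
    """Number and fraction of trajectories that escaped the starting basin."""

    count: int
    n_traj: int

    @property
    def fraction(self) -> float:
        return self.count / self.n_traj if self.n_traj else 0.0


def count_tipping(ensemble: Ensemble, model: ModelSpec | None = None,
                  c: float | None = None, dwell: float = 5.0,
                  branch: str = "upper") -> TippingCount:
    """Classify trajectories as tipped relative to the reference branch.

    A trajectory is tipped iff it sits beyond the unstable equilibrium
    separating the basins (on the side away from the ``branch`` attractor)
    for at least ``dwell`` consecutive time units; the dwell rule avoids
    counting grazing excursions. With no unstable root (monostable), the
    midpoint between the reference point and the single attractor is used
    as the separatrix.
    """
    model = model or ensemble.model
    if c is not None:
        model = model.with_params(c=c)
    eq = equilibria(model)
    stable = eq.stable()
    if stable:
        x_ref = (stable[-1] if branch == "upper" else stable[0]).x
    else:
        x_ref = ensemble.x0
    unstable = eq.unstable()
    if unstable:
        # separatrix adjacent to the reference attractor
        xu = min(unstable, key=lambda e: abs(e.x - x_ref)).x
    else:
        if not stable:
            raise DomainError("no equilibria to classify tipping against")
        # monostable (e.g. past the fold): classify by the basin of the
        # single attractor relative to where the ensemble started
        x_ref = ensemble.x0
        xa = stable[0].x
        if abs(xa - x_ref) < 1e-6:
            # the reference attractor is the only one: nothing to tip to
            tipped = np.zeros(ensemble.n_traj, dtype=bool)
            ensemble.tipped = tipped
            return TippingCount(0, ensemble.n_traj)
        xu = 0.5 * (x_ref + xa)
    D = max(1, int(round(dwell / ensemble.dt_sample)))
    s = 1.0 if x_ref > xu else -1.0
    far = (ensemble.samples - xu) * s < 0  # beyond the separatrix
    tipped = np.zeros(ensemble.n_traj, dtype=bool)
    for i in range(ensemble.n_traj):
        run = 0
        for flag in far[i]:
            run = run + 1 if flag else 0
            if run >= D:
                tipped[i] = True
                break
    ensemble.tipped = tipped
    return TippingCount(int(tipped.sum()), ensemble.n_traj)


@dataclass
class ParameterSweep:
    """Quasi-steady-state ensembles along an ordered control-parameter grid.

    The first grid point is the far-from-bifurcation baseline; ``c0`` is
    the fold location when known.
    """

    c_grid: np.ndarray
    ensembles: list[Ensemble]
    model: ModelSpec
    noise: NoiseSpec
    seed: int
    c0: float | None = None
    param: str = "c"

    def __post_init__(self):
        self.c_grid = np.asarray(self.c_grid, dtype=float)

    @property
    def n_levels(self) -> int:
        return len(self.c_grid)

    def tipping_fractions(self) -> np.ndarray:
        return np.array(
            [e.tipped.mean() if e.tipped is not None else np.nan
             for e in self.ensembles]
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: one row per recorded sample."""
        rows = []
        for c, ens in zip(self.c_grid, self.ensembles):
            n_traj, L = ens.samples.shape
            rows.append(pd.DataFrame({
                "c": np.repeat(c, n_traj * L),
                "trajectory_id": np.repeat(np.arange(n_traj), L),
                "sample_index": np.tile(np.arange(L), n_traj),
                "x": ens.samples.ravel(),
                "tipped": np.repeat(
                    ens.tipped if ens.tipped is not None
                    else np.zeros(n_traj, dtype=bool), L),
            }))
        return pd.concat(rows, ignore_index=True)


def sweep(model: ModelSpec, noise: NoiseSpec, c_grid: Sequence[float],
          n_traj: int = 50, param: str = "c", dwell: float = 5.0,
          seed: int = 0, **sim_kwargs) -> ParameterSweep:
    """Ensembles at every level of an ordered grid (baseline first),
    with per-trajectory tip flags filled in."""
    c_grid = np.asarray(list(c_grid), dtype=float)
    if c_grid.size == 0:
        raise ConfigurationError("empty parameter grid")
    level_seeds = np.random.SeedSequence(seed).generate_state(c_grid.size) % (2**31)
    ensembles = []
    for c, s in zip(c_grid, level_seeds):
        m = model.with_params(**{param: float(c)})
        ens = simulate_ensemble(m, noise, n_traj=n_traj, seed=int(s), **sim_kwargs)
        count_tipping(ens, m, dwell=dwell)
        ensembles.append(ens)
    c0 = None
    if model.family == "autocatalytic":
        try:
            _, c0 = saddle_node_point(model.params["K"],
                                      int(model.params["n_h"]), "upper")
        except DomainError:
            c0 = None
    elif model.family in ("saddle_node", "transcritical",
                          "pitchfork_super", "pitchfork_sub"):
        c0 = 0.0
    return ParameterSweep(c_grid, ensembles, model, noise, seed, c0=c0, param=param)
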