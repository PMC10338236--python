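"""Empirical estimators of early-warning indicators and the composite.

Estimators follow standard definitions: variance with the N-1
denominator, lag-1 autocorrelation on time-ordered segments,
autocorrelation time ACT = -1/log(AC(1)), Shannon entropy from histogram
bin probabilities HS = -sum p_j log p_j (bin width by the
Freedman-Diaconis rule, per level by default so the entropy is
shape-sensitive rather than scale-tracking), skewness and kurtosis as
the standardized third and fourth sample moments (kurtosis not
excess-corrected, so the Gaussian value is 3).

The composite indicator is a weighted sum of baseline-standardized
indicators, S = sum_k w_k I_k with non-negative weights on the unit
simplex; standardization (subtract the baseline bootstrap mean, divide by
the baseline bootstrap SD) puts heterogeneous units on a common scale so
weights are comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DomainError, EstimatorError
from .stochastic import ParameterSweep
from .theory import entropy_gaussian

__all__ = [
    "INDICATOR_NAMES",
    "CompositeWeights",
    "IndicatorSeries",
    "estimate",
    "ac1_segments",
    "estimate_sweep",
    "bootstrap_pooled",
    "composite",
    "fd_bin_width",
]

INDICATOR_NAMES = ("mean", "var", "ac1", "act", "cv", "id", "skew", "kurt", "hs")


def fd_bin_width(samples) -> float:
    """Freedman-Diaconis histogram bin width, 2 IQR / N^(1/3)."""
    samples = np.asarray(samples, dtype=float)
    iqr = np.subtract(*np.percentile(samples, [75, 25]))
    if iqr <= 0:
        raise EstimatorError("degenerate sample spread; cannot fix bin width")
    return 2.0 * iqr / len(samples) ** (1.0 / 3.0)


def _hist_entropy(samples, bin_width=None, edges=None):
    samples = np.asarray(samples, dtype=float)
    if edges is None:
        w = bin_width if bin_width is not None else fd_bin_width(samples)
        lo, hi = samples.min(), samples.max()
        n_bins = max(1, int(math.ceil((hi - lo) / w))) if hi > lo else 1
        edges = lo + w * np.arange(n_bins + 1)
        if edges[-1] <= hi:
            edges = np.append(edges, edges[-1] + w)
    counts, _ = np.histogram(samples, bins=edges)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def ac1(samples) -> float:
    """Lag-1 sample autocorrelation of a time-ordered series."""
    x = np.asarray(samples, dtype=float)
    if len(x) < 2:
        raise EstimatorError("ac1 needs at least 2 ordered samples")
    m = x.mean()
    denom = ((x - m) ** 2).sum()
    if denom == 0:
        raise EstimatorError("ac1 undefined for a constant series")
    return float(((x[:-1] - m) * (x[1:] - m)).sum() / denom)


def estimate(samples, name: str, *, bin_width=None, edges=None,
             hs_method: str = "hist") -> float:
    """One indicator from a sample vector (time-ordered for ac1/act)."""
    if name not in INDICATOR_NAMES:
        raise ConfigurationError(f"unknown indicator {name!r}")
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 2 or (name == "kurt" and n < 4):
        raise EstimatorError(f"{name} needs more samples (got {n})")
    if name == "mean":
        return float(x.mean())
    if name == "var":
        return float(x.var(ddof=1))
    if name == "ac1":
        return ac1(x)
    if name == "act":
        r = ac1(x)
        if not 0.0 < r < 1.0:
            raise EstimatorError("ACT undefined unless 0 < AC(1) < 1")
        return -1.0 / math.log(r)
    if name == "cv":
        m = x.mean()
        if m == 0:
            raise EstimatorError("CV undefined at zero mean")
        return float(x.std(ddof=1) / m)
    if name == "id":
        m = x.mean()
        if m == 0:
            raise EstimatorError("ID undefined at zero mean")
        return float(x.var(ddof=1) / m)
    if name == "skew":
        return float(stats.skew(x, bias=True))
    if name == "kurt":
        return float(stats.kurtosis(x, fisher=False, bias=True))
    # hs
    if hs_method == "gaussian":
        return entropy_gaussian(float(x.var(ddof=1)))
    return _hist_entropy(x, bin_width=bin_width, edges=edges)


def ac1_segments(segments) -> float:
    """AC(1) averaged over per-trajectory stationary segments."""
    vals = [ac1(row) for row in np.asarray(segments, dtype=float)]
    return float(np.mean(vals))


@dataclass
class IndicatorSeries:
    """Per-level point estimates and bootstrap distributions of indicators.

    ``boot[name]`` has shape (n_levels, B); ``point[name]`` length n_levels.
    """

    levels: np.ndarray
    boot: dict[str, np.ndarray]
    point: dict[str, np.ndarray]
    baseline_index: int = 0
    c0: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def names(self):
        return tuple(self.boot)

    @property
    def n_levels(self):
        return len(self.levels)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format (level, indicator, replicate, value)."""
        rows = []
        for name, arr in self.boot.items():
            L, B = arr.shape
            rows.append(pd.DataFrame({
                "level": np.repeat(self.levels, B),
                "indicator": name,
                "replicate": np.tile(np.arange(B), L),
                "value": arr.ravel(),
            }))
        return pd.concat(rows, ignore_index=True)


def bootstrap_pooled(pooled, name, B, rng, *, bin_width=None, hs_method="hist"):
    """B bootstrap replicates of one indicator from a flat sample pool."""
    pooled = np.asarray(pooled, dtype=float)
    n = len(pooled)
    out = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        out[b] = estimate(pooled[idx], name, bin_width=bin_width,
                          hs_method=hs_method)
    return out


def estimate_sweep(sw: ParameterSweep, names, B: int = 50, seed: int = 0,
                   hs_method: str = "hist", hs_bins: str = "adaptive",
                   exclude_tipped: bool = False) -> IndicatorSeries:
    """Indicator series with bootstrap distributions from a parameter sweep.

    Moment-based indicators are computed on the pooled level distribution
    (resampled with replacement); ac1/act are averaged over per-trajectory
    time-ordered segments and bootstrapped by resampling trajectories. The
    entropy bin width is fixed from the baseline pool.

    By default every trajectory contributes to the level's distribution
    data, tipped ones included (noise-induced escapes are part of the
    observed ensemble and are tracked separately by the tipping counter).
    ``exclude_tipped=True`` restricts each level to trajectories still on
    the starting branch; when fewer than 4 survive, the level's bootstrap
    entries are NaN.

    ``hs_bins='adaptive'`` (default) fixes the entropy bin width per level
    by the Freedman-Diaconis rule on that level's pool, making the
    histogram entropy approximately scale-free: it responds to changes of
    distribution *shape* (bimodality, heavy tails) rather than to plain
    widening, which the variance already measures. ``'baseline'`` freezes
    the width from the baseline level instead, making HS track log-Var.
    """
    names = tuple(names)
    for nm in names:
        if nm not in INDICATOR_NAMES:
            raise ConfigurationError(f"unknown indicator {nm!r}")
    rng = np.random.default_rng(seed)
    base_pool = sw.ensembles[sw_baseline_index(sw)].samples.ravel()
    try:
        bw = fd_bin_width(base_pool)
    except EstimatorError:
        bw = None  # noise-free sweep; histogram entropy will be 0
    L = sw.n_levels
    boot = {nm: np.full((L, B), np.nan) for nm in names}
    point = {nm: np.full(L, np.nan) for nm in names}
    for i, ens in enumerate(sw.ensembles):
        segs = ens.samples
        if exclude_tipped and ens.tipped is not None:
            segs = segs[~ens.tipped]
        if segs.shape[0] < 4:
            continue  # too few surviving trajectories; level reported NaN
        pooled = segs.ravel()
        for nm in names:
            if nm in ("ac1", "act"):
                per_traj = np.array([ac1(row) for row in segs])
                point[nm][i] = _act_or_ac1(per_traj.mean(), nm)
                for b in range(B):
                    idx = rng.integers(0, len(per_traj), size=len(per_traj))
                    boot[nm][i, b] = _act_or_ac1(per_traj[idx].mean(), nm)
            else:
                kw = {}
                if nm == "hs":
                    if hs_bins == "adaptive":
                        try:
                            bw_i = fd_bin_width(pooled)
                        except EstimatorError:
                            bw_i = None
                    else:
                        bw_i = bw
                    kw = {"bin_width": bw_i, "hs_method": hs_method}
                    if bw_i is None and hs_method == "hist":
                        point[nm][i] = 0.0
                        boot[nm][i, :] = 0.0
                        continue
                point[nm][i] = estimate(pooled, nm, **kw)
                boot[nm][i, :] = bootstrap_pooled(pooled, nm, B, rng, **kw)
    return IndicatorSeries(np.asarray(sw.c_grid), boot, point,
                           baseline_index=0, c0=sw.c0,
                           meta={"B": B, "seed": seed, "hs_method": hs_method})


def sw_baseline_index(sw: ParameterSweep) -> int:
    return 0  # first grid point is the baseline by contract


def _act_or_ac1(r: float, name: str) -> float:
    if name == "ac1":
        return r
    if not 0.0 < r < 1.0:
        raise EstimatorError("ACT undefined unless 0 < AC(1) < 1")
    return -1.0 / math.log(r)


@dataclass(frozen=True)
class CompositeWeights:
    """Non-negative weights over an ordered indicator set, summing to 1."""

    names: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        if len(self.names) != len(self.weights):
            raise ConfigurationError("names and weights must align")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < -1e-12):
            raise ConfigurationError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError("weights must sum to 1")
        object.__setattr__(self, "weights", tuple(float(v) for v in w))


def composite(series: IndicatorSeries, weights: CompositeWeights,
              normalization: str = "baseline_z") -> IndicatorSeries:
    """Composite indicator S = sum_k w_k I_k as a bootstrap distribution.

    Each component is standardized against its baseline bootstrap
    distribution (subtract baseline mean, divide by baseline SD), then the
    weighted sum is taken per bootstrap replicate. ``normalization='none'``
    skips standardization (raw weighted sum).
    """
    missing = [nm for nm in weights.names if nm not in series.boot]
    if missing:
        raise ConfigurationError(f"series lacks indicator(s) {missing}")
    b0 = series.baseline_index
    comp_boot = None
    comp_point = None
    for nm, w in zip(weights.names, weights.weights):
        arr = series.boot[nm]
        pt = series.point[nm]
        if normalization == "baseline_z":
            mu = arr[b0].mean()
            sd = arr[b0].std(ddof=1)
            if sd == 0:
                raise DomainError(
                    f"degenerate normalization: baseline bootstrap SD of {nm} is 0")
            arr = (arr - mu) / sd
            pt = (pt - mu) / sd
        elif normalization != "none":
            raise ConfigurationError(f"unknown normalization {normalization!r}")
        comp_boot = w * arr if comp_boot is None else comp_boot + w * arr
        comp_point = w * pt if comp_point is None else comp_point + w * pt
    return IndicatorSeries(series.levels, {"composite": comp_boot},
                           {"composite": comp_point},
                           baseline_index=b0, c0=series.c0,
                           meta={**series.meta, "weights": weights})
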