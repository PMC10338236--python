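"""Lead-parameter detection from Welch-type p-value sequences.

Each level's indicator bootstrap distribution is compared against the
baseline level with a one-sided unequal-variance statistic in the
increasing direction. The lead parameter c_sig is the earliest level at
which the p value falls below the significance threshold *stably*: the
raw and the moving-median-smoothed p value must stay below psig over a
run of consecutive levels (or, under the stricter ``tail`` rule, all the
way to the end of the grid), and the level mean must exceed the baseline
mean (direction gate). Absence of a trigger is a valid result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError, EstimatorError
from .indicators import CompositeWeights, IndicatorSeries, composite

__all__ = [
    "DetectionResult",
    "welch_series",
    "extract_csig",
    "detect",
    "lead_table",
    "moving_median",
]


@dataclass
class DetectionResult:
    """Smoothed p-value sequence and the extracted lead parameter."""

    levels: np.ndarray
    p_raw: np.ndarray
    p_smoothed: np.ndarray
    direction: np.ndarray  # level mean exceeds baseline mean
    psig: float
    csig: float | None = None
    csig_index: int | None = None
    lead_distance: float | None = None  # |csig - c0| when c0 known
    meta: dict = field(default_factory=dict)

    @property
    def triggered(self) -> bool:
        return self.csig_index is not None

    def to_dict(self) -> dict:
        return {
            "levels": list(map(float, self.levels)),
            "p_raw": [None if np.isnan(p) else float(p) for p in self.p_raw],
            "p_smoothed": [None if np.isnan(p) else float(p) for p in self.p_smoothed],
            "direction": list(map(bool, self.direction)),
            "psig": self.psig,
            "csig": self.csig,
            "csig_index": self.csig_index,
            "lead_distance": self.lead_distance,
        }


def welch_series(series: IndicatorSeries, name: str | None = None,
                 baseline_index: int | None = None):
    """One-sided Welch-type p values of each level's indicator bootstrap
    distribution against the baseline's, in the increasing direction.

    The bootstrap spread of an indicator estimates the estimator's own
    sampling deviation, so the unequal-variance statistic combines the two
    bootstrap SDs directly, z = (mean_j - mean_0) / sqrt(s_j^2 + s_0^2),
    without dividing by the replicate count (which would mistake bootstrap
    replicates for independent data and destroy the null calibration of
    the trigger rate). Returns (p_raw, direction); the baseline entry is
    NaN / False.
    """
    if name is None:
        if len(series.boot) != 1:
            raise ConfigurationError("series holds several indicators; name one")
        name = next(iter(series.boot))
    arr = series.boot[name]
    b0 = series.baseline_index if baseline_index is None else baseline_index
    base = arr[b0]
    if arr.shape[1] < 2:
        raise EstimatorError("Welch test needs >= 2 replicates per level")
    L = arr.shape[0]
    p_raw = np.full(L, np.nan)
    direction = np.zeros(L, dtype=bool)
    base_mean = base.mean()
    s0 = base.std(ddof=1)
    # numerically degenerate shifts (rounding noise on constant data) are
    # treated as no difference
    eps = 64 * np.finfo(float).eps
    for i in range(L):
        if i == b0 or np.isnan(arr[i]).any():
            continue
        delta = arr[i].mean() - base_mean
        s2 = arr[i].var(ddof=1) + s0**2
        if abs(delta) < eps * max(1.0, abs(base_mean), abs(arr[i].mean())):
            delta = 0.0
        if s2 == 0 or delta == 0.0:
            p_raw[i] = 0.5 if delta == 0 else (0.0 if delta > 0 else 1.0)
        else:
            p_raw[i] = stats.norm.sf(delta / np.sqrt(s2))
        direction[i] = delta > 0
    return p_raw, direction


def moving_median(p, window: int = 3):
    """Centered moving median with edge replication; NaNs pass through."""
    p = np.asarray(p, dtype=float)
    half = window // 2
    padded = np.concatenate([np.repeat(p[:1], half), p, np.repeat(p[-1:], half)])
    out = np.empty_like(p)
    for i in range(len(p)):
        win = padded[i:i + window]
        out[i] = np.nan if np.isnan(p[i]) else np.nanmedian(win)
    return out


def extract_csig(p_raw, levels=None, psig: float = 0.05, window: int = 3,
                 direction=None, c0: float | None = None,
                 rule: str = "consecutive", m: int = 3) -> DetectionResult:
    """Earliest level at which significance holds stably.

    A level is *significant* iff its raw AND moving-median-smoothed p are
    below psig and the direction gate (mean increased vs baseline)
    passes. Under the default ``rule='consecutive'`` the trigger is the
    first level opening a run of at least ``m`` consecutive significant
    levels (truncated at the end of the grid), which ignores isolated
    dips and remains meaningful on grids that extend past the fold, where
    late post-collapse levels lose significance again.
    ``rule='tail'`` demands significance from the trigger through the
    last level. Baseline entries (NaN p) are excluded from the
    requirement.
    """
    p_raw = np.asarray(p_raw, dtype=float)
    L = len(p_raw)
    levels = np.arange(L, dtype=float) if levels is None else np.asarray(levels, dtype=float)
    direction = np.ones(L, dtype=bool) if direction is None else np.asarray(direction, dtype=bool)
    p_sm = moving_median(p_raw, window=window)
    valid = ~np.isnan(p_raw)
    sig = valid & (p_raw < psig) & (p_sm < psig) & direction
    if rule not in ("consecutive", "tail"):
        raise ConfigurationError(f"unknown stability rule {rule!r}")
    csig_index = None
    if rule == "tail":
        tail_ok = np.ones(L, dtype=bool)
        ok = True
        for j in range(L - 1, -1, -1):
            if valid[j]:
                ok = ok and sig[j]
            tail_ok[j] = ok
        for j in range(L):
            if valid[j] and sig[j] and tail_ok[j]:
                csig_index = j
                break
    else:
        idx = [j for j in range(L) if valid[j]]
        for pos, j in enumerate(idx):
            run = idx[pos:pos + m]
            if all(sig[r] for r in run):
                csig_index = j
                break
    csig = float(levels[csig_index]) if csig_index is not None else None
    lead = abs(csig - c0) if (csig is not None and c0 is not None) else None
    return DetectionResult(levels, p_raw, p_sm, direction, psig,
                           csig=csig, csig_index=csig_index,
                           lead_distance=lead)


def detect(series: IndicatorSeries, name: str | None = None,
           weights: CompositeWeights | None = None, psig: float = 0.05,
           window: int = 3, rule: str = "consecutive",
           m: int = 3) -> DetectionResult:
    """Full chain: (optional composite) -> Welch p series -> c_sig."""
    if weights is not None:
        series = composite(series, weights)
        name = "composite"
    p_raw, direction = welch_series(series, name)
    res = extract_csig(p_raw, levels=series.levels, psig=psig,
                       window=window, direction=direction, c0=series.c0,
                       rule=rule, m=m)
    res.meta["indicator"] = name
    return res


def lead_table(series_by_sigma: dict, name: str | None = None,
               weights: CompositeWeights | None = None, psig: float = 0.05,
               tipping_by_sigma: dict | None = None,
               detect_threshold: float = 0.05, **detect_kwargs) -> dict:
    """c_sig per noise level, labeled 'anticipating' when the tipping
    fraction at the trigger level is below ``detect_threshold`` and
    'detecting' when warnings co-occur with ongoing noise-induced
    transitions."""
    out = {}
    for sig_level, series in series_by_sigma.items():
        res = detect(series, name=name, weights=weights, psig=psig,
                     **detect_kwargs)
        entry = {"csig": res.csig, "lead_distance": res.lead_distance,
                 "result": res}
        if tipping_by_sigma is not None and res.csig_index is not None:
            frac = float(np.asarray(tipping_by_sigma[sig_level])[res.csig_index])
            entry["tipping_fraction"] = frac
            entry["label"] = ("anticipating" if frac < detect_threshold
                              else "detecting")
        out[sig_level] = entry
    return out
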