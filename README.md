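# ewsbif

Early-warning signals (EWS) for critical transitions driven by noisy
bifurcations — simulation, closed-form theory, significance-tested
detection and composite-indicator optimization, for systems-biology-style
*distribution data* (replicate ensembles measured at successive values of
a control parameter).

## The problem

Many biological systems — genetic toggle switches, collapsing microbial
populations, cell-fate decisions — sit on a stable branch of a bistable
landscape while a slow control parameter drifts toward a saddle-node
(fold) bifurcation. Near the fold the local decay rate
k = |∂ₓf(x̃ₛ)| → 0 (critical slowing down), which inflates statistical
indicators of the fluctuations: for the linearized residual process
dy = −k y dt + h dW,

    AC(τ) = e^(−kτ),   Var = h²/(2k),   CV = √Var/x̃ₛ,
    HS = ½[log(2π Var) + 1]   (Gaussian entropy).

Whether these indicators actually rise before a transition depends on the
noise: the autocorrelation ignores the amplitude h(x), but variance-based
indicators can flatten or reverse under multiplicative (state-dependent)
noise, and strong noise triggers escapes (n-tipping) before the fold is
reached. `ewsbif` implements the whole analysis chain:

- **models** — normal forms and the autocatalytic feedback loop
  f(x,c) = K + c xⁿ/(1+xⁿ) − x (toggle-switch reduction), with equilibria,
  folds and decay rates derived from the drift;
- **stochastic** — Milstein integration of dx = f dt + σ[α+(1−α)h(x)] dW,
  quasi-steady-state ensemble sweeps, ramped-parameter runs and tipping
  counters;
- **theory** — the closed forms above plus spectra, offset moments,
  measurement noise, ramping moments and Kramers escape times;
- **indicators** — empirical estimators with per-level bootstrap, and the
  weighted composite S = Σ w_k I_k (baseline-standardized);
- **detection** — one-sided Welch-type p values of each level's indicator
  bootstrap against a far-from-fold baseline, and the lead parameter
  c_sig (first stably significant level);
- **optimize** — exhaustive simplex grid search for the weights
  maximizing the summed lead distance across noise intensities;
- **empirical** — CSV/TSV distribution tables, the end-to-end pipeline
  (bootstrap → p values → DF_sig) and a synthetic yeast-style fixture
  generator.

## Worked example

```python
import numpy as np
import ewsbif as e

# bistable autocatalytic loop: folds and decay rate
x0, c0 = e.saddle_node_point(K=0.1, n_h=2, branch="upper")
print(f"upper fold: x0={x0:.3f}, c0={c0:.3f}")
m = e.autocatalytic(2.0)
print(f"decay rate at c=2.0: {e.decay_rate(m):.3f}")

# sweep toward the fold under additive noise, detect the warning
sw = e.sweep(m, e.NoiseSpec(sigma=0.1), np.arange(2.4, 1.84, -0.04),
             n_traj=50, n_samples=4, dt_sample=5.0, seed=12)
series = e.estimate_sweep(sw, ("var", "ac1", "hs"), B=50, seed=12)
res = e.detect(series, name="var", psig=0.01)
print(f"variance EWS triggers at c_sig={res.csig:.2f}, "
      f"lead |c_sig - c0| = {res.lead_distance:.3f}")
```

prints

```
upper fold: x0=0.879, c0=1.787
decay rate at c=2.0: 0.407
variance EWS triggers at c_sig=2.04, lead |c_sig - c0| = 0.253
```

The fold of the high-expression branch sits at c₀ ≈ 1.787; at c = 2.0 the
branch relaxes at rate k ≈ 0.41. Sweeping the production rate down from
2.4, the variance bootstrap becomes stably significant against the
baseline at c ≈ 2.04 — a warning about 0.25 parameter units before the
collapse.

The same pipeline runs on empirical tables:

```sh
ewsbif fixture make --out table.csv --sigma 0.12 --seed 5
ewsbif empirical run table.csv --out report.json --names var,hs --psig 0.01
```

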