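# Methods

`ewsbif` studies early-warning signals (EWS) for critical transitions
driven by noisy bifurcations: a slowly drifting control parameter carries
a one-dimensional system toward a fold while stochastic forcing excites
fluctuations around the stable branch. The package covers the full chain
from mechanistic simulation to statistical detection and the optimization
of a composite indicator.

## Models

The drift catalog holds the codimension-1 normal forms — fold
(f = −p − x², stable branch at x = +√(−p)), transcritical (px − x²),
super/subcritical pitchfork (px ∓ x³), the unfolded pitchfork
(q + p(x−1) − (x−1)³) and the cusp (a + bx − x³) — plus the autocatalytic
positive-feedback loop

    f(x, c) = K + c xⁿ / (1 + xⁿ) − x,   x ≥ 0,

the slow-fast reduction of a genetic toggle switch. `K` is the basal
production rate, `c` the maximal production rate (control parameter) and
`n_h` the Hill exponent (default 2). The loop is bistable for
0 < K < 1/(3√3) when n_h = 2; at K = 0.1 its upper branch vanishes at the
fold (x₀, c₀) ≈ (0.879, 1.787) and the lower branch at ≈ (0.209, 2.605).
Fold points solve f = 0 ∧ ∂ₓf = 0; for n_h = 2 the abscissae are the
positive roots of x³ − x + 2K = 0, and c₀ = (x₀ⁿ + 1)²/(n x₀ⁿ⁻¹).
Equilibria and decay rates are always derived from the drift itself
(polynomial root finding after clearing the Hill denominator, stability by
the sign of ∂ₓf); no printed shortcut expressions are hard-coded. The
local decay rate k = |∂ₓf(x̃ₛ)| is the resilience of the branch; k → 0 at
the fold is the critical slowing down that all indicators feed on.

A note on symbols: the toggle-switch literature uses `k` both for the
Hill coefficient and for the decay rate. Here `n_h` is always the Hill
exponent and `k` always the decay rate.

## Stochastic simulation

The Itô SDE dx = f(x) dt + g(x) dW with
g(x) = σ[α + (1−α) h(x)] mixes additive (α = 1) and multiplicative noise
through h ∈ {1, x, x², f, √max(f, 0)}. Integration uses the Milstein
scheme (strong order 1); with constant g it degenerates bit-exactly to
Euler–Maruyama. The diffusion derivative g′ is analytic for every h
(finite-difference fallback with step 1e−6 for user-supplied
diffusions). The time step is dt = 0.01 throughout.

Ensembles draw per-trajectory Wiener streams from children of a single
root `SeedSequence`, so results are bit-reproducible and independent of
execution order or chunking. Quasi-steady-state sweeps hold the control
parameter fixed per level, discard a transient of 50 time units and
record L stationary samples per trajectory at interval Δt_s.

A trajectory counts as *tipped* when it sits beyond the unstable
equilibrium (separatrix), on the side away from the reference branch, for
at least a dwell time of 5 time units; the dwell rule ignores grazing
excursions. Past the fold (monostable) the basin of the surviving
attractor decides. Tipped trajectories stay in the level's distribution
data — noise-induced escapes are part of what an observer measures — and
are tallied separately by the normalized tipping counter.

## Closed-form theory

Linearizing around the stable branch gives the Ornstein–Uhlenbeck
residual process dy = −k y dt + h(x̃ₛ) dW with
AC(τ) = e^(−kτ), Lorentzian spectrum h²/(k² + ω²), Var = h²/(2k),
CV = √Var/x̃ₛ, ID = Var/x̃ₛ and Gaussian entropy ½[log(2π Var) + 1].
Only the amplitude h²(x̃ₛ) carries the noise type; the autocorrelation
does not, which is why multiplicative noise can flatten or reverse
variance-based trends while leaving AC(1) untouched. Auxiliary results:
moments about an offset reference μ of the stationary density (third
moment −μ(3 + 2kμ²)/(2k), fourth-to-Var² ratio 3 + 4kμ²(3 + kμ²), both
with the noise scale normalized to 1 — zero skew and Gaussian ratio 3 at
μ = 0); measurement noise added in quadrature inflates the variance to
Var + σ_m² and scales the measured lag-1 autocorrelation to
Var·e^(−k)/(Var + σ_m²); linearly ramped decay k(t) = k₀ − a t yields a
closed-form mean exp(−k₀t + a t²/2) and a variance integral evaluated by
adaptive quadrature (tolerance 1e−8; the closed form involves the error
function). Kramers escape times use the barrier ΔU = −∫f dx between the
stable point and the separatrix with curvature prefactor
2π/√(|U″(x̃ₛ)U″(x̃ᵤ)|); the exponent is taken as ΔU/σ, a convention kept
for regime ranking only, never for absolute first-passage prediction.

## Indicators and bootstrap

Estimators follow standard definitions (variance with N−1, skew/kurtosis
as standardized moments with the Gaussian kurtosis at 3, ACT =
−1/log AC(1)). Shannon entropy is the histogram entropy −Σ pⱼ log pⱼ with
the bin width set per level by the Freedman–Diaconis rule on that level's
pool. Because an FD width scales with the sample IQR, this discrete
entropy is approximately scale-free: it responds to changes of
distribution *shape* — bimodality at the onset of noise-induced escapes,
heavy tails, skew — rather than to plain widening, which the variance
already measures; under additive noise on a stable branch it stays
nearly flat. A `baseline` binning option freezes the width from the
baseline level instead (entropy then tracks log-variance), and a
`gaussian` plug-in option gives ½[log(2π·s²) + 1] exactly. AC(1)
requires time order: on simulated sweeps it is the lag-one-sample
autocorrelation averaged over trajectory segments (bootstrap by
resampling trajectories); on empirical tables it is computed across
day-ordered within-level series when day labels exist and reported absent
otherwise.

Per level, moment indicators are bootstrapped by resampling the pooled
distribution with replacement, B = 50 replicates by default (matching the
typical number of independent data entries per level; configurable up to
1000 for robustness checks). The pooled bootstrap treats samples as
exchangeable, so the sweep pipeline records samples several decay times
apart (see study conditions) to keep within-segment dependence weak.

The composite indicator S = Σ w_k I_k carries non-negative weights on the
unit simplex. Components are standardized against the baseline bootstrap
(subtract baseline mean, divide by baseline SD) before weighting —
without a common scale the variance, in squared data units, would
numerically swamp entropy and autocorrelation.

## Detection

Each level's indicator bootstrap distribution is compared against the
baseline level with a one-sided unequal-variance statistic in the
increasing direction,

    z = (Ī_j − Ī_0) / √(s_j² + s_0²),    p = 1 − Φ(z),

where s are the bootstrap SDs. The bootstrap spread estimates the
estimator's own sampling deviation, so the two SDs combine directly;
dividing them by the replicate count (as a textbook two-sample test on
the replicates would) mistakes bootstrap copies for independent data and
destroys the calibration of the trigger rate under the null. Degenerate
shifts at floating-point rounding scale are treated as no difference.

The lead parameter c_sig is the earliest level at which significance
holds *stably*: the raw and the moving-median-smoothed (window 3) p value
both stay below p_sig over a run of m = 3 consecutive levels (truncated
at the end of the grid), and the level mean exceeds the baseline mean
(direction gate, the automatic version of checking that the trend points
the right way). The consecutive-run rule ignores isolated dips yet stays
meaningful on grids that extend into the collapse region, where late
levels lose significance again; a stricter `tail` rule (significant
through the last level) is available. Defaults: p_sig = 0.05 for generic
detection, 0.01 for the empirical pipeline and the headline study.
Absence of a trigger is a valid outcome. Either stability rule keeps the
null false-trigger rate conservative (≤ p_sig); leads are reported both
as the raw level value and as the distance |c_sig − c₀| when the fold is
known. Paired with the tipping counter, a detection is labeled
*anticipating* when the tipping fraction at c_sig is negligible and
*detecting* when warnings co-occur with ongoing noise-induced escapes.

## Weight optimization

The score of a weight vector is the sum over noise intensities of the
composite detector's lead distance (absent detections contribute 0). The
search is exhaustive over the stride-0.1 simplex lattice (66 points for
three indicators) because the problem is non-convex; the full argmax set
is reported since lead distances are quantized by the parameter grid and
exact ties are genuine. The deterministic representative of a tied set is
the ascending-lexicographic first vector in indicator order (var, ac1,
hs). Sensitivity analysis re-scores ±δ perturbations of each argmax
component re-projected onto the simplex. A Kramers regime map over
(σ, c − c₀) separates the bifurcation-dominated regime (escape time far
beyond the observation window) from the noise-dominated one and guides
the choice of noise grids that span both.

## Study conditions (desk scale)

The headline optimization runs the autocatalytic loop (K = 0.1, n_h = 2)
on its upper branch with control grid c: 2.40 → 1.80 in steps of 0.01
(61 levels; the baseline c = 2.40 is far from the fold c₀ ≈ 1.7872 and
essentially free of n-tipping), a noise grid of 8 log-spaced intensities
σ ∈ [0.05, 0.4] spanning both Kramers regimes, 50 trajectories per
level with 4 stationary samples each at Δt_s = 5 (≥ 3 baseline decay
times apart, so the ~200 pooled entries per level are weakly dependent
and sit at the few-dozen-to-few-hundred-entries scale of typical
replicate-ensemble experiments), transient 50, B = 50 bootstrap
replicates and the conservative p_sig = 0.01. Because the argmax of a
non-convex, noise-quantized score wobbles between seeds, the whole study
is replicated 3 times with independent seeds and the lattice is ranked
by the score summed over replicates. Under these conditions the additive
optimum concentrates weight on the variance (with a minor AC(1)/entropy
share), while under purely multiplicative noise (h = x) the optimum
shifts toward entropy-bearing mixtures; the variance retains part of the
multiplicative-noise weight because the onset of partial tipping
inflates it sharply, a real feature of the pooled ensemble data. These
sizes are the package's declared desk-scale conditions; the same
machinery accepts denser grids and larger ensembles unchanged.

## Synthetic fixture generator

`empirical.make_fixture` emulates the layout of the budding-yeast
collapse experiments (daily-dilution populations approaching an
Allee-effect fold): eight ordered control levels mapped linearly onto c
from a far baseline to just above the fold, ~60 pooled stationary
measurements per level with synthetic day labels 1–5. What it reproduces:
the bistable collapse structure, level-resolved replicate distributions,
day pooling. What it does not: calibration-curve unit conversion,
day-to-day drift and batch effects, unequal replicate counts, and any
correlation structure of real microplate measurements — so green
fixture-based tests demonstrate the pipeline's statistical behavior, not
agreement with the deposited data (which the pipeline accepts via
`load_table` when available locally).

## Numerical choices and limitations

Root finding clears the Hill denominator and uses `numpy.roots` plus
bisection polishing; near-duplicate roots within 1e−9 are merged (folds).
Stability at |∂ₓf| < 1e−10 is treated as non-stable (no decay rate).
Quadratures use `scipy.integrate.quad` at tolerances 1e−8–1e−10.
`sqrt_f` noise clips negative drift to zero under the radical, and its
derivative is zero where f ≤ 0. Ties in the argmax set are resolved only
for reporting, never silently dropped. Known limitations: one-dimensional
drifts only (reductions of higher-dimensional networks are assumed done
upstream); white noise only (no colored-noise processes); the pooled
bootstrap requires weakly dependent samples, so densely sampled segments
should be thinned before the distribution-data pipeline; the Kramers
expression is used comparatively, not as a quantitative first-passage
model.
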