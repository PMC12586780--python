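# Methods

## Heat-exchange model

Muscle temperature is modelled as a single well-mixed compartment
exchanging heat with the ambient water,

    dTb/dt = k (Ta(t) − Tb(t)) + Ṫm,

with `Tb` the muscle temperature (°C), `Ta` the ambient water temperature
along the animal's track, `k` the whole-body heat transfer coefficient
(°C min⁻¹ °C⁻¹ ≡ min⁻¹) and `Ṫm` a constant internal heat production rate
(°C min⁻¹). Constancy of `Ṫm` assumes roughly constant cruising effort over
the analysis window; time-varying heat production is out of scope. The
two-regime variant replaces `k` with `k_warm` when `Ta ≥ Tb` (the fish is
warming) and `k_cool` when `Ta < Tb`. The ratio `k_warm/k_cool` is the
quantity of biological interest: a fish that cannot modulate its
heat-exchange rate has a ratio near 1, while active control of exchanger
efficiency or circulation produces ratios of 10–50.

**Discretisation.** The data are uniform 1-min series but the model is a
continuous ODE. Two schemes are provided. Forward Euler
(`tb[t+1] = tb[t] + Δt·(k(ta[t] − tb[t]) + Ṫm)`) is the default; it is
stable and accurate for the rates encountered here (k ≤ 0.1 min⁻¹ at
Δt = 1 min) and raises when `k·Δt ≥ 1`, where the step would overshoot.
The exact exponential step integrates the linear ODE across each interval
holding `Ta` piecewise constant and is unconditionally stable; with the
`k = 0` limit `tb[t+1] = tb[t] + Ṫm·Δt`. The two schemes agree to first
order in `Δt` (tested), so at 1-min resolution the choice is immaterial to
the fitted parameters at the precision reported.

**Regime rule.** The warming/cooling switch is keyed to the *predicted*
muscle temperature, making the prediction a closed forward simulation from
the first observed value — no information from the observed trace leaks
into the trajectory after its initial condition. Keying to the observed
trace is available (`tb_obs=` / `regime_on_observed=`) as a sensitivity
check; for well-fitting traces the two choices give indistinguishable
estimates.

**Fitting.** All free parameters (k or k_warm/k_cool, and Ṫm) start at
0.01 with box bounds [0, 1] and are estimated by bounded nonlinear least
squares (trust-region reflective) on the residual between the observed
trace and the forward simulation. When the Euler scheme is used, the upper
k bound is clipped infinitesimally below `1/Δt` so the optimizer cannot
step onto the unstable boundary. Non-convergence triggers up to five
restarts from log-normally jittered initials before raising. A series in
which `Ta ≡ Tb` throughout carries no information about `k` and is
rejected as degenerate.

**Goodness of fit and selection.** `rss`, `MAE = Σ|e|/n`, and the Gaussian
least-squares AIC `n·ln(rss/n) + 2(p+1)` (error variance counted as a
parameter) are reported; only AIC *differences* on the same data are
meaningful, and no attempt is made to match any particular software's
additive AIC convention. A perfect fit yields an `aic = −inf` sentinel.
Model selection takes the lower-AIC model unless the two-regime model's
relative MAE improvement is below a guard threshold (default 10%), in
which case the constant model is kept: AIC on long autocorrelated traces
essentially always rewards the extra parameter, while a near-zero MAE gain
is the practical signature of overfitting. The threshold is configurable
and the decision is recorded in the selection rationale.

## Preprocessing and segmentation

Deployments natively sampled at 1 s are reduced to 1-min series:
block means for water-column profiling, first-of-block subsampling for
model fitting (the reader auto-detects the native step). The first 6 h
(configurable) are discarded to remove capture effects, and time is
re-zeroed afterwards by default since `Ṫm` is assumed constant only over
the analysed window.

The thermocline is detected per deployment: ambient temperature is grouped
into 1-m depth bins, empty interior bins are filled by linear
interpolation between neighbouring bin means (count logged, so sparse
coverage is auditable), and the bin means are smoothed by a centred moving
average spanning ±10 m (21 bins; truncated at the profile edges). A
symmetric window is used so the gradient location is unbiased. The
thermocline is the midpoint of the adjacent-bin pair with the steepest
first-difference gradient. Smoothing converts a sharp interface into a
linear ramp whose gradient ties across the window, so exact ties resolve
to the centre of the shallowest maximal tied run — this recovers the
interface depth exactly for a step profile; for a degenerate perfectly
linear profile it returns the profile midpoint. Profiles with under 30 m
of depth coverage, or fewer than 21 smoothed bins, are rejected. Note the
smoothed profile is a *box-averaged* version of the water column: for a
sigmoid column with 10-m transition scale the smoothing itself biases
temperatures near the inflection by up to ~0.2 °C, but the gradient
*location* — the quantity used downstream — is unbiased (recovered within
2 m across seeds in tests).

Deep dives are maximal runs of consecutive samples strictly below the
thermocline; runs lasting ≤ 10 min (inclusive threshold) are excluded. A
run's duration is the time it covers (samples × step). Separate runs are
never merged: a brief return above the thermocline splits a dive, the
simplest defensible convention in the absence of a stated merging rule.

## Comparative analysis

Per-individual heat transfer coefficients across species are modelled on
the log10 scale:

    log10(k) = Xβ + u + s + ε,
    u ~ N(0, σ²_p A),   s ~ N(0, σ²_s I),   ε ~ N(0, σ²_e I),

where `X` contains an intercept, `log10 Mass`, endothermy, and optionally
their interaction; `u` is a phylogenetic species effect with Brownian
covariance `A`; `s` an independent species effect absorbing intraspecific
replicate structure; `ε` individual residual. The ratio response
`k_warm/k_cool` is computed per individual before the log transform.
Captive and field individuals of a species are pooled.

**Tree handling.** Topologies are read from Newick (branch lengths, if
present, are ignored). Grafen branch lengths are assigned: node height =
descendant tip count − 1, scaled to unit root height; the result is
ultrametric with root-to-tip depth 1, so `A` has unit diagonal and entries
equal to the relative depth of each pair's most recent common ancestor. A
basal polytomy (star tree) is a valid input and yields `A = I`.

**Sampler.** With a Gaussian response every full conditional is
closed-form, so the posterior is drawn by a blocked Gibbs sampler: normal
updates for β (diffuse prior, variance 1e8), the vector `u` (using a
fixed precomputed `A⁻¹`, jittered by 1e-10 on the diagonal) and `s`;
inverse-gamma(0.001, 0.001) updates for the three variances. The chain is
initialised at the OLS solution. Defaults are 20 000 iterations, 2 000
burn-in, thinning 20 (900 retained draws) — deliberately scaled down from
long production chains (a 500 000/50 000/500 preset is provided as
`FULL_MCMC`) because the Gaussian conjugate chain mixes quickly at these
problem sizes; the star-tree fit matches the OLS oracle within Monte-Carlo
error at these settings (tested). With one individual per species, `u`,
`s` and `ε` are only weakly separable; their sum — and hence β and DIC —
remains well identified, which is what the analysis uses.

**Model ranking.** DIC is computed from the conditional deviance (random
effects in focus, as is common for hierarchical Gaussian models):
`D(θ) = −2 log N(y | Xβ + u + s, σ²_e I)`, `pD = D̄ − D(θ̄)` at posterior
means, `DIC = D̄ + pD`. Other software may integrate the random effects
out or focus differently; DIC differences between formulas on the same
data are the meaningful output. Candidate formulas (`mass`, `mass+endo`,
`mass*endo`) are ranked ascending with Δ DIC to the best; a data hash
guards against ranking fits of different data.

**Contrasts.** Posterior-mean group lines `k = 10^intercept · Mass^slope`
are evaluated at a reference mass; fold-differences are reported in the
direction in which endothermy is distinctive — endo/ecto for `k_warm` and
for the warming:cooling ratio, ecto/endo for `k_cool`.

## Synthetic data

The generator defines the study conditions for every test:

* **Water column** — logistic profile from 25 °C at the surface to 14 °C
  at depth, midpoint 100 m, half-width 10 m (a typical low-latitude
  stratification with a 11 °C contrast). Logistic was chosen so the
  steepest-gradient thermocline has an exact analytic location; it is an
  artifact choice, not a claim about any particular site.
* **Dive schedule** — 24 h at 1-min steps: three dives to 250 m with
  120-min bottom phases and 120-min surface intervals, descent/ascent at
  50 m min⁻¹. This mirrors repeated multi-hour foraging excursions below
  the thermocline; depth is exactly trapezoidal so below-thermocline runs
  are countable by construction.
* **Deployment** — ambient from the column along the track (treated as
  exact); muscle from the forward heat model (two-regime defaults
  k_warm = 0.052, k_cool = 0.0036 min⁻¹, Ṫm = 0.0062 °C min⁻¹ — the scale
  estimated for a large, strongly regulating individual) plus i.i.d.
  Gaussian sensor noise, 0.1 °C by default. One seeded generator, one
  normal vector.
* **Comparative table** — masses log-uniform over 0.01–1600 kg (the span
  of published datasets); group lines default to the published endothermic
  and ectothermic warming/cooling allometries; effect scales
  σ_phylo = 0.10, σ_species = 0.10, σ_resid = 0.15 on the log10 scale,
  i.e. phylogenetic and species scatter comparable to, and residual
  scatter somewhat larger than, a ~0.1-dex measurement repeatability.
  Draw order per seed: masses, then per response phylogenetic effects,
  species effects, residuals.

What the generator does **not** emulate: behavioural realism (speed,
acceleration, bout structure), depth-dependent sensor lag, solar heating
at the surface, pre-dive warming driven by physiological anticipation, or
measurement error in literature-digitised coefficients. Passing recovery
tests therefore demonstrates correctness of the estimators under the
stated model, not robustness to those field phenomena — in real traces,
episodes of active thermogenesis appear precisely as structured residuals
against this model.

## Numerical conventions and edge cases

* Temperatures are validated to the open interval (−5, 45) °C; time steps
  must be uniform within 1e-9 min; rows with non-finite fields are dropped
  on read with a logged count.
* Resampling requires the interval to be an integer multiple of the native
  step; incomplete trailing blocks are dropped.
* The time-above-ambient fraction uses strict inequality (`Tb > Ta`).
* `argmax` ties in thermocline detection: see segmentation above.
* Dive extraction uses strict `depth > thermocline`.
* `rss = 0` maps to an `aic = −inf` sentinel rather than an error.
* All stochastic entry points take an integer seed and are reproducible
  byte-for-byte; the CLI records the seed and a config hash in
  `provenance.json`.

## Known limitations

* The heat model has a single compartment; muscle–core gradients and
  circulatory time lags (tens of minutes in some sharks) are not
  represented and will appear as fit residuals.
* AIC and DIC magnitudes are convention-dependent; only differences within
  this package's conventions are comparable.
* The Gibbs sampler assumes a Gaussian response after log10 transform;
  non-Gaussian responses and measurement-error models are out of scope.
* Grafen lengths are a topology-only surrogate for divergence times;
  absolute phylogenetic variance estimates inherit that arbitrariness,
  though fixed-effect inference is insensitive to it at these sample
  sizes.
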