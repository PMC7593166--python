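# Methods

This note documents the models, the synthetic study design, the numerical
choices and the known limitations of the package, in the order a reader
would meet them.

## The growth model

The plant is a six-pool system: shoot and root structural mass
(`M_s`, `M_r`), carbon substrate in shoot and root (`C_s`, `C_r`) and
nitrogen substrate in shoot and root (`N_s`, `N_r`), all in arbitrary mass
units. Per month (the model's native time unit):

- carbon uptake (shoot): `U_C = σ_C · f_photo · M_s / (1 + M_s/K_M)`
- nitrogen uptake (root): `U_N = σ_N · f_N · M_r / (1 + M_r/K_M)`
- growth (each organ `i`): `G_i = g · f_growth · (C_i/M_i)(N_i/M_i) M_i`,
  consuming substrate with fixed stoichiometry (0.45 carbon and 0.03
  nitrogen per unit of new structure)
- substrate transport against a resistance:
  `τ_C = (C_s/M_s − C_r/M_r) / (r · (1/M_s + 1/M_r))` shoot→root, and the
  mirror-image nitrogen flux root→shoot
- structural loss: `(m_turn + 0.2 · f_resp) · M_i`.

The environmental modifiers are all bounded in [0, 1] and combined by
Liebig's law of the minimum:

- `f_photo = min(trapezoid(T_day; β1..β4), ramp(R; β5,β6), ramp(W; β7,β8))`
  in the standard variant, or the Farquhar modifier (below);
- `f_N = min(trapezoid(W; γ1..γ4), ramp(N_soil; γ5,γ6), ramp(T_soil; γ7,γ8))`;
- `f_growth = trapezoid(T_day; δ1..δ4)`; `f_resp = ramp(T_day; ρ1,ρ2)`.

A trapezoid is the piecewise-linear 0→1→0 response with four ordered knots
(tolerance limits and optimum plateau); a ramp is the saturating 0→1
response with two knots. `T_day = (tmax + tmean)/2` stands in for daytime
air temperature and `T_soil = tmean` for soil temperature; these are
conventions, chosen once, since monthly climate layers carry no sub-daily
information.

Seven scalars complete the parameter vector: `σ_C`, `σ_N`, `g`, `K_M`,
`m_turn`, `r` and the cloglog scale `φ`, giving 29 free parameters in the
standard variant. The respiration amplitude (0.2 of the loss-rate scale)
and the growth stoichiometry are fixed constants so that the free count
stays at 29. The Farquhar variant freezes β1..β8, leaving 21.

### Integration and steady state

Explicit Euler with 10 sub-steps per month (reference default). The yearly
cycle repeats until the relative change of annual-mean biomass falls below
`tol = 1e-4`, up to `max_years = 200`; non-convergence returns the last
value with a warning, never an exception, so optimization stays total. All
pools are floored at `1e-9` and substrate pools are capped at the
structural mass they sit in (concentrations ≤ 1); the cap bounds the
dynamics for every parameter combination an optimizer can propose, which a
raw Euler scheme does not otherwise guarantee. Pure-Python `step()` and the
compiled batch kernel implement the identical update rule and are tested
for exact agreement over a simulated year.

The year-over-year stopping rule under-detects slow geometric
convergence (residual error is roughly `tol · ρ/(1−ρ)` for contraction
rate `ρ` near one), so checks that compare steady states across initial
conditions run at `tol = 1e-7`; at the default tolerance the worst
slowly-equilibrating cells agree only to about 1e-3. At the range margin
the model is genuinely bistable — a small initial plant dies while a
large one persists, an Allee-like consequence of growth scaling with the
product of substrate concentrations — so initial-condition independence
holds (and is verified) for core-range cells, not for cells at the edge
of viability.

The fitting layer integrates more coarsely — 3 sub-steps per month,
60-year horizon — which agrees with the reference settings to about 1e-3
in relative biomass while making a DE population evaluation roughly seven
times cheaper. Steady-state biomass is reported as the annual mean of
month-end biomass, so a seasonally oscillating steady cycle has a
well-defined summary.

## Farquhar photosynthesis variant

Net assimilation is the minimum of the Rubisco-limited and
RuBP-regeneration-limited rates at `Ci = 0.7 · Ca` with `Ca = 338 ppm`,
minus dark respiration. Kinetic constants are von Caemmerer-style C3
textbook values (Vcmax25 = 80, Jmax25 = 128 µmol m⁻² s⁻¹, Kc25 = 259 µbar,
Ko25 = 179 mbar, Γ*25 = 38.6 µbar, O = 205 mbar, α = 0.3, θ = 0.7,
Rd25 = 0.8), exposed through a config dataclass. Vcmax and Jmax use a
peaked Arrhenius response (deactivation enthalpy 200 kJ mol⁻¹, entropy
650 J mol⁻¹ K⁻¹) so the temperature response is unimodal; the Michaelis
constants, Γ* and Rd scale with plain Arrhenius terms. Radiation in
MJ m⁻² day⁻¹ converts to photon flux via a 50% PAR fraction, 4.57 µmol/J
and a 12-h photoperiod.

The modifier handed to the growth model is `max(A, 0) / A_ref` clipped to
[0, 1], where `A_ref` is net assimilation at 25 °C under saturating light
(2000 µmol m⁻² s⁻¹ — full sunlight; with these constants the electron
transport branch remains marginally limiting there, which is realistic
physiology). Because the Farquhar model carries no soil-moisture
dependence but moisture limitation of carbon gain must persist after β7,β8
are removed, the modifier is multiplied by a fixed, non-estimated ramp
`ramp(W; 0.05, 0.35)`. This is a design choice of the package; the
alternative — dropping moisture limitation of photosynthesis entirely —
would silently shift all moisture response onto nitrogen uptake.

## Inverse estimation

The Bernoulli negative log-likelihood of presence/pseudoabsence labels is
evaluated at probabilities clipped to `[1e-9, 1 − 1e-9]`; duplicate forcing
rows (records sharing a grid cell) share one steady-state simulation per
candidate.

Ordering constraints never reach the optimizer: trapezoids are searched as
(first knot, three non-negative increments) and ramps as (first knot,
positive increment), with knot boxes spanning the observed training range
of the driving variable ±20%. Rates are searched in log10 over four
decades; `φ` over six, because it must track the spread of steady-state
biomass across candidate physiologies, which varies more than any single
rate.

The optimizer is classic DE/rand/1/bin (mutation 0.8, crossover 0.9,
greedy selection, population-batched objective). The low-level routine
defaults to the textbook population of 10 × dimension; the `TTRSDM`
estimator uses a desk-scale default of 32–40 members for 30–40 generations,
which fits one species in under a minute on one CPU. Half the initial
population is uniform over the box; the other half is biased toward
permissive modifiers (wide trapezoids, low ramp thresholds), because a
uniformly random physiology almost always yields zero biomass everywhere
and a flat likelihood. Twelve *climate-envelope* candidates are also
seeded: response plateaus at presence-cell quantiles (computed both from
per-cell annual means and from pooled monthly values — different species
geometries favour one or the other), ramps saturating near the low end of
the presence range, mid-range rates and three cloglog scales. These use
only the training data. A fit is `converged` when the best value is
unchanged over the final 20% of at least ten generations.

Recovery of a species' thermal niche is judged behaviourally, not on knot
values: the fitted model is probed on synthetic cells with constant
temperature and mean moisture/radiation/nitrogen, and the midpoint of the
half-maximum span of the resulting suitability curve is compared with the
generating species' midpoint. During inverse estimation the temperature
constraint can be absorbed by the photosynthesis trapezoid, the growth
trapezoid, or their interaction with seasonal dynamics; probing behaviour
is the only parameterization-independent measure.

## The correlative baseline

A maxnet-style model: linear, quadratic and hinge features (10 knots per
variable; forward and reverse hinges), plus pairwise products when at
least 80 presences are available — mirroring maxnet's sample-size-dependent
feature classes — all built from training statistics and rescaled to
[0, 1] by training ranges, then an L1-penalized binomial fit over a
decreasing penalty path ending at 1% of `λ_max` (the glmnet convention;
`reg_multiplier` scales this endpoint). Prediction features are clamped to
the training range by default, as MaxEnt clamps. The implementation is a
penalized logistic regression on the equal-size presence/pseudoabsence
sets rather than the infinitely-weighted Gibbs formulation; the evaluation
battery consumes suitability rankings, for which the two agree.

## Synthetic study design

The grid (default 60 × 40 cells at 0.25°, 12 months) is split into a
western training region and an eastern test region. All stochastic fields
are generated on the western half and replicated eastward, so at
`novelty_strength = 0` the test region is an exact environmental replica
of the training region — regional exchangeability holds by construction —
and the novelty transform is the only systematic inter-region difference.
Every layer is a latitudinal gradient plus Gaussian-filtered (smooth,
spatially autocorrelated) noise plus a small white per-cell component; the
white component keeps the 61-variable environmental covariance well
conditioned, the role microclimate variation plays in real layers.
Moisture shares temperature's latitudinal gradient (wet-cool to dry-warm),
tightly confounding the two drivers inside the training region as
continental climate gradients do.

Novelty (strength `s`) shifts the test region's temperature by up to
`2.5·s` °C and moisture by up to `−0.06·s` along an eastward ramp, and
adds `0.10·s · t_anomaly` to moisture — a rotation of the
moisture-temperature coupling, so novelty changes the multivariate
combination and not just univariate ranges. At `s = 2` the NT2 scores of
test cells straddle 1 (graded extrapolation).

Virtual species are jointly temperature- and moisture-limited: the
photosynthesis temperature trapezoid sits at a chosen centre (plateau
±1.5 °C, support ±3 °C) and the nitrogen-uptake moisture trapezoid
(plateau ±0.10, support ±0.20) is anchored at the moisture conditions
prevailing where that temperature occurs in the training region. Because
growth integrates the seasonal cycle, the realized range width is governed
by the balance of favourable-month carbon gain against year-round
turnover, not by the trapezoid alone; the turnover rate is therefore
calibrated by bisection so each species occupies ≈15% of the training
region, and `φ` is then set so the best cells reach suitability 0.98.
`moisture_limited=False` produces the purely thermal species used for
parameter-recovery runs. True suitability always goes through the full
growth-model prediction path — no shortcut formula.

Presences are drawn from training-region cells by Bernoulli thinning of
true suitability (and from test-region cells, the same way, for test-domain
evaluation only). Zonation is clara-style k-medoids (24 zones; repeated
PAM on 200-row subsamples, Euclidean distance on z-scored variables, best
medoid set by total dissimilarity). Presences are thinned to at most 1,000
spread evenly across occupied zones; pseudoabsences equal presences in
number, half from the training region stratified by its zones, half from
the test region stratified over all zones, and the identical set feeds
every model.

The default experiment (10 species, 150 presences each, DE budget 40
generations × 40 members) runs in about ten minutes on one CPU. Per-species
seeds derive from the master seed via `numpy.random.SeedSequence.spawn`.

## Evaluation battery

Sensitivity `S = TP/(TP+FN)`, specificity `s = TN/(FP+TN)`, prevalence
`P = (TP+FP)/total`, bias `B = P − (TP+FN)/total`. TSS is implemented as
`S + s − 1` (the Allouche et al. true skill statistic); a
`printed_tss` compatibility flag exposes the `S − s` variant found in some
sources, which is inconsistent with TSS's definition and is off by
default. Undefined ratios are NaN, never 0. The classification threshold
maximizes `S + s` over observed score values, ties broken toward the lower
threshold (favouring sensitivity); test-domain confusion matrices use the
training-derived threshold (configurable in principle — the alternative of
re-optimizing on test data answers a different question). AUC is the
rank-based Mann-Whitney estimator with half credit for ties. Spatial
disagreement counts quarter-degree cells whose thresholded classifications
differ. NT2 is the squared Mahalanobis distance to the training mean under
the training covariance, scaled by the maximum squared distance among
training points, so training points score ≤ 1 and scores > 1 flag
extrapolation. Test-domain evaluation requires a species to occupy at
least 20 test-region cells.

The correctness-vs-novelty regression is a logistic model with
model-specific intercepts and NT2 slopes and a species random effect on
the intercept, fitted by the Laplace/MAP approximation of statsmodels'
Bayesian binomial mixed GLM (weak N(0, 5²) priors on fixed effects);
with a single species it collapses to a plain GLM. Paired model
comparisons use the two-sided paired t-test on per-species metrics.

## What the synthetic experiment does and does not show

Passing the transferability criteria on virtual species shows that *when
the data-generating process is the growth model itself and the training
region confounds the causal drivers*, inverse estimation recovers
structure that extrapolates, while an L1-penalized feature model drops
drivers that add no discriminative signal in training and mispredicts
where the confounding breaks. That is the mechanism claimed for real
species, demonstrated under controlled conditions. It does not show that
real plants follow transport-resistance dynamics, that real adventive
ranges differ from native ones only through climate (no dispersal limits,
no biotic interactions, no land use), or that the magnitude of the
advantage on real data matches the synthetic one. The generator also omits
topography, spatially biased sampling, and observation error in the
occurrence coordinates.

Two further honest caveats. First, the Bernoulli likelihood on
native-range presences plus half-outside pseudoabsences actively rewards
suppressing predicted suitability in the test region; the process model's
structural rigidity is what limits this carving, and the paired AUC
contrast in the test domain is accordingly small (the sensitivity and
novelty-slope contrasts are large). Second, DE fit quality varies across
species at desk-scale budgets; a species occasionally fits poorly in the
training domain, which the experiment reports rather than retries.

## Numerical and degenerate-input choices

Equal trapezoid knots degrade to step transitions; `ramp` requires
strictly increasing knots. `liebig` of an empty set is an error. Constant
feature columns are dropped with a warning; a constant score vector has no
threshold and is flagged. A singular NT2 covariance falls back to the
pseudo-inverse with a warning. An all-zero coefficient vector from the
penalized path gets the exact closed-form null intercept
(logit prevalence), which the stochastic-gradient solver approaches too
slowly at extreme penalties. Non-convergent steady states return the last
annual mean with a warning. Fits with fewer than 15 presence cells raise a
typed error, and the CLI translates it to a non-zero exit with a message
naming the rule.
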