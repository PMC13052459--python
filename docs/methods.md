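# Methods

This note documents the models implemented in `postsmolt`, the choices
made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the package's numerical
conventions.

## Detection cleaning

Raw receiver offloads contain false detections (code collisions,
multipath echoes) alongside genuine tag transmissions. Three filters run
in a fixed order:

1. **Unknown tags** — records whose ID matches no deployed transmitter.
2. **Minimum gap** — within each (tag, receiver) stream, a record less
   than `min_gap` (default 15 s) after the last *retained* record is
   dropped. The 15 s threshold sits below the 18 s minimum transmitter
   delay, so no genuine ping pair can violate it. The greedy
   keep-first rule is deterministic; the alternative (compare with the
   previous *raw* record) differs only on runs of three or more
   sub-threshold records and is not used.
3. **Singletons** — a record with no other same-tag, same-receiver record
   within ±`singleton_window` (default 30 × the 35 s upper nominal delay
   = 1050 s = 17.5 min) is dropped. The window is two-sided and is
   evaluated on the stream that survives the minimum-gap rule.

The audit identity `n_output = n_input − n_unknown − n_min_gap −
n_singleton` is enforced structurally. `clean` is idempotent, and with
`min_gap → 0`, `singleton_window → ∞` reduces to the unknown-tag filter
alone. A post-cleaning plausibility report compares implied between-array
speeds with a configurable ceiling (default 10 km h⁻¹) but never deletes
records: cleaning decisions are restricted to the three mechanical rules.

## By-water distances

The seascape is a binary raster (water/land) with square pixels, default
40 m. Movement between water cells uses a 16-direction topology: the
8 king moves (weights 1 and √2 pixels) plus the 8 knight moves (weight √5
pixels). A knight move is admitted only when at least one of the two
orthogonally adjacent intermediate cells on its path is water, so paths
cannot jump thin land barriers. Distances are Dijkstra shortest paths on
this sparse graph (`scipy.sparse.csgraph`), giving by-water distances with
roughly one-pixel precision and a lattice overshoot below ~3% relative to
the Euclidean metric in open water.

Open choices, exposed as configuration: off-water points snap to the
nearest water cell within 3 pixels (receivers are digitised near
shorelines); an array's representative point for the array-to-array
matrix is its median-rank receiver, which is robust to array length.
Coordinates are planar metres; at a study extent of ~100 km a local
projection is adequate and the module stays CRS-agnostic.

## Distance-scaled Cormack–Jolly–Seber model

Each expected migration pathway (a `PathwayGroup`) is an ordered sequence
of occasions — the river (entry) receiver, then arrays — with a habitat
label and a by-water distance per transition. A fish's encounter history
is 1/0 per occasion; fish enter the model only if detected at the entry
occasion, so the first digit is always 1.

The likelihood is the standard CJS product multinomial with one change:
segment survival is `s_t ** d_t`, where `s_t` is the *per-kilometre*
migration success rate and `d_t` the segment length in km. This is the
unequal-interval device of classical capture–mark–recapture software with
distance in place of time; `s = 0.9` means a 90% chance of completing one
kilometre. Never-seen-again probabilities use the usual χ recursion.
Parameters live on a logit link. The survival submodel may include
habitat (marine inlet vs coastal) and year; the detection submodel may
include array identity and year; both are additive (no interactions) —
the global models are deliberately small because pathway sample sizes are
a few hundred fish. Two constraints are always applied: freshwater
transitions have Φ ≡ 1 (entry into the study conditions on surviving the
river) and the final array has p ≡ 1 (beyond it only the product Φ·p is
identifiable; the final estimate therefore absorbs any shortfall in
terminal detection).

Fitting is quasi-Newton (BFGS) from five seeded starts with a gradient
tolerance of 1e-8; the objective is capped at 1e12 to keep finite
differencing clean near the boundary. Standard errors come from the
inverse numerical Hessian (central differences); natural-scale intervals
are computed on the link scale and back-transformed. Estimates with
|link| > 12 are flagged as boundary cases. `n_eff` for AICc is the
number of fish entering the model.

**Overdispersion.** ĉ is the mean of three resampling estimators
computed on the global model: observed deviance over mean parametric-
bootstrap deviance; observed deviance/df over its bootstrap mean; and a
median-ĉ — datasets are simulated at 10 dispersion levels spanning
[1, 3] (dispersion induced by cluster resampling: simulate N/c
independent fish, resample with replacement to N), 100 replicates per
level by default, and the 50% point of a logistic regression of the
exceedance indicator on the level is taken. Deviance is measured against
the saturated per-cohort multinomial. A model that saturates its cell
space carries no dispersion information and returns ĉ = 1, flagged.
Raw ĉ is reported; it is floored at 1 when computing QAICc (which also
charges one extra parameter for the estimated dispersion).

**Model averaging.** Candidate sets are all nested combinations of the
global model's terms (16 models for two-zone pathways with two estimable
arrays and two years; 4 for single-zone pathways; degenerate covariates
are dropped automatically). Models within δ ≤ 13.044 of the best
(Q)AICc are averaged with weights ∝ exp(−δ/2) on the real-parameter
scale, cell by cell (per transition/array × year), with Buckland
unconditional standard errors. Models with non-positive coefficient
variances are retained in the set.

## Migration timing

The arrival day at an array is the integer (floored) day of year of the
first detection there. The timing model is
`arrival_day ~ year × river + (1 | array) + (1 | tag)`, fitted by maximum
likelihood (not REML, so likelihood-ratio tests between fixed-effect
structures are valid). The two random intercepts are crossed — every tag
can appear at every array — and are implemented as variance components of
a single-group mixed model (`statsmodels MixedLM`). Marginal and
conditional R² follow the variance-partition formulation (fixed-effect
variance over total, and fixed plus random over total).

Prediction intervals are simulation-based: fixed effects are drawn from
their estimated sampling distribution, the array intercept enters at its
conditional mean, and fresh individual and residual noise are added;
default 1000 draws at the 95% level, seeded. A migration window for a
river-year runs from the smallest lower to the largest upper interval
limit across its arrays; the cross-population overlap interval is also
reported.

## Migration speed

Speed is by-water distance divided by the elapsed time between first
detections at the segment's two arrays (default: marine-inlet exit to the
coastal array), in km h⁻¹. Records with non-positive elapsed time are
rejected with a log entry. The model is an ordinary Gaussian linear
model (the ML fit of an identity-link GLM) in year, river and
marine-entry day (centred) with pairwise interactions, reduced by
backward likelihood-ratio elimination: interactions are droppable before
their main effects, the largest p-value above α = 0.05 goes first, and
every test is recorded. Per-river predicted means with 95% confidence
intervals are reported from the final model.

## Passage points and corridors

The receiver (rank 1 = most southerly) first detecting a fish on an array
is its passage point. Ranks are mapped to the open unit interval by
y′ = (y − a)/(b − a) and y″ = (y′(n − 1) + 0.5)/n with n the number of
observations entering the model fit (a single global n keeps scaled
values comparable across river-year groups; a per-group alternative is a
function argument away). The inverse transformation rounds to the
nearest integer rank, clamped to [a, b]; it inverts the forward map
exactly for every rank when n ≥ 2 (n = 1 collapses all information to
0.5 by construction).

Empirical corridors are the 5/25/50/75/95% quantiles of rank (linear
interpolation, rounded to integer ranks). The model is a
variable-dispersion beta regression with density Beta(μτ, (1 − μ)τ):
E[y″] = μ (logit link) and Var[y″] = μ(1 − μ)/(1 + τ), so τ (log link)
is inverse spread. Both submodels may include year, river, arrival day
(centred at its sample mean for stable interactions) and pairwise
interactions. Fitting delegates to `statsmodels`' beta model; an
independent log-density implementation is kept in the package and
cross-checked against the fitted likelihood in the tests. Backward LRT
selection runs over both submodels jointly with the same marginality and
α rules as the speed model. Model corridors are the central 50% and 90%
quantiles of the predicted beta distribution back-transformed to ranks;
groups with fewer than 5 fish raise a small-sample warning.

## Synthetic data

The generator emits complete study bundles with the structure every
downstream stage assumes, under one seed (two runs are identical):

* **Cohorts** — the published per-river, per-year study-design table
  (15 cohorts, 1559 tags, mean 103.9 per cohort) supplies cohort sizes,
  fork-length/mass distributions, tagging-date windows and in-river
  attrition before the entry receiver.
* **Geometry** — an open-water rectangle (50 × 80 km) with river
  receivers near the west shore, five 7-receiver inlet arrays, and a
  127-receiver coastal array at 603 m spacing running south to north.
  The scenario grid uses 250 m pixels (the distance module's default
  remains 40 m): at the study's array separations the added metric error
  is far below the survival estimates' sampling error, and graph
  construction stays light.
* **Survival truth** — per-km rates per habitat (default 0.990 for inlet
  and coastal water), applied as `s ** d` with the *same* by-water
  distance matrix the analysis later computes, so recovery tests are not
  confounded by metric error.
* **Detection** — fish cross arrays on constant-speed tracks; tags ping
  at uniform 18–35 s delays; each ping reaches each in-range receiver
  with probability α/(1 + exp(k(r − D50))), D50 = 320 m (within the
  sentinel-tag 293–354 m range) and k chosen so detection falls to 5% of
  α at 2 × D50. The per-ping scale α is calibrated by bisection so that
  the probability a crossing leaves a *cleanable* record (two hits on one
  receiver within the singleton window) matches the configured array
  efficiency; realised post-cleaning efficiencies land within ±0.03 of
  target. Terminal arrays are generated at saturation, matching their
  fixed p = 1 role in the CJS.
* **Timing and speed** — release days are uniform within each cohort's
  published tagging window; per-fish speeds are lognormal around
  1.1 km h⁻¹ (σ = 0.25); inter-array arrival times follow from distance
  over speed, so array timing offsets emerge as mean travel times. A
  purely additive arrival-day generator (river-year mean + array offset +
  individual offset + residual — exactly the timing model's data-
  generating process) is provided separately for the timing module's
  recovery tests, because combining a free additive day structure with
  constant-speed tracks can imply negative travel times.
* **Passage** — positions on the coastal array are beta draws per
  river-year (2019 means from ~0.07 for the southernmost river to ~0.30
  for the Kyle rivers, τ = 20; 2021 shifted by the published year-
  correction coefficients), inverted through the unit-interval scaling to
  receiver ranks.
* **Noise** — 0.5% unknown-ID records, 1% isolated pings (post-release,
  random receivers) and 0.2% sub-15 s echo duplicates exercise all three
  cleaning rules without dominating the stream.

Not emulated: currents and tides (tracks are straight, speeds constant),
depth or temperature effects on detection range, predator-carried tags,
clock drift, and between-receiver heterogeneity within an array. Passing
recovery tests therefore show the estimators are correct for data meeting
the models' assumptions; they do not show robustness to these field
realities.

## Problem sizes and runtime conventions

The default test and acceptance runs use the full 1559-tag scenario for
end-to-end recovery; 500 replicates at n = 300 for confidence-interval
coverage; 500 null replicates at n = 120 for the speed LRT calibration;
six replicate fits of 600 rows (25 tags × 24 arrays) for the
mixed-model variance recovery, averaged to stabilise the array component
(a variance component with a few dozen levels has ~30% sampling noise per
fit); and 200 replicates for the null backward-selection rate, asserted
at ≥ 0.75 against an expected (1 − α)⁴ ≈ 0.81 with four noise terms.
Pipeline defaults scale the ĉ resampling to 100 bootstrap and 10 × 20
median-ĉ replicates; the `estimate_chat` function defaults remain at the
canonical 1000 and 10 × 100. Recovery of survival and detection is
assessed on the median across pathway cells, mirroring how a multi-river
study summarises many small cohorts; individual small cohorts (e.g. a
river with ~30 entrants) have wider errors.

## Known limitations

* Additive global CJS models only; interaction structures (habitat × year)
  are out of scope, as are individual covariates on Φ and multi-state
  models.
* The ĉ cluster-resampling scheme induces approximate, not exact,
  multinomial variance inflation; median-ĉ is accordingly an
  approximation of the classical procedure.
* Fixing p = 1 at the terminal array means the last segment's Φ absorbs
  any true detection shortfall there — an identifiability fact, not an
  implementation choice.
* Prediction intervals treat the array intercept's conditional mean as
  known; for arrays with very few arrivals the intervals are slightly
  narrow.
* The beta regression's global n in the unit-interval scaling makes
  scaled values comparable across groups but ties the transformation to
  the fitted dataset's size; refitting on a subset changes y″ slightly.
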