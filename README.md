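# postsmolt

Analysis pipeline for the inshore marine migration of acoustic-tagged
Atlantic salmon (*Salmo salar*) post-smolts. Juvenile salmon tagged in
their natal rivers are re-detected (or not) at lines of moored hydrophone
receivers ("arrays") as they cross the freshwater exit, a marine inlet and
the open coastal zone. From raw receiver offloads the package estimates
how many fish survive the crossing, when they travel, how fast, and
*where* along a coastal receiver curtain they pass.

It is written for fish ecologists and telemetry analysts working with
coded acoustic tags (fixed-delay transmitters, receiver-curtain designs)
who want a scripted, auditable version of this analysis chain:

1. **Cleaning** (`postsmolt.cleaning`) — three sequential filters on raw
   detections: unknown transmitter IDs; sequential detections at one
   receiver closer than 15 s (below the minimum transmitter delay);
   single detections with no same-tag/same-receiver neighbour within
   17.5 min (30 × the 35 s upper nominal delay). Every removal is
   reconciled in an audit.
2. **Seascape** (`postsmolt.seascape`) — by-water least-cost distances on
   a rasterised water mask (default 40 m pixels) with a 16-direction
   movement graph (king + knight moves), plus minimum-distance pathway
   polylines between array passage points.
3. **Survival** (`postsmolt.cmr`) — a distance-scaled Cormack–Jolly–Seber
   model. Per-fish encounter histories over the ordered arrays enter a
   product-multinomial likelihood in which the probability of completing a
   segment of length *d* km is *s*^*d*, with *s* the per-km migration
   success rate (logit link; habitat and year covariates) and *p* the
   array detection efficiency (logit link; array and year covariates).
   Freshwater passage is fixed at Φ = 1 and detection at the final array
   at *p* = 1. Overdispersion ĉ is estimated by parametric bootstrap
   (mean of three resampling estimators), candidate models are ranked by
   AICc/QAICc, and estimates are model-averaged over all models within
   δ ≤ 13.044 with Buckland unconditional standard errors.
4. **Timing** (`postsmolt.timing`) — arrival day of year per tag × array,
   modelled as `arrival_day ~ year × river + (1 | array) + (1 | tag)`
   by maximum likelihood; simulation-based 95% prediction intervals;
   migration windows spanning the extreme interval limits per river-year.
5. **Speed** (`postsmolt.speed`) — by-water distance divided by elapsed
   time between first detections, modelled with a Gaussian linear model
   and backward likelihood-ratio selection.
6. **Passage** (`postsmolt.passage`) — the receiver rank (south → north)
   first detecting each fish on an array, mapped to the open unit interval
   via y′ = (y − a)/(b − a), y″ = (y′(n − 1) + 0.5)/n, and modelled with a
   variable-dispersion beta regression: location μ (logit link) and
   precision τ (log link), density Beta(μτ, (1 − μ)τ), each a function of
   year, river, arrival day and pairwise interactions. Corridor widths
   are central 50%/90% quantile bands back-transformed to receiver ranks.
7. **Synthetic data** (`postsmolt.simulate`) — complete seeded study
   bundles (eight rivers, two years, ~100 tags per cohort, a 127-receiver
   coastal array at 603 m spacing) with ping-level detection under a
   logistic range curve (D50 ≈ 320 m, calibrated per-array efficiency),
   per-km survival truth, beta-distributed passage positions, lognormal
   speeds around 1.1 km/h and injected noise to exercise cleaning.

## Worked example

```python
from postsmolt import cleaning, cmr, simulate

bundle = simulate.scenario_moray(seed=1)            # full synthetic study
cleaned, audit = cleaning.clean(bundle.detections, bundle.deployments,
                                cleaning.CleaningConfig())
print(audit.as_dict())

group = bundle.groups["OykelShin"]                  # shared Kyle pathway
hist = cmr.build_encounter_histories(cleaned, bundle.deployments,
                                     bundle.receivers, group)
print(len(hist), cmr.min_migration_success(hist, 1))
mset = cmr.fit_model_set(hist, group, n_boot=0)
print(mset.table.head(3))
print(mset.averaged.query("kind == 's_per_km' and not fixed"))
```

prints (abbreviated):

```
{'n_input': 86367, 'n_unknown_tag': 425, 'n_min_gap_removed': 170,
 'n_singleton_removed': 2811, 'n_output': 82961}
367 79.56...
              model  K  logLik    AICc  delta  weight  retained
      Phi(~1) p(~1)  2 -539.84 1083.71   0.00    0.17      True
Phi(~habitat) p(~1)  3 -539.15 1084.36   0.65    0.12      True
   Phi(~year) p(~1)  3 -539.22 1084.52   0.81    0.11      True
       label  year  estimate  se_unconditional
marine_inlet  2019    0.9901            0.0018
marine_inlet  2021    0.9893            0.0021
     coastal  2019    0.9912            0.0010
     coastal  2021    0.9905            0.0012
```

Reading this: 86 367 raw detection records reduce to 82 961 after the
three cleaning rules; 367 Oykel/Shin fish entered the study; 79.6% of
those detected leaving freshwater were re-detected at the inlet array
(raw minimum success, uncorrected for detection efficiency); and the
model-averaged per-km migration success rate is ≈ 0.990 in both habitats
and years — i.e. a 99.0% probability of migrating each kilometre — which
matches the generator's configured truth of 0.990 km⁻¹.

The same analysis runs from the shell:

```sh
postsmolt simulate --seed 1 --out-dir study/
postsmolt clean --detections study/detections.csv \
    --deployments study/deployments.csv --out study/cleaned.csv \
    --audit study/audit.json
postsmolt run --seed 1 --out-dir results/
```

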