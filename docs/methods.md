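# Methods

This note documents the statistical models, conventions and design
choices behind `firesync`, in the spirit of a model-description appendix:
what each procedure assumes, which knobs matter, and what the validation
suite does and does not establish.

## Fire record model

A fire-scar record is a set of tree series, each with a calendar span,
optional pith/bark bounds, dated fire scars (season classes D/E/M/L/A or
U for undetermined) and per-year recorder status. Two invariants are
enforced at construction: scars lie within the series span, and every
scar year is a recording year (a scarred tree is by definition a recorder
in that year — a scar read from inside a non-recording run is promoted
with a logged warning).

FHX dialect conventions (the format in circulation varies): both `FHX2
FORMAT` and `FIRE2 FORMAT` headers are accepted and `FHX2 FORMAT` is
emitted; every series span is delimited by explicit start/end markers
(`[`/`{`, `]`/`}`), with `.` filler outside; a boundary year inherits the
recording status of its interior neighbour, since the single boundary
character cannot carry both the bound type and recorder state; site name
and series-to-plot mapping persist in `;`-comment preamble lines so a
collection round-trips field-for-field.

## Composite chronology rules

* **Event rule**: a year is a fire event when ≥ `min_trees` (default 2)
  trees carry a dated fire scar. Injuries (lowercase codes) never count.
* **Cohort verification**: a single-scar year becomes a
  `cohort_verified` event when ≥ `min_cohort` establishment years fall in
  `(year, year + 10]`. The window is half-open because cohorts are
  post-fire; establishment within a decade of an *existing* event is
  attributed to that event and cannot verify another year. `min_cohort`
  defaults to 5 trees — the record-reliability convention used for
  sample depth in composite chronologies; the number of recruits that
  constitutes a cohort is genuinely unstated in field practice, so it is
  exposed as a parameter.
* **Intervals**: MFI is the mean of successive composite event-year
  differences (identically span/(n−1)); PFI pools within-tree successive
  scar intervals over trees with ≥ 2 scars. No Weibull median interval is
  computed — only mean intervals are reported. Both raise
  `UndefinedIntervalError` below the minimum event/scar count.
* **Severity**: an event is `mixed` when a post-event cohort established
  in ≥ 1 burned plot within the cohort window, else `low`. With an
  unknown burned-plot set, any plot counts.
* The composite is computed at the study-area scale by default (the
  scale at which interval statistics and the synchrony analysis are
  defined); per-plot composites are available by filtering the
  collection.

## Extreme-climate event sets

Event sets are rank-based and therefore invariant under monotone
transformations of the index values. Single-index sets take the k = 50
most extreme years in the chosen phase direction within the analysis
period (each index's native reconstruction span intersected with an
analysis window that by default ends at 1893, the last fire year).
Phase combinations rank each index in its phase direction (rank 1 = most
extreme), sum ranks per year, and keep the k = 100 smallest rank sums.
Rank-sum was chosen over union/intersection because it always returns
exactly k years; the alternatives are available via `rule=`. All ties —
in values and in rank sums — break toward the earlier year,
deterministically.

Fire-year moisture classification thresholds the PDSI at ±1 by default
(≤ −1 warm/dry, ≥ +1 cool/wet, else average). The thresholds are
conventional round numbers on the PDSI scale, not estimated quantities,
and are configurable.

## Bivariate event analysis

Discrete-time convention: years are integer points; the backward window
at lag t contains t + 1 years (lags 0..t), because fires may respond to
the *current* year's climate as well as previous years. Edge correction
is Ripley-style: each fire's pair count at lag t is divided by
w(f, t) = (window years inside the domain)/(t + 1), up-weighting fires
near the domain start rather than discarding them; `edge_correction="none"`
is provided for oracle comparisons. Under the uniform null
E[K̂(t)] = t + 1 exactly, which the envelope means reproduce.

Null models: the default redraws the n₂ climate years uniformly without
replacement (fixes the count, destroys all structure); a circular-shift
alternative preserves the event set's internal spacing/autocorrelation
for users who want a more conservative null. Envelopes are pointwise
percentile bands (2.5/97.5 and 0.5/99.5 for the 95% and 99% levels) over
n_reps = 1000 replicates by default — *not* simultaneous bands, so with
~40 lags a few pointwise exceedances are expected under the null; the
reported alpha is the band's two-sided level, stated explicitly in the
result object rather than converted to a per-tail "p". Classification is
strict: synchronous iff K̂ above the upper band, asynchronous iff below
the lower band.

t_max defaults to 40 years, comfortably covering multidecadal climate
lags while staying well below typical domain lengths (~600 years); the
estimator refuses t_max ≥ T.

A `randomization_sanity` helper re-runs the full envelope analysis with
uniformly random "fire" years against real climate-event sets; with no
signal present, non-independent lags should appear at about the nominal
pointwise rate.

## Frequency tests

G = 2 Σ Oᵢ ln(Oᵢ/Eᵢ) with the 0·ln 0 = 0 convention, df = categories − 1,
p from the χ² upper tail. Expected counts follow the equal-likelihood
null: Eᵢ = total fires × (years in category i)/(total years). Williams'
correction is off by default and available as an option; with few fires
the expecteds are small, so any Eᵢ < 5 is flagged and an exact Monte
Carlo multinomial p-value can be requested. Phase-combination tests are
binary by default (in vs. out of the combined extreme set); three-way
combinations are conventionally evaluated on a late sub-period (default
1700–1893) where the record is densest, passed explicitly as the test
period.

## Spatial GLMs

Poisson GLMs with log link are fitted by IRLS (via statsmodels), with
convergence at relative log-likelihood change < 1e−8 within 100
iterations; non-converged or rank-deficient candidates are excluded from
selection with a logged warning (rank deficiencies name the aliased
columns). The candidate set is all 64 subsets of the six conceptual
predictors, with vegetation entering as one dummy block (reference:
blanket bog) and aspect as northness = cos(aspect) by default — a
circular variable should not enter a linear predictor raw, though raw
degrees are available for strict emulation of legacy analyses.
Model scores: AICc, ΔAICc, Akaike weights over the full candidate set,
evidence ratios, and deviance-based pseudo-R² (1 − D_res/D_null; the
"which pseudo-R²" question is open in general, and deviance-explained is
the natural one for GLMs). Averaging uses the smallest top set with
cumulative weight ≥ 0.95, renormalised weights, shrinkage for absent
predictors (contribute 0), Buckland-style unconditional standard errors,
and relative importance = weight sum over set models containing the
predictor. No overdispersion correction is applied — plain Poisson is
the stated model; with ~30 plots and small counts, quasi-likelihood
corrections would be poorly identified anyway.

## Synthetic generator

The generator emulates a ~700-year, ~30-plot coastal study system:
AR(1) climate indices (PDSI rescaled to sd 2 and clipped to ±6; optional
ENSO–PDO cross-correlation 0.4), a uniform-random plot scatter over a
2000 × 1500 m extent with three fixed habitation sites, and an annual
Bernoulli fire process per plot with log-odds
β₀ + β_dist·d + Σ γ_lag·index(year − lag). Defaults: β₀ = −8.5,
β_dist = −0.002 m⁻¹, forcing −1.5 per PDSI unit at lag 1 (antecedent
drought raises fire odds), human ignitions ending in 1893 with an
essentially zero background thereafter (the system is ignition-limited:
negligible lightning). These rates were set so a realisation yields on
the order of 40–50 scarred trees, ~60–110 scars and ~16–28 composite
events before cessation — the size of record such a field campaign
produces — and the validation suite asserts totals within a factor two
of (45 trees, 99 scars, 16 events) across seeds.

Tree records: two candidate trees per plot (pith uniform 1225–1325,
alive with bark through the period end) each register a plot fire with
probability 0.6 as a 'U' scar — season undetermined, the realistic case
for rot-prone wet-forest samples — and become recorders from their first
scar. Each plot fire triggers an establishment cohort (8 recruits,
uniform 1–10-year lags) with probability 0.5, on top of 10 background
recruitment years per plot.

What the generator does **not** emulate: spatial fire spread (plots burn
conditionally independently given climate, so "events" are synchronous
scars rather than contiguous burns), variable tree longevity and
mortality, seasonality of scars, dating error, and non-stationary
climate. Passing recovery tests therefore demonstrates that the
estimators work when their assumptions hold — not that real records meet
those assumptions.

## Validation design and problem sizes

The suite validates each stage against an independent route:

* K estimator vs. a brute-force pair-counting oracle, exactly, on 1000
  random instances (n₁, n₂ ≤ 20, T ≤ 200, t_max ≤ 50).
* Envelope calibration: 500 independent null datasets (16 fires, 50
  climate events, T = 600, t_max = 10, 1000 replicates each); the
  pointwise 95% exceedance rate must fall in [3%, 7%].
* Planted-signal power: fires placed exactly 3 years after 50 climate
  events on T = 600; synchrony at every lag ≥ 3 must be detected in
  ≥ 90 of 100 seeds.
* G statistic vs. scipy's log-likelihood-ratio power divergence, plus a
  1000-dataset null simulation with 100 fires (large enough that the χ²
  reference is accurate; with ~16 fires the discreteness of the count
  distribution makes the nominal 5% level unattainable pointwise, which
  is exactly why small expecteds are flagged).
* GLM recovery at the study's size (n = 30 plots, slope −0.002 m⁻¹):
  Wald 2-SE coverage over 500 replicates (≥ 95%) and AICc top-model
  recovery of the true predictor over 200 all-subsets selections
  (≥ 90%).
* FHX round-trip identity on 100 random collections, plus property
  tests for rank invariances, monotonicity of the event rule in
  `min_trees`, and MFI = span/(n−1).

These sizes keep the whole suite around a minute on one CPU while giving
binomial Monte Carlo error well inside each asserted band.

## Known limitations

* MFI/PFI on sparse records are sensitive to single added/removed
  events; the package reports them but deliberately attaches no
  uncertainty (interval distributions are not modelled).
* Pointwise envelopes do not control the family-wise error over lags; a
  contiguous multi-lag excursion is stronger evidence than an isolated
  one, and the window summaries are meant to be read that way.
* The G-test's χ² reference is anticonservative at small expected
  counts; use the Monte Carlo p-value when the flag is raised.
* The rank-sum phase-combination rule is one defensible reading of
  "combining the highest/lowest ranked values"; union and intersection
  readings are provided but produce variable set sizes.
* Edge correction assumes the process is stationary across the domain;
  a record whose early centuries are recorder-poor violates this in
  spirit, which is why recorder depth is reported alongside events.
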