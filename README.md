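# firesync

Fire-history reconstruction and fire–climate synchrony analysis for
fire-scar tree-ring records, built for the kind of study system where the
questions are hardest: wet, ignition-limited forests with sparse fire
evidence, where a few dozen scarred trees across ~30 plots must carry the
entire inference about who or what set the fires.

`firesync` is aimed at fire ecologists and dendrochronologists working
with composite fire-scar chronologies. It covers the full chain:

* **FHX I/O** — read/write the standard Fire History Exchange text matrix
  (`firesync.fhx`), with per-tree scar records and recorder-depth curves.
* **Composite chronologies** (`firesync.chronology`) — the multi-tree
  event rule (a fire year needs scars on ≥ 2 trees), promotion of
  single-scar years corroborated by post-fire establishment cohorts
  within a decade, mean fire interval (MFI) and point fire interval
  (PFI), and low/mixed severity labelling.
* **Extreme-climate event sets** (`firesync.climate`) — top-*k* years of
  a reconstructed annual index (PDSI, ENSO, PDO, AO) in either phase, and
  rank-sum combinations of two or three index phases.
* **Bivariate event analysis** (`firesync.bea`) — a one-dimensional
  bivariate Ripley's K testing whether climate events cluster in the lag
  window before fire years, with Monte Carlo envelopes.
* **G-tests** (`firesync.frequency`) — annual-scale frequency tests of
  fire occurrence in vs. outside climate phases against an
  equal-likelihood-of-burning null.
* **Spatial Poisson GLMs** (`firesync.spatial_glm`) — per-plot scar
  abundance and event frequency on topographic/cultural predictors, with
  all-subsets AICc selection, Akaike weights, evidence ratios and
  confidence-set model averaging.
* **Synthetic data** (`firesync.synthetic`) — a generator producing
  complete study systems (landscape, climate, fires, tree records) with
  known ground truth, used throughout the validation suite.

## The statistics at the core

For fire years $\{f_i\}_{i=1}^{n_1}$ and climate-event years
$\{c_j\}_{j=1}^{n_2}$ on a calendar domain of $T$ years, the
one-directional bivariate K at integer lag $t$ is

$$\hat K(t) = \frac{T}{n_1 n_2} \sum_i \sum_j
  \frac{\mathbf 1\,[\,0 \le f_i - c_j \le t\,]}{w(f_i, t)},$$

where $w(f,t)$ is the fraction of the backward window $[f-t,\,f]$ inside
the domain (Ripley-style edge correction). Under a uniform null
$\mathrm E[\hat K(t)] = t + 1$; significance comes from pointwise 95%/99%
envelopes over 1000 Monte Carlo randomisations of the climate events.
$\hat K$ above the band at lag $t$ means climate events occurred more
often than expected within $t$ years before fires (synchrony); below the
band, asynchrony.

Annual-scale phase preference uses the G-test,
$G = 2\sum_i O_i \ln(O_i/E_i)$ with $E_i$ proportional to the years each
phase covers, and spatial structure is modelled with Poisson GLMs ranked
by $\mathrm{AICc} = -2\log L + 2K + 2K(K+1)/(n-K-1)$, Akaike weights
$w_i = e^{-\Delta_i/2} / \sum_j e^{-\Delta_j/2}$, and shrinkage model
averaging over the 95% confidence set.

## Worked example

```python
from firesync import (SyntheticConfig, simulate_dataset, detect_fire_events,
                      verify_single_scar_events, mean_fire_interval,
                      point_fire_interval, select_extreme_years,
                      BivariateEventAnalysis, FireRegimeSelection)

ds = simulate_dataset(SyntheticConfig(), seed=3)

chron = detect_fire_events(ds.collection, min_trees=2)
chron = verify_single_scar_events(ds.collection, chron,
                                  ds.establishment_by_plot)
print(len(chron), mean_fire_interval(chron), point_fire_interval(ds.collection))

pdsi = ds.climate["PDSI"]
period = (pdsi.start, 1893)
dry = select_extreme_years(pdsi, "-", k=50, period=period)
fires = [y for y in chron.fire_years if period[0] <= y <= period[1]]
res = BivariateEventAnalysis(fires, dry.event_years, period,
                             t_max=40).fit(n_reps=1000, seed=3)
print(res.summary())

sel = FireRegimeSelection(ds.plots, "scar_abundance").fit()
print(sel.summary(max_rows=4))
```

This prints (seed 3):

```
events: 24  first: 1338  last: 1879
MFI: 23.5 yr   PFI: 145.3 yr

Bivariate event analysis (1-D bivariate Ripley's K)
  fires: 24  climate events: 50  domain: 1300-1893 (594 yr)
  Monte Carlo replicates: 1000  envelope levels: [0.95, 0.99]  (pointwise, two-sided)
  synchronous at 95% envelope: lags 1-40 yr prior
  synchronous at 99% envelope: lags 1-40 yr prior

Poisson-GLM AICc selection - response: scar_abundance (n = 30 plots, 64 candidate models)
                                               model  K pseudo_R2 dAICc     w   ER
dist_habitation + dist_shoreline + elevation + slope  5      0.28  0.00 0.259 1.00
        dist_habitation + dist_shoreline + elevation  4      0.24  0.72 0.181 1.43
                 dist_habitation + elevation + slope  4      0.22  2.59 0.071 3.65
                         dist_habitation + elevation  3      0.18  2.95 0.059 4.37
```

The synthetic regime plants two mechanisms, and the analysis recovers
both: fire odds rise after dry (negative-PDSI) years, so the drought
event set is synchronous from lag 1 onward ($\hat K$ is cumulative, so
synchrony persists at larger lags), and fire counts decay with distance
from former habitation sites, so `dist_habitation` leads every top model
(model-averaged slope −0.0017 per metre, relative importance 1.00).

A full pipeline run — chronology, event sets, G-tests, BEA per phase
combination, both GLM responses, plus a reproducibility manifest — is one
call (or `firesync run --out outdir`):

```python
from firesync import RunConfig, run_all
run_all(RunConfig(seed=3), "outdir")
```

## Command line

```
firesync simulate --seed 3 --out sim/        # synthetic dataset (FHX, CSVs)
firesync fhx validate sim/record.fhx
firesync fhx depth sim/record.fhx --out depth.csv
firesync chron detect --fhx sim/record.fhx --min-trees 2
firesync climate events --index sim/pdo.csv --sign + --k 50
firesync bea --fires fires.txt --climate events.txt --domain 1300:1893
firesync glm --plots sim/plots.csv --response event_frequency
firesync run --out outdir                    # full pipeline
```

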