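# phyllochron

Successive time-to-event modelling of leaf appearance dynamics from
interval-censored field phenotyping data.

## The problem

The *phyllochron* — the thermal time between the appearance of successive
leaves on a plant — is a central trait of cereal development, but it is
never observed directly: field crews visit a plot every few days and record
only the number of visible leaves per plant. Each leaf's appearance time is
therefore known only up to the interval between two visits, and naive
regressions of leaf count on time ignore both this censoring and the fact
that a plant late for one leaf stays late for the next ones.

`phyllochron` is written for quantitative geneticists and crop
physiologists analysing such longitudinal leaf-count data — for example
from divergent-selection experiments in maize with a hierarchical plant
material (ancestral line > Early/Late selection population > genotype,
grown in field rows over several years). It provides:

* a successive time-to-event model of leaf appearance with exact handling
  of interval censoring,
* Monte Carlo EM estimation of per-rank phyllochron parameters,
* row-permutation likelihood-ratio tests of genetic group effects across
  seven nested parameter-sharing models,
* parametric sub-models of the within-season phyllochron trend with
  LRT + AIC selection,
* a windowed-climate lasso regression with a "false climate" significance
  test,
* a full simulator so every stage is testable without field data.

## The model

On a leaf-rank window `[f_min, f_max]`, the appearance time (in
accumulated thermal time since sowing) of leaf `f` on a plant is

    H_f = H_{f-1} + Y_f,   Y_f ~ N(mu_f, sigma_f^2)   independent,
    H_{f_min} ~ N(mu_C, sigma_C^2),

where `(mu_C, sigma_C)` describe the **cumulated phyllochron** (sowing to
first modeled leaf, absorbing all earlier ranks) and `(mu_f, sigma_f)` the
**instant phyllochron** for ranks `f_min < f <= f_max`. Observations
constrain each `H_f` to an interval `(L_f, U_f]` read off the visit times;
the likelihood of a plant is the box probability of this Gaussian Markov
chain, computed exactly by forward Gauss–Legendre quadrature. Estimation
is by MCEM with a Gibbs sampler on the truncated chain. See
`docs/methods.md` for the complete description.

## Worked example

Simulate one genotype (120 plants in 12 rows, visits every 20 degree-days),
extract censoring intervals, select the identifiable leaf-rank window and
fit the model:

```python
import numpy as np
from phyllochron import (GenotypeKey, LeafRangeWindow, PhyllochronParams,
                         SimulationDesign, simulate_plants, fit_mcem,
                         McemSettings, extract_intervals, select_leaf_range)

key = GenotypeKey(line="F252", selection="Early", genotype="FE036", year="2015")
window = LeafRangeWindow(8, 12)
truth = PhyllochronParams(key=key, window=window, mu_C=160.0, sigma_C=10.0,
                          mu=[20.0, 22.0, 24.0, 21.0], sigma=[4.0, 5.0, 4.5, 4.0])
design = SimulationDesign(params={key: truth}, n_rows=12, plants_per_row=10,
                          schedule=np.arange(100.0, 360.0, 20.0), seed=42)
series, latent = simulate_plants(design)

intervals = [extract_intervals(s) for s in series]
windows, common = select_leaf_range({key: intervals}, min_plants=10)
est, trace = fit_mcem(intervals, windows[key], McemSettings(seed=0),
                      rng=np.random.default_rng(0))
```

Printed summary of the fit:

```
window: [9, 12]
mu_C = 177.4 dd   sigma_C = 10.3 dd
rank   mu_hat  sigma_hat
  10     21.4      5.3
  11     25.3      3.7
  12     20.1      3.5
observed-data log-likelihood: -295.4
iterations: 48, converged: True
```

The selected window starts at rank 9, not 8: the rule requires the rank
*before* the window to be observed (a visit before and after its
appearance) on at least 10 plants, and rank 7 never is, because counting
started at rank 8. Accordingly `mu_C` estimates the mean appearance time
of leaf 9 (truth 160 + 20 = 180 dd; estimate 177.4 dd) and the instant
estimates sit within a standard error of the true 22, 24, 21 dd.
Interval censoring at 20-dd visits limits the per-rank precision of
`mu_f` to roughly `sqrt((sigma_f^2 + 20^2/12) / n)` — about 0.6 dd at
n = 200 — which is worth keeping in mind when sizing a field design.

Group comparisons, trend selection and the climate model follow the same
pattern (`fit_shared`, `permutation_test`, `fit_submodel`,
`select_submodel`, `build_features`, `fit_climate_lasso`,
`false_climate_test`); the `phyllochron` command line exposes the pipeline
(`simulate`, `fit`, `compare`, `select`, `run` with a YAML config).

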