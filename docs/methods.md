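# Methods

## The model

A maize plant visited at discrete times reveals only its current number of
visible leaves; the appearance time of each leaf is interval-censored
between consecutive visits.  `phyllochron` models the appearance times of
one plant on a leaf-rank window `[f_min, f_max]` as a Gaussian Markov
chain:

* `H_{f_min} ~ N(mu_C, sigma_C^2)` — the **cumulated phyllochron**, the
  thermal time from sowing to the first modeled leaf, absorbing all earlier
  (unobserved) ranks;
* `H_f = H_{f-1} + Y_f`, `Y_f ~ N(mu_f, sigma_f^2)` independent — the
  **instant phyllochron** per rank `f` in `(f_min, f_max]`.

All times are accumulated thermal time (ATT, degree-days above a base
temperature, origin at sowing).  The chain structure means a plant that is
late for one leaf stays late for the following leaves, which a per-rank
regression on leaf counts cannot capture.  The Gaussian form is an
approximation adequate while `sigma_f` is small relative to `mu_f`; the
likelihood treats the model as an untruncated Gaussian, and positivity of
increments is only a simulation policy (`resample` by default, `allow` to
match the likelihood exactly, `truncate` as a third option).

Observations enter as per-rank boxes `(L_f, U_f]`: `L_f` is the last visit
at which fewer than `f` leaves were visible, `U_f` the first visit with at
least `f`.  Plants dissected mid-season contribute their prefix of
doubly-bounded ranks; one-sided tail constraints are dropped (dissection is
scheduled, not outcome-dependent, so the exclusion does not bias the
estimates).  Plants whose recorded counts ever decrease are discarded, and
the top two ranks of completely observed plants are flagged as unmodeled
(leaf emergence near panicle emergence is unreliable to score); both rules
are applied verbatim, with the trim depth configurable (`n_top_trim`).

A rank window is retained for analysis when ranks `f_min - 1` and `f_max`
are *observed* — at least one visit strictly before and one at/after the
appearance — on at least `min_plants` plants (default 10).  The window
common to all genotype-years is the intersection of the per-group windows.

## Exact likelihood

The observed-data likelihood of a plant is `P(L_f < H_f <= U_f for all f)`,
a box probability of a Gaussian Markov chain.  It is computed by a forward
pass: the density of `H_f` restricted to its box is carried on
Gauss-Legendre nodes and pushed through the `N(mu_{f+1}, sigma_{f+1}^2)`
increment kernel.  Integration ranges are the boxes intersected with the
marginal mean ± 10 sd; running products are rescaled to avoid underflow.
Gauss-Legendre quadrature was chosen over an equispaced trapezoid rule
because the integrands are analytic: 64 nodes already reproduce the
single-rank closed form `log[Phi((U-mu)/sigma) - Phi((L-mu)/sigma)]` to
1e-9, and doubling the node count changes multi-rank results by far less
than 1e-6 (the package default is 128 nodes for reported values, 48 for
per-iteration traces).

## MCEM

Parameters are estimated by Monte Carlo EM.  The E-step samples the latent
chains given the boxes with a red-black (even/odd rank) systematic Gibbs
scan: each `H_f` has a truncated-Gaussian full conditional obtained from
the Brownian-bridge-style conditioning on its neighbours, so one parity
class is updated in a single vectorized truncated-normal draw across all
plants.  The M-step is the closed-form Gaussian MLE (variances divided by
N) over all retained (plant, draw) pairs per rank.

Defaults: 50 Monte Carlo draws at the first iteration growing by 1.2 per
iteration, capped at 600; 100 burn-in sweeps at the first iteration only —
chains persist across EM iterations and get 10 re-burn sweeps after each
parameter update; thinning 5; convergence when the maximum relative
parameter change stays below 1e-3 for 3 consecutive iterations; the final
estimate averages the last 5 iterates to smooth residual Monte Carlo noise.
The cap and the warm-started chains are the package's own additions to the
classic increasing-sample-size schedule; both were validated against a
rejection-sampling oracle (moments of the constrained chain agree within
Monte Carlo error) and leave the fixed point of EM unchanged.
Initialization is method-of-moments on interval midpoints with sigma floored
at 1 degree-day.

Simulation studies at the package's reference conditions (200 plants, 12
ranks, visits every 20 dd, `mu_f ~ U[18, 25]`, `sigma_f ~ U[3, 6]`) put the
per-rank standard error of `mu_f` at about 0.6 dd.  This matches the
observed Fisher information of the exact censored-chain likelihood: with
20-dd visit intervals each plant's information about a rank mean is roughly
`1 / (sigma^2 + w^2/12)` with `w = 20`, so no estimator can do materially
better under this design; tighter recovery requires denser visit schedules
or more plants, not algorithmic changes.

## Group comparisons

Seven nested models `M_ij` tie the cumulated (`i`) and instant (`j`)
parameters at depth 0 (identical), 1 (ancestral line), 2 (selection
population) or 3 (genotype), with `(i,j)` restricted to the lattice chain
(0,0)-(1,0)-(1,1)-(2,1)-(2,2)-(3,2)-(3,3).  Mixed models are single joint
MCEM fits with two sharing index maps.  Each sharing cell contributes
`2 + 2 (f_max - f_min)` free parameters (mu and sigma are tied together, so
sigma parameters count).

Model pairs are compared by the LRT statistic.  Because plants within a
field row are correlated (shared micro-environment), the null distribution
is built by permuting whole rows: the permuted attribute is the deepest
level the full model distinguishes, shuffled between rows within strata
given by the next level up (and always within year).  Assignments
preserving per-group row counts are enumerated exhaustively when there are
at most `max_perms` of them (p = proportion of null LRTs >= observed,
identity included), otherwise sampled without replacement
(p = (1 + #{null >= obs}) / (1 + max_perms)).  Tests with <= 20 distinct
assignments are refused.  Null refits use a reduced MCEM budget
warm-started from the observed fit, and the observed statistic is computed
by the same reduced-budget procedure on the identity assignment, so
observed and null statistics are exchangeable under the null; all null
refits for one test run as a single batched fit through the vectorized
engine.  A reduced model that does not involve the permuted level is fitted
once (its fit is invariant by construction).  The asymptotic chi-square
p-value is reported alongside for reference.

## Parametric trend sub-models

The instant-phyllochron vector can be summarized per genotype-year by:
constant; constant-rate (linear in rank, centered at `f_min + 1`);
piecewise-constant (one level change at an integer breakpoint `kappa`
strictly inside `(f_min + 1, f_max)`); continuous piecewise-linear (two
slopes joined at `kappa`); or left free ("complete").  Fits use MCEM with a
constrained M-step: the unconstrained mean update is projected onto the
family by least squares weighted by per-rank contributing-sample counts;
`sigma_f`, `mu_C`, `sigma_C` stay free.  The breakpoint is chosen by
discrete search maximizing the observed-data (quadrature) likelihood; the
first candidate gets a full run and the rest short warm-started runs, which
reaches the same argmax at a fraction of the cost on well-separated
problems.  `kappa` counts as one estimated parameter.  Selection: families
beating the constant model in a chi-square LRT at p < 0.01 are admissible;
the admissible model with the lowest AIC = 2k - 2 log L wins, the constant
model wins by default, and when the complete model wins the best admissible
strictly-parametric family is reported alongside.

## Climate model

Estimated phyllochron means are converted to calendar days (`mu_cal`)
through the year's thermal-time series (linear interpolation within days;
day-resolution increments).  For each genotype-year and rank, the response
`mu_cal_{y,lsg,f}` is regressed on cumulative climate sums over backward
windows `W0 = (1, 2, 3, 5, 10, 20)` days before the anchor day
`floor(cal(mean appearance of leaf f))`, with unpenalized year-line
(`alpha_{y,l}`) and genotype (`beta_{lsg}`) effects (reference-coded, full
rank) and L1-penalized climate coefficients `gamma_{y,l,c,w}` (per
year-line by default; a pooled-gamma option exists).  The solver is
coordinate descent (scikit-learn) on internally standardized features;
weights enter exactly via row scaling; the unpenalized block is handled by
weighted partialling-out and refit after the L1 step.  The penalty is
selected by leave-one-genotype-year-out cross-validation (weighted when
weights are used).  Weights `omega_{y,lsg,f}` count the plants with at
least one visit before and one after the appearance of leaf `f`.

Prediction error (per held-out genotype-year, model refit on the rest) is
converted back to degree-days through the held-out year's thermal-time
series before computing `MSE = sum (mu_pred - mu_hat)^2 omega`.  The
false-climate test rebuilds the features and recomputes the
cross-validated MSE for many assignments of surrogate daily climates to the
experimental years; `p` = proportion of false climates with strictly
smaller MSE (ties count against significance).  A pool yielding fewer than
20 false assignments is refused.  No variable-selection interpretation is
attached to the gamma support by default: correlated climate variables make
the selected support unstable (`ClimateLassoFit.support()` exposes it with
that caveat).

## What the simulator emulates — and what it does not

`simulate` draws plants from the exact generative model: per-genotype
parameter sets, fixed ATT visit schedules (optionally jittered per row),
scheduled dissection (right-censoring at a target rank), and additive
row-level shifts producing within-row correlation for permutation-test
studies.  Counts below `f_min` are compressed into the baseline
`f_min - 1`.  Real field data additionally contain scoring errors (handled
only by the discard rule), non-Gaussian and possibly correlated increments,
spatial structure beyond rows, and thermal-time model misspecification;
passing tests therefore demonstrate the correctness and calibration of the
machinery under its own assumptions, not the biological adequacy of the
model for any particular dataset.

## Reference study conditions

Fixed once for the simulation studies in `phyllochron.simstudies` (sizes
chosen to emulate one year of a divergent-selection phenotyping trial at
desk scale):

* sampler/likelihood oracles: 2- and 3-rank boxes near the mean, 1e5
  retained Gibbs draws (50 parallel chains), 1e7 Monte-Carlo chain draws;
* recovery: 200 plants (20 rows of 10), ranks 5-16, visits every 20 dd
  from 60 dd, 20 seeds; doubling check at 400 plants, 4 seeds;
* permutation: 2 lines x 6 rows x 3 plants, ranks 6-8, 199 sampled
  permutations, 200 null and 50 power replicates, 30 dd cumulated effect;
* sub-models: ranks 8-14, 150 plants, jump of 6 dd at kappa = 11, 20
  seeds; constant-truth arm 10 seeds;
* climate: 3 years x 3 genotypes, ranks 8-13, 80 plants per genotype-year,
  one active variable ("T", 5-day window) whose generative anchor days are
  solved self-consistently with the feature construction, 39 false climates
  from an AR(1) surrogate pool, 10 strong and 8 null seeds.  The study uses
  the pooled-gamma analysis (one climate coefficient per (variable, window)
  across years) because the generative effect is shared across years — the
  correctly-specified choice there; per-year-line gamma remains the package
  default.  The null arm uses the true parameters directly: under
  climate-independence, estimation noise is irrelevant to the question
  being tested.

## Numerical choices and edge cases

* Truncated-normal draws by inverse CDF with clipping into the open box;
  degenerate boxes (width -> 0) concentrate mass correctly (uniform-limit
  variance `width^2/12`).
* Empty boxes (`L >= U`) are rejected at construction; boxes wholly outside
  mean ± 10 sd yield probability 0 (log-probability -inf with a warning).
* Sigma estimates are floored at 1e-2 dd during EM to avoid collapse on
  degenerate data; identical latent samples raise an error instead of
  returning sigma = 0.
* A rank with fewer than 2 contributing plants aborts the M-step with the
  rank named.
* `calendar_from_att` resolves flat (zero-increment) stretches to the
  earliest day, keeping the conversion monotone.
* LRT statistics may be slightly negative from Monte Carlo noise; values
  below -0.5 trigger a warning.
* In cross-validation, a year-line absent from the training fold gets the
  mean fitted year-line deviation (documented fallback).

## Known limitations

* No standard errors or confidence intervals on phyllochron parameters;
  uncertainty enters only through permutation tests and climate weights.
* The leaf-number prediction uses the marginal-difference formula; the
  event {H_f > t, H_{f+1} <= t} (possible only with negative increments) is
  clipped away — negligible while `sigma_f << mu_f`.
* Climate effects are additive and monotone within a window; no
  interaction or saturating response.
* Thermal-time response parameters are user-supplied (linear-above-base by
  default); they are never re-estimated.
* One-sided censoring information beyond a plant's last doubly-bounded rank
  is discarded.
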