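# Methods

`climconflict` implements a ladder of models for a balanced region x month
panel of conflict-event counts with climate regressors, together with the
evaluation machinery needed to compare the rungs, and a synthetic-panel
generator with known ground truth so that every stage is testable without
any external data.

## Data model

The universal input is a balanced panel: one row per (region, month) with a
non-negative integer event count `conflict` and three regressors —
temperature anomaly `TA` (deg C, deviation from a calendar-month
climatology, trailing 3-month mean), drought length `DL` (running count of
consecutive months with positive `TA`), and precipitation anomaly `PA`.
Region order is lexical and period order chronological throughout, so all
design matrices are reproducible. Unbalanced panels are rejected in strict
mode rather than imputed: silent mean-imputation would contaminate
fixed-effects estimates. Counts supplied as reals are accepted only when
integral to 1e-9.

Region geometry (centroids in decimal degrees) enters only the HAC
covariance; distances are haversine great circles at the IUGG mean Earth
radius 6371.0088 km.

## Feature construction

* **Monthly anomaly**: value minus the calendar-month mean over a baseline
  window. The climatology mean over the window is exactly zero per month by
  construction.
* **Rolling mean**: trailing (current month and the `window-1` preceding
  ones). Trailing rather than centered alignment keeps the regressor known
  at time *t*; the leading `window-1` entries are partial means so panel
  balance survives. Both choices are configurable.
* **Drought length**: `DL_t = DL_{t-1}+1` if `TA_t > 0` else 0.
* **Climate forcing** `C_t`: primary definition `sum_i c_it / Q_i(0.5)`
  with `Q_i` the per-region median, emphasizing common threshold
  exceedance. For anomaly series the per-region median is ~0 and the ratio
  is undefined; a floor of 1e-6 on `|Q_i|` triggers a hard error that
  points to the alternative standardized-deviation mode
  `sum_i (c_it - mean_i)/sd_i`, which is the default wherever the forcing
  is built from `PA`.
* **Group means**: region-level means of (TA, DL, PA) — the within-between
  (Mundlak) covariates — and period-level means feeding the temporally
  pooled model.

## The model ladder

1. **Gaussian fixed-effects OLS.**
   `conflict ~ TA + DL + PA` with region, year-month and region-month fixed
   effects, absorbed by alternating within-group demeaning iterated to a
   1e-10 change (cross-checked against full dummy expansion to 1e-8).
   Reported statistics: multiple R^2; within R^2 = 1 - SSR / SS(region-
   demeaned outcome); adjusted within R^2 with numerator df `n - n_regions`
   and denominator df `n - (slopes + absorbed FE rank)`, the FE rank
   computed exactly from the dummy matrix; Gaussian AIC with
   `k = slopes + FE rank + 1`. The absorbed-FE count conventions differ
   across software, so `n_params` is reported alongside.

2. **Spatial-temporal HAC covariance** (Conley x Newey-West). Sandwich
   `(X'X)^-1 M (X'X)^-1` on the absorbed design, with meat summed over all
   observation pairs weighted by a spatial kernel in centroid distance
   (uniform with 263 km cutoff by default, Bartlett optional) and a serial
   kernel in month lag (uniform with 4-month cutoff by default, Bartlett
   `1-|l|/(L+1)` optional). Within-region pairs have distance 0 and are
   always inside the spatial cutoff. Uniform-kernel meats need not be PSD;
   negative eigenvalues are clipped at zero and flagged. With both cutoffs
   zero the estimator reduces exactly to White's heteroskedasticity-robust
   sandwich — a test identity.

3. **NB2 GLM.** `conflict ~ NB(mu, Theta)` with log link and explicit
   reference-dropped FE dummies. Alternating IRLS for the coefficients
   (step-halving keeps the deviance monotone within each run) with a
   1-D profile update of `Theta` (bounded scalar optimization on
   `log Theta`), outer loop converged at a relative log-likelihood change
   below 1e-9. A ridge of 1e-6 on FE columns handles separation (a region
   with no events) and any residual dummy collinearity; large ridged FE
   coefficients are flagged. `AIC = -2 loglik + 2(k + 1)`, the `+1` for
   `Theta`.
   Randomized quantile residuals: draw `u ~ U(F(y-1), F(y))` under the
   fitted NB and map through the standard-normal quantile; under a correct
   model they are iid N(0,1) (probability integral transform). Values
   beyond the double-precision resolution of the normal quantile are capped
   at |z| = 8.2 and flagged.

4. **Bayesian hierarchy.** Three nested specifications (NB2 likelihood with
   log link; a Gaussian/identity variant of each for family comparisons):
   * *no pooling*: common slopes, free region intercepts, free year-month
     effects;
   * *region pooling*: region coefficient vectors (a_i, b_i, c_i, f_i) ~
     MVN(hypermeans, diag(tau) Omega diag(tau)), plus the group-mean
     covariates with slopes eta_1..3 — the within-between correction that
     keeps the partially pooled intercepts from leaking time-invariant
     confounding into the slopes;
   * *region + time pooling*: year-month effects pooled through
     `w_t ~ normal(psi0 + psi1 TAbar_t + psi2 DLbar_t + psi3 C_t, sigma_w)`.

   Priors (all overridable): coefficients, hypermeans, eta, psi and
   unpooled period effects ~ normal(0, 5); tau and sigma_w ~
   half-normal(0, 2); Omega ~ LKJ(2); `1/sqrt(Theta)` ~ half-normal(0, 1);
   Gaussian residual scale ~ half-normal(0, 2 sd(y)). These are deliberate
   weakly informative defaults chosen to regularize without overwhelming
   2808 observations.

### Parameterization

The LKJ prior is implemented in canonical-partial-correlation space: the
strictly-lower-triangular entries of the correlation Cholesky factor come
from tanh-transformed unconstrained values, and under LKJ(eta) the CPCs are
independent shifted-Beta variables, giving a closed-form log prior and
gradient. The implied Beta((eta-1)+d/2, .) marginal of a single correlation
is verified by sampling in the tests.

The region-coefficient block is **non-centered** (each region contributes
only a few dozen informative observations per coefficient; the centered
form funnels when a tau component is small, which `tau_b` typically is).
The period-effect block in the temporally pooled model is **centered**:
each `w_t` is informed by all regions in that month, and the non-centered
form couples (psi0, sigma_w, z_w) through the likelihood so strongly that
chains stall. Both blocks can be switched via `HierModelSpec`; gradients
for all four combinations are verified against finite differences.

### Sampling

Inference is by a self-contained No-U-Turn sampler: leapfrog integration
with a diagonal mass matrix estimated in expanding warmup windows, dual
averaging of the step size toward a 0.8 acceptance target (the averaging
state restarts whenever the metric changes), and binary trajectory doubling
with a slice variable, depth-capped at 9. Gradients of every model's log
posterior are analytic (hand-derived, finite-difference-checked), including
the chain rule through the CPC/Cholesky construction. Energy errors above
1000 are recorded as divergences and their subtrees rejected. A
fixed-trajectory HMC mode and a dense (shrinkage-regularized covariance)
metric exist as options.

A fit is *delivered* regardless of diagnostics; split R-hat >= 1.01,
bulk ESS <= 400 (arviz) or any divergence raises explicit flags with a
remediation hint. Two caveats are inherent to these models rather than to
the sampler: the absolute levels (phi0 vs psi0 vs the eta terms times
near-constant group means) are identified only through the priors, so their
marginal chains move slowly along a wide ridge — the scientifically
interpreted slope hypermeans and `Theta` are the well-mixing quantities —
and the small-sample marginal posterior of `Theta` can sit away from the
profile MLE because dozens of FE nuisance parameters are integrated rather
than profiled out.

All chain seeds derive deterministically from one master seed
(`SeedSequence([seed, chain])`); identical configurations reproduce draws
bit-for-bit.

## Evaluation

* **PSIS-LOO.** Importance ratios proportional to 1/likelihood per
  observation; the largest 20% (at least 5) are replaced by expected order
  statistics of a generalized Pareto fit to the exceedances (Zhang-Stephens
  profile posterior mean, with the usual weak pull of k toward 0.5),
  truncated at the raw maximum. Pointwise elpd is the log smoothed-weighted
  average of per-draw likelihoods; `k_hat > 0.7` observations are counted
  and reported, not refit. Validated against exact leave-one-out refits at
  n = 40 and against arviz with matched effective-sample settings.
* **ELPD comparison.** Differences against the best model with
  `se_diff = sqrt(N var(pointwise differences))`; the best row is exactly
  (0, 0).
* **Posterior predictive checks.** Replicated panels are simulated from
  the likelihood at posterior draws (uniformly resampled when more
  replicates than draws are requested; 8000 replicates by default, fewer in
  routine runs) using the observed predictors; the default statistic is the
  proportion of zeros, with a two-sided tail probability
  `ppp = 2 min(P(rep >= obs), P(rep <= obs))`. Gaussian-family replicates
  are continuous, so the statistic counts values that round to zero — this
  keeps it well defined while preserving the family contrast (a Gaussian
  fit to 60%-zero count data produces almost no near-zero replicates).

## Scenario projection

Posterior draws combine with a shifted panel ("+1 SD of TA" uses per-region
historical SDs; DL is re-derived from the shifted TA). In-sample horizons
reuse each draw's realized period effects; out-of-sample horizons require
the temporally pooled model and sample `w` from its level model with period
averages and forcing recomputed from the scenario panel, so parameter,
period and sampling uncertainty all propagate. Models with free period
effects are refused for out-of-sample horizons — they have no generative
story for unseen months.

## Synthetic panels

The generator mirrors the hierarchical data-generating process at the
study scale (18 regions x 156 months from 1997): jittered-grid centroids
over a Horn-of-Africa-sized box; raw monthly temperature and precipitation
as seasonal sine plus AR(1) innovations with exponential spatial
correlation (range 300 km, so the 263 km HAC cutoff is exercised); a
17-year pre-panel stretch so anomalies use a proper climatology and the
drought counter carries no start-of-window artifact; `DL` always derived
from `TA`, never simulated independently; region coefficients drawn from
the configured MVN; period effects from the `w` level model with the
standardized-deviation forcing; counts from NB2 via a gamma-Poisson
mixture.

Default truth values are fixed once to produce Somalia-like marginals —
`phi0 = -0.5`, `Theta = 0.8`, slope hypermeans of order 0.1,
`tau = (0.2, 0.05, 0.2, 1.0)` with modest coefficient correlations — giving
~55-65% zeros, occasional large counts and a heavy right tail. The
`confounding_strength` knob adds `kappa x standardized(TAbar_i)` to each
region's intercept mean, inducing exactly the dependence between region
baselines and region-mean climate that the within-between device exists to
neutralize.

What the generator does *not* emulate: the real joint distribution of
ACLED-style counts and CRU-style climate (only its statistical structure),
conflict spillovers between regions, serial dependence in counts beyond
what the regressors carry, and reporting artifacts. Passing tests
demonstrate that the estimators recover the structure they assume, not that
the substantive Somalia estimates are correct.

### A measured limitation of the within-between contrast

With `confounding_strength = 1`, the fully pooled NB slope on TA (no region
terms at all) is biased upward by ~0.35-0.65 against a true hypermean of
0.1 — the group-mean-corrected hierarchical fit removes essentially all of
it (replicated bias ratio well above 10x). The subtler contrast — the
hierarchical model *with* versus *without* the eta-terms — shows only a
replicate-noise-level difference at 36+ months per region: with that much
within-region data the region intercepts are barely shrunk, so omitting the
group means leaks almost nothing into the slopes. The correction is
retained because it is what licenses the fixed-effects-like causal reading
of the within-region slopes; its practical bite grows as panels get
shorter.

## Problem sizes used in the tests

Routine verification runs scaled-down versions of the full analyses, chosen
to exercise every code path at useful statistical resolution: study-scale
(18 x 156) refits with 2 chains x (300 + 300) draws for the frequentist and
region-pooled rungs; parameter recovery over 10 replicates at 18 x 36 with
2 x (250 + 250); the directional-findings ladder at 10 x 72 with
2 x (300 + 300); simulation-based calibration over 32 prior draws at 6 x 24
with tightened prior scales (weakly informative scales on log-link slopes
produce astronomically overdispersed prior-predictive counts; calibration
is a property of whatever prior is used). The analysis drivers under
`analysis/` and `scripts/acceptance.py` run the full 18 x 156 ladder.

## Known limitations

* No spatially structured random effects (regions are exchangeable given
  the covariates), no zero-inflated or hurdle variants, no K-fold or
  leave-one-region-out cross-validation.
* The HAC estimator assumes the balanced panel layout; unbalanced support
  would need re-derivation of the score bookkeeping.
* NUTS here is the classic slice-variable formulation with a diagonal
  metric; heavily ridged level parameters mix slowly (flagged, and their
  posterior spread is honest), and runs that need them resolved should
  raise warmup and tree depth.
* The median-ratio climate forcing is intentionally refused near zero
  medians instead of guessing a rescue; the standardized-deviation mode is
  the documented alternative.
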