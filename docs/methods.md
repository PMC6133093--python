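# Methods

## The model

A subject who dies at time `T` carries a biomarker (prothrombin index, %)
that is modelled in *revival time* `s = T − t`, i.e. backwards from death.
Observations at follow-up times `t_1 < … < t_k < T` are jointly Gaussian
with mean

    mu(s; T, arm) = beta_const + beta_arm + beta_T·T + beta_s·s
                    + beta_log·ln(s + delta)

and covariance

    Cov(i, j) = sigma2_b + sigma2_w·exp(−|s_i − s_j| / phi) + sigma2_e·1{i=j},

the sum of a subject-level random effect, a stationary serial process with
exponential correlation in revival time, and measurement error.  The
marginal survival distribution is exponential with rate `lambda0`.

Default mean coefficients are the uncensored-data values from the
prednisone/liver-cirrhosis trial analysis this package revisits:
constant 63.47, control offset 2.49, prednisone offset 13.56, `T` slope
1.74 per year, `s` slope −2.11 per year, `ln(s+delta)` coefficient 4.66,
with `lambda0 = 0.164` events/year.  The `ln(s+delta)` term produces the
steep biomarker collapse in the final months of life, which is the whole
source of the model's short-horizon predictive signal.

### Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `delta` | 0.1 | years | floor of the terminal drop; the source gives no value, 0.1 keeps the drop steep but finite |
| `sigma2_b / sigma2_w / sigma2_e` | 300 / 200 / 125 | (biomarker)^2 | only the total (625) is anchored; the split makes the patient effect dominant, as a shared-level random effect should be |
| `phi` | 1 | years | serial correlation range; the Ornstein–Uhlenbeck-style exponential kernel is the standard joint-model choice and is explicit and testable |
| `lambda0` | 0.164 | events/year | exponential marginal death rate |
| `t_lim` | 9 | years | observation limit; the alternative model refuses to say anything past it |

## What the generator emulates — and what it does not

`generate_cohort` draws `T ~ Exp(lambda0)`, a Bernoulli(0.5) arm, an
independent censoring time from a mixture `0.3·U(0,2) + 0.7·U(0,10)`
(reproducing a high early-censoring rate without asserting a fitted
mechanism), visits from the planned schedule
`{0, 0.25, 0.5, 1, 2, …, 9}` years attended with probability 0.9 and
truncated strictly before the end of follow-up, and biomarker values
`mu(s) + b_i + W_i(s) + eps` computed against the *latent* death time, also
for subjects who end up censored.

Real trial data differ in ways the generator deliberately ignores:
informative censoring, missed visits that correlate with health, biomarker
floors/ceilings and non-Gaussian tails, and calendar-time effects.  Tests
passing on these cohorts therefore demonstrate internal correctness of the
machinery (likelihoods, posteriors, calibration fits), not that the revival
model describes any particular trial.

## Fitting

With the variance components held at their configured values the mean is
linear, so the maximum-likelihood fit is generalized least squares with
per-subject covariance blocks; standard errors come from the inverse
information.  A flagged option profiles the four covariance parameters by
Nelder–Mead with the mean solved exactly at each step.

The three-way decomposition (constant + control offset + prednisone
offset) is aliased: the two arm indicators sum to the intercept column.
The fit estimates the identified quantities — control-arm level
(constant + control) and the prednisone−control contrast — and reports the
familiar decomposition by anchoring the control offset at a configurable
value (default 2.49).  The anchor is bookkeeping, not an estimate, and its
reported standard error is zero.

Three fitting subsets mirror the analysis designs: all uncensored
subjects; uncensored subjects dying before `t_lim`; and subjects followed
to `t_lim`, for whom the death time is unknown and the revival clock is
anchored at the limit (`s = t_lim − t`, measurements at `t ≤ t_lim`), with
the `T` covariate standing in as the observed follow-up end (or `t_lim`,
configurable).  The proxy is flagged in reports because it is a
convention, not an estimate.

## Profile inference on T

For a subject alive at a landmark `t_LM`, `ll(T)` is scanned on a grid
(default step 0.05 years) over `[t_LM, 9]` using the measurement
likelihood only — no marginal density of `T`; the grid's lower end encodes
survival to the landmark.  Because the covariance depends only on
measurement-time lags, one Cholesky factorization serves the whole grid.
Ties in the argmax resolve to the smallest `T` (logged); "boundary" means
within one grid step of either end; a quasi chi-square
`2·(ll_max − ll_min)` below 3.84 with an interior maximum marks a history
that does not localize `T` at all.  A sensitivity flag to add the log
marginal density exists but is off by default, keeping the inference
classical.

## Predictive distributions

**Standard model.**  The posterior over `T > t_LM` is proportional to the
history likelihood times the exponential density.  It is evaluated on
cells of width 0.02 years spanning 60 years past the landmark: each cell
carries its *exact* exponential prior mass times the likelihood at the
cell midpoint, and the prior mass beyond the grid is kept as an explicit
tail atom (likelihood frozen at the last edge, mass logged).  This makes
the empty-history case collapse exactly to the memoryless exponential
tail, and keeps `H_pred = −ln P(T > t_hor)` closed-form-correct there.
All accumulation is in log space with max-subtraction.  Stale measurements
need no special treatment: their revival time grows with `T − t`
automatically.

**Alternative model.**  Everyone is censored at `t_lim = 9`; the marginal
is the Kaplan–Meier curve; the posterior is discrete over the KM jump
times in `(t_LM, t_lim)` with prior mass from the KM increments, plus one
residual atom `{T ≥ t_lim}` carrying the KM survival mass at the limit.
Jump likelihoods use the before-limit revival fit; the atom uses the
survivor fit with the anchored clock and `T` covariate `t_lim` (the
fitting-time proxy, observed follow-up, is unknowable for a subject being
predicted).  No mean, covariance or likelihood is ever evaluated at a
death time beyond the limit — no imputation, by design.

## Landmark calibration

At each `t_LM` (default 1…7, window 2 years) the at-risk subjects are
followed to `t_hor = t_LM + 2` with administrative censoring.  Three fits:

* simple rate factor `c = deaths / (reference cumulative hazard)`, with
  `se = c/√deaths`; the reference is `lambda0 · exposure` for the standard
  model and the KM-implied per-subject cumulative hazard for the
  alternative (so a model-free marginal gives `c ≈ 1` up to KM
  discreteness);
* the exponential calibration regression
  `ln λ(t|H_pred) = α + β·ln H_pred`, maximized as a Poisson event-count
  GLM with log-exposure offset (identical score equations to the censored
  exponential likelihood); perfect calibration of a 2-year window means
  `β = 1`, `α = ln 0.5 ≈ −0.69`;
* a Cox fit with `ln H_pred` as the only covariate (Breslow ties).

Rows with `H_pred` numerically zero are excluded from the log-covariate
fits with a logged count.  The reported `Z` is the Wald statistic of the
exponential-calibration slope; the Cox slope and its `se` sit in adjacent
columns.

### A note on the perfect-calibration reference

The `(β, α) = (1, ln 0.5)` reference is exact when the hazard over the
window is constant given `H_pred`; `exp_calibration` recovers it to three
digits on large cohorts simulated that way.  Under revival self-simulation
the window hazard given the history is front-loaded for high-risk subjects
(the terminal drop says "dying now"), which pushes the realized rate per
unit exposure up faster than `H_pred` and nudges the fitted slope slightly
above 1 on average; with 2000-subject cohorts the single-replicate spread
of the slope is about 0.3, so slope and intercept are assessed (and
reported by `scripts/acceptance.py`) as means over 20 replicate cohorts.

## Problem sizes and numerical choices

Self-simulation checks run at: 20 replicates of 2000 subjects for the
calibration reference; 25,000 subjects with full attendance (≈117,000
measurement occasions) for the variance budget; 100,000 draws for the
marginal-rate refit; 1000 subjects for the KM self-calibration; 8
replicates of 2000 for coefficient recovery.  Posterior grids: step 0.02
years, span 60 years (tail mass ~5·10⁻⁵ at the default rate, logged).
Degenerate inputs fail loudly: empty fit subsets, single-arm designs,
constant `ln H_pred`, zero predicted survival, posteriors that underflow
on the whole grid.

## Known limitations

* The anchored arm-offset decomposition is a reporting convention; only
  the control-arm level and the arm contrast are estimated.
* The survivor-subset `T` proxy is a stand-in; coefficients from that
  subset (especially the `T` slope) inherit its arbitrariness.
* The exponential-calibration slope is not exactly 1 under self-simulation
  (see above); the reference is an idealization tied to window-constant
  hazards.
* Calibration on the same data used for fitting is optimistically biased;
  cross-validation is out of scope here.
* The generator's censoring and visit mechanisms are explicit stand-ins,
  not reconstructions of any trial's mechanisms.
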