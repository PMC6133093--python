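# revivalpred

Dynamic prediction of survival from longitudinal biomarker histories using
the **revival** (reverse-time) model, with landmark-based calibration of
the implied predictions — built for biostatisticians studying joint
longitudinal–survival modelling on trial-like cohorts (the motivating
setting is the prothrombin index in a prednisone/liver-cirrhosis trial).

## The model in brief

The biomarker of a subject dying at time `T` is modelled in revival time
`s = T − t` (time before death):

```
Y(t) ~ N( β₀ + β_arm + β_T·T + β_s·s + β_log·ln(s+δ),
          σ²_b + σ²_w·e^{−Δs/φ} + σ²_e )
```

with exponential marginal survival `T ~ Exp(λ₀)`, `λ₀ = 0.164`/year.  For
a subject alive at a landmark `t_LM`, Bayes' rule turns the history
likelihood `f(observations | T)` into a posterior over `T`, and the
predicted cumulative hazard over a window is
`H_pred = −ln P(T > t_hor | history, T > t_LM)`.  Landmark calibration
regresses the realized window hazard on `ln H_pred`:
`ln λ(t|H_pred) = α_c + β_c·ln H_pred`, with `(β_c, α_c) = (1, ln 0.5)`
the perfect-calibration reference for a 2-year window.  An alternative
model censors everything at an observation limit `t_lim = 9` years,
estimates the marginal by Kaplan–Meier, and carries the survival mass at
the limit as a single atom — no modelling beyond the data's support.

Because such trial data are not redistributable, the package includes a
first-class synthetic-cohort generator with this exact joint structure
(visit schedule, attendance, early-heavy censoring), which all tests and
acceptance checks run against.  See `docs/methods.md` for the full
account.

## Worked example

```python
from revivalpred import (CohortConfig, generate_cohort, fit_revival,
                         standard_prediction_engine, calibration_table,
                         reports_frame)

cfg = CohortConfig(n_subjects=2000, seed=1)
cohort = generate_cohort(cfg)

fit = fit_revival(cohort, "all_uncensored")
print(f"prednisone offset {fit.params.beta_prednisone:.2f} "
      f"(+/- {fit.standard_errors['prednisone']:.2f})")

engine = standard_prediction_engine(cfg.revival)
reports = calibration_table(cohort, engine, landmarks=[2.0], window=2.0,
                            lambda_ref=cfg.lambda0)
print(reports_frame(reports)[["t_lm", "n", "deaths", "c_hat",
                              "beta_hat", "beta_cox"]].round(3).to_string(index=False))
```

prints

```
prednisone offset 12.35 (+/- 1.52)
 t_lm   n  deaths  c_hat  beta_hat  beta_cox
  2.0 814     193  0.951     1.243     1.243
```

The fitted prednisone offset recovers the generating value 13.56 within
one standard error.  At the 2-year landmark, 814 subjects are at risk and
193 die in the window; the simple rate factor `c ≈ 0.95` says the
exponential marginal needs essentially no correction on self-simulated
data, and the exponential and Cox calibration slopes agree to three
digits and sit near the perfect-calibration value 1 (single-cohort
estimates of the slope carry a replicate sd of roughly 0.3).

The same pipeline runs from the shell:

```
revivalpred run-all --seed 1 --n-subjects 2000 --out-dir out/
```

writes the cohort CSVs, revival fits for all three subject subsets, the
profile-likelihood cross-tabulation at `t_LM = 2`, calibration tables for
the standard and alternative models, and the overview figures.

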