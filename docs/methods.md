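# Methods

This note records the models, parameter choices and numerical conventions
behind `noshowpricing`, and what the synthetic world does and does not
establish.

## Synthetic cohort generator

**Model.** Each appointment is a row of thirteen covariates drawn
independently; the outcome is Bernoulli with a logistic link:

```
logit P(show-up) = b0 + Σ_j c_j x_j
```

Binary flags contribute `c_j·x_j`; age contributes per year centred at 45;
the appointment date contributes an annual sinusoid `c_date·sin(2π·doy/365.25)`
(the "seasonal" component of the calendar); gender contributes for female
patients; the two larger categoricals (department, residence zone) contribute
fixed zero-mean per-level offsets shaped as a sinusoid over the level index
and scaled by one amplitude coefficient, so a single scalar controls each
block's strength without hidden randomness.

**Defaults.** 1073 patients, nine departments with weights 111/124/126/113/
104/123/118/137/117 ÷ 1073, gender split 706/1073 female, 66 residence
zones, one calendar year of dates (weekend flag derived from the date),
age ~ truncated normal(45, 18) on [0, 95], binary marginals: SMS 0.5,
vehicle 0.5, companion 0.4, insurance 0.7, health issue 0.3, treatment
change 0.2, citizen 0.9. No age distribution, zone count rationale or
covariance structure is available from the reference setting beyond the
totals, so independence and these marginals are the simplest defensible
choices; they are fixed once and recorded in every run's metadata.

**Effect calibration.** The default coefficients (intercept −1.2; SMS +3.2;
age +0.045/yr; weekend −1.0; season amplitude 0.3; vehicle +0.15; health
issue +0.5; zone amplitude 1.0; gender, insurance, companion, citizenship,
treatment change, department exactly 0) are calibrated so the expected
partial F-statistics of the downstream screen at n = 1073 echo the reference
effect ordering — SMS in the hundreds-to-thousands, age ~100, weekend ~30-40,
health issue and season ~10, vehicle ~1, zones jointly significant — with the
null factors at the nominal 5% false-positive rate. Measured over 200
replicate cohorts, every null factor's rejection rate sits at 0.04–0.06.

**What a green test establishes.** The generator reproduces marginal
structure and an additive logistic effect pattern. It does not emulate
covariate correlation (e.g. age with chronic conditions), repeat visits by
the same patient, overdispersion, or calendar autocorrelation; conclusions
about those features cannot be drawn from these tests. Classifier accuracy
in this world tops out near 0.75–0.80 because the Bernoulli noise is
irreducible — the high accuracies quoted for real cohorts reflect their
different signal-to-noise, not a property this package can or should
reproduce.

## Factor screen

A linear probability model (OLS on the 0/1 outcome) over all thirteen
covariates; each factor's adjusted sum of squares is the residual-SS increase
when the factor alone is dropped from the full model (partial SS; identical
to Type III here because the model is additive), tested against the residual
mean square with an F test. Date enters the screen as its annual sinusoid
(1 df) — a linear day-number regressor is nearly orthogonal to a seasonal
effect and would have no power against it. The 66-zone residence factor
carries 65 df with an intercept in the model. Significance uses p ≤ 0.05,
boundary inclusive. The implementation is a hand-vectorised `lstsq` sweep
(one fit per dropped factor) for speed; `statsmodels.anova_lm(typ=2)` serves
as an independent oracle in the tests, agreeing to 1e-6 relative. Rank
deficiency is reported by naming the aliased factors rather than silently
dropping columns.

Under the global null the pooled factor p-values are uniform
(Kolmogorov–Smirnov over 200 replicates at n = 5000); the LPM's
heteroscedasticity is too mild at these effect sizes to distort the F test
detectably.

## Classifiers and evaluation

Stratified split (default 70/30, seed 42; an ≈80/20 alternative matches a
214-patient test phase), exhaustive grid search over the per-algorithm
hyperparameter grids, scored by stratified k-fold CV (default k = 5,
accuracy; AUC switchable). Ties and duplicate configurations resolve to the
first configuration in enumeration order; configurations that fail any fold
are scored NaN, logged and excluded. Predicted labels are always the show-up
probability thresholded at 0.5, so labels and scores cannot disagree.

All metrics are computed from the four confusion cells directly. Single
summary values use the support-weighted two-class average — the only
convention under which the published confusion counts reproduce the published
summary table. Rate matrices normalise by predicted-class column: `alpha =
TN/(TN+FN)`, `beta = TP/(TP+FP)`; `beta` is thus the positive predictive
value of show-up calls. Zero denominators yield 0 with a logged warning so
batch evaluation never aborts. ROC groups tied scores into one threshold
step and integrates by trapezoid, making AUC exactly the normalised
Mann–Whitney U; calibration uses equal-width bins with empty bins omitted.
Reported precision: three decimals for metrics, one for percentage matrices.

## Pricing model

Derivation and closed form are in the README. Numerical conventions:

- φ is the symbolic solution of the zero-loss condition, verified by
  plug-back to |Rr| ≤ 1e-9·scale over 10⁵ random parameter draws; the two
  algebraic forms of revised revenue (tiered slot-fill form and collapsed
  form) agree to 1e-12 relative.
- φ is undefined when β ∈ {0, 1} or there is no no-show (the φ coefficient
  in the zero-loss equation vanishes); this raises rather than returning a
  sentinel.
- φ is not clamped: φ < cm (subsidy) and φ > Pf (super-fee) are flagged.
- Monotonicity: φ is strictly increasing in cp always; in ns its derivative
  has the sign of `cp − nt·(Pf−cm)`, so φ falls with extra show-ups exactly
  when full attendance would at least break even, and rises when the
  personnel cost dominates. The unconditional "decreasing in ns" intuition
  holds only in that break-even-or-better regime.
- Repeat offenders: an optional escalation multiplier sequence (default 1.0,
  1.5, 2.0, saturating) applied to φ per offense count.

**Horizon simulation.** Per day: demand `nt ~ Poisson(mean 10.73)` (≈1073
patients per 100 days); a no-show fraction uniform on `(0, 1−β]` — the
classifier's no-show ceiling; each booked patient then no-shows independently
with that fraction, i.e. `nn ~ Binomial(nt, fraction)` drawn by inverse CDF.
Demand, fraction and quantile draws are shared across algorithms (common
random numbers), so differences between series isolate β. Days without an
unfilled no-show contribute no rate; the average is the arithmetic mean over
contributing days, and a horizon with no contributing day raises. Default
costs: Pf = 100, cm = 20, cp = E[nt]·(Pf−cm) (mean-demand break-even). In
that default regime daily fees swing between subsidy and super-fee as demand
fluctuates around its mean; the cross-classifier ordering claim (lower β →
lower average rate) is made, and tested, in a cp-dominant shortfall regime
(e.g. cp = 2000) where every priced day has a positive shortfall. The
reference analysis's printed average rates depend on day-level cost and
demand inputs that are not public, so only this ordering — not the printed
percentages — is asserted.

## Pipeline

One `RunConfig` drives generate → split/tune/fit → evaluate → ANOVA → price,
writing CSV/JSON artifacts and a manifest of SHA-256 hashes. No artifact
embeds a timestamp (run-metadata sidecars take an optional timestamp argument
that the pipeline leaves unset), so identical configs give bit-identical
hashes. Stage failures abort with the stage name and mark the manifest
partial. Routine runs use small "fast" grids; the full default grids remain
available on `ModelSpec(grid=None)`.

## Known limitations

- The cohort world is additive and independent by construction; interactions
  or confounded covariates will not be represented.
- The slot-refill expectations `nnr`, `nsn` are means, not integer draws; the
  pricing identities are exact in expectation only.
- The horizon simulation prices each day in isolation — no carry-over of
  unfilled slots, no patient-level tracking of repeat offenses (escalation is
  exposed as a separate helper).
- The evaluation stack is strictly binary; multi-class generalisation is out
  of scope.
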