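# Methods

## Data-generating model

Each synthetic cohort draws a true exposure–confounder pair (X, Z) from a
standard bivariate normal with correlation ρ, adds independent classical
measurement error

X\* = X + ε_x, ε_x ~ N(0, σ²_x);  Z\* = Z + ε_z, ε_z ~ N(0, σ²_z),

and generates the outcome from the *true* covariates through a linear
predictor α + βX + γZ:

- **binary** — Y ~ Bernoulli(expit(α + βX + γZ)); default
  α = ln(1/9), giving 10 % baseline prevalence;
- **continuous** — Y = βX + γZ + ε_y with ε_y ~ N(0, σ²_y), default
  σ²_y = 1;
- **survival** — the linear predictor L = βX + γZ is shifted by its
  within-cohort minimum so it is non-negative, each subject's event time
  is exponential with **mean** equal to the shifted predictor, and all
  times are administratively censored at t = 0.1 (events are observed
  only when the raw time is below the horizon). The subject attaining
  the cohort minimum gets an immediate event in the mean reading (a
  degenerate exponential with mean 0). A `survival_param="rate"` switch
  instead treats the shifted predictor as the rate; a zero rate then
  yields an infinite, censored time. The mean reading is the default
  because it is the parameterization that reproduces the reference Cox
  calibration results; the event fraction it realizes under the default
  effects (β = γ = 0.1) is ≈ 17 % (the rate reading gives ≈ 6 %). Note
  that the generation mechanism is *not* a canonical proportional-hazards
  model, so the survival estimand is defined by the oracle fit (below),
  not assumed equal to exp(β).

Defaults everywhere follow the simulation design the package targets:
β = γ = 0.1, ρ ∈ [0.1, 0.9], σ² ∈ {0.25, 1}, cohort sizes 500 and 2000,
N = K = 10,000 Monte Carlo replicates. Error variances are *variances*
throughout (σ = 0.5 when σ² = 0.25).

Reproducibility: a cohort's root seed spawns four child streams (pair,
ε_x, ε_z, outcome noise), so toggling one error variance never perturbs
the other draws; evaluation replicates and grid cells get independent
child seeds, so results are identical regardless of scheduling.

## Effect scales

Fits are maximum likelihood: OLS (continuous), logistic regression
(binary, statsmodels Newton), and a Cox partial-likelihood Newton solver
written in-package (Breslow tie handling; validated against lifelines to
1e-6 and roughly 50× faster, which the 20,000-fit calibrations require).
P-values are Wald throughout.

The reporting effect θ is the raw coefficient (continuous), the hazard
ratio exp(b) (survival), and for the binary family the **risk ratio**
obtained from the odds ratio via

RR = OR / (1 − p₀ + p₀·OR)

at baseline risk p₀ = expit(intercept). The risk-ratio choice follows
the convention of reporting RR from logistic fits in this literature;
`effect_scale`/`reporting_theta` expose the odds ratio as an option.
When a change in estimate is computed between two fitted models, both
odds ratios are converted with the *same* p₀ (the unadjusted model's),
so Δ reflects the exposure coefficient's movement rather than the
intercept shift that mechanically accompanies adding a covariate.

## Simulated CIE cutoffs

Δ = |(θ₀ − θ_Z)/θ₀| on the reporting scale. Two calibrations:

- **Type-I (null) cutoff.** K replicates; each regenerates a complete
  cohort from the design (including the confounded outcome and the
  measurement-error layers) and adjusts for an independent
  Z₀ ~ N(0, 1 + σ²_z) — the marginal of Z\*. The cutoff is the
  (1−q)·100th percentile of the Δ sample (95th for a 5 % type-I error).
  In *data mode* the observed (Y, X\*) are held fixed and Z₀ is a random
  permutation of the observed confounder column, which preserves its
  marginal exactly with no distributional assumption.
- **Type-II (alternative) cutoff.** K replicates regenerate full cohorts
  under the assumed confounded structure and compare the fits with and
  without adjustment for the mis-measured Z\*; the cutoff is the s·100th
  percentile (20th for 20 % type-II error), read so that the s-th
  percentile yields type-II error s — the self-consistent reading of the
  two conventions in circulation.

Numerical choices: percentiles use linear interpolation between order
statistics (numpy default / R type 7), pinned for reproducibility; the
cutoff's Monte Carlo uncertainty is a 200-draw bootstrap SE of the
percentile; replicates with an exactly zero unadjusted effect (undefined
Δ) or a non-converged fit are excluded and counted, with a warning above
1 % exclusions and an error when all replicates are degenerate.

Known behavior worth noting: the null cutoff is strongly design-dependent
— it grows with the exposure error variance (which shrinks the
denominator θ₀) and shrinks with n — which is exactly why fixed 10 %
advice fails; and the Δ distribution's upper tail is heavy whenever θ₀
is within a few standard errors of zero, so type-I cutoffs at small n
carry visible Monte Carlo uncertainty even at K = 10,000.

## Screening and the two-stage decision

The pre-screen is a two-sided t-test of the Pearson correlation between
X\* and Z\* at α = 0.05 (boundary kept). A screened-out candidate is
rejected outright and the unadjusted estimate becomes final. Otherwise
one of five rules decides: covariate p ≤ 0.05, p ≤ 0.20, Δ ≥ 10 %,
Δ ≥ δ_c(type I), Δ ≥ δ_c(type II) — all boundary-inclusive.

Without the screen, a strong pure risk factor (γ large, ρ = 0) is
falsely identified as a structural confounder in roughly half of
simulated samples, because conditioning on nothing leaves the chance
X\*–Z\* correlation free to move the estimate by more than the calibrated
cutoff; the screen caps this false-identification rate at its α. The
cost is power against genuinely weak confounding (observed correlation
below the test's detection limit at the given n).

## Monte Carlo evaluation

For each design cell, cutoffs are calibrated once (as at a real design
stage), then N replicate cohorts are generated and every strategy is
applied to the *same* replicates (common random numbers; strategy
contrasts are paired). Reported per strategy: the adjust rate (power
when the DGP contains a true confounder; screened-out replicates count
in the denominator) and RMSE = √(Σ(φ_n − θ)²/N), where φ_n is the
strategy-selected final estimate and θ the true reporting-scale effect
obtained from one adjusted fit on an error-free mega-cohort (default
2·10⁵; the survival estimand is whatever this oracle returns).
Replicates with non-converged fits are dropped and counted (rare at the
design sizes; the dropped fraction is reported).

Two empirical facts the harness reproduces and the test suite pins:
p-value-based power is *not* monotone in ρ at strong confounding (X\*–Z\*
collinearity inflates the confounder SE; power peaks near ρ ≈ 0.3 at
n = 500, σ² = 0.25), and the calibrated type-I rule dominates both the
p ≤ 0.05 rule and the fixed 10 % rule in identification power in the
measurement-error settings studied.

## Planning emulator

The planning module targets the design question "how well must the
confounder be measured so that adjustment recovers the true (null)
exposure–outcome association?" for a structure with a latent confounder:
F ~ N(0,1) (habitual fish intake), exposure E with corr(E, F) = 0.39
(blood mercury, treated as error-free), and a binary outcome D
(depression) generated by dichotomizing a latent Gaussian liability with
corr(liability, F) = −0.35 at the quantile matching a configurable
prevalence; any direct E→D effect (default 0, the null) enters the
liability linearly. The default prevalence 0.2295 is the baseline risk
at which the OR↔RR conversion reproduces the reference unadjusted pair
(OR ≈ 0.79, RR ≈ 0.83), so the emulator's unadjusted mercury–depression
RR lands near 0.83 without any real data.

For each noise-to-signal ratio σ² in the grid, K replicate studies are
drawn (a fixed-study mode that redraws only W = F + ε is available), the
logistic fit D ~ E + W records the exposure p-value and adjusted RR, and
the module reports: the proportion of null findings (p > 0.05), the mean
adjusted RR with its empirical 95 % interval, and the simulated type-I
CIE cutoff for the setting. Under the default structure the null-recovery
proportion falls monotonically with σ² while the adjusted RR migrates
from ≈1 toward the unadjusted value — yet for any moderate σ² every
adjusted estimate is closer to the null than the unadjusted one, the
quantitative argument for forcing theoretically motivated confounders
into the model even when poorly measured.

What the emulator does *not* reproduce: survey weights, covariates of the
original depression model, mercury's etiologic exposure window, and the
real data's non-Gaussian marginals. Conclusions about those require the
actual cohort; the emulator preserves only the printed structural
parameters (n = 6911, ρ_FE = 0.39, ρ_FD = −0.35, null direct effect).

## Problem sizes used in the test suite

The shipped tests run the same machinery at reduced scale, chosen so the
Monte Carlo bands stay meaningful: K = 2,000 for cutoff smoke tests
(±20 % relative bands), 1,200–1,500 replicates for calibration-closure
checks (3-binomial-SE bands), N = 2,000 for the strategy comparison, and
10⁵–10⁶ for closed-form moment and mega-simulation anchors. The
acceptance script runs the five reference calibrations at the full
K = 10,000.

## Limitations

Single candidate confounder; Gaussian covariates and classical,
uncorrelated, non-differential error only; no measurement-error
*correction* (regression calibration, SIMEX, Bayesian adjustment) — the
package quantifies how identification strategies behave under error, it
does not remove the error; covariate-independent censoring only in the
survival recipe. Simulated cutoffs are design-specific by construction:
a cutoff calibrated for one (n, ρ, σ²_x, σ²_z, family) combination has
no validity for another, and the calibrations' guarantees are exactly the
nominal type-I/II error rates that the closure tests confirm — not
robustness to a mis-specified assumed structure.
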