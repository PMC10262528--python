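# Methods

This note documents the statistical procedures implemented in `frailtykit`,
their assumptions, the tunable parameters that matter, and the design
choices made where several defensible options existed.

## Frailty index construction

The frailty index follows the standard cumulative-deficit procedure: any
health-related item that rises in prevalence with age and does not saturate
too early can serve as a deficit; an index should contain at least 30
deficits spanning at least five physiological systems (enforced in strict
catalog validation; permissive mode demotes violations to warnings so small
catalogs remain usable in tests).

Scoring conventions:

- binary deficits: 0 absent, 1 present;
- ordinal deficits with `n` declared levels: level `k` (0-indexed) scores
  `k/(n-1)`, i.e. an equally spaced grid on [0, 1];
- threshold deficits: 1 when the raw value is at or beyond the cut-point in
  the deficit direction (`above` → raw ≥ cut, `below` → raw ≤ cut), else 0;
- medication-inferred conditions: present iff any concomitant-medication
  class code maps to the condition (set semantics — duplicate codes are
  idempotent, unknown codes are counted and ignored);
- polypharmacy: 1 iff the participant takes ≥ 5 *distinct* medications.

Missing deficits are removed from numerator and denominator. A participant
is excluded iff the missing fraction strictly exceeds 20%; the comparison
uses integer arithmetic (`5 · n_missing > n_total`), so exactly 20% missing
is retained and the boundary is exact in floating point.

Categories use the electronic-frailty-index cut-points 0.12 / 0.24 / 0.36
with a half-open convention (robust ≤ 0.12 < mild ≤ 0.24 < moderate ≤ 0.36
< severe). Published category rows often print overlapping labels
("0.12–0.24", "0.24–0.36") without resolving the boundaries; the half-open
convention is the one under which a prevalence of "FI > 0.24" equals
moderate + severe exactly, which is what `prevalence_over_threshold`
computes from either raw values or a printed category row.

The descriptive 99th centile is the linear-interpolation empirical
quantile; a model-based 99th centile from the fitted distribution is also
available (`dist.model_summary`) because summaries exported from secure
enclaves are usually model-based. The two are asserted to agree within
±0.02 on well-fitting samples in the tests.

## Distribution fitting

Candidate families on positive support, location fixed at zero: lognormal,
gamma, Weibull, generalised gamma. The generalised gamma uses the Stacy
parameterisation `f(x) = p x^(d-1) exp(-(x/a)^p) / (a^d Γ(d/p))` with scale
`a`, shape `d`, power `p` (all > 0); `p = 1` recovers the gamma and `d = p`
the Weibull, and it maps onto `scipy.stats.gengamma(a=d/p, c=p, scale=a)`.

Estimation: lognormal by closed form on logs; gamma and Weibull by scipy's
constrained MLE with `floc=0`; the generalised gamma by direct
minimisation of the negative log-likelihood over `(log a, log d, log p)`
with multiple moment-/nested-model starts (the gamma and Weibull MLEs are
themselves candidate solutions, so the fitted log-likelihood can never fall
below theirs — the nesting inequality holds by construction, not luck).
Exact zeros (possible in low-frailty samples) are shifted to
`1/(2·n_deficits)` before fitting when the deficit count is supplied,
otherwise they raise an error; this keeps the shift interpretable as "half
a deficit".

Fit comparison uses the exact two-sided Kolmogorov–Smirnov statistic
(both one-sided ECDF limits at each observation). KS is used as a relative
fit statistic only; p-values are not reported because parameters are
estimated from the same sample (the Lilliefors problem). `select_best_fit`
treats KS differences below `0.5/√n` — the statistic's own sampling scale —
as ties and breaks them toward the family with fewer parameters, so a
2-parameter nested member is preferred when the generalised gamma adds
nothing. Note the generalised-gamma likelihood is quite flat in `(d, p)`;
at n = 10,000 the MLE typically lands within a few percent of the truth but
occasional samples put it near 10%.

## Outcome models

Serious adverse events: because participants are censored at their first
SAE or at end of follow-up, the event count is 0/1 and a Poisson GLM of the
indicator with offset `log(observation time)` is exactly the censored
constant-hazard (exponential) likelihood, up to a term not involving the
parameters. The FI is rescaled by 10 inside the model so the exponentiated
coefficient is the incidence rate ratio per 0.1-unit FI; the offset's time
unit cancels from the IRR (tested). Total-SAE-count models are out of
scope: under censoring at first event, counts above one cannot occur.

Attrition (withdrawal before the stipulated endpoint) uses a logistic GLM,
same covariates and scaling. Both models adjust for age (linear, in years)
and sex (female = 1); a sex × FI product term with its Wald p is available
post hoc, and an optional quadratic FI term (off by default) supports
checks for non-linearity. Intervals are Wald, `beta ± 1.96·se`, with
model-based (not sandwich) standard errors. Zero events, a single attrition
outcome, single-sex interaction samples, and separation (detected via
non-convergence, non-finite estimates, or diverging coefficients) raise
errors rather than returning numbers.

## Random-effects meta-analysis

Per-trial log-scale coefficients and standard errors are pooled with
DerSimonian–Laird: fixed-effect weights `w_i = 1/se_i²`, heterogeneity
`Q = Σ w_i (b_i − b_FE)²`, `tau² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))`,
re-weighting by `1/(se_i² + tau²)`; `I² = max(0, (Q−(k−1))/Q)·100`. With
one study the pool is that study. Paule–Mandel (solving `Q(tau²) = k−1`) is
offered as the alternative `tau²` estimator — it was chosen over REML for
its clean fixed-point characterisation and because an independent
implementation exists in statsmodels for cross-checking; DL remains the
default and the primary tested path. No Knapp–Hartung adjustment; with
k = 3 trials, `tau²` is weakly identified and publication-bias diagnostics
are meaningless, so neither is provided.

## Synthetic-trial generator

The generator exists because the real IPD cannot leave its repository; it
reproduces the structure the analysis assumes rather than any particular
dataset.

Mechanism: participant `i` draws a latent frailty liability
`z_i ~ N(0, 1)`; binary deficit `j` is present with probability
`invlogit(α_j + λ_j z_i + γ_j (age_i − 70)/10)`; ordinal deficits use the
cumulative-logit analogue (a logistic latent variable against increasing
cut-points); threshold deficits generate a raw value strictly beyond or
inside the cut consistent with the simulated exceedance; condition deficits
emit a medication of a class that maps back to them, plus
truncated-Poisson noise medications drawn from unmapped classes (mean 2),
so medication mapping and polypharmacy are exercised end to end, exactly.
Non-negative loadings and age slopes give positive inter-deficit
correlation and age gradients; the mixture over `z` produces the
right-skewed FI distribution seen in real cohorts.

Outcomes are generated from the complete-data (pre-missingness) physical
FI: exponential time to first SAE with log-rate
`β₀ + β_FI·(10·FI) + β_age·age + β_sex·female`, administratively censored
at follow-up, and Bernoulli attrition with the logistic analogue. Baseline
missingness is MCAR per deficit column at `missing_rate` (preset default
0.02, reflecting the near-zero exclusion counts such trials report).

Preset calibration is analytic, not simulation tuning: FI mean and SD under
the latent model are computed by 24-point Gauss–Hermite quadrature over
(liability, age) — using conditional independence of deficits given both,
an exact Poisson-binomial recursion for the polypharmacy deficit, and the
comonotone-indicator variance for ordinal scores — and a global prevalence
shift plus liability scale are solved by least squares to hit the targets
(physical FI mean/SD 0.14/0.06 for `mci`, 0.24/0.08 for `dementia`),
followed by a one-dimensional solve of a cognitive-deficit shift so the
combined index means are ≈ 0.145 and 0.29. Demographics (age 70.0 ± 7.5 vs
83.3 ± 6.5 years, 55% vs 81% female), follow-up (12 vs 24 months) and
default sizes (987 / 408) mirror typical MCI and severe-dementia trial
populations. The generating outcome effects are IRR 1.6 per 0.1 FI for SAEs
in both presets and attrition OR 1.66 (dementia) / 1.05 (MCI); the baseline
SAE and attrition levels (≈ 35%/12% SAE over follow-up, ≈ 35%/20%
attrition) are plausible-magnitude choices, since published reports rarely
print them.

What the generator does *not* emulate: informative (non-MCAR) missingness,
treatment-arm effects, site/country structure, non-constant hazards, and
deficit dependence beyond one factor. Passing tests therefore demonstrate
that the pipeline is correct under its own modelling assumptions — the
Poisson-offset model is exactly correctly specified for the generator — not
that those assumptions hold in any real trial.

## Numerical and validation choices

- Recovery/coverage simulations use `missing_rate = 0`, so the fitted models
  are exactly correctly specified; with MCAR missingness the observed FI is
  an error-prone proxy for the FI that generated outcomes, and nominal
  coverage is not the correct expectation.
- Problem sizes in the test suite (e.g. 200 replicates of n = 4,000 trials
  for coverage; n = 10,000 for distribution recovery; n = 5,000 for preset
  calibration checks) were chosen as the smallest sizes at which the
  Monte-Carlo error of each check is comfortably below its tolerance.
- GLM correctness is checked against closed-form two-group MLEs and an
  independent likelihood-grid oracle; the FI formula against an
  exact-rational brute-force oracle; DL pooling against hand arithmetic and
  statsmodels' implementation.
- Rendered report percentages round half-up to one decimal; raw values are
  retained in the JSON outputs, and every rendered number is a rounded copy
  of a machine-readable field.
- Sex is modelled as a binary female indicator; other codings pass through
  only if explicitly mapped, otherwise they raise a data error.

## Known limitations

- The deficit catalog shipped with the package is a plausible synthetic
  stand-in (18 medication-inferred conditions, 8 laboratory thresholds,
  5 ADL ordinals, 5 neurological-exam binaries, BP/BMI/ECG/polypharmacy,
  5 cognitive deficits); real analyses must supply the catalog that matches
  their trial's baseline assessments.
- Medication vocabulary is a flat class-code string space, not a licensed
  drug dictionary; no coded-terminology (ATC/MedDRA/SNOMED) integration.
- No imputation beyond the denominator-removal rule; no survival (Cox) or
  recurrent-event models; no Bayesian or censored-data distribution fits.
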