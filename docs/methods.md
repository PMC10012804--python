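# Methods

## Scope and data model

The package analyzes three binary health-plan choices (voluntary
deductible, alternative/managed-care plan, supplementary hospital
insurance) as functions of 16 predictor sets: sex, five age groups, three
education levels, OECD-equivalized log household income, marital status,
urban residence, self-rated good health, chronic condition, doctor visits,
hospital stays, a five-category risk attitude, and the five Big Five
constructs. The real microdata (Swiss Household Panel, adults 26+) are
contract-restricted, so all computations here run on synthetic tables with
the same schema; nothing in the package claims to reproduce the restricted
sample's estimates.

## Variable derivation

* **Equivalized income.** ln(household income / OECD scale) with weights
  1.0 for the first adult, 0.5 per additional member aged 14+, 0.3 per
  child under 14. Income must be strictly positive (CHF/year).
* **Risk attitude.** The 0–10 willingness-to-take-risks item is collapsed
  to five categories: 0 → averse, 1–3 → moderately averse, 4–5 → neutral,
  6–7 → moderately seeking, 8–10 → seeking; category 1 is the reference.
* **Binary indicators.** Good health = self-rating 1–2 on the 1–5 scale;
  voluntary deductible = any of CHF 500–2,500 vs. the CHF 300 standard.
  Reference categories throughout: male, age 26–35, low education, not
  married, rural, fair/poor health.
* **Trait constructs.** Each trait has three 0–10 items; the negatively
  keyed items ("tends to be lazy", "is reserved", "is sometimes rude to
  others", "remains calm in tense situations") are flipped as 10 − x before
  scoring. Default scoring fits a one-factor model per trait and returns
  regression-method factor scores; with three indicators the model is
  just-identified, so the ML loadings have the closed form
  λ₁ = √(r₁₂r₁₃/r₂₃) (and cyclic). When the solution is inadmissible
  (inconsistent correlation signs, or a Heywood loading ≥ 1) the scorer
  falls back to the item mean with a warning — the same pragmatic fallback
  the extraversion construct needs on the real survey. Scores entering the
  models are standardized per analysis sample, which leaves every dominance
  statistic unchanged and makes odds ratios per-SD; the published
  construct scales (e.g. a negative agreeableness mean) are opaque and are
  deliberately not replicated.

## Estimation

Logistic fits use Newton–Raphson/IRLS with step-halving; convergence when
the maximum absolute score is below 1e-8 or the relative log-likelihood
change is below 1e-10 (at most 100 iterations). Complete separation is
detected by divergence of slope coefficients beyond |β| > 15 — under
separation the score also vanishes as coefficients diverge, so coefficient
magnitude, not the gradient, is the reliable signal — and raised as an
explicit error; subset models inside the dominance lattice are then
retried once with a tiny ridge (1e-6, never on the intercept) and flagged.
Wald intervals (not profile likelihood) match the reporting convention of
the odds-ratio figures this pipeline emulates. McFadden's R² = 1 − ℓ/ℓ₀ is
the only fit statistic wired into the dominance machinery.

## Dominance analysis

The unit of importance is the predictor *set* (a dummy block counts as one
predictor). All 2ᵖ subsets are fit on the identical complete-case sample,
fixed once per outcome, so R² values are comparable; each subset is fit
exactly once (memoized by bitmask) and warm-started from its parent subset,
which roughly halves Newton iterations without changing any result — every
fit still iterates to the same 1e-8 score tolerance regardless of
evaluation order. Conditional dominance averages additional contributions
within each model size; general dominance averages across sizes and is
algebraically the Shapley value of R², so ΣG = R²_full is checked to 1e-6.
Complete dominance requires a strictly larger contribution (margin 1e-10)
in every shared subset. A hard cap of p ≤ 20 sets keeps the 2ᵖ lattice
tractable. Failed subsets reduce averaging denominators with a warning;
more than 1% failures aborts the analysis.

Weights are reported both raw (summing to R²_full) and as percentages of
R²_full, since published usage mixes the two readings. Rankings are
computed on weights rounded to 3 decimals — the printed precision of the
tables this mirrors — with dense tie handling and ranks only for the six
largest distinct values; unrounded weights are retained.

## Bootstrap

Rank stability uses a case bootstrap: whole rows resampled with
replacement, the full dominance analysis recomputed per replicate, and
pairwise agreement proportions P(Gᵢ > Gⱼ) reported. Replicate seeds derive
from the master seed by replicate index, so replicates are independent and
individually reproducible. The default is B = 200; B = 10 reproduces the
scale of the original ten-replication robustness check. Failed replicates
are dropped and counted, never imputed.

## Synthetic data generator

The generator defines the study conditions for all tests. Nine continuous
latents (income, risk propensity, five traits, health liability, education
propensity) follow a Gaussian copula; the default correlation matrix is a
placeholder — the survey's joint covariate law is not public — with signs
from the risk-preference literature (e.g. income–education 0.45,
risk–extraversion 0.25, risk–neuroticism −0.25). Discrete covariates come
from thresholding latents at quantiles of configurable marginal shares set
near published pooled descriptives (~55% female, ~62% married, ~73% urban,
~84% good health); age and household composition are drawn independently.
Income is log-normal (μ = 11.6, σ = 0.5 on the log scale) so equivalized
log income lands in the published 10.9–11.2 range. BFI items are
loading × latent + noise (defaults 0.8/0.7/0.6 per trait, noise SD 0.6),
affinely mapped to the 0–10 response scale, rounded to integers and
clipped (mild boundary inflation accepted), with reverse-keyed items
stored flipped as answered. Outcomes are Bernoulli draws from logistic
models on the derived-predictor scale; default coefficients follow the
published odds-ratio directions (female OR 0.76 on deductible choice,
income OR 3.64 and age-66+ OR 5.15 on supplementary insurance) with trait
and risk weights sized so those sets lead the importance ranking;
intercepts are calibrated so prevalences sit near the published pooled
uptake shares (0.61 / 0.65 / 0.35). Every column draws from a
counter-based substream of the master seed keyed by column name, so
adding a column never perturbs existing ones.

The generator internally derives its design with mean-scored traits
(deterministic, no factor-model fallback), so generative coefficients are
exactly the truth for a mean-scored refit; CFA and mean scores correlate
above 0.95 on these unidimensional items. What the generator does *not*
emulate: panel attrition, survey weights, household clustering, item
missingness, and ordinal response styles. Passing tests therefore
demonstrate correctness of the estimators and decompositions under a
well-specified sampling model, not robustness to the real survey's
complications.

## Problem sizes used in the checks

The identity and recovery suites run at n = 2,000 respondents with p = 8
predictor sets (256 subset fits per outcome, 100 seeded datasets), plus a
single complete p = 16 decomposition (65,536 fits) at n = 2,000; the
enumeration oracles (p! permutation Shapley, exhaustive subset loops) run
at p ≤ 5, n = 250–400; odds-ratio recovery uses one n = 50,000 sample and
coverage pools 23 coefficients over 100 replicates at n = 2,000. The
packaged demo configuration uses n = 3,000 with the 8-set lattice.

## Known limitations

* One-factor-per-trait scoring only; no joint 15-item CFA.
* No survey-weighted, clustered, or panel estimators.
* McFadden's R² is the only dominance statistic; other pseudo-R² analogs
  are out of scope.
* Bootstrap intervals are rank-agreement summaries, not BCa/studentized
  intervals for the weights.
* With near-tied generative weights (the regime the published trait
  results suggest), bootstrap top-rank agreement is genuinely unstable;
  stability claims only make sense for clearly separated weights.
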