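# Methods

## Model and assumptions

`pairsig` builds prognostic signatures from binary within-sample
gene-pair indicators: `s(g1, g2) = 1` iff gene g1's abundance is
strictly below g2's in the same sample, with ties scoring 0.  Because an
indicator sees only the order of two genes inside one profile, it is
exactly invariant under any strictly increasing per-sample transform of
abundance.  This is the level at which the cross-platform claim is
literally true, and the package asserts it bitwise in tests; what it
does **not** guarantee is robustness to transformations that reorder
genes within a sample (probe-specific biases, gene-length effects when
moving between FPKM-like and count-like units for *different* genes).

Risk is modelled by a Cox proportional-hazards linear predictor over
pair indicators.  Assumptions inherited from that choice: proportional
hazards over the follow-up window, independent (non-informative)
censoring, and samples that are exchangeable given the covariates.

Pipeline stages and their contracts:

1. **Preprocessing** (optional for scoring, used for candidate
   nomination): `log2(x + offset)` conversion; quantile normalization
   (columns forced onto the mean-of-sorted-columns reference, ties
   averaged); Welch two-sample t screening with `p <= 0.05` and
   `|log2 FC| >= 1` defaults.  The moderated-variance statistics used by
   array pipelines are deliberately replaced by Welch's test: the screen
   only nominates candidates, and a self-contained test keeps the stage
   dependency-free.  No multiplicity correction is applied here; error
   control enters at pair screening.
2. **Pair construction**: all C(k, 2) canonical (lexicographic) pairs;
   pairs constant in any participating dataset are dropped (strict
   constancy, read literally from the rule it implements).  A fitted
   signature stores its own (gene1, gene2) orientation, because the
   coefficients are order-dependent.
3. **Screening**: per-pair two-group log-rank test with Holm
   familywise-error control at α = 0.05 (Bonferroni available).  Holm
   is the default because it is uniformly more powerful while
   controlling the same error rate.
4. **Penalized fit**: lasso-Cox on the Breslow partial likelihood,
   objective `−ℓ(β)/n + λ‖β‖₁`.  Proximal-Newton outer iterations with
   cyclic coordinate descent on the exact local quadratic; warm starts
   along a geometric 100-point path from λ_max (null-score bound) down
   to 0.01·λ_max; per-λ convergence when the maximum coefficient change
   is below 1e−7; a backtracking safeguard keeps the true penalized
   objective non-increasing.  KKT residuals are checked to 1e−5 in
   tests, and the path is verified against an independent Coxnet
   implementation.  Binary indicators are *not* standardized — they
   already share the {0,1} scale and standardizing would distort the
   sparsity pattern.
5. **Cross-validation**: 10-fold, folds assigned by a seeded shuffle
   stratified on the event indicator (prevents event-free folds at
   small n).  Criterion: partial-likelihood deviance in the
   Verweij–van Houwelingen form, `−2·(ℓ_full(β_{−f}) − ℓ_{−f}(β_{−f}))`,
   normalized per held-out event and averaged with event-count weights
   (the grouped convention of the reference penalized-regression
   software; without the normalization, fold-size noise inflates the
   standard error and the one-SE rule collapses to the null model).
   `lambda_1se` — the largest λ whose mean deviance is within one SE of
   the minimum — is the default rule; `lambda_min` is available and is
   the advised fallback when the 1-SE rule keeps nothing (a known
   conservative behaviour observed in roughly 5% of synthetic training
   runs at default conditions).
6. **Cutoff**: Youden-optimal threshold on a time-dependent ROC curve at
   60 months (the headline evaluation horizon; 12/36/60 are evaluated),
   estimated with the nearest-neighbour smoother below, ties broken
   toward the smaller threshold so the high-risk group is larger.  A
   cohort-median cutoff is the alternative (`cutoff_method="median"`).
   The RPI cutoff is a fixed number that transfers to new cohorts; only
   the RCPI recomputes its median per cohort.  Both conventions exist in
   the literature this package follows — the ROC-derived transferable
   cutoff is the default, and the contradiction between them is left to
   the user's choice rather than resolved silently.
7. **RCPI**: stepwise Cox (forward entry at Wald p < 0.15, backward
   removal at p > 0.05, pruned terms never re-enter, deterministic)
   over clinical covariates plus the RPI; the composite weights are the
   joint Cox coefficients, with the RPI entering as a continuous score
   (a single printed weight implies one degree of freedom); the cutoff
   is the median of the composite score in the cohort being stratified.

## Survival machinery

Kaplan-Meier, the (multi-group) log-rank test and Newton-Raphson Cox
fitting are implemented in-package on the Breslow tie convention, with
events preceding censorings at tied times.  This is deliberate: the
penalized path, its KKT checks and the cross-validated deviance all need
the partial likelihood's score and Hessian explicitly, and using one
likelihood everywhere keeps the unpenalized fit the exact λ→0 limit of
the penalized one (asserted to 1e−4).  Convergence: max |score| < 1e−8
or relative log-likelihood change < 1e−10, at most 100 iterations, with
step-halving; monotone likelihoods raise an error advising penalization.
The median survival time is the smallest event time with S(t) ≤ 0.5,
reported as "not reached" (NaN) otherwise.  lifelines serves as an
independent oracle in the test suite, never as the implementation.
FWER adjustment delegates to statsmodels' multiple-testing routines.

The time-dependent ROC uses the nearest-neighbour estimator:
S(t | marker) is a Kaplan-Meier over a symmetric rank window of fraction
2·span (default span 0.25·n^(−1/5)), and

    sens(c) = Σ_{mᵢ>c} (1 − Sᵢ) / Σᵢ (1 − Sᵢ),
    spec(c) = Σ_{mᵢ≤c} Sᵢ / Σᵢ Sᵢ.

The curve is monotonized by cumulative maxima before trapezoidal
integration (raw NNE curves can be locally non-monotone).  Only marker
ranks enter, so the AUC is exactly monotone-transform invariant.  A
perfectly separating marker attains AUC 1.0 exactly only as the span
shrinks below the rank spacing; at practical spans the smoothing leaks a
little mass across the boundary.

## Synthetic cohorts

The generator emulates a two-cohort (training/validation) design:
log-normal per-gene abundances with shared gene identities, a global
per-cohort scale factor standing in for the FPKM-vs-RPM platform
difference (strictly monotone, hence invisible to the indicators),
deliberately imbalanced clinical mixes (cohort 1: 82% stage 4, 81%
≥18 months; cohort 2: 37% and 39%, echoing how a high-risk-enriched
training cohort differs from a broader validation cohort), exponential event times (Weibull shape exposed)
and independent uniform censoring calibrated by root-finding to a target
censored fraction.  The hazard is
`h·exp(Σ βₖ sₖ + β_stage·stage4 + β_age·age − E[lp])`; centring at the
expected linear predictor keeps the baseline hazard (default ln 2 / 36
per month, i.e. a 36-month median for the average patient) interpretable
on the month scale.  EFS is generated as the earlier of death and a
progression process at 1.4× the death hazard, so EFS ≤ OS always.

The pair signal is planted directly on the order relation: each planted
pair's two genes share an abundance distribution and a latent Bernoulli
state decides which draw is larger, so the indicator *is* the true
hazard driver and screening power is analytically tractable.

Default effect sizes were fixed by a power/attenuation analysis rather
than mimicry of any single number: omitted covariates attenuate marginal
hazard ratios by roughly `1/√(1 + σ²_omitted)`, so with three planted
pairs at conditional log-HR log 4 and clinical effects at their
conditional magnitudes (stage HR 5.44, age HR 1.15), each pair's
*marginal* HR lands near 2.5–3 — strong enough for a familywise-error
screen over ~800 pairs at n = 153 to operate, which is the regime the
two-cohort design presupposes — while the composite score dichotomizes
at a group HR near 4–6, a realistic scale for a validated signature.
Planting many simultaneous strong pairs instead makes every *marginal*
association weak (the screen then favours spurious "cross pairs" that
straddle two latent states) — an instructive failure mode, not a useful
default.  A 40% censoring target keeps follow-up beyond the 60-month
evaluation horizon under uniform censoring.  Cohort sizes default to
153 and 498.

What the generator does **not** emulate: count-level noise
(negative-binomial library-size effects), batch effects beyond global
scaling, informative censoring, non-proportional hazards, and gene-gene
correlation outside the planted pairs.  Passing tests therefore show the
pipeline's statistical machinery is calibrated and recovers planted
structure — not that any particular real cohort satisfies the model.

## Numerical and interface conventions

* Ties in a pair score 0; a score exactly at a cutoff stratifies low.
* Duplicate gene rows collapse to their mean at load time and rows are
  sorted by id, so loading is independent of input row order.
* All floats serialize via `repr` (17 significant digits); signature
  files round-trip bit-exactly.
* Times are months; day-denominated inputs divide by 30.4375.
* Missing clinical categories are kept as NaN and dropped listwise only
  by the operations that use the field.
* All randomness flows from seeded `numpy` generators; fits and
  simulations are bit-reproducible given a seed.
* Quantile normalization is exactly idempotent on tie-free data; with
  ties the tie-averaging perturbs the reference on re-application, so
  idempotence holds only approximately.

## Known limitations

* Breslow ties only (no Efron), no stratified or time-varying Cox, no
  robust variance.
* The NNE ROC provides no incident/dynamic variants and no
  IPCW-weighted alternative.
* The DEG screen's Welch test is not variance-moderated; at very small
  group sizes it is conservative.
* Stepwise selection inherits the usual instability of stepwise
  procedures; the resampling selection-frequency of pairs is reported by
  the lasso path but no stability threshold is enforced.
* The 1-SE rule can legitimately return an empty model on weak data;
  the error message advises the `lambda_min` rule rather than silently
  substituting it.
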