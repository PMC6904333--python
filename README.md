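# pairsig

Rank-based gene-pair prognostic signatures for survival-annotated
expression data.

## The problem

Multi-gene prognostic scores usually depend on the absolute scale of the
expression values, so a model trained on one platform (say FPKM from an
RNA-seq cohort) cannot be applied to a sample measured on another (RPM,
arrays) without cross-cohort normalization — which is impossible for a
single new patient. `pairsig` builds signatures from **within-sample
gene-pair indicators**

```
s(g1, g2) = 1  if  x[g1] < x[g2]  in the same sample,  else 0
```

which depend only on the ordering of two genes inside one profile.  Any
strictly increasing per-sample transform of the abundances (unit changes,
library-size scaling, log transforms) leaves every indicator — and hence
the risk score and the risk-group call — *bitwise* identical, so a fitted
signature scores one sample at a time with no reference distribution.

The package was built around neuroblastoma risk stratification (two
cohorts on different abundance units, overall and event-free survival,
MYCN/stage/age covariates), but nothing in it is specific to that
setting.

## The model

For a cohort with right-censored outcomes `(tᵢ, δᵢ)`:

1. **Candidate pairs.** All C(k, 2) indicators over k candidate genes;
   pairs constant (all 0 or all 1) in any participating dataset are
   removed.
2. **Screening.** Each pair splits the cohort by its indicator; pairs
   are tested by the log-rank statistic and kept when the
   familywise-error-adjusted p (Holm by default) is below α = 0.05.
3. **Sparse Cox fit.** The retained indicators enter an L1-penalized Cox
   proportional-hazards model, `min −ℓ(β)/n + λ‖β‖₁` with the Breslow
   partial likelihood, solved by coordinate descent along a 100-point
   λ-path.  λ is chosen by 10-fold cross-validated partial-likelihood
   deviance at the one-standard-error rule.  The risk score (RPI) of a
   sample is `Σ βₖ sₖ`.
4. **Cutoff.** The high/low risk threshold maximizes Youden's J on a
   time-dependent ROC curve at a 60-month horizon, estimated for
   censored data with a nearest-neighbour smoother (span 0.25·n^(−1/5));
   a cohort-median cutoff is available as an alternative.  The numeric
   cutoff transfers to validation cohorts as-is.
5. **Clinical adjustment (RCPI).** Clinical covariates are screened
   (log-rank + univariate/multivariate Cox), selected by forward/backward
   stepwise Cox, and combined with the continuous RPI into a composite
   score whose cutoff is the median of the cohort it is applied to.

A bundled 10-pair neuroblastoma signature (coefficients and the −4.774
cutoff) ships with the package; `pairsig.load_published_signature()`
returns it ready for scoring.

## Worked example

```python
import pairsig as ps

model = ps.load_published_signature()
profile = {g: 1.0 for g in model.genes}   # every pair ties -> indicator 0
profile["EREG"] = 2.0                     # now EFNB3 < EREG only
score = ps.score_rpi(profile, model)
print(float(score.score[0]))              # -1.48200304
groups = ps.stratify(score, model.cutoff) # cutoff -4.774
print(groups.group[0])                    # high
```

`-1.48200304` is the (EFNB3, EREG) coefficient — the only active pair —
and `high` because the score exceeds the −4.774 cutoff.  End-to-end on
synthetic cohorts:

```python
from pairsig import PairSignatureCox, SimConfig, generate_two_cohorts

two = generate_two_cohorts(SimConfig(seed=1))
(e1, c1), (e2, c2) = two.cohorts
res = PairSignatureCox(e1, c1.survival("OS")).fit()
print(res.summary())                       # stage counts, pairs, cutoff
ev = res.evaluate(c2.survival("OS"), scores=res.predict(e2))
print(ev.logrank.p_value, ev.hr_high_vs_low)
```

The same pipeline is scriptable:

```bash
pairsig simulate --seed 1 --out sim/
pairsig train    --expression sim/cohort1_expression.tsv \
                 --clinical  sim/cohort1_clinical.tsv --out fit/
pairsig validate --signature fit/signature.txt \
                 --expression sim/cohort2_expression.tsv \
                 --clinical  sim/cohort2_clinical.tsv --out val/
```

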