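# scoreboot

Tools for designing **additive integer clinical scoring systems** and for
attaching **statistically honest outcome-probability estimates** to each
score, via bias-corrected and accelerated (BCa) bootstrap confidence
intervals.

Clinical scoring systems predict an adverse outcome with an integer a
physician can compute at the bedside:

```
s = Σᵢ λᵢ · sᵢ ,   i = 1 … d
```

where each of the *d* predictors is a binary risk indicator (λᵢ = 1 when
the patient lies on the risk side of the predictor's cutoff), and sᵢ is
its integer weight.  Discrimination is easy to optimize; the hard part is
*calibration* — what outcome probability a given score actually implies.
`scoreboot` addresses this by estimating, for every score class, a 95%
BCa bootstrap confidence interval of the observed outcome proportion, and
by pooling adjacent classes whose intervals overlap (their risks are not
statistically distinguishable).

The pipeline, aimed at biostatisticians building risk-stratification
models for binary outcomes (the bundled synthetic cohort emulates ICU
morbidity after coronary artery bypass grafting):

1. **Split** the cohort into training and testing halves with equal
   outcome prevalence, with Fisher / z-test / Mann-Whitney balance checks.
2. **Dichotomize** continuous candidates at the ROC point closest to the
   upper-left corner (sensitivity = specificity = 1), and **screen** all
   binary indicators: keep those whose Woolf 95% odds-ratio CI lies above 1.
3. **Select** predictors by forward stepwise search maximizing the training
   AUC of the integer score; already-entered predictors may re-enter, which
   increments their weight.  A soft rule stops the search when five
   consecutive steps gain less than 0.01 AUC cumulatively.
4. **Estimate** a 95% BCa interval of the outcome proportion for every
   score class at every step (1000 whole-training-set resamples).
5. **Pool** adjacent classes with overlapping intervals (greedy, from the
   sparse top of the score range), re-estimating intervals and AUC.

## Worked example

The real study cohort is not public, so the example uses the package's
synthetic emulation of it: 1090 patients, 78 candidate variables, five of
them genuinely predictive (the oxygen extraction ratio O2ER carrying twice
the unit effect), 20.7% target morbidity.

```python
import scoreboot as sb
from scoreboot.bootstrap import class_table

cohort, truth = sb.generate_cohort(sb.default_cohort_spec(n=1090, seed=1))
train, test = sb.stratified_split(cohort, 0.5, seed=3)
predictors = sb.screen_predictors(train)
results = sb.ForwardScoreSelection(train, predictors, test=test).fit()
print(results.summary())
```

```
 step           action variable  train_auc  test_auc
    1            enter     O2ER     0.6717    0.6483
    2            enter     CPBt     0.7214    0.6444
    3            enter       EM     0.7381    0.6359
    4            enter      PVD     0.7551    0.6507
    5 increment-weight     O2ER     0.7680    0.6773
    6            enter   CardID     0.7834    0.6949
    7            enter noise_36     0.7963    0.6896
    ...
   20 increment-weight       EM     0.8317    0.6436
stopped at step 20 (window)
```

Training AUC rises at every step by construction, but test AUC peaks at
step 6 — exactly when the five planted predictors are all in and O2ER has
been re-entered to weight 2; later steps fit noise.  Choosing that step and
estimating per-class intervals:

```python
step = results.final_step("test-auc")        # -> 6
model = results.model_at(step)
stats = sb.score_class_cis(train, model, B=1000, seed=7, test=test)
pooled = sb.pool_scores(train, model, stats, B=1000, seed=7, test=test)
print(class_table(pooled.stats))
```

```
class_label    n  pct_occurrence  proportion  ci_low  ci_high  test_proportion
        0-1  287          52.661       0.066   0.042    0.102            0.113
          2  131          24.037       0.237   0.170    0.316            0.236
        >=3  127          23.303       0.457   0.368    0.541            0.422
train AUC 0.783 -> 0.757; test AUC 0.695 -> 0.683
```

The greedy pooling united the sparse high scores (and the two lowest
classes, whose intervals overlapped), leaving three risk strata with
separated confidence intervals: low (~7%), moderate (~24%) and high
(~46%) morbidity probability.  The test-set proportions (stars in a
whisker diagram) fall inside the training intervals, and pooling cost
little discrimination.

The same pipeline is scriptable from a shell (`scoreboot simulate | split |
balance | screen | build | ci | pool | run`); `scoreboot run` writes the
full TSV/JSON report bundle.

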