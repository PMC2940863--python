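# Methods

## The model

A scoring system is an additive integer model over binary risk
indicators.  Patient score: `s = Σ λᵢ sᵢ` with λᵢ ∈ {0, 1} the indicator
of predictor *i* (1 on the risk side of its cutoff or risk level) and
sᵢ ≥ 1 its integer weight.  The model assumes nothing about the joint
distribution of predictors; it is judged on three axes:

- **discrimination** — rank AUC of the score against the binary outcome
  (Mann-Whitney form, ties ½; identical to trapezoidal ROC area);
- **generalization** — the same AUC on a held-out cohort;
- **probability calibration** — per-score-class outcome proportions with
  bootstrap confidence intervals, instead of a single calibration test,
  because classical goodness-of-fit tests are awkward for discrete model
  outputs.

## Dichotomization and screening

Continuous candidates are cut at the ROC point minimizing
`(1−sens)² + (1−spec)²` (squared Euclidean distance to the perfect
corner).  Candidate cutoffs are midpoints between consecutive sorted
distinct values — the ROC changes nowhere else.  Both risk directions
are searched, so protective variables (risk at low values) are handled
symmetrically.  Ties break toward higher sensitivity, then the lower
cutoff, then "at-or-above": deterministic, and favouring detection of
morbid patients.  Intrinsically binary variables are oriented so the
risk-positive level is coded 1 (the orientation is chosen on the training
data, which makes the subsequent screen effectively two-sided).

The screen keeps indicators whose odds ratio is significantly above 1 at
the 5% level, operationalized as the Woolf (logit) 95% CI lower bound
exceeding 1.  Woolf was chosen over exact or score intervals for its
transparency and closed form; a zero cell triggers the Haldane–Anscombe
+0.5 correction before both the estimate and the interval.  A simulation
test confirms ~95% coverage of the Woolf interval at moderate counts.

## Forward selection

Step 1 enters the candidate with the highest single-variable AUC.  Every
later step evaluates all candidates — unseen ones by entry, entered ones
by incrementing their weight — and applies the action maximizing training
AUC (ties: a new entry beats a weight increment, then lexicographic
name).  Selection stops when the cumulative AUC gain over five completed
consecutive steps falls below 0.01 ("1%" is read in absolute AUC units on
[0, 1], matching how selection curves are plotted), or immediately when no
action strictly improves the training AUC — a greedy search cannot
meaningfully continue on a non-positive best increment.  Windows are only
checked from step `window+1` on: five completed increments are required.

Test-set AUC is recorded per step and never consulted by the search.
Choosing the *conclusive* step is a separate act:
`ForwardSelectionResults.final_step("test-auc")` picks the earliest step
maximizing test AUC, automating the usual judgment of reading the
generalization curve; `"last"` returns the stop step.  Missing values:
screening is complete-case per variable; selection and scoring require
complete rows over the involved predictors (rows are dropped with a
warning during selection and rejected, naming the predictor, at scoring).

## Bootstrap confidence intervals

The statistic is the outcome proportion within a score class.  The
resampling unit is the **entire training set**: B = 1000 replicates (an
accepted sufficient count for bootstrap CIs) redraw n patients with
replacement, and class membership is recomputed per replicate, so class
sizes vary as they would across repeated cohorts.  No stratification by
outcome or class is applied.  One seeded generator produces a single
(B × n) index stream shared by all classes, for replicate coherence and
bit reproducibility.

- **Percentile interval**: nearest-rank (ceiling) empirical quantiles at
  (1−level)/2 and 1−(1−level)/2 — endpoints are actual replicate values.
  At least 40 effective replicates are required at the 95% level.
- **BCa interval**: percentile levels adjusted by
  `αₖ = Φ(z₀ + (z₀+zₖ)/(1 − a(z₀+zₖ)))`.
  The bias coefficient `z₀ = Φ⁻¹[(#{θ*<θ̂} + ½#{θ*=θ̂})/B_eff]` uses the
  midrank convention because proportions on resampled cohorts are heavily
  tied; fractions of 0 or 1 are clamped to `1/(2B_eff)` before the probit.
  The acceleration `a = Σ(θ̄−θᵢ)³ / (6[Σ(θ̄−θᵢ)²]^{3/2})` comes from the
  leave-one-patient-out jackknife over the full training sample (matching
  the resampling unit), with `a = 0` for a flat jackknife.  A non-positive
  adjustment denominator pushes the level to the corresponding extreme.
- **Empty classes in replicates** are dropped per class; `B_effective` is
  reported, with a warning below 0.9 B and an error below 0.5 B, so small
  high-score classes stay honest without silent degradation.  A class
  empty in the original training set is an error: the class definition is
  invalid for that model.

Forcing z₀ = a = 0 reproduces the percentile interval exactly (tested as
an identity).  Coverage is verified two ways: ~95% for a binomial
proportion (n = 200, p = 0.2), and ~95% for a mid-prevalence score-class
conditional probability against the generator's enumerated truth.

## Pooling

Adjacent classes whose **closed** intervals intersect (a shared endpoint
counts — conservative toward pooling) are candidates for merging, as are
classes holding under 2% of training patients (configurable), which are
too small for a stable interval even without overlap.  The greedy
strategy merges the highest-score candidate pair first — sparsity, and
hence overlap, concentrates at the top of the score range — re-estimates
all intervals with the same replicate stream, and repeats until no
candidate remains or one class is left.  A `manual` strategy applies a
user-supplied plan verbatim, because pooling in practice is
judgment-assisted.  AUC before/after is computed on pooled class ranks.
Note that merging two adjacent classes lowers rank AUC only when the
upper class has the larger observed risk (otherwise wrong-ordered pairs
become ties and AUC can tick up); the package reports both values rather
than assuming monotonicity.

## Synthetic cohorts

The generator draws independent Bernoulli risk indicators at stated
prevalences and a Bernoulli outcome through an additive logit
`β₀ + Σ βⱼ xⱼ`.  Continuous carriers hide an indicator behind a
two-component Gaussian mixture centred at `cutoff ± separation/2`
(risk-side component matching the intended direction), so corner-cutoff
recovery is testable at controlled overlap; the default separation of
3 standard deviations misclassifies ~7% per side.  Noise variables
(alternating binary and Gaussian) are independent of the outcome.

β₀ is calibrated so the *population* prevalence equals the target
exactly: with independent indicators the prevalence is a finite sum over
2^d indicator patterns, strictly increasing in β₀, solved by Brent
root-finding (no Monte-Carlo calibration or extra seed needed; d ≤ 20
enforced).  The same enumeration yields exact per-class occupancy and
conditional outcome probabilities — the oracle behind coverage and
monotonicity tests.

The default spec mirrors the motivating ICU cohort: five planted
predictors named after the published selected variables with their
published prevalences (O2ER 21.3% with double effect, Card-ID 13.6%,
PVD 21.3%, EM 8.3%, CPBt 40.9%), unit log-odds 1.0 (OR ≈ 2.7, a typical
clinical effect), 2.0 for O2ER, target prevalence 20.7%, and 73 noise
variables for a 78-column candidate table.  What the generator does *not*
emulate: predictor correlation (an independence assumption real ICU data
violates), measurement error, missingness patterns, or time-varying risk
— so passing tests certify the machinery and its statistical guarantees
under the assumed data law, not performance on real cohorts.  An
optional dependence mechanism was considered and left out: with
independent indicators every oracle stays exact, and correlation would
make planted-truth tests approximate.

## Numerical and design choices

- Stratified splitting assigns `ceil(fraction · n_stratum)` of each
  outcome stratum to training (odd strata favour training);
  deterministic per seed.
- Normality gate for the balance checks: Shapiro-Wilk at α = 0.05 in
  both sets (z-test only if both pass, Mann-Whitney otherwise) — the
  conventional, deterministic choice.
- AUC action ties in selection use a 1e-12 tolerance.
- Quantile ranks guard float noise (`⌈αB − 1e-9⌉`).
- Problem sizes in the test suite (coverage at 500–2000 replicates,
  recovery at 20 seeds × n = 2000) were chosen as the smallest sizes at
  which the Monte-Carlo error is comfortably inside the asserted
  tolerances.

## Known limitations

- Greedy forward selection with re-entry has no optimality guarantee;
  it reproduces the published procedure, not best-subset search.
- Woolf intervals are first-order asymptotic; very sparse tables rest on
  the Haldane correction.
- BCa endpoints are nearest-rank order statistics, so interval
  resolution is limited by B; B = 1000 is the default, not a ceiling.
- The final-step choice automates a judgment call; on noisy test sets
  the test-AUC argmax can sit one step away from the most parsimonious
  equivalent model, which is why every step's model remains accessible.
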