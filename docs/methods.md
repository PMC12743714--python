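# Methods

## Problem setting

`pucase` studies case ascertainment from hospital administrative data as a
positive-unlabeled (PU) learning problem. A condition such as sepsis is
systematically under-coded: cases that carry an explicit diagnosis code are
reliably positive, but the absence of a code does not make a case negative.
Formally, each case is a triplet (x, y, s): a feature vector x of cost and
procedure attributes, a latent class y ∈ {0, 1}, and an observed label
s ∈ {0, 1} with

- p(s=1 | x, y=0) = 0 — only true positives are ever labeled, and
- p(y=1 | s=1) = 1 — a labeled case is certainly positive.

The class prior is α = p(y=1) and the label frequency c = p(s=1 | y=1).
Under SCAR (Selected Completely At Random) every latent positive is labeled
with the same probability c; under SAR the labeling propensity
e(x) = p(s=1 | x, y=1) depends on a subset of attributes. The package's
analyses assume SCAR (or a SAR→SCAR reduction: the propensity attributes —
coder experience, documentation quality — are disjoint from the cost
attributes used for classification).

## Synthetic-data generator

The generator (`pucase.datagen`) emulates the statistical structure of an
inpatient case-cost table, not any real dataset's values:

- latent classes Bernoulli(α), default α = 0.2;
- observed labels drawn for latent positives with probability c (default
  0.5); in SAR mode the propensity is logistic in named features, rescaled
  so its mean over latent positives equals c;
- cost features are zero-inflated log-normals with class-conditional zero
  mass and log-location (an ICU-free case has ICU cost exactly 0; cost
  distributions are heavily right-skewed); procedure-chapter counts are
  class-conditional Poissons; total costs = a log-normal base stay cost
  plus the component costs;
- the explicit coding flag equals the observed label (labels are assigned
  by explicit coding); the implicit (infection + organ dysfunction) flag is
  drawn with probability 0.65 for latent positives and 0.045 for latent
  negatives, producing the overlapping scenario constellations A–E;
- cohort fields (5-year age bands, length of stay, main-diagnosis and DRG
  indicators) let the inclusion filters act; positives are older and stay
  longer.

Two cost profiles ship with the package. The default profile is tuned
qualitatively to published descriptives of coded sepsis cases (total costs
roughly three-fold higher for positives, many exact zeros, strong ICU and
laboratory involvement) and leaves genuine class overlap: a supervised SVM
reaches out-of-fold recall@0.1 ≈ 0.95. `strong_shift_cost_features()` makes
the classes nearly separable (supervised recall@0.1 ≈ 0.998) and is the
profile used for parameter-recovery experiments, where the separability
assumption is meant to hold nearly exactly.

What the generator does **not** emulate: the real catalogue of ~70 cost
attributes and their empirical correlations (features here are independent
given the class), hospital-level clustering, coding drift over time, and
any dependence of the implicit flag on the cost features. Passing
parameter-recovery tests on this generator therefore shows the algorithms
behave as designed under their stated assumptions — not that those
assumptions hold in any particular administrative dataset.

All stochastic stages derive child seeds from one master seed via
`numpy.random.SeedSequence`; identical configurations produce byte-identical
CSV exports.

## Preprocessing

Cohort filters keep adult acute-care cases with a main diagnosis, a DRG
code, complete cost data (any missing cost cell excludes — the stricter
reading, flagged to users), positive total costs and at least one day of
stay. Exclusions are attributed first-match in a fixed rule order; the
order affects only the report, never the surviving set. Undersampling keeps
every labeled positive and a uniform random subsample of the unlabeled
pool. Min–max normalization is fitted on the training partition of each
fold only; held-out values outside the training range are deliberately not
clipped (radial-kernel classifiers tolerate them, and clipping would
distort distances).

## Spy learner

Step 1 seeds 10% of labeled positives ("spies") into the unlabeled pool and
fits a probabilistic classifier with positives as class 1 and
unlabeled-plus-spies as class 0. The minimum predicted probability among
the spies bounds how low a genuine positive can score; unlabeled cases
strictly below it become reliable negatives. Because a single unlucky spy
can drag that minimum arbitrarily low, the step is repeated (default 1,000
times) with a fresh spy draw each repeat, and the threshold is the mean of
the per-repeat minima. Per-case step-1 probabilities are likewise averaged
across repeats (per-repeat minima are stored, so the single-run reading is
reproducible from the fit object). Step 2 trains a supervised classifier on
all labeled positives versus the reliable negatives; remaining unlabeled
cases are scored by that model. The step-2 training label mean is recorded
and serves as the classification threshold.

Reference classifier pairs: logistic regression + Gaussian naive Bayes
(baseline) and gradient-boosted trees for both steps (updated variant), all
at library defaults. The logistic scorer runs behind a standardizer because
raw cost attributes span orders of magnitude.

## Adaptive-resampling ensemble

Unlabeled cases start as putative negatives with mislabel probability 0.
Each iteration draws a training set, fits the base classifier (default: an
RBF-kernel SVM on min–max-scaled features, with probabilities from Platt
scaling — a one-dimensional logistic fit on the training decision values),
and updates every instance's mislabel probability to the predicted
probability of the class opposite its putative label. The loop runs at most
5 iterations with early stop when the largest change falls below 1e-3.
Finally, 20 ensemble members are fitted on independent low-mislabel
resamples; the prediction is their unweighted mean. The ensemble covers the
final classifier only, not the adaptive loop: the loop's purpose is the
mislabel estimates, and ensembling over independent resamples of those
estimates is what reduces prediction variance.

Two design choices in the resampling deserve emphasis, both found
necessary during development:

1. **Per-class fixed-size resampling.** Each putative class is bootstrap-
   resampled at its own size with selection weight 1 − mislabel, so an
   instance's exclusion pressure equals its mislabel probability while
   class sizes stay fixed. Excluding instances globally instead lets the
   labeled positives (mislabel = 1 − p) thin out faster than the hidden
   positives among the negatives (mislabel = p) whenever p dips below 0.5
   in the positive cluster; at c = 0.5 the fit then collapses to the
   majority class (measured recall 0.29 versus 0.96).
2. **Pinning labeled positives** (`pin_labeled_positives=True`, default).
   A labeled positive is positive by construction of PU data
   (p(y=1|s=1) = 1), so down-weighting it by an *estimated* mislabel
   probability contradicts the labeling mechanism and lets early errors
   evict genuine positives permanently (recall plateaued at 0.78 without
   pinning versus 0.96 with it, out-of-fold at α = 0.2, c = 0.5). The
   mislabel estimate p(y=0|x) is still recorded for labeled positives as a
   diagnostic; pinning only removes it from the resampling weights and can
   be switched off.

A caveat on the mislabel scale: as contamination of the putative-negative
class grows, the base classifier's probability estimates blur, so the
*absolute* mislabel scores of hidden positives soften even while they
remain far above true negatives. Mislabel probabilities separate the two
groups reliably; they are not calibrated contamination rates.

## Evaluation

Real PU data contain no verified negatives, so false positives and true
negatives are uncountable. The package reports the PU-estimable metrics:
recall r = TP/(TP+FN), recall@k (share of all truth positives inside the
top k% of probability-ranked cases) and precision@k (share of truth
positives within that top set), for k ∈ {10, 20, 30}. Under SCAR, recall
against labeled positives is an unbiased estimate of recall against all
latent positives — but only for held-out predictions; transductively scored
training positives are optimistic. Evaluation therefore uses five-fold
stratified cross-validation with pooled out-of-fold predictions. Both
pooled and per-fold-averaged summaries are emitted, since either reading of
a cross-validated table is defensible.

Truth is defined by observed coding flags in five constellations —
A explicit, B explicit∧implicit, C implicit, D explicit∨implicit,
E implicit∧¬explicit — which satisfy E ⊆ C ⊆ D and B ⊆ A ⊆ D and
|D| = |A| + |C| − |B| on any dataset. On synthetic data, metrics against
latent truth ("oracle metrics") can be computed separately.

Numerical conventions: classification is positive at probability ≥
threshold (the training-set label mean of the fold); the top-k set has
floor(k·N/100) members (floor never inflates precision); ranking ties break
by ascending case id, making every ranking deterministic and auditable.

## External validity

Relabeling the unlabeled cases above a threshold implies a new population
disease rate. With l_i labeled positives and u_i unlabeled cases in the
initial sample (n_i = l_i + u_i), and u_t unlabeled cases in the
undersampled learning sample, a relabel count r transfers as
u_i · r / u_t, giving s_i = l_i + u_i·r/u_t new positives and the new rate
s = s_i / n_i. The ratio of the new rate to the raw coded rate l_i/n_i
reduces to s_i / l_i and is benchmarked against the 2.4–4.1 multiplier
range that medical record review studies report for sepsis: ratios above
the band flag over-relabeling, below it over-conservatism. Thresholds come
from the top-5%…top-30% of ranked predictions (per fold, averaged across
folds) or from the class label mean; relabeling applies the averaged
threshold to pooled out-of-fold predictions so each unlabeled case receives
exactly one decision. Transferred counts stay real-valued until report
formatting (thresholds 5 d.p., rates 2 d.p. in percent, ratios 1 d.p.,
recall 3 d.p.).

Note a symbol collision in the field's notation: r_k denotes recall@k in
evaluation and the relabeled count in the rate transfer; the package names
the latter `relabel_count_t`.

## Problem sizes used in tests and the acceptance script

Parameter-recovery experiments run at n = 5,000 cases (five seeds,
five-fold CV) with the strong-shift profile; the acceptance script's
synthetic run uses n = 3,000 and one seed, and its spy-stability check
n = 240 with 10/200 repeats over 10 replicates — sizes chosen so the whole
analysis reruns from scratch in minutes on a single core while leaving the
binomial standard errors small relative to the effects tested. The
rate-transfer arithmetic is exact at any size and uses the published
counts directly.

## Known limitations

- The spy learner's reliable-negative threshold is an average of minima;
  with a badly miscalibrated step-1 classifier the threshold can approach
  0 and leave no reliable negatives (this raises an explicit error rather
  than fitting a degenerate step 2).
- Platt-scaled SVM probabilities are monotone transforms of margins, not
  calibrated posteriors; ensemble means inherit this.
- The adaptive learner's recall degrades when the class-conditional cost
  distributions overlap substantially (default profile: out-of-fold recall
  ≈ 0.78 at c = 0.5), which is a property of the problem, not a failure of
  the implementation — the supervised ceiling with latent labels is higher
  because hidden positives no longer contaminate the negative class.
- SAR mode exists for robustness experiments only; no SAR-specific
  propensity estimation is implemented.
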