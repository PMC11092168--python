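# Methods

## Model and assumptions

`mvboost` learns a multi-class classifier from K feature views of the same
individuals, where each view j observes only a subset `N_j` of the full
sample set `N = ∪_j N_j`. The algorithm couples two components:

* **Shared-weight boosting.** One weight distribution `w` over `N` is
  shared by every view. Each round, a weak hypothesis fitted on the winning
  view updates `w` multiplicatively by its agreement with the labels. The
  multi-class agreement indicator `I[a=b] ∈ {0,1}` generalizes the binary
  ±1 label product through the identity
  `Σ w_i y_i h_i = 2 Σ w_i (I[y_i=h_i] − ½)`, which the test suite checks
  exhaustively (bit-exactly) for all ±1 labelings up to n = 8.
* **Adversarial bandit over views.** Views are arms; no distributional
  assumption is made on rewards. Selection probabilities follow an
  exponentially-weighted-average forecaster over cumulative
  importance-weighted rewards, mixed with uniform exploration:
  `p_j = (1−γ)·softmax(σR)_j + γ/K`, `R_j += edge/p_j` for the played arm.
  Dividing by `p_j` makes the estimate unbiased and favors rarely-played
  views (diversity). Rewards are accumulated, not averaged: the forecaster
  normalization realizes the exponential dependence on average reward.

**Incompleteness semantics.** A sample absent from the selected view gets
the artificial label 0 — reserved, since real classes are `1..C` — and the
zero probability vector. It therefore contributes exactly zero to the edge
and its weight is touched only by the final renormalization; in the
prediction phase the zero vector participates harmlessly in the weighted
sum, so a test instance is scored by exactly the views that observe it.
The core never imputes; mean imputation exists only as an explicit baseline
adapter (fold-local means, reused at test time, so no leakage).

Samples are identified by string identifier, not position; views may order
and subset samples freely. Rows with in-row missing values are rejected at
read time: missingness is expressed only by a sample's absence from a view.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `sigma` (σ) | 0.15 | forecaster learning rate on cumulative rewards (> 0) |
| `gamma` (γ) | 0.3 | exploration rate; enforces the floor `p_j ≥ γ/K` (0 < γ < 1) |
| `T` | 50 | boosting iterations |
| `base_learner` | `"rf"` (random forest, 50 trees) | weak hypothesis family; `"dt-<depth>"` gives depth-limited trees |
| `k` (CV folds) | 10 | cross-validation folds |

σ = 0.15 and γ = 0.3 are the conventional settings for this forecaster
family and are the package defaults. One pseudo-random stream drives each
fit, consumed in a fixed order per iteration (bandit draw, then the weak
learner's seed), so fits are bit-reproducible under a fixed seed.

## Numerical choices

* The softmax over `σR` subtracts `max_k σR_k` before exponentiation
  (log-sum-exp); probabilities are translation-invariant in `R`, so this is
  exact, and it keeps the update finite although importance-weighted
  rewards grow unboundedly with T.
* The vote weight `α = ½ ln((1+e)/(1−e))` clips the edge into
  `[−1+ε, 1−ε]`, ε = 1e-10, so perfect rounds stay finite (α ≈ 11.86).
* Rounds with edge ≤ 0 are recorded with α = 0: they still feed the bandit
  (penalizing uninformative views) and count in the winner tally, but are
  excluded from the combined classifier, because a multi-class hypothesis
  cannot be inverted the way a binary one can.
* Weights passed to the weak learner are restricted to the view's present
  samples and renormalized, so the learner always sees a distribution.
* Argmax ties in prediction break toward the smallest class index; the
  binary predecessor maps a zero score to the smaller class. Both are
  determinism contracts.
* A selected view that is empty (possible after fold restriction) or whose
  learner fails yields a recorded zero-weight round with reward 0.
* Weight underflow (all weights 0 after update) raises rather than
  renormalizing garbage.

## Cross-validation design

Each sample receives **one global fold assignment**: a sample shared by
several views must never be in one view's training split and another
view's test split. Folds are built greedily — membership patterns spanning
more views first, each sample placed in the fold minimizing the induced
counts of the views containing it, then its class count — which keeps
every view's induced split within one sample of equal-sized for
overlapping-cohort structures (verified constructively in the tests).
Precision/recall/F1 are macro-averaged by default (a weighted mode is
available and flagged in reports); AUC is one-vs-rest macro over the
ensembles' normalized score vectors. The binary predecessor reports no AUC
since it emits labels, not scores. Method comparisons use two-sided
Wilcoxon signed-rank tests on per-fold paired scores with
Benjamini–Hochberg correction across comparisons; the pairing unit (folds)
is a package choice and is noted in reports.

## Synthetic data

The generator emulates the structure of multi-assay cohorts, not their
biology. Present samples of view j are drawn from class-conditional
spherical Gaussians whose means sit `s_j` noise-SDs apart (`s_j = 0` gives
a label-independent noise view); per-view missingness masks are sampled
with a coverage constraint (every sample present somewhere). For two
balanced classes the per-view Bayes accuracy is `Φ(s_j/2)`, recorded in
the ground-truth output for calibration. A negative-binomial mode produces
sparse OTU-like count tables (lognormal baseline abundances, class effects
as log fold-changes, dispersion 2). A *complementarity* switch makes view j
informative only about class j versus the rest, so no single view can solve
the task but the union can. `make_incomplete_mvasd_like` reproduces, at any
scale, the two-assay membership structure of a cohort where a large assay
covers most individuals and a small one covers a subset plus a few
exclusives.

What the generator does **not** model: compositionality, phylogenetic
correlation among taxa, batch effects, or label noise. Passing tests on
these fixtures shows the algorithmic contracts hold, not that the method
attains any particular accuracy on real microbiome cohorts.

Default sizes used by the tests and the acceptance script (chosen as the
smallest settings at which the measured properties stabilize): 10 features
per view; winner-share experiment n = 200, T = 50, 20 generator seeds;
multi-view benefit n = 300, C = 3, 30% missingness per view, 10-fold CV
over 10 seeds in the tests and 5 seeds in the acceptance script.

## Design choices on genuinely open points

* **Edge over present samples only.** The two algebraic forms of the edge
  disagree for absent samples (`y·0 = 0` versus `2(0−½) = −1`); the
  zero-contribution reading is the stated intent of the incompleteness
  semantics and is what is implemented.
* **Reward = edge.** The edge is the only per-view quality scalar the
  update defines; the alternative (α·edge) is isolated behind the same
  single mapping and was measured to discriminate no better.
* **Input values are passed through unchanged** (no relative-abundance or
  log transform) and presence for filtering means a strictly positive
  value, evaluated on the raw table; prevalence bounds are inclusive.
* **Fold-local imputation means** for the baselines, rather than global
  means, to avoid test-information leakage.

## Known limitations

* **Edge saturation with strong base learners.** A fully-grown random
  forest reproduces its (weighted) training labels almost exactly, so every
  view's training edge saturates at 1: all vote weights become equal and
  the bandit reward carries no information, making winner frequencies drift
  (herding) rather than track view relevance. This is why the
  winner-frequency experiments use a depth-1 tree — the weak-hypothesis
  premise of boosting — and why winner shares should be read as a coarse
  relevance indicator. Even with weak learners the shared weight
  distribution equalizes view edges over rounds (the self-limiting property
  of boosting), and the importance-weighted reward has variance
  ~`edge²/p`, so with σ = 0.15 and T = 50 per-run winner shares are noisy
  (SD ≈ 0.11 around a mean of ≈ 0.55 for an informative-vs-noise pair);
  relevance rankings should be averaged over many runs.
* On complementary-view tasks with a saturating base learner the combined
  classifier reduces to an (unevenly) weighted average of per-view models,
  and feature concatenation — which can join complementary features inside
  one tree — is a statistically indistinguishable or slightly stronger
  competitor; the clear advantage of the multi-view booster is over the
  best *single* view and over imputation-based pipelines.
* The binary predecessor requires complete views by construction; the
  harness pairs it with mean imputation on incomplete data.
* No semi-supervised mode, regression or multi-label targets; no
  sequence-level preprocessing (the package consumes feature tables).
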