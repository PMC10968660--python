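# Methods

This note documents the models, procedures and design choices behind
metaselect: what each component computes, the defaults and why, what the
synthetic data does and does not emulate, and the numerical conventions
that make runs reproducible bit-for-bit.

## The selection problem and the wrapper model

Feature selection is posed as optimization over binary masks m ∈ {0,1}^p.
The objective is wrapper fitness: the mean accuracy of a naive-Bayes
classifier over a stratified 5-fold cross-validation of the training
partition, using only the features with m_j = 1. Accuracy (not weighted F1)
is deliberately the search criterion — the held-out evaluation then reports
imbalance-aware metrics, which keeps the search and the assessment roles
distinct.

### Naive Bayes on mixed-type data with missing cells

The wrapper classifier assumes conditional independence of features given
the class and handles the survey data exactly as collected:

- **Priors** are class frequencies of the training fold.
- **Nominal likelihoods**: P(x_j = v | c) = (n_{cv} + 1) / (n_c + V), with
  add-one (Laplace) smoothing over the V categories observed in the
  training fold for that feature; a category seen only at prediction time
  receives 1 / (n_c + V). Here n_c counts that feature's non-missing
  training cells in class c.
- **Numeric likelihoods** are Gaussian with per-(feature, class) mean and
  standard deviation. The standard deviation is floored at
  max(1e-6 × feature's training range, 1e-9) to prevent zero-variance
  singularities. The floor is a documented constant of this implementation,
  not a claim about any other toolkit's internal precision.
- **Missing cells** are skipped — excluded from counts and moments at fit
  time and from the likelihood product at prediction time. There is no
  imputation anywhere in the package; an instance with all features missing
  is scored by the priors alone.
- If a feature has *no* non-missing training data for one class, that
  (feature, class) pair contributes nothing at prediction, leaving the
  other classes' evidence intact.
- Posteriors are computed in log space and normalized; prediction is the
  argmax with ties broken toward the first class in declaration order
  (positive class first). The empty mask is legal and yields the
  prior-only classifier, so the optimizers never need a special case for
  the all-zeros mask.

### The precomputing evaluator

`cv_fitness` is the plain route: per fold, fit on k−1 folds, predict the
held-out fold. `CVFitnessEvaluator` exploits the factorization of naive
Bayes: for every fold it precomputes, once, the log-likelihood of each
validation cell under each class from that fold's training statistics.
Any mask's score is then log-priors plus a sum over the selected features'
precomputed slices — O(|m| · n_valid) per fold instead of a full refit. The
two routes apply identical statistical rules and the test suite asserts
per-fold agreement; the evaluator also memoizes results by mask bits, which
is sound because fitness is a pure function of the mask. This is what makes
runs with tens of thousands of evaluations take seconds.

## Optimizers

Both optimizers treat the evaluator as an injected black box (any callable
mask → fitness), initialize masks with i.i.d. Bernoulli(0.5) bits (no fixed
subset size), and are driven entirely by a single integer seed.

### Genetic algorithm

Defaults: population 30, mutation rate 0.01, parent-selection rate 0.5,
top-3 elitism. Per generation, the best ⌈30·(1−0.5)⌉ = 15 individuals
survive by fitness (a superset of the top-3 elites, so the stated elite
guarantee is subsumed), and 15 offspring fill the remaining slots: parents
are drawn by roulette wheel over the full previous population (elites
included; with an all-zero fitness vector the wheel degrades to uniform),
recombined by one-point crossover with the cut uniform in [1, p−1], and
each child is bit-flip-mutated independently. Duplicates are allowed — the
memoizing evaluator makes re-scoring them free. The survivor sort is
stable, so equal-fitness ties keep the earlier individual and runs are
reproducible. Bookkeeping follows: G generations breed exactly 15·G new
solutions (1,500 / 7,500 / 15,000 for G = 100 / 500 / 1000), and the
best-fitness trace is nondecreasing.

### Harmony search

Defaults: HMS 30, HMCR 0.85, PAR 0.7, one improvisation per iteration,
replace-the-worst on strict improvement (ties are rejected, so acceptance
always means progress and memory size is invariant). Memory consideration
draws the source harmony independently per bit, the canonical per-variable
rule.

**PAR semantics in binary encoding** was a genuinely open design point.
Pitch adjustment of a continuous variable has no unique binary analogue; a
literal per-bit flip probability of 0.7 applied to memory-derived bits
would randomize most inherited information and destroy convergence. The
default `per_harmony` mode therefore flips exactly one uniformly chosen bit
of the candidate with probability PAR — the mutation-like reading that
preserves convergent behavior at PAR = 0.7. The literal `per_bit` mode is
retained behind a switch for comparison; neither is claimed to be anyone
else's exact mechanics.

The improvisation consumes its random stream in a fixed order (memory
uniforms, source indices, random bits, pitch draws) regardless of the HMCR
value, so a degenerate schedule and a fixed parameter produce bit-identical
runs from the same seed — the structural precondition for any
fixed-vs-dynamic comparison, and a tested invariant.

### Dynamic schedules

HMCR rises linearly from 0.7 to 1.0 over the iterations (explore early,
exploit late); the GA mutation rate falls linearly from 0.1 to 0.001 and is
floored at 0.001 so mutation never vanishes. Interpolation is over
index/(total−1) so both endpoints are attained exactly; a one-step run uses
the starting value. PAR is kept fixed: scheduling it in binary encoding
risks false convergence, for the same reason the per-bit PAR mode is not
the default.

## Filter baselines

Entropy-based scores operate on discrete columns; numeric features are
discretized by equal-frequency binning (10 bins by default) — a simple,
deterministic choice, documented as this package's dialect rather than a
reproduction of any particular MDL discretizer. Missing values are excluded
pairwise from contingency counts.

- **Information gain**: IG(X; y) = H(y) − H(y | X) in bits over
  pairwise-complete rows; selection keeps features with IG ≥ 0.1, the
  threshold being inclusive.
- **CFS**: symmetrical uncertainty SU = 2·I/(H_X + H_Y) (0 when both
  entropies vanish) feeds the Ghiselli merit
  k·r̄_cf / sqrt(k + k(k−1)·r̄_ff). Search is forward best-first with a
  priority queue on merit, single-feature expansions, and termination after
  5 consecutive expansions without a new global best; merit ties prefer
  the lexicographically smaller subset, so results are deterministic.
  Feature–feature SUs are computed lazily and cached.

## Data handling

- Cells are category tokens, floats, or missing (NaN); missingness is a
  first-class state, never imputed.
- Column kinds are inferred as numeric iff every non-missing cell parses as
  a float; survey ordinal codes therefore stay nominal unless the column is
  genuinely numeric. No scaling, one-hot encoding or other feature
  engineering is applied anywhere.
- The handgrip diagnosis rule labels a record positive iff grip is
  *strictly below* the sex threshold (28 kg male / 16 kg female); a grip
  exactly at threshold is negative. Records with missing grip or an
  unmappable sex token are dropped and counted, and the grip column is
  removed from the feature set so the label cannot leak.
- The unreliable-feature screen drops items with fewer than 6 non-missing
  responses ("five or fewer") and ID-like nominal columns (≥ 99% distinct
  tokens relative to the instance count), scanning left-to-right. The
  response rule counts non-missing responses, not distinct answer
  categories — the more conservative of the two readings.
- The stratified 80/20 split gives each class exactly
  ⌊0.8·n_c⌋ training instances (remainder to test); floor rounding is what
  reproduces the cohort's printed counts 2,051/3,139 train and 513/785 test
  from 2,564/3,924. Stratified k-fold splits each class into chunks whose
  sizes differ by at most one, remainder on the leading folds.
- Evaluation-side adapters for the scikit-learn classifiers ordinal-encode
  nominal tokens and median-fill numeric missing cells *inside the
  adapter*; this is plumbing for estimators that cannot take mixed input,
  not dataset preprocessing, and the native naive Bayes uses none of it.

## Synthetic data: what it emulates and what it does not

`generate_survey` produces a cohort with exactly n_positive positive labels
(default 2,564 of 6,488), p features (default 778, 80% nominal) arranged in
contiguous blocks sharing category-count ranges (2–6 categories) to mimic
survey sections, i.i.d. missingness (default rate 0.05 — chosen once as a
realistic survey missingness level), and a planted informative subset
(default 20 features).

**Effect size** is a single probability tilt δ ∈ (0, 0.5] applied
uniformly: informative nominal features are binary with
P(signal category | positive) = 0.5 + δ and 0.5 − δ for negatives;
informative *numeric* features are shifted by 2·Φ⁻¹(0.5 + δ) standard
deviations, the shift at which a midpoint threshold separates the classes
with probability 0.5 + δ. This probit mapping makes nominal and numeric
planted features equally discriminative, so a single δ calibrates the whole
generator: at δ = 0.3 and cohort-scale n, every informative feature clears
0.02 bits of information gain while noise features stay below 0.005 bits
(a tested property). A raw δ-SD mean shift would not achieve this — at
δ = 0.3 it carries only ~0.014 bits.

What the generator does **not** emulate: real questionnaire semantics,
inter-item correlation structure beyond the planted signal, informative
missingness (missing cells are independent of the label), or ordinal
response scales. Consequently, passing recovery tests demonstrate that the
optimizers find marginally informative items under missingness and
imbalance — not that they untangle correlated or interaction-only signals
in real survey data.

`make_grip_table` builds raw sex + grip tables whose per-sex normal grip
distributions (SD 8 kg male, 6 kg female) are centered so the thresholds
yield the requested positive fraction, for end-to-end exercises of the
labelling rule.

## Verification experiments and problem sizes

The benchmark harnesses (`metaselect.benchmarks`, driven by both the
acceptance tests and `scripts/acceptance.py`) use deliberately small
problems so each runs in seconds to a few minutes on one CPU:

- **Bookkeeping**: GA offspring totals on a 150 × 8 survey; split counts at
  full cohort scale (6,488 instances) with a narrow 20-feature grid, since
  the counts depend only on the labels.
- **Oracle equivalence**: one 150 × 10 survey (3 informative, δ = 0.3); the
  2^10 = 1,024 masks are enumerated exactly, then 20 seeded GA runs
  (100 generations = 1,500 offspring) and 20 seeded HS runs (1,000
  iterations) are compared against the enumerated optimum at a 0.02
  accuracy tolerance.
- **Recovery**: a 2,000 × 50 survey with 5 informative features at δ = 0.3;
  success means the selected mask's overlap with the planted set strictly
  exceeds the hypergeometric expectation at the same mask size.
- **Parity**: 200 × 12 survey, GA 25 generations / HS 300 iterations,
  degenerate schedules vs fixed parameters, compared bit-for-bit.

Child seeds for every stochastic component are derived from the single
top-level seed via `numpy.random.SeedSequence`, kept below 2^31.

## Known limitations

- The naive-Bayes variance floor and smoothing conventions are this
  package's own; other implementations differ in their internal precision
  constants, so absolute fitness values are comparable only within the
  package.
- Binary labels are the tested path; the metric and NB formulas generalize
  to more classes but are not exercised there.
- Best-first CFS enumerates single-feature additions per expansion; on very
  wide data (hundreds of features) the lazily cached pairwise SU matrix can
  still grow expensive.
- Wrapper selection optimizes NB accuracy; feature sets transferred to
  other classifiers (tree/forest/SVM) carry no optimality guarantee — the
  experiment harness exists precisely to measure that transfer.
- No feature-count penalty is applied, so selected masks tend to keep
  roughly half the features unless the signal is sparse and strong.
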