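# Methods

## Problem setting

Kidney-transplant registries record donor and recipient covariates at the
time of the operation and follow each patient until graft failure (return
to dialysis), death, or loss to follow-up. The modelling task here is the
binarized five-year question — will the graft still function 1826 days
after transplantation? — treated as supervised classification on
pre-operative covariates only. Records whose follow-up ends before the
horizon with a functioning graft are censored; for the binary label they
are grouped with survivors (class 1, "survive"), since the graft had not
failed when last observed. That grouping biases the class-1 rate upward
relative to the true five-year survival probability and is the standard
price of forcing a censored outcome into a binary label; time-to-event
modelling is explicitly out of scope.

## Preprocessing

Cleaning keeps pre-operative covariates, the three date columns and the
outcome; identifier and post-operative columns are dropped (the model must
be usable before the operation, and identifiers carry no predictive
value). Rows missing more than 30% of their feature cells are deleted —
the registry practice of discarding unusable records, with the threshold a
package choice since no canonical value exists; it is configurable.

Missing covariates are imputed with the *temporal-neighbour mean*: records
are ordered by transplant date and a missing value becomes the arithmetic
mean of the nearest preceding and nearest following observed values in
that order. At a temporal boundary the single nearest observed neighbour
is used. This estimator assumes slow drift of covariate distributions over
enrolment time; at the ~1% missingness the pipeline targets, the choice of
imputer is immaterial to downstream results, which is why a simple rule
was preferred over multiple imputation.

Graft time is `dialysis_start − transplant_date` when a dialysis
re-initiation date exists (the graft failed), else
`last_followup − transplant_date`. Durations are calendar-day differences
(leap days counted). A dialysis date preceding the transplant is rejected
as a data error.

The train/test split is 70/30, stratified by outcome by default (the
outcome is mildly imbalanced and test sets are small enough for prevalence
drift to matter); a flag disables stratification. The training-partition
size is `round(0.7·n)`.

## The buffalo-herd optimizer

Each of `n_buffalo` animals holds an exploitation position `w` and an
exploration move `m`, updated elementwise per iteration:

    m ← m + le₁(bg − w) + le₂(bp − w)
    w ← clamp(w + m/λ*, bounds)

`bg` is the herd-wide best position found so far (the democratic,
cooperative term), `bp` the buffalo's personal best (the memory term).
Defaults le₁ = 0.6, le₂ = 0.5, λ* = 1, herd 20 follow the conventions of
the originating swarm literature; all are configurable. λ* acts as a time
unit dividing the move into a position step.

A structural property of this update matters for implementation: the
linearized per-coordinate map (w, m) → (w′, m′) has unit determinant for
every choice of le₁, le₂, λ*, so the herd oscillates around its bests
without intrinsic damping and cannot refine indefinitely on its own. The
package therefore drives late-stage convergence through its restart rule:
when the herd best has not improved for `restart_patience` (default 10)
consecutive iterations, every buffalo except the incumbent best is
re-scattered uniformly in a box centred on the herd best, with moves
zeroed and personal bests reset to the fresh positions. The scatter radius
starts at half the bound width and is multiplied by `restart_shrink`
(default 0.5) at each restart, giving a standard coarse-to-fine restart
schedule. With these defaults the optimizer reaches the 5-dimensional
sphere optimum to ~10⁻⁶ within 200 iterations across seeds.

Objective values must be finite; a non-finite value aborts the run with
the offending point reported. The best-so-far history is recorded per
iteration and is non-increasing by construction.

For subset search, a real position is binarized by passing each coordinate
through the logistic function and comparing to a cutoff (0.5); a raw
threshold transfer is also available. An all-false mask is repaired by
switching on the highest-scoring coordinate, so candidate subsets are
never empty.

## Hybrid feature selection

**Filter.** Information gain is computed in bits against the binary label.
Continuous features (more distinct values than bins) are discretized by
equal-frequency binning, default 10 bins — equal-frequency rather than
equal-width because registry covariates are routinely skewed. The
threshold-zero rule keeps features with strictly positive gain. Note that
with continuous covariates the *empirical* gain of even a pure-noise
feature is almost surely positive at finite n, so the zero threshold
removes only genuinely degenerate columns (constants, pure identifiers);
the burden of discarding noise falls on the wrapper stages. An empty
filter result is repaired to the single top-ranked feature.

**Wrapper.** The herd optimizer searches a continuous vector of length
equal to the incoming mask, binarized per candidate; fitness is
1 − validation accuracy of a classifier trained on the candidate subset.
The incoming mask itself seeds the herd, so the result never scores worse
than the input. Fitness carries no subset-size penalty, but ties are
broken toward parsimony: among all subsets evaluated during the search
that achieve the best validation accuracy, the smallest is returned
(lexicographic on indices, for determinism). Without this secondary
ordering, equal-accuracy ties would systematically retain noise features.
Candidate evaluations are cached per subset.

**Backward elimination.** Features are scanned in ascending information-
gain order (weakest candidates tested first) and tentatively removed one
at a time; a removal is made permanent only when validation accuracy
*strictly* improves — a tie keeps the feature, the conservative reading.
Scanning repeats until a full pass makes no removal or one feature
remains, so the final validation accuracy never falls below the initial
one.

Both wrapper stages use an internal stratified 80/20 validation split of
the training partition with a seed derived from the stage seed; test rows
are never visible to selection (the stages receive only the training
table).

**Classifier choice.** The subset-scoring classifier is configurable:
`logistic` (regularized, behind a standardizer; the default), `tree`
(depth-limited CART), or `ann` (the buffalo-trained perceptron itself at a
reduced herd budget). The default is the linear model because wrapper
search refits the classifier hundreds of times and the perceptron's own
herd training inside that loop multiplies cost for no measurable gain in
recovered-feature recall on the synthetic cohorts; the perceptron remains
the final prediction model in every case.

## The perceptron and its training

One hidden layer: `t = f′(m + μx)`, `s = g′(a + bᵗt)`, with f′ ∈
{tanh, logistic, linear} (default tanh) and g′ ∈ {logistic, linear}
(default logistic, giving probability semantics). Default hidden width is
max(3, ⌈√p⌉) for p inputs — small on purpose, since the weight vector is
searched globally rather than follow a gradient. Covariates are
standardized with training-partition statistics that travel with the model
and are reused verbatim at prediction time.

Training minimizes the mean squared error between s and the 0/1 label
over the flattened weight vector (ordering: hidden intercepts, hidden
weights row-major, output bias, output weights); misclassification rate is
available as an alternative fitness. The MSE surface is smooth and matches
the probability-scale RMSE reported downstream. `scope="last_layer"`
freezes random hidden weights (a random-projection layer, scaled by
1/√p) and searches only the output layer — a much smaller, better-
conditioned search retained for when the full search is too expensive.

The library-level default search box is [−5, 5] per weight. The pipeline's
default training configuration narrows it to [−2, 2] with a herd of 40,
1000 iterations and restart patience 5: on standardized inputs, tanh
units saturate well inside ±5, and the narrower box roughly doubles
end-to-end held-out accuracy at the default study size. Hard labels use
the s ≥ cutoff convention (default 0.5).

## Metrics

With survival as the positive class: accuracy (tp+tn)/n, precision
tp/(tp+fp), recall tp/(tp+fn), F-measure 2PR/(P+R). RMSE and MAE are
computed by default between predicted probabilities and the 0/1 labels
(the convention of standard classifier toolkits; a flag switches to hard
labels). Zero denominators return 0 with a logged warning. A
`strict_paper` precision flag reproduces a misprinted tp/(tn+fp) variant
found in some of this model family's literature, for audit comparisons
only.

## The synthetic cohort generator

The generator emulates the *shape* of a transplant registry, not its
clinical content: 67 default columns (2 identifiers, 61 pre-operative
covariates, 4 post-operative decoys) plus three date columns and the
outcome. Ten planted covariates drive a logistic outcome model with
default coefficients alternating ±1 — a strong but plausible effect on
standardized covariates, chosen once so that the information in the data
(n = 2000 at the default study size) supports feature recovery without
making it trivial. About 30% of covariates are categorical with 2–5
levels, entering the model through fixed symmetric integer codes
(level − (k−1)//2), which keeps prevalence near one half at zero
intercept. Missing cells are completely at random at rate 1% in feature
columns, never in two temporally adjacent cells of the same column, so
neighbour-mean imputation is always defined. Dates are drawn consistently
with the outcome: failed grafts receive a dialysis-initiation date within
the horizon; functioning grafts have no dialysis date, and 15% of them are
censored (follow-up shorter than the horizon). Rows are sorted by
transplant date.

What passing tests on these cohorts do **not** show: robustness to
informative censoring, competing risks (death with functioning graft as a
separate hazard), realistic clinical marginals (HLA matching,
immunosuppressive regimens), covariate interactions, or
missing-not-at-random patterns. The generator makes no claim of clinical
realism; it provides known ground truth.

## Reproducibility and numerical choices

Every randomized stage derives its seed deterministically from the single
global seed (via spawned seed sequences), so a full run is reproducible
bit for bit from (input, configuration, seed); the manifest records a
configuration hash that ignores the output path. Ties in the gain ranking
are broken by stable sort; subset ties in the wrapper as described above.
Imputation of an all-missing column, splits of single-row tables,
single-class training labels, and probability queries on linear-output
networks are all rejected with typed errors rather than silently handled.

Problem sizes used by the test suite and the acceptance script — ten
seeds per stochastic check, 2000-patient cohorts for selection, 200-point
cluster problems for classifier sanity, 800-patient cohorts for the
bit-level reproducibility check — are the package's chosen study
conditions: large enough for the planted signal to be recoverable, small
enough that the whole suite runs in well under a minute per component.

## Known limitations

- The binary label conflates censored-functioning with survived; with
  heavy censoring the learned classifier overestimates survival.
- The optimizer's convergence relies on the restart schedule; on
  high-dimensional weight vectors (many selected features) training is
  the pipeline's noisiest stage, and held-out accuracy varies by a few
  points across seeds.
- The zero-threshold gain filter is non-selective for continuous
  covariates (see above); it exists for fidelity to the method family,
  not as a noise gate.
- Wrapper validation accuracy on an 80/20 split is a high-variance
  criterion at small n; no nested cross-validation is attempted.
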