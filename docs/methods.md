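# Methods

## Problem setting

`csdelm` targets small-sample, high-dimensional, imbalanced classification
problems of the kind found in gene-expression diagnostics, where the two
error directions are not equally costly: calling a diseased sample healthy
(a miss) is far more expensive than the reverse (a false alarm). Plain
accuracy-maximising classifiers trained on such data favour the majority
class and concentrate their errors exactly where they hurt most. The
package implements a three-stage remedy: a cheap randomized-network
ensemble, disagreement-based pruning of that ensemble, and decision rules
that minimise expected cost — optionally abstaining on unreliable samples.

## Model

### Extreme learning machine (ELM)

Each base learner is a single-hidden-layer feedforward network with `L`
hidden nodes. The hidden parameters — input weights `a_j` and biases
`b_j` — are drawn i.i.d. uniform on [-1, 1] (the convention of the ELM
literature; nothing else in the method depends on this choice) and never
updated. With activation `g` (sigmoid by default; tanh and ReLU are
available) the hidden output matrix on `n` samples is
`H[k, j] = g(a_j · x_k + b_j)`, and the only fitted parameters are the
output weights

    beta = H⁺ T,

the minimum-norm least-squares solution against the one-hot class target
matrix `T` (1 for the true class, 0 elsewhere), computed by SVD with the
default numerical rank tolerance and no ridge term. Prediction decodes
`H beta` by argmax, ties to the lowest class index. Features are
standardized to zero mean and unit variance using training-split
statistics before training: random-projection networks are scale
sensitive, and the standardization is part of the fitted model.

### Dissimilarity pruning (D-ELM)

`N` ELMs are trained with independent seeded random streams. On `M`
reference samples (the training set itself; a held-out reference set can
be supplied instead) the pairwise disagreement matrix is

    Div[i, j] = #{k : member i and member j predict different labels on sample k},

symmetric with zero diagonal and entries in [0, M], and each member's
total disagreement is the row sum `eta_i = Σ_j Div[i, j]`. With mean
member accuracy `p̄` on the reference samples:

* `0 < p̄ ≤ 0.5` — the crowd is mostly wrong; members with the *smallest*
  eta (those agreeing with the wrong crowd) are eliminated;
* `0.5 < p̄ < 1` — the crowd is mostly right; members with the *largest*
  eta are eliminated;
* `p̄ = 1` (or 0) — the rule is undefined; pruning is skipped with a
  warning. `p̄ = 1` occurs routinely when `n ≤ L`, where minimum-norm
  least squares interpolates the training targets.

Ties in eta eliminate the higher original index first; survivors keep
their original order. The number eliminated is a free parameter
(default `⌈N/4⌉`); only the *direction* of elimination is part of the
method. Survivors are reused as trained — refitting them with fresh
random hidden layers would invalidate the very disagreement structure
that selected them — though a `retrain_survivors` flag provides the
literal refit for comparison experiments.

The `K` survivors vote: `W(j)` counts votes for class `j` and
`P(j|tx) = W(j)/K`, an exact rational quantity that sums to 1.

### Cost-sensitive decision (CS-D-ELM)

With cost matrix `C(i, j)` — the cost of assigning class `i` to a
true-class-`j` sample, zero diagonal — the conditional risk of assigning
class `i` is `R(i|tx) = Σ_j P(j|tx) C(i, j)` and the decision is
`argmin_i R(i|tx)` (ties to the lowest class index). With uniform
off-diagonal costs this reduces exactly to the majority vote, so the
plain and cost-sensitive decisions differ only where costs are
asymmetric; the decision is also invariant to positive rescaling of `C`.

### Rejection option

The risk margin `f(tx) = min_{i≠s} R(i|tx) − R(s|tx) ≥ 0` (with `s` the
risk-minimising class) measures how decisively the costs separate the
candidate labels. Given a threshold `δ ≥ 0`: classify into `s` when
`f(tx) ≥ δ`, otherwise reject. A rejected sample of true class `j`
incurs the rejection cost `C(0, j)` instead of a misclassification cost.
Two compositions of margin test and rejection costs are plausible and
both are implemented:

* **margin rule** (default): reject iff `f(tx) < δ`; the rejection costs
  enter only the scoring. This is the rule the threshold-sweep
  calibration procedure presupposes.
* **three-action rule**: rejection is an extra action with risk
  `Σ_j P(j|tx) C(0, j)`, minimised jointly with the class risks (classes
  win ties against rejection).

The margin and per-class rejection costs generalise verbatim from two
classes to `m` classes and are applied unchanged to multiclass problems.
`δ` is data-dependent and is calibrated by sweeping a grid over held-out
data at fixed vote probabilities and taking the cost-minimising value
(lowest `δ` on ties). Rejection is monotone in `δ`: the rejected set can
only grow as the threshold rises, so the sweep is well behaved.

## Evaluation

Per-class accuracies (PC on the positive class, NC on the negative; the
`positive_class` argument fixes the mapping, defaulting to the first
class of the cost spec), their geometric mean (G-means, the standard
imbalanced-data summary; for `m` classes the `m`-th root of the product
over classes present in the truth), the mean realised cost, and the
rejection fraction. Rejected samples count against the per-class
accuracies by default (they are not correct classifications) while
contributing only `C(0, j)` to cost; a flag excludes them from the
accuracy denominators instead, since either convention is defensible.
The empirical rejection fraction is reported directly; no per-sample
rejection probability is modelled.

The repeated-experiment protocol draws seeded random train/test splits,
fits one ensemble per repeat, and evaluates all decision modes on the
*same* test-set vote probabilities, so mode comparisons are paired and
differences are attributable to the decision rule alone. When a `δ` grid
is supplied, `δ` is tuned per repeat on a tuning split carved from the
training portion (default 25%), never on the test set.

## Synthetic data generator

The generator emulates reduced gene-expression classification sets:
class-conditional Gaussian features in which a small informative block
carries the signal — adjacent class means separated by
`effect_size × noise_sd` on each informative feature, giving mutually
redundant signal features — and all remaining features are pure noise.
Class counts are exact (largest-remainder rounding of the proportions),
so imbalance is controlled, and generation is fully seeded. Six presets
reproduce the post-feature-selection shapes of common benchmarks
(62–334 samples, 8–7129 features, 2–3 imbalanced classes).

Defaults: `effect_size = 1.5`, `noise_sd = 1`, `n_informative = 2`. The
informative-block size was fixed so that a pruned voting ensemble at the
default settings lands in the accuracy regime these benchmarks are
reported to occupy (minority-class accuracy roughly 0.4–0.6, with
frequent expensive-class errors); larger blocks make the task nearly
separable, at which point cost-sensitivity has nothing to improve.

What the generator does **not** model: microarray-specific noise
(heteroscedasticity, batch effects, heavy tails), feature correlation
beyond the shared-shift redundancy of the informative block, and label
noise. Passing tests therefore demonstrate the decision-theoretic and
algorithmic properties of the pipeline under a controlled signal model,
not performance on any real expression dataset.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_members` (N) | 20 (50 in the repeated experiment) | ensemble size before pruning |
| `hidden_size` (L) | 50 | hidden nodes per ELM; no canonical value exists, treat as a config parameter |
| `n_eliminate` | ⌈N/4⌉ | members pruned; only the direction of pruning is intrinsic to the method |
| `activation` | sigmoid | hidden-node nonlinearity |
| cost matrix | — | study setting: false alarm 1, miss 5 |
| rejection costs | — | study setting: 0.2 per class |
| `delta` (δ) | tuned | rejection threshold, in risk units; calibrated by grid sweep on held-out data |
| `train_size` | 2n/3 | per-split training samples; clamped with a warning when infeasible |

## Numerical choices

* All randomness flows through seeded `numpy` generators; one base seed
  expands via `SeedSequence.spawn` into per-member, per-split and
  per-repeat streams, so adding repeats never perturbs earlier ones and
  every run is reproducible from its manifest.
* Tie-breaks are everywhere "lowest class index" (argmax/argmin order),
  and eta ties eliminate the higher member index first.
* `p̄ = 0.5` falls in the smallest-eta branch; `p̄ ∈ {0, 1}` skips
  pruning with a warning.
* Vote probabilities are counts over K — exact in binary64 — so the
  probability-sum invariant holds with equality.
* The probability-vector precondition is enforced to 1e-9; cost matrices
  must have a zero diagonal and nonnegative entries.

## Scaled problem sizes

The shipped repeated experiment uses n = 400 samples (300 train / 100
test, mirroring the 300-sample training protocol of the benchmark
setting), 50 features, 50-member ensembles and 30 repeats — sizes chosen
so the full comparison runs in seconds on one core while leaving the
paired cost ordering (plain vote > cost-sensitive > tuned rejection)
statistically unambiguous.

## Known limitations

* The Gaussian generator is a stand-in; no claim is made about real
  expression data.
* δ tuned on a small split is noisy; with only ~75 tuning samples the
  chosen δ varies considerably across repeats (the median over repeats is
  the stable summary).
* Rejection lowers realised cost but also G-means under the default
  convention (rejected samples count as errors in accuracy); the two
  metrics deliberately answer different questions.
* Multiclass rejection uses the two-smallest-risk margin; with many
  near-tied classes a different margin (e.g. risk gap to the mean) could
  be preferable but is not implemented.
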