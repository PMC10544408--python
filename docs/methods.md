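# Methods

## The estimation problem

High-throughput selection experiments sequence a library under two (or
more) conditions — typically pre- and post-selection. Each condition's
library is a probability distribution over sequences, p^A and p^B, and the
quantity of interest is the log density ratio log d(x) = log[p^B(x)/p^A(x)]:
the population log-enrichment (LE). Counting gives the classical plug-in
estimate (cLE); this package's central method, model-based enrichment
(MBE), estimates log d directly by training a probabilistic classifier to
predict a read's condition and converting its class probabilities through
Bayes' rule:

    d(x) ≈ [g(x) / (1 − g(x))] · (N^A / N^B),

where g(x) is the predicted probability that a read with sequence x came
from condition B and N^j are the per-condition read totals (the class
priors). The read-level logistic loss, rewritten over unique sequences, is
a count-weighted loss — sequences sequenced more often pull harder on the
fit — which is how MBE absorbs heteroscedastic sequencing noise without an
explicit weighting scheme. The weighted-regression baseline (wLER) instead
computes cLE labels first and fits them by least squares with weights
w_i = 1/(2σ_i²), σ_i² being the delta-method asymptotic variance of the
cLE estimate.

## Counting conventions

- Natural logarithms throughout.
- Pseudocount c (default 1) is added to every raw count; adjusted totals
  are recomputed as Ñ^j = N^j + c·M′ so frequencies stay normalized.
- The variance/weight formula is evaluated on the same adjusted counts, so
  zero-count sequences receive finite weights; the unadjusted behavior is
  available by passing `pseudocount=0` (which demands strictly positive
  counts). σ² = 0 can only occur when one sequence owns an entire library;
  it raises by default, with an opt-in weight cap.
- Sequence identity is exact string match after case normalization;
  synonymous codons are *not* collapsed at the counting level (translation
  happens before modeling, where fitness is defined on amino acids).

## Class imbalance and the prior term

With unequal depths the classifier would otherwise favor the deeper
condition, so each class's term in the loss can be rescaled by
max_j N^j / N^class ("class weighting", applied automatically when totals
differ by more than 1%, overridable). The prior-correction factor
N^A/N^B and class weighting are two views of the same imbalance: weighted
training makes the effective class priors equal, so the prior term is
applied only when the classifier was trained unweighted. (Applying both
double-counts the imbalance — the error is caught by the oracle test that
compares a converged saturated classifier against cLE on an imbalanced
table.) Predicted probabilities are clamped to [1e-7, 1 − 1e-7] before
ratios are taken; saturated outputs emit a warning.

Multi-round or multi-property experiments are modeled as extra classes of
one multi-class classifier; pairwise LEs come from class-probability
ratios, aggregates from sums of class probabilities, and multi-round
predictions average the per-round pairwise LEs against the reference
condition.

## Model grid and training recipe

Both heads (classification for MBE, regression for wLER) share one
architecture grid: linear models on independent-site (IS), neighbor, and
all-pairs one-hot features; fully-connected nets with two hidden layers of
100/200/500/1000 units on IS features; and fully-convolutional nets with
2/4/8/16 residual blocks (window 5, 100 filters), skip connections summed
into a global max pool, for variable-length input. The optimizer is the
AMSGrad variant of Adam at learning rate 1e-3 for exactly ten epochs, no
early stopping; Adam ε is 1e-7 for linear/fully-connected models and 1e-4
with global-norm gradient clipping at 1 for the CNNs. The neural stack is
implemented directly in numpy with hand-derived gradients (verified by
finite differences in the test suite).

Choices the recipe leaves open, fixed here and documented as this
package's own:

- **Residual/skip wiring.** Each conv block adds its ReLU-activated
  convolution back onto its input; the stem and every block output are
  *summed* into the global max pool.
- **Weight initialization.** Fan-in-scaled Gaussians (He gain ahead of
  ReLU), seeded from the model config.
- **Batching.** Default batch size 1024. Variable-length reads are
  bucketed by length, so no padding token ever reaches a convolution.
  The scaled-down benchmark presets use batch 128: under a fixed epoch
  count the optimizer *step* budget is what full-scale training actually
  provides, and the presets are ~200× smaller; the choice applies
  identically to both estimators.
- **Grouped training.** Models train on unique sequences with
  count-weighted losses — exactly equivalent to read-level training at the
  full-epoch gradient level — with per-batch losses normalized by the
  batch's total (weighted) read count so the learning rate behaves like
  read-level mean-loss minibatching. wLER weights are normalized to mean 1
  per output (scale only; the minimizer is unchanged).

A "saturated" model (one free parameter per unique sequence, realized as a
linear model on indicator features) is provided as the closed-form oracle:
converged, its classification head reproduces cLE exactly and its
regression head interpolates the labels.

## Simulator

Ground-truth fitness over amino-acid sequences of length L_a is a linear
function of one-hot features of position subsets: all singletons plus T
higher-order index sets, each of order round(N(3, 1/2)) clamped to
[2, L_a] with positions sampled without replacement; coefficients are
N(0, 2^{−|J|}) per component. The default T = 260·L_a/13 = 20·L_a. The T
draws are with replacement (duplicate index sets permitted; their
coefficients effectively sum) — switchable to distinct sampling. Dense
coefficient arrays are stored for orders ≤ 3; higher orders draw
coefficients lazily from a counter-based generator keyed by (term seed,
subsequence index), exactly reproducible without materializing 20^R-sized
arrays.

Selection and sequencing: p_pre ~ Dirichlet(c_1..c_M′) perturbs the
library's empirical distribution (modeling PCR-style distortion and
providing replicates); p_post ∝ exp(F)·p_pre, normalized (computed
max-shifted so large fitness cannot overflow) — hence
log(p_post/p_pre) − F is constant across sequences, the identity every
estimator is scored against; read counts are multinomial at the requested
depths; short reads clip to a contiguous window (default 100 codons,
i.e. 300 nt) at a uniformly random codon-aligned start; hybrid sets mix
full-length and windowed reads; substitution errors replace each
nucleotide independently at a configurable rate (default presets use
1e-3) with a uniformly random different base. Indel/long-read-specific
error models are out of scope.

Library constructions: **NNK insertion** (each codon uniform over the 32
NNK codons; sequences accumulated until the target unique count, with
multiplicities retained; translations containing stops rejected and
counted); **random mutagenesis** (each position of a translated reference
mutated independently at a per-site rate — default 0.01 — to a uniformly
random different residue; back-translated by a fixed codon table for read
emission; nucleotide-level mutation available); **recombination**
(equally sized contiguous blocks, remainder to leading blocks, crossovers
snapped to codon boundaries so stop-free parents give stop-free chimeras;
exhaustive or sampled construction). Real serotype panels are external
data; `random_parents` generates synthetic aligned parents in their place.

## Evaluation protocol

Cross-validation is three-fold at the level of unique (translated)
sequences; every read follows its source sequence's fold, so no read of a
held-out sequence — truncated or not — reaches training data. Accuracy is
Spearman correlation between predictions and ground truth, averaged over
folds; the generalized form restricts to the ⌈f·n⌉ sequences with highest
(or lowest) ground-truth value, ties broken by stable order, average
ranks. Selectivity experiments rank by predicted positive-minus-negative
LE, take the top ten per fold, and measure Euclidean distance in the
(positive, negative) fitness plane from the mean selected point to the
theoretical optimum (max positive, min negative). Significance: Williams'
t (Steiger's T2 form) for two dependent correlations sharing the truth
variable; McNemar's test (exact binomial below 25 discordant pairs,
continuity-corrected χ² above) on paired top-fraction hit indicators; a
paired t-test across datasets. Under very strong selection a training
fold can end up with zero reads in one condition (all of that condition's
mass on held-out sequences); such folds carry no training signal for any
estimator and are skipped for all of them.

## Scaled-down benchmark presets and what they show

The presets preserve each full-scale configuration's construction,
T-scaling, read mode and pre/post balance while shrinking absolute sizes
to minutes on one CPU: the 21-mer NNK insertion at 5×10⁴ unique sequences
and 5×10⁵ reads per condition, a 60-residue mutagenesis library, and a
78-residue / 9-parent / 8-block recombination library with a sparse
(0.2 reads per sequence) long-read depth — sparse enough that count-based
labels are mostly pseudocount noise, which is the regime where the
classifier's information sharing matters; at the literal full-scale
sparsity (0.02) a library this small would leave almost no post-selection
signal at all.

Known limitation, deliberately not papered over: keeping T at its
full-scale value while shrinking the library caps achievable held-out
accuracy. At T = 20·L_a the simulated fitness carries on the order of
10⁵–10⁶ independent coefficients; a 5×10⁴-sequence library identifies
only their low-order projections, so cross-validated Spearman plateaus
near 0.5 regardless of architecture or read depth (verified empirically
with 10× reads and 40× parameters). The benchmark suite therefore
demonstrates *relative* estimator behavior (MBE ≥ wLER in sparse-read
regimes, both beating raw cLE) rather than the absolute accuracy
attainable at full scale.

What the simulator does not emulate: PCR amplification bias beyond the
Dirichlet perturbation, position-dependent or indel sequencing errors,
codon-usage effects (fitness is purely amino-acid-level), and epistasis
distributions estimated from any particular protein family. Passing tests
show the estimators behave as designed under the generative model's
assumptions; they do not certify accuracy on real selection data.
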