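# Methods

## Problem setting

The pipeline targets case/control cohorts measured on copy-number arrays:
each sample is a vector of log2-ratio values over many probes (the
motivating design has 52,842 chromosome-21 probes over 236 cases and 290
controls), and the goal is (i) a ranking of probes by discriminative
value, (ii) an optimal probe subset with an honest cross-validated
estimate of class separability, and (iii) a handful of human-readable
threshold rules. No real cohort is bundled; all development and testing
run on synthetic data with planted ground truth.

## Monte Carlo feature selection

Relative importance aggregates, over `s·t` trees, the information gain of
every split on a feature, weighted by the tree's held-out weighted
accuracy (`wAcc^u`) and by the fraction of the tree's training samples
reaching the node (`(n_node/n_tree)^v`), with `u = v = 1` by default.

Protocol details that the method's description leaves open, fixed here:

* **Subset/tree counts.** Defaults `m = max(⌈0.05·M⌉, 10)`, `t = 5`, and
  `s` chosen so that the expected number of subsets containing any given
  feature, `s·m/M`, is 15. This follows the MCFS authors' published
  guidance ("s and t sufficiently large") while staying desk-scale: for
  M = 500 it gives m = 25, s = 300, i.e. 1,500 trees.
* **Train/test split per tree.** Stratified, train fraction 0.66. The
  stratification guarantees both classes appear in every held-out set, so
  `wAcc` is always defined.
* **Tree induction.** Greedy binary information-gain trees; thresholds at
  midpoints of adjacent sorted distinct values; `value ≤ threshold` goes
  left; ties in gain broken by lowest feature index then lowest
  threshold; stopping at purity, child size < 2, or zero best gain. With
  this stopping rule a tree cannot split on an *exactly* symmetric
  interaction (e.g. noise-free XOR, where every single split has zero
  gain); with real-valued data this situation has measure zero.
* **Ranking.** Total order: descending RI, ties by feature (probe) index.

The split search has two implementations — a vectorized numpy scan
(reference) and a numba-compiled loop used when numba is importable —
asserted equivalent in the test suite.

## Incremental feature selection

Stage 1 evaluates prefixes `k, 2k, …, n_max` (default `k = 10`); stage 2
evaluates every size inside a selected interval. The interval rule makes
reproducible what is otherwise a visual judgment: take the widest
contiguous run of stage-1 points with MCC within `delta` (default 0.05)
of the maximum, expand one step on each side exclusively, clip to
`[1, n_max]`. The optimum is the stage-2 argmax of MCC with ties broken
toward fewer features; the same cross-validation seed is reused at every
prefix size so curve points differ only in the features used.

**What the optimum size means.** When planted probes are individually
strong (several noise-sd's of mean shift), a small prefix already attains
the maximal MCC and the tie-break yields an optimum *smaller* than the
planted count; when probes are individually weak the argmax wanders over
a noisy plateau *above* it. The optimum is a parsimonious
sufficient subset, not an estimator of the number of informative probes —
the tests assert precision of the recovered subset (its members are
planted) rather than a size match.

## Classifiers

**Self-normalizing network.** Three SELU hidden layers of 200 units,
weights `N(0, 1/fan_in)`, biases 0, logistic output, cross-entropy loss.
The SELU parameters are the unique solution of
`E[selu(Z)] = 0, E[selu(Z)²] = 1` (Z standard normal), computed by
closed-form moments (normal CDF terms) plus 2-D root finding and verified
against direct quadrature; rounded they are λ = 1.0507, α = 1.6733.
Alpha dropout replaces dropped units by `−λα` and applies the affine
correction `a·x + b`, `a = (q + λ²α²·p·q)^{−1/2}`, `b = −a·p·(−λα)`
(p = rate, q = 1−p), preserving both moments in expectation.

Training details are not dictated by the method and are configuration:
SGD with momentum 0.9, learning rate 0.01, batch 32, 200 epochs, alpha
dropout 0.05, early stopping on a stratified 10% validation split
(patience 20, best weights restored). Inputs are standardized per feature
with training-fold statistics inside `fit` — the fixed point assumes
unit-variance inputs. All randomness flows from one `numpy` generator
seeded by the config, so fits are bit-reproducible.

**Random forest.** `B = 100` trees by default on bootstrap resamples of
the training-set size, with a fresh random subset of
`⌊log2(M)+1⌋` features at every node (the Weka-style defaults); score =
fraction of trees voting positive; a tied vote classifies negative. The
trees are the same information-gain trees as in MCFS with `min_leaf = 1`
and no depth cap.

## Evaluation

Stratified k-fold cross-validation (default k = 10), seeded. MCC is
computed on the fold-pooled confusion matrix (robust to degenerate
folds), with the zero-denominator convention MCC = 0; AUC on the pooled
scores via the rank/Mann-Whitney definition. Pooled-vs-averaged and
stratified-vs-plain are deliberate choices where the protocol description
is silent.

## Rule extraction

The top p% of the ranking (default p = 1) is discretized per feature by
the entropy-best binary cut, and the Johnson reducer greedily covers the
case/control discernibility pairs (ties by feature index). RIPPER then
operates on the *raw continuous* values of the reduct: grow/prune split
2:1 (stratified), FOIL information gain for growing, `(p−n)/(p+n)` for
pruning trailing conditions, a rule discarded when its prune-set
precision drops to 1/2, rule addition stopped when the total description
length (theory bits at half weight + binomial exception coding) exceeds
the best seen by 64 bits, two optimization passes with replacement
candidates, and a final DL-based simplification that deletes rules whose
removal lowers the total DL — this last step is what reliably returns a
default-only rule list on pure-noise labels. Rules for the minority class
(ties: the case class), default class for the rest; at most one `≤` and
one `≥` per feature per rule. Odds ratios use `(TP·TN)/(FP·FN)` with the
Haldane–Anscombe 0.5 correction (flagged) on zero cells, CI via
`exp(ln OR ± 1.96·SE)`, p from the two-sided z-test on `ln OR`.

## Synthetic data

`generate_dataset` emulates a single-chromosome aCGH cohort: mean-zero
Gaussian probe noise (sd 0.05 by default, matching the magnitude of
log2-ratio rule thresholds seen in such studies), AR(1) correlation 0.3
along probe order to mimic segmental CNVs, and a planted set of
informative probes whose case-class mean is shifted by ±effect_size
(default 0.1, within the realistic 0.02–0.2 band). Class sizes default to
236/290. `generate_rule_dataset` plants an explicit threshold conjunction
as the labeling rule (optional label-flip noise); `generate_xor_dataset`
plants a two-probe interaction with no marginal signal (defaults: 400
samples, 20 probes, ±0.3 effect, sd 0.1) to probe classifiers that model
interactions against axis-aligned ones. Everything derives from one
seeded generator: identical spec + seed ⇒ bitwise-identical data.

What the generator does **not** model: trisomy-wide baseline shifts, GC
and platform artifacts, heavy-tailed noise, probe-specific variances, and
linkage between informative probes. Passing tests therefore demonstrate
correctness of the algorithms under idealized noise, not performance on
real arrays.

## Problem sizes used in the automated checks

The test suite runs the full stack at deliberately desk-scale sizes — 
e.g. 500 probes × 526 samples for ranking-recovery checks (1,500 MCFS
trees per seed, 10 seeds), IFS scans to n_max = 40–50 with 10-fold CV,
and 10-seed repetitions for stochastic properties. These sizes are the
package's own regression conditions; the pipeline itself accepts
arbitrary `n_max`, forest sizes and epochs for full-scale studies.

## Known limitations

* Binary classification only is tested; the entropy/wAcc formulas admit
  more classes but no multi-class path is exercised.
* The MCFS permutation-based significance cutoff and interdependency
  graph of the original software are out of scope; the ranking plus a
  fixed prefix cut is the supported workflow.
* The RIPPER optimization pass implements replacement candidates judged
  by description length; the full revision-candidate machinery of the
  original is simplified.
* SNN training is plain SGD; no GPU, no hyperparameter search.
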