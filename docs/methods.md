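# Methods

This note documents the mathematical conventions implemented by the
package. Everything here is reproduced by the code in `src/drrbm/` and
exercised by the test suite.

## 1. Restricted Boltzmann machine core

A Bernoulli RBM over visible units `u ∈ {0,1}^m` and hidden units
`l ∈ {0,1}^n` has energy

```
E(u, l) = − aᵀu − bᵀl − uᵀW l
```

with weight matrix `W (m×n)` and biases `a`, `b`. The joint distribution
is `p(u, l) = exp(−E) / Z` with partition function
`Z = Σ_{u,l} exp(−E(u, l))`.

**Exact inference.** For machines with `m + n ≤ 20` the package computes
`Z`, joint probabilities, the free energy
`F(v) = −aᵀv − Σ_j softplus(b_j + (vᵀW)_j)` and the exact
log-likelihood by enumeration. These serve as oracles: the joint must sum
to one, and `Σ_u exp(−F(u)) = Z`.

**Conditionals.** Factorised logistic conditionals
`p(l_j = 1 | u) = σ(b_j + (uᵀW)_j)` and
`p(u_i = 1 | l) = σ(a_i + (W l)_i)`.

**Contrastive divergence (CD-k).** One update runs a k-step Gibbs chain
from each data row: binary hidden samples drive the chain; the sufficient
statistics use hidden *probabilities*, and the reconstructed visible
state is the visible *probability* vector. The parameter delta is the
batch mean of `⟨u lᵀ⟩_data − ⟨u lᵀ⟩_recon` (and the analogous bias
terms), scaled by the learning rate. Inputs must lie in `[0, 1]` and are
treated as Bernoulli means.

**Exact gradient.** For enumerable machines the true likelihood gradient
replaces the reconstruction term with the exact model expectation
(computed from the visible marginals). Substituting it for CD in the
training loop must increase the exact log-likelihood monotonically at a
small learning rate; the mean of many independent CD-10 chains must
align with it (cosine similarity > 0.9). Both properties are acceptance
tests.

## 2. Deep residual model (DRRBM / DRSVM / ADRSVM)

The classifier maps a feature vector `x ∈ R^d` (d = 100 after PCA)
through two residual blocks:

```
x₁ = x  + W₂ · ReLU(W₁ · LN(x))
x₂ = x₁ + W₄ · ReLU(W₃ · LN(x₁))
```

`W₁, W₃` are `d × d/2` and `W₂, W₄` are `d/2 × d`, giving the layer
widths 100 / 50 / 50 / 100. `LN` is per-sample layer normalisation over
the feature axis (population variance, ε = 1e−5) with learnable gain and
bias initialised to 1 and 0. With all weights zero a block is exactly
the identity.

**Attention gate (ADRSVM).** Each feature `i` of `x₂` carries an
embedding row `W_score[i, :]`; its score is
`s_i = v_scoreᵀ tanh(x₂ᵢ · W_score[i, :])`, `α = softmax(s)`, and the
gated output is `d · (α ⊙ x₂)`. Because `Σ α_i = 1`, uniform attention
(`W_score = 0`) multiplies every coordinate by exactly 1 — the gate
starts as the identity and cannot degrade the pretrained network at
initialisation.

**Heads.**
- *Softmax (DRRBM):* `p = softmax(x₂ᵀ W_head + b_head)`, cross-entropy
  loss.
- *One-vs-rest squared hinge (DRSVM / ADRSVM):* scores
  `o = x₂ᵀ W_head + b_head`, targets `t_j = +1` for the true class, −1
  otherwise, loss `C · Σ_j max(0, 1 − t_j o_j)²`.

Predictions are the 1-based argmax with ties broken toward the lowest
class index.

## 3. Pretraining and fine-tuning

**Greedy layer-wise RBM pretraining.** Block 1's `W₁` is the weight
matrix of a `d`-visible / `d/2`-hidden RBM fit by CD-1 on the
layer-normalised input data (clipped to `[0, 1]`, the Bernoulli-mean
convention); `W₂` comes from a `d/2`-visible / `d`-hidden RBM fit on the
first RBM's hidden activations. Block 2 repeats the scheme on block 1's
output. Head and attention-projection weights start at small Gaussian
values; attention scores start at zero (identity gate).

**Fine-tuning.** End-to-end gradient descent with Adam (β₁ = 0.9,
β₂ = 0.999, ε = 1e−8), learning rate 1e−3, batch size 100, 600 epochs
by default. All gradients (layer norm, attention, both heads) are
computed analytically and are verified against central finite
differences in the test suite.

**Margin regularisation.** The hinge objective is the usual SVM
trade-off `(λ/2) Σ‖W‖² + C · mean hinge`, with `λ` (`weight_decay`)
applied to the four block matrices and `W_head` only — biases,
layer-norm and attention parameters are exempt. The motivation is a
measured pathology of this architecture on PCA inputs: per-sample layer
normalisation over components with strongly heterogeneous scales lets
each row's leading components modulate the normalisation of all others,
which the over-parameterised network memorises (training accuracy 1.0
with depressed test accuracy). A sufficiently strong margin penalty
restores generalisation at the published learning rate and epoch budget.

**Selection of λ.** `DeepClassifier` holds out a fifth of the training
split (two folds of a seeded 10-fold partition), fits each value of the
half-decade grid {1e−3, 3e−3, 1e−2, 3e−2, 1e−1} once on the remainder
while recording held-out accuracy every 25 epochs, and scores each decay
by its best accuracy along the trajectory (the trajectory maximum is a
much less noisy score than any single epoch's value). The winning decay
— ties resolve toward the stronger penalty — is refitted on the full
training split at the configured epoch budget. Selection never touches
the test split.

## 4. Survey preprocessing

Order of operations (statistics always fitted on the training split
only):

1. **Sentinel recoding:** the label code −8 ("can't answer") becomes the
   neutral class 3.
2. **Imputation:** per-column rules — household counts → constant 1,
   income columns → observed column mean, everything else → 0. A column
   that is entirely missing under the mean rule is an error.
3. **Split:** seeded shuffle into train:test following the requested
   ratio (3:1 by default; 1,200 rows → 900/300), remainder to train.
4. **Min-max normalisation:** `(x − min)/(max − min)` per feature;
   constant features map to 0; test values outside the training range
   are clipped to `[0, 1]`.
5. **PCA:** centred, components ordered by decreasing explained
   variance, reduced to 100 components by default.
6. **Global rescale:** one affine map of all cells into `[0, 1]`, fitted
   on the training split's overall minimum and maximum. A second
   *per-component* min-max here would equalise the components' scales
   and destroy the variance ordering PCA provides (measured as a large
   accuracy loss); the single global map preserves relative scales while
   restoring the `[0, 1]` input contract the RBM pretraining expects.

## 5. Synthetic survey generator

Each draw uses one seeded PCG64 stream in a documented order: (1) a
`latent_dim × p` Gaussian mixing matrix, (2) class labels from
`class_probs`, (3) latent vectors from class-specific means plus
isotropic `noise_sd` noise, (4) feature noise at `0.5 · noise_sd`. Class
means are equally spaced along latent axis 0 with spacing
`class_separation`, giving ordinal structure.

Raw features are squashed onto survey archetypes cycling through the
columns: binary {1, 2}, ordinal 1–5, ordinal 1–7, and positive
continuous incomes `exp(1 + 0.25 g) · 10⁴`. The ordinal codes come from
monotone quantile binning, so class-conditional ordering along the
latent projection survives the squash; with
`class_separation ≥ 4 · noise_sd` a plain linear classifier reaches
≥ 0.9 held-out accuracy (the generator's separability oracle).

Missingness is MCAR at `missing_rate` per feature cell; labels are
replaced by the −8 sentinel at `sentinel_rate` (default 0.02). Sentinels
appear only in the label column.

## 6. Evaluation protocol

- **Metrics:** accuracy, macro precision, macro F1 (per-class 0/0
  defined as 0), with the full confusion matrix.
- **Ratio experiment:** rows are shuffled into four equal subsets; the
  last is a fixed test set and the first 1 / 2 / 3 subsets are the
  training sets for ratios 1:1, 2:1, 3:1, with per-cell metrics and row
  averages.
- **Significance:** pairwise two-tailed paired t-tests over per-fold
  metric vectors from a common seeded 10-fold cross-validation of the
  training portion, `t = d̄ / (s_d/√n)` with `n−1` degrees of freedom.
  Degenerate cases: all-zero differences → (0, 1); constant non-zero
  differences → (±∞, 0).
- **Report:** three plain-text tables (methods × metrics, methods ×
  ratios with averages, pairwise p-value grid) with the best value per
  column marked by `**`.

## 7. Reproducibility

Every stochastic component takes an explicit seed (NumPy `default_rng`,
PCG64); equal seeds give bit-identical tables, models and reports. Model
serialisation is JSON with full float round-tripping: two saves of the
same model are byte-identical, and a loaded model reproduces the
original's predictions exactly.
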