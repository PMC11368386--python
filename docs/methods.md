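# Methods

## Overview

`scdiffuse` generates single-cell gene expression profiles with a latent
diffusion model. Three trainable parts cooperate:

1. an **autoencoder** mapping log-normalized expression (cells x genes) to a
   128-dimensional latent code and back;
2. a **denoising diffusion model** (DDPM) over the latent codes, with a
   skip-connected MLP noise predictor;
3. optional **guidance classifiers** over noisy latent codes whose
   log-probability gradients steer the reverse chain toward a condition,
   toward a combination of conditions (one classifier per factor, gradients
   summed), or toward a blend of two conditions (gradient interpolation).

Everything runs on synthetic negative-binomial fixtures with known ground
truth, so each stage is testable without external datasets.

## Preprocessing

Raw counts are filtered (cells with fewer than 10 total counts, then genes
detected in fewer than 3 cells, single pass in that order), scaled per cell
to 10,000 total counts, and transformed with natural `log1p`. Splits are
80/20 train/test, stratified on the first label column.

## Diffusion model

The forward process corrupts a latent code over `T` steps with
`q(x_i | x_(i-1)) = N(sqrt(1-beta_i) x_(i-1), beta_i I)`; the per-step rate
is linear from `beta_min/T` to `beta_max/T` with defaults
`beta_min = 0.1`, `beta_max = 20` (so with `T = 1000`, `beta` spans
`1e-4 ... 0.02`, the standard variance-preserving convention). `T` defaults
to 1000; the reduced "desk-scale" profile uses `T = 200`.

The denoiser predicts the injected noise from `(x_i, i)`: input projection
to width 512, three hidden blocks with a long skip connection
(concatenation of the first block's output into the last block's input),
SiLU activations, and a sinusoidal timestep embedding passed through a
two-layer projection and added to the input projection. The objective is
the simple epsilon-prediction MSE with steps drawn uniformly from `1..T`.

Latent codes are standardized per dimension before diffusion (statistics
stored with the model and inverted on output) so the chain's terminal
distribution matches the standard normal it starts from.

**Reverse variance.** The reverse transition adds Gaussian noise with one
of four selectable variances: plain `beta_i` (default), the exact
forward-posterior variance
`beta_tilde_i = (1-abar_(i-1))/(1-abar_i) * beta_i`,
`exp(w)*beta_i`, or `exp(w*beta_i)`. The literature on this
model family prints the variance as `exp(w*beta_i)` with `w = 0.5`, which
is ambiguous as written: read literally it is ~1 per step and swamps the
signal. We measured the readings at desk scale: `exp(w)*beta_i` inflated
the sampled latent spread roughly threefold (each late step injects more
noise than the trained denoiser can remove, driving the chain
off-manifold), while the posterior variance under-dispersed the samples
by a similar mechanism in reverse (an imperfect noise predictor plus
vanishing late-chain noise over-contracts toward mode centers). Plain
`beta_i` reproduced the real latent spread most closely and is the
default; `w` only affects the two exponential readings.

## Autoencoder

Symmetric MLPs (hidden widths [512, 256] by default, SiLU) with a 128-D
bottleneck, trained with Adam on reconstruction MSE. Two numerical
choices matter:

- **Output nonlinearity.** The decoder trains through a leaky ReLU
  (slope 0.05) and `decode` clamps at zero. A softplus output can never
  produce the exact zeros that dominate log-normalized counts, and a hard
  ReLU at the output layer suffers dead units (entire genes collapse to
  zero and never recover because the gradient is zero there); the leaky
  slope keeps gradients informative while the clamp restores exact zeros.
- **Latent-noise training.** During training each latent code is
  perturbed by 10% of the batch's per-dimension latent spread before
  decoding. Diffusion-sampled codes always land slightly off the encoded
  manifold; this augmentation keeps the decoder well-behaved there.

Finetuning on a new gene set reuses every trained layer except the
encoder's first and the decoder's last, which are re-initialized at the
new width; the whole model then trains on the new data. Gene matching
between datasets is exact string equality.

## From decoded profiles to realistic cells

Real log-normalized counts live on a discrete grid: a gene's value is
`log1p(1e4 * k / L)` for integer count `k` and library size `L`, so the
open interval between 0 and the smallest representable positive value is
empty in real data. Any continuous decoder output occupies that gap and a
depth-5 random forest separates it from real data with AUC near 1
regardless of how well the distribution is modeled — at fixture scale
(hundreds of counts per cell) the gap is wide. Two post-hoc steps, both
fitted on training data only and applied identically to every generated
cell regardless of condition, close the gap:

1. **Quantile calibration.** A per-gene monotone map from the generator's
   output distribution to the real training distribution, fitted once at
   training time by matching sorted decoded values of an *unconditional*
   latent sample to sorted training values. This corrects the systematic
   marginal bias of the decoder and sampler (bimodal genes shrink toward
   intermediate values) and restores exact zeros at the right per-gene
   rates; being monotone per gene it does not alter the joint structure
   the diffusion model produced. The construction mirrors the
   empirical-marginal half of copula-based expression simulators.
2. **Count rendering.** Each generated cell receives a library size
   resampled from the real training totals; calibrated values are
   inverted to rates, rounded to integer counts (deterministic given the
   drawn library; a Poisson option exists), and log-normalized again. The
   generated matrix then lives on exactly the real value manifold.

## Guidance

A four-layer MLP classifier (hidden widths [256, 128, 64], softmax head)
takes `(x_i, i)` with a 32-D sinusoidal step embedding concatenated to the
latent code. Training examples are codes corrupted to a step drawn
uniformly from `{0, 1, ..., floor(T/2)}` (clean codes included); beyond
`T/2` the signal is too degraded to classify, so at inference the guidance
gradient is exactly zero above that ceiling. Minibatches are drawn
uniformly over cells, so the network estimates the true conditional
`p(y | x_i)` including the class prior — the quantity the guidance term
uses; a class-balanced option exists but estimates a prior-shifted
conditional and empirically weakens guidance toward rare classes.
Gradients w.r.t. the input are obtained by backpropagation; classifier
parameters are never updated at inference.

Each reverse step adds `beta_i * gamma * grad log p(y | x_i)` to the
posterior mean (default `gamma = 2`). Multiple classifiers contribute a
weighted sum, enabling condition combinations absent from training.

**Ensemble guidance.** Guidance with a single classifier suffers
adversarial drift: the chain crosses the classifier's decision boundary
(log-probability saturates, the gradient vanishes) and stalls midway
between modes, so the classifier is satisfied while the decoded cell is
not of the target type — the dominant failure mode when steering toward a
rare class. The workflows therefore guide with an ensemble of
independently seeded classifiers (default 5) whose gradients are summed,
each with its own weight `gamma = 2` — the same summation used for
multi-condition control. Idiosyncratic boundary artifacts cancel across
members, and samples are driven to the region all members agree on, which
coincides with the target manifold.

Gradient interpolation replaces the single gradient with
`gamma1 * grad log p(y1) + gamma2 * grad log p(y2)` and starts the chain
from real cells of the initial condition noised to step `t`
(default `t = 600` of `T = 1000`, i.e. `0.6 T`; desk scale uses 120 of
200), preserving their broad characteristics.

## Evaluation metrics

- **SCC**: Spearman correlation between per-gene mean lognorm profiles —
  the only per-gene reading well-defined for unpaired cell sets.
- **MMD**: unbiased squared maximum mean discrepancy, RBF kernel with the
  median-distance bandwidth, computed on the top 50 joint PCs by default
  (gene space selectable). The unbiased estimator may be slightly
  negative for matched samples.
- **LISI**: per-cell inverse Simpson index of the real/generated label
  among the 90 nearest neighbors in joint PCA space, averaged and
  rescaled from [1, 2] to [0, 1].
- **Discriminator AUC**: random forest (1000 trees, depth 5, 0.75/0.25
  split) or KNN (k = 5, 0.7/0.3 split) trained to separate real from
  generated; 0.5 means indistinguishable.
- **QQ points**: matched empirical quantiles at evenly spaced
  probabilities for one gene in one cell type.
- **Conditional purity**: the fraction of generated cells that a
  multinomial-logistic oracle — trained only on real cells — assigns to
  the requested label. This stands in for an external cell-type annotation
  tool, which keeps the check self-contained.

All metric configurations (bandwidths, k, splits, seeds) are recorded in
the evaluation report.

## Synthetic fixtures

Counts are gamma-Poisson (negative binomial, dispersion 2 shared across
genes) around per-condition log-means: a baseline drawn log-uniform on
[0.1, 10] plus condition effects of +/- the stated log-fold-change (2.0 by
default) on disjoint gene blocks (10% of genes per condition), with a
lognormal(0, 0.35) per-cell library factor. Designs: a three-type mixture
with proportions (0.5, 0.475, 0.025) — the last type deliberately rare; a
2x2 type-by-organ layout with additive log-effects and one combination
held out of training but generated separately as ground truth; and a
trajectory whose per-timepoint log-means interpolate linearly between two
programs with mixing weight `s = j/(n_timepoints - 1)`.

What the fixtures do **not** emulate: gene-gene correlation beyond the
block structure, per-gene dispersion variation, zero inflation beyond
NB sampling, batch effects, or doublets. Passing tests show the pipeline
recovers NB mixture structure at these depths, not that it matches the
full complexity of real tissue atlases.

## Problem sizes and numerical choices

Experiments in the tests and the reproduction script run at desk scale:
2000 cells x 200 genes (three-type fixture), T = 200, autoencoder hidden
widths [1024, 512] trained ~200 epochs, denoiser trained 5000-6000 Adam
steps (batch 128, learning rate 1e-3 with step decay to 0.3x and 0.1x at
60% and 85% of training), classifier ensembles of 5 members at 1500-2500
steps each. Smaller designs (1200 x 150) with lighter budgets are used for
the two-factor and trajectory studies. Full-size defaults (T = 1000)
remain the package defaults for real use.

Degenerate inputs are rejected loudly rather than silently repaired:
zero-total cells at normalization, single-class classifier training,
zero-variance inputs to MMD, out-of-range step indices everywhere.
Reverse-chain randomness is suppressed at the final step (z = 0 at i = 1).
One named rng stream is used for training and another for sampling; all
are seedable.

## Known limitations

- The autoencoder deliberately overfits its training cells (that is what
  makes decoded samples sharp); reconstructions of *unseen* cells are
  noticeably blurrier. The generator is therefore a density model of the
  training population, as in the original latent-diffusion setting.
- Guidance toward very rare classes inherits the classifier's uncertainty
  at high noise levels; purity degrades gracefully rather than failing
  loudly.
- No DDIM/accelerated sampling, no learned reverse variance, no EMA of
  weights.
- LISI here uses a joint-PCA KNN graph, not an integration method's graph;
  absolute values are comparable only within this package.
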