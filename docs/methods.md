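# Methods

This note records the statistical model, the choices made where the design
was genuinely open, and what the synthetic data does and does not emulate.

## Signal model and normalization

A nanopore read is a pico-ampere time series sampled at roughly 3 kHz.
Segmentation (f5c/nanopolish `eventalign`) assigns each basecalled k-mer a
contiguous range of raw samples; everything outside those ranges —
ligated-aptamer prefix, skipped samples — is the non-basecalled signal
X_r. `poresip` consumes the eventalign TSV dialect but ignores its
pre-scaled event levels: normalization is recomputed from raw samples as

    R̂_r = (R_r − med(R_r)) / mad(R_r),    X̂_r = (X_r − med(R_r)) / mad(R_r),

one location/scale pair per read. Median/MAD rather than mean/sd keeps
the normalization insensitive to current spikes, and the affine
equivariance of this map is exactly what removes per-read gain and offset
drift (verified as a property test). The MAD consistency constant
defaults to 1.0 — the plain median absolute deviation — with the
Gaussian-consistent 1.4826 available by configuration; the choice rescales
all features uniformly and is absorbed by the regression coefficients.
A read whose MAD falls below `zero_scale_epsilon` (default 1e−8, which no
real pA vector reaches) has its scale clamped so degenerate synthetic
inputs cannot produce infinities.

## Per-read k-mer statistics

For each read and each of the 4ᵏ k-mers, all normalized samples of all
occurrences of that k-mer in the read are pooled; the pool's median is the
signal-median feature m, its MAD the signal-MAD feature, and the median of
per-occurrence dwell counts the dwell feature. Pooling raw samples (rather
than reducing each occurrence to its median first) is the simpler
estimator; the per-occurrence alternative is available via the `pooling`
switch. K-mers absent from a read are recorded in an explicit presence
mask — never as zeros, since zero is a meaningful value after centering.
K-mer strings come from the `model_kmer` column (the strand that actually
occupied the pore); `reference_kmer` is selectable.

Signal MAD and dwell medians are strictly positive and right-skewed, so
both are Box-Cox transformed. The exponent maximizes the profile
log-likelihood

    L(λ) = (λ−1) Σ log y_i − (N/2) log( Σ (b(λ) − b̄(λ))² / N ),

by bounded scalar search on [−2, 2] to 1e−4. The deviation term is the
*squared* (variance) form — the canonical Box-Cox profile likelihood; an
unsquared sum can be negative inside the logarithm and is dimensionally
inconsistent. Separate λs are fitted for the MAD and dwell families
(a shared-λ mode exists); both are estimated on training folds only and
then frozen for prediction.

## The classifier

Read class follows a Bernoulli GLM with logit link over the centered,
standardized feature blocks; missing entries are imputed with the training
mean (zero after centering), and the same stored centering is applied to
test reads. Priors are independent Normal(0, 1) on all coefficient
vectors and Normal(0, 2) on the intercept — weakly informative for
standardized features, and configurable. The dwell (δ) and
non-basecalled (ν) blocks are feature switches on the identical code path,
so the simplified median+MAD model is literally the full model with two
blocks disabled.

Two inference backends share the analytic log-joint gradient
X'(y − p) − θ/s²:

* **Mean-field VI with adagrad** (default): the variational family is
  N(μ, diag σ²); ELBO gradients are estimated from two reparameterized
  draws per step (the entropy contributes +1 to the log-σ gradient
  exactly), with adagrad updates at learning rate 0.1 for 10,000
  iterations. These defaults were chosen by benchmarking against NUTS and
  the MAP on k=1 problems: plain adagrad at learning rate 0.01 still sits
  far from the mode after tens of thousands of iterations, whereas 0.1
  reproduces NUTS posterior means and standard deviations within a few
  percent by ~3,000 iterations. Posterior "samples" are draws from the
  fitted Gaussian. Mean-field VI slightly understates marginal variances,
  as it always does under correlated designs.
* **NUTS**: the No-U-Turn sampler with slice-based tree doubling, unit
  mass matrix, and dual-averaging step-size adaptation (target acceptance
  0.8, default 500 warmup iterations). Used where posterior calibration
  matters more than speed.

Both backends are fully driven by one integer seed; identical
configuration and data give bit-identical posterior arrays.

A read's probability is the mean of logit⁻¹(linear predictor) over
posterior draws (1000 by default). A probability of exactly 0.5 assigns
class 0 and counts as incorrect for either true class, so ties never
inflate accuracy.

## Evaluation protocol

Cross-validation repeats a random five-fold partition three times (15
splits). Per split, the training portion is class-balanced by subsampling
the larger class, then filtered to reads containing every possible k-mer;
Box-Cox λs and feature centering are fitted on that training portion only.
Test folds are never balanced or filtered — reads missing k-mers are
predicted through mean imputation. F1 and MCC use their standard
confusion-count forms and return an undefined flag (None) on degenerate
tables rather than an arbitrary 0. The FDR curve evaluates 101 cutoffs
(step 0.005) on [0, 0.5]; an empty classified set yields an undefined FDR,
not 0, so vacuous cutoffs cannot "pass" a target. `cutoff_for_fdr`
returns the largest cutoff whose empirical FDR meets the target, i.e. the
loosest threshold that still controls the error.

## Synthetic data

The generator produces what the classifier assumes and nothing more: each
k-mer has a baseline level drawn N(0, 1) in normalized units (a real pore
model table can be supplied); reads draw a log-normal length, a log-normal
gain and Normal offset, a non-basecalled aptamer prefix at a distinct
current level, and per-event geometric-tailed dwells (mean 7 samples,
≈3 kHz at 450 bases/s). In the labeled class a sparse `affected_fraction`
of k-mers (default 10%) shifts its median level by N(0, τ_m = 0.3) and
rescales its within-event spread by exp N(0, τ_s = 0.25) — mirroring the
two observed families of deuterium response (medians mostly shifted,
MADs mostly rescaled, with many k-mers untouched). Partial labeling
scales both effects deterministically by `labeling_fraction`; a
per-event Bernoulli incorporation switch exists but is off by default,
since no incorporation-site model is established. Default read length is
log-normal with mean 20,000 nt so that a realistic fraction of reads
contains all 1024 5-mers.

What the generator does **not** emulate: basecalling errors and
misalignment, event stays/skips kinetics, pore-state drift within a read,
sequence-composition bias, or any physical model of the isotope effect.
Passing tests therefore demonstrate that the pipeline recovers the
structure it models — not that real deuterated DNA is this easy; on real
data effect sizes, segmentation noise and class overlap are set by the
instrument, not by τ parameters.

A direct feature-level path (`generate_features_direct`) draws the per-read
statistic vectors from the implied class-conditional distributions,
skipping signal synthesis for fast model-level tests; its MAD and dwell
features are produced on the log scale (the λ = 0 Box-Cox member).

## Problem sizes and numerical choices

Tests and the acceptance script run the 3-mer model on 500 reads/class
(signal-level path, triplicate five-fold CV, VI at 3,000 iterations) and
2,000 reads/class (feature-level path) — sizes at which the synthetic
effects are comfortably detectable and a full run completes in minutes on
one CPU. The 5-mer model uses the same code path and scales linearly in
4ᵏ. Degenerate inputs are handled explicitly throughout: zero-MAD pools
are clamped to a positivity epsilon before Box-Cox; zero-variance design
columns get unit scale; empty non-basecalled signal leaves x undefined and
mean-imputed.

## Known limitations

* Mean-field VI underestimates posterior variance under the strongly
  collinear designs that arise when one latent direction (the class)
  drives many columns; coefficient HDIs from the VI backend are mildly
  anti-conservative. Use the NUTS backend when interval calibration
  matters.
* With sparse effects, rank correlations between fitted coefficients and
  injected effect vectors are ceiling-limited by the mass of exactly-zero
  truth entries (tied ranks).
* The k-mer completeness filter interacts with read length; short-read
  datasets at k = 5 retain few complete reads, exactly as in real runs.
* FAST5 input and the segmentation algorithm itself are out of scope; the
  package consumes eventalign output (or its own synthetic equivalent).
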