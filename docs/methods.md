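# Methods

## The problem

Multi-compartment biophysical models of the diffusion-MRI signal are
*degenerate* under conventional multi-shell acquisitions: many parameter
settings produce the same measurements, so voxelwise inversion either fails
outright or requires fixing a subset of parameters to assumed values, which
biases whatever is left free.  Yet in most studies the question is not "what
are the parameters" but "which parameter *changed*" between two conditions
(patients vs controls, lesion vs normal tissue, two time points).

`dmribench` answers that question without inverting the model.  Each
hypothesis is a *pattern of change*: a unit vector Δv̂ in the model's
free-parameter space (here, one pattern per parameter).  Given a baseline
summary measurement y and an observed change Δy, the posterior probability of
each pattern is computed from

  P(Δy | y, Δv̂, a) = N(Δy; a·μ_Δv̂(y), a²·Σ_Δv̂(y) + Σ_n)

where a = |Δv| is the (positive) amount of change, Σ_n is the measurement
noise covariance, and (μ_Δv̂(y), Σ_Δv̂(y)) describe the distribution of the
directional derivative of the measurements along Δv̂ *conditional on the
observed baseline* — the degeneracy of the model is carried by Σ_Δv̂, since
many underlying parameter settings (each with its own derivative) are
compatible with the same y.  The amount is marginalised against a log-normal
prior, the no-change hypothesis gets likelihood N(Δy; 0, Σ_n), and a uniform
prior over hypotheses yields posterior probabilities by Bayes' rule.

## Forward model

Three-compartment "standard model" of white matter, per-measurement signal

  S(b, g) = s_iso·exp(−b·d_iso) + s_in·A_in(b, g) + s_ex·A_ex(b, g)

* intra-axonal: sticks (zero radial diffusivity, axial diffusivity d_in_a)
  dispersed by a Watson distribution with mean axis μ and concentration
  κ = cot(π·ODI/2);
* extra-axonal: zeppelins sharing the same Watson orientation distribution,
  axial diffusivity d_ex_a and radial diffusivity τ·d_ex_a, τ ∈ [0, 1];
* free water: isotropic, diffusivity d_iso.

Units: b in ms/μm², diffusivities in μm²/ms.  The 8 free parameters are
(s_iso, s_in, s_ex, d_iso, d_in_a, d_ex_a, τ, ODI); the fibre axis μ is a
nuisance parameter removed by the rotation-invariant summaries.

Both spherical convolutions are zonal (the kernel exp(−β(gᵀn)²) and the
Watson density are axially symmetric), so by the Funk–Hecke theorem the
convolution reduces to a Legendre series in cos∠(g, μ) whose coefficients are
1-D Gauss–Legendre integrals (order 128, even degrees ≤ 60).  A dense
product-quadrature evaluation over the sphere
(`diffusion_model.quadrature_attenuation`) ships as an independent reference;
the two agree to ~1e−13, far inside the 1e−4 contract asserted in tests.
The Watson moments are computed with the overflow-safe factor
exp(κ(t²−1)), valid to κ ≈ 64, i.e. ODI ≥ 0.01; the prior clips ODI to
[0.01, 0.99] (affects ~0.2% of Beta(2,5) draws).

The *constrained* (NODDI-style) variant fixes d_iso = 3, d_in_a = d_ex_a =
1.7 μm²/ms and couples the tortuosity to the fraction of sticks in the
neurite compartment, τ = s_ex/(s_in+s_ex) (the mean-field hindrance rule
d_ex,r = d_ex,a·(1 − v_ic)).  This leaves 4 free parameters
(s_iso, s_in, s_ex, ODI) and is cleanly invertible from two-shell data — we
verified that noise-level fits scatter according to their Laplace standard
errors, whereas the reversed coupling s_in/(s_in+s_ex) makes the model
bimodal and non-invertible.

## Acquisition and summary measures

The default protocol mimics a large population study: shells at b = 1 and
2 ms/μm² with 50 quasi-uniform directions each (spherical Fibonacci set with
a seed-controlled random rotation per shell) plus 5 b=0 measurements — 105
in total.  Per shell, the signal is projected onto real orthonormal
even-degree spherical harmonics (least squares, l_max = 2 by default: with 50
directions the l=2 fit is well conditioned and higher degrees carry mostly
noise at these b-values).  The summary vector is

  [b0-mean, b1-mean, b1-l2, b2-mean, b2-l2]

where "mean" is the degree-0 invariant calibrated to the spherical mean
signal and "l2" is log(y₂ + ε) with y₂ = (1/5)·Σ_m C₂,m² and ε = 1e−12.  The
log transform gaussianises the anisotropy measure and sensitises it to small
changes; ε only matters for perfectly isotropic noise-free signals.  All
summaries are invariant to joint rotations of the gradient table and fibre
axis to < 1e−5 (tested over 100 random rotations).

Real or test data are normalised by the baseline b0-mean: mean-type
coordinates of both y and Δy are divided by it, baseline log coordinates are
shifted by −2·log(b0-mean), and changes in log coordinates pass through
(they are scale invariant).  Covariances transform accordingly.

## Change models (surrogate regressions)

For each pattern, 20,000 baselines are drawn from the sampling prior
(fractions renormalised to sum to 1; d_iso ~ N(3, 0.1), axial diffusivities
~ N(1.7, 0.3) truncated at 0, τ ~ U(0,1), ODI ~ Beta(2,5), s_iso a 50/50
mixture of a point mass at 0 and U(0,1) to represent pure tissue and partial
free-water voxels).  The directional derivative of the summary vector is a
central difference with relative step 1e−4 of the pattern's characteristic
scale; steps that would leave the valid ranges are halved per sample, and
samples sitting exactly on a range boundary — notably the prior's point mass
at s_iso = 0, half of all draws — fall back to the valid one-sided
difference rather than being discarded (first-order consistency is verified
by a Richardson-style step-halving test).

The derivative distribution is regressed on the baseline summaries:
quadratic design with cross terms for the mean, linear design for the
covariance, which is parameterised by the lower-triangular Cholesky factor
with log diagonal so that any regression output maps to an SPD matrix.
Weights maximise the Gaussian likelihood: ridge-regularised least squares
warm start (pooled residual covariance), joint BFGS with an analytic
gradient, then a short Nelder–Mead polish; the negative log likelihood is
non-increasing across stages by construction.

Three robustness choices matter and are deliberate design decisions:

* **Observed-baseline conditioning.**  Inference conditions on the *noisy*
  baseline summary.  Experiments therefore train on noisy, b0-normalised
  baseline summaries (derivative targets stay noise-free).  This is more than
  cosmetic: for the constrained model the noise-free summaries occupy a 4-D
  manifold inside the 5-D summary space, and a regression fitted only on the
  manifold is unidentified transverse to it — off-manifold test points
  produce runaway predictions.  Conditioning on the observable baseline fixes
  the geometry and raised constrained-model dispersion detection from ~55% to
  ~92%.  Training with `noise_sigma=0` remains available and is the library
  default for the builder functions.
* **Derivative trimming.**  The derivative of log(y₂ + ε) explodes for
  near-isotropic noise-free baselines (y₂ → ε).  Samples whose derivative
  lies more than 12 interquartile ranges from the per-coordinate median
  (<1% of draws) are dropped before fitting; otherwise these outliers inflate
  the fitted residual scale by two orders of magnitude.
* **Ridge + extrapolation guard.**  A small L2 penalty (1e−5 per sample, on
  standardised designs) suppresses the large mutually-cancelling weights that
  collinear summary coordinates (b1-l2 vs b2-l2) otherwise induce, and at
  predict time the covariance regression output is clipped to the range it
  spanned on its training data.

Trained pattern sets serialise to a single JSON archive with an integrity
checksum and the protocol hash; loading verifies both.

## Inference numerics

All density work is in log space.  The amount prior defaults to log-normal
with median 0.1 and log-scale 1.0, spanning several orders of magnitude.
The marginal likelihood is a trapezoid quadrature on a 128-point log-spaced
grid covering the prior's 1e−6 .. 1−1e−6 quantiles; the wide span is needed
because the likelihood tends to the finite no-change density as the amount
tends to zero, so a narrow lower truncation discards real mass (we verified
agreement with Monte-Carlo integration to within 3 standard errors over
random cases, and self-convergence under grid doubling to <0.1%).  The MAP
amount refines the grid argmax with a 65-point sub-grid plus bounded scalar
optimisation, so likelihoods much narrower than the grid spacing are still
located; the posterior-mean amount uses the same quadrature.  A flat
likelihood (amount not informed by the data) is flagged.  Exact ties between
hypotheses resolve to registration order (no-change first) — deterministic
by construction.

## Validation harness

Test pairs follow the two-condition design: a baseline drawn from the prior,
at most one parameter increased by effect size 0.1 (resampling baselines
whose perturbation would leave the valid range), Gaussian noise with
σ = 0.01 (SNR 100 relative to a unit b0 signal) added independently to both
signals.  The per-pair noise covariance Σ_n is the sample covariance of
summary differences over 100 noisy instance pairs of the baseline signal.

The direct-inversion baseline fits the constrained model to each signal by
bounded nonlinear least squares (multi-start), takes the Laplace covariance
σ²(JᵀJ)⁻¹ at the optimum, and labels the pair by the minimum
Bonferroni-corrected two-sided z-test p-value across the 4 parameters
(no-change if min p > 0.05).

Problem sizes are chosen to keep a complete run on one CPU within minutes
while leaving Monte-Carlo error well below the asserted margins: 20,000
training draws per pattern (the builder's default argument remains 100,000),
100 test pairs per class for the constrained comparison, 50 per class for
the 9-class full-model experiment, 40 pairs per class for amount recovery,
and a 50-voxel two-group study with 100 subjects per group.

## What the synthetic data do and do not emulate

The generator reproduces: the two-shell population-imaging acquisition,
additive Gaussian noise at SNR 100, prior-matched tissue heterogeneity, and
(for the two-group study) subject-level replicates with a known injected
increase in the extra-axonal signal fraction.  It does **not** emulate:
Rician noise, multiple fibre populations, exchange or non-Gaussian
diffusion, between-subject biological variability (group replicates differ
only by measurement noise), spatial structure, registration error, or
segmentation noise.  Passing tests therefore demonstrate the correctness and
calibration of the machinery under the stated model, not robustness of the
scientific conclusions to model misspecification on real cohorts.

## Known limitations

* Detection of diffusivity changes at b = 1, 2 ms/μm² is intrinsically poor:
  d_iso changes are mostly invisible (labelled no-change) and
  d_in_a/d_ex_a/τ changes confuse among themselves — a property of the
  acquisition, reproduced rather than solved here.
* Patterns are single-parameter and positive; multi-parameter hyperplane
  changes and signed patterns are out of scope (negated patterns can be
  registered manually).
* The surrogate is a global polynomial; strongly nonlinear derivative fields
  (ODI near its bounds) are captured only through the covariance inflation.
* MAP fitting of the constrained model uses flat box priors; the sampling
  prior is not injected into the MAP objective.
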