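# dmribench

Inversion-free Bayesian inference of **which microstructural parameter
changed** between two diffusion-MRI measurements, for degenerate biophysical
models that cannot be inverted voxel by voxel.

## Who this is for

Researchers comparing diffusion MRI between conditions — patient vs control
groups, lesion vs normal-appearing tissue, longitudinal time points — who
want statements like "the extra-axonal signal fraction increased" without
fixing model parameters to assumed values first.  The package implements the
full pipeline on the three-compartment *standard model* of white matter
(isotropic free water + Watson-dispersed sticks + Watson-dispersed
zeppelins; 8 free parameters) with a conventional two-shell acquisition, and
includes the classical alternative (a constrained, invertible NODDI-style
model fitted per voxel plus z-tests) as a baseline.

## The idea

A candidate explanation is a *pattern of change* Δv̂ — a unit vector in
parameter space, e.g. "only s_ex changes".  For a baseline summary
measurement y, an observed change Δy, and an amount of change a, the
likelihood of a pattern is

    P(Δy | y, Δv̂, a) = N(Δy; a·μ_Δv̂(y), a²·Σ_Δv̂(y) + Σₙ)

where (μ_Δv̂(y), Σ_Δv̂(y)) is the distribution of the *derivative* of the
measurements along Δv̂ given the baseline — its spread encodes exactly the
model degeneracy (all parameter settings compatible with y, each with its own
derivative).  These two functions are learned once, from pure simulation, by
maximum-likelihood regression (quadratic mean, linear Cholesky-parameterised
covariance) on prior draws.  At inference time the amount is marginalised
against a log-normal prior by 1-D quadrature, the no-change hypothesis gets
likelihood N(Δy; 0, Σₙ), and Bayes' rule with a uniform hypothesis prior
yields posterior probabilities per pattern — no model inversion anywhere.

Measurements are compressed to rotation-invariant per-shell summaries from a
spherical-harmonics decomposition: the spherical-mean signal (degree 0) and
the log degree-2 power per shell, plus the b0 mean — five numbers for the
default two-shell protocol.

## Worked example

Train change models for three candidate patterns, simulate a pair of noisy
measurements whose true difference is an s_ex increase of 0.1, and ask which
pattern explains it:

```python
import numpy as np
from dmribench import (AmountPrior, StandardModel, make_ukb_protocol,
                       posterior_over_models)
from dmribench.change_models import ChangePattern, train_pattern_set
from dmribench.diffusion_model import (add_noise, sample_prior, PriorSpec,
                                       STANDARD_PARAM_NAMES)
from dmribench.summary_measures import (estimate_noise_covariance,
                                        log_coordinate_mask,
                                        normalize_covariance, normalize_pair,
                                        summarize)

protocol = make_ukb_protocol(seed=1)          # 2 shells x 50 dirs + 5 b=0
model = StandardModel()

patterns = [ChangePattern.single(p, STANDARD_PARAM_NAMES)
            for p in ("s_in", "s_ex", "odi")]
models = train_pattern_set(model, protocol, patterns=patterns,
                           n=20_000, seed=0, noise_sigma=0.01)

rng = np.random.default_rng(42)
base = sample_prior(PriorSpec(), 1, seed=7)
mu_axis = base.pop("mu")[0]
changed = {k: v.copy() for k, v in base.items()}
changed["s_ex"] += 0.1
signal_a = add_noise(model.signals(base, protocol, mu=mu_axis), 0.01, rng)[0]
signal_b = add_noise(model.signals(changed, protocol, mu=mu_axis), 0.01,
                     rng)[0]

y_a = summarize(signal_a, protocol)
dy = summarize(signal_b, protocol) - y_a
sigma_n = estimate_noise_covariance(
    model.signals(base, protocol, mu=mu_axis)[0], protocol, sigma=0.01,
    seed=1)
log_mask = log_coordinate_mask(protocol)
y_n, dy_n = normalize_pair(y_a, dy, log_mask)
sigma_n = normalize_covariance(sigma_n, y_a[0], log_mask)

result = posterior_over_models(dy_n, y_n, models, sigma_n, AmountPrior())
for name, p in zip(result.model_names, result.probabilities):
    print(f"P({name:9s}| y, dy) = {p:.3f}")
print(f"MAP amount of s_ex change: {result.map_amounts['s_ex']:.3f}")
```

Output (≈1 minute, dominated by training):

```
P(no_change| y, dy) = 0.000
P(s_in     | y, dy) = 0.000
P(s_ex     | y, dy) = 1.000
P(odi      | y, dy) = 0.000
MAP amount of s_ex change: 0.099
```

The posterior puts all mass on the true pattern, and the maximum-a-posteriori
amount (0.099) recovers the injected change of 0.1.

## Command line

A thin `bench` CLI wraps the library:

```bash
bench simulate --n 100 --seed 1 -o data/         # synthetic 4-D NIfTI + bvals/bvecs
bench train --mode full --n 100000 --seed 1 -o models.json
bench summarise data/dwi.nii.gz --bvals data/bvals --bvecs data/bvecs \
      --mask data/mask.nii.gz -o summaries.nii.gz
bench infer --models models.json --baseline y.nii.gz --change dy.nii.gz \
      --noise-cov sigma_n.npz --mask mask.nii.gz -o out/
bench validate --mode constrained --n 100 --seed 1 -o report/
```

`bench validate` reproduces the simulation study: balanced test pairs with at
most one parameter changed (effect 0.1, SNR 100), classified both by the
inversion-free posterior and — for the constrained model — by per-voxel MAP
fits with Bonferroni-corrected z-tests; it writes column-normalised
percentage confusion matrices (CSV + figure).

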