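"""Posterior inference over patterns of change and the amount of change.

Given a baseline summary vector y, an observed change dy, a noise covariance
Sigma_n and a set of trained change models, the likelihood of a change of
amount a along pattern p is

    P(dy | y, p, a) = N(dy; a * mu_p(y), a^2 * Sigma_p(y) + Sigma_n)

The amount is marginalised against a log-normal prior by deterministic
trapezoid quadrature on a log-spaced grid, yielding a marginal likelihood per
pattern; together with the no-change model N(dy; 0, Sigma_n) and a uniform
model prior these give posterior probabilities over the candidate patterns.
The posterior over the amount for a given pattern is summarised by its MAP
(grid argmax refined by bounded local optimisation) and its expectation.  All
density work happens in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import lognorm

__all__ = [
    "AmountPrior",
    "PosteriorResult",
    "NO_CHANGE",
    "amount_grid",
    "gaussian_logpdf",
    "likelihood_at_amount",
    "log_likelihood_curve",
    "marginal_likelihood",
    "log_marginal_likelihood",
    "posterior_over_models",
    "infer_amount",
    "infer_voxelwise",
]

NO_CHANGE = "no_change"


@dataclass(frozen=True)
class AmountPrior:
    """Log-normal prior on the (positive) amount of parameter change.

    ``median`` is the prior median (the log-location is log(median)) and
    ``log_scale`` the standard deviation of log-amount.  The default spans
    several orders of magnitude around a typical effect of 0.1.
    """

    median: float = 0.1
    log_scale: float = 1.0

    def __post_init__(self):
        if self.median <= 0 or self.log_scale <= 0:
            raise ValueError("median and log_scale must be positive")

    def logpdf(self, amount):
        return lognorm.logpdf(amount, s=self.log_scale,
                              scale=self.median)

    def ppf(self, q):
        return lognorm.ppf(q, s=self.log_scale, scale=self.median)


def amount_grid(prior: AmountPrior, n: int = 128) -> np.ndarray:
    """Log-spaced quadrature grid spanning the prior's 1e-6..1-1e-6 quantiles.

    The wide span matters: as the amount tends to zero the likelihood tends to
    the (finite, often large) no-change density, so a narrowly truncated lower
    tail would discard real marginal-likelihood mass.
    """
    lo, hi = prior.ppf(1e-6), prior.ppf(1 - 1e-6)
    return np.geomspace(lo, hi, n)


def _trapezoid_logweights(x: np.ndarray) -> np.ndarray:
    w = np.empty_like(x)
    w[0] = (x[1] - x[0]) / 2
    w[-1] = (x[-1] - x[-2]) / 2
    w[1:-1] = (x[2:] - x[:-2]) / 2
    return np.log(w)


def gaussian_logpdf(x: np.ndarray, mean: np.ndarray,
                    cov: np.ndarray) -> np.ndarray:
    """Batched multivariate-normal log density via Cholesky.

    ``cov`` may carry leading batch dimensions matching ``mean``/``x``.
    """
    x = np.asarray(x, dtype=float)
    r = x - mean
    cov = 0.5 * (cov + np.swapaxes(np.asarray(cov, dtype=float), -1, -2))
    k = x.shape[-1]
    # escalating relative jitter: a grossly inflated covariance (e.g. a
    # surrogate extrapolating off its training support) can lose positive
    # definiteness to roundoff; its density is ~0 there, so regularising the
    # factorisation does not affect any posterior mass that matters
    scale = np.maximum(np.diagonal(cov, axis1=-2, axis2=-1).max(axis=-1), 1.0)
    for rel in (0.0, 1e-14, 1e-10, 1e-6):
        try:
            L = np.linalg.cholesky(
                cov + rel * scale[..., None, None] * np.eye(k))
            break
        except np.linalg.LinAlgError:
            continue
    else:
        raise np.linalg.LinAlgError("covariance is not positive definite")
    u = np.linalg.solve(L, r[..., None])[..., 0]
    logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=-2, axis2=-1)), axis=-1)
    return -0.5 * (k * np.log(2 * np.pi) + logdet + np.sum(u * u, axis=-1))


def log_likelihood_curve(dy, mu, sigma, sigma_n, amounts) -> np.ndarray:
    """log N(dy; a*mu, a^2*sigma + sigma_n) over an array of amounts."""
    amounts = np.atleast_1d(np.asarray(amounts, dtype=float))
    if np.any(amounts <= 0):
        raise ValueError("amounts must be positive")
    a = amounts[:, None, None]
    cov = a ** 2 * sigma[None] + sigma_n[None]
    mean = amounts[:, None] * mu[None]
    return gaussian_logpdf(np.asarray(dy, dtype=float)[None], mean, cov)


def likelihood_at_amount(dy, y, model, amount, sigma_n):
    """Density N(dy; a*mu(y), a^2*Sigma(y) + Sigma_n) at one or more amounts."""
    mu, sigma = model.predict(y)
    ll = log_likelihood_curve(dy, mu, sigma, np.asarray(sigma_n, float),
                              amount)
    out = np.exp(ll)
    return float(out[0]) if np.ndim(amount) == 0 else out


def log_marginal_likelihood(dy, y, model, sigma_n, prior: AmountPrior,
                            n_grid: int = 128) -> float:
    """log of Eq. integral: trapezoid quadrature of P(a) * P(dy|y,p,a)."""
    grid = amount_grid(prior, n_grid)
    log_int = (prior.logpdf(grid)
               + _log_curve_for(dy, y, model, sigma_n, grid)
               + _trapezoid_logweights(grid))
    out = float(logsumexp(log_int))
    if not np.isfinite(out):
        raise FloatingPointError("marginal-likelihood quadrature not finite")
    return out


def _log_curve_for(dy, y, model, sigma_n, grid):
    mu, sigma = model.predict(y)
    return log_likelihood_curve(dy, mu, sigma, np.asarray(sigma_n, float),
                                grid)


def marginal_likelihood(dy, y, model, sigma_n, prior: AmountPrior,
                        n_grid: int = 128) -> float:
    return float(np.exp(log_marginal_likelihood(dy, y, model, sigma_n, prior,
                                                n_grid)))


@dataclass
class PosteriorResult:
    """Posterior over {no-change} + patterns, with per-pattern amounts."""

    model_names: list
    probabilities: np.ndarray
    log_marginals: np.ndarray
    map_amounts: dict = field(default_factory=dict)
    expected_amounts: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    @property
    def winner(self) -> str:
        # deterministic tie-break: registration order (no-change first)
        return self.model_names[int(np.argmax(self.probabilities))]


def infer_amount(dy, y, model, sigma_n, prior: AmountPrior,
                 n_grid: int = 128):
    """MAP and posterior-mean amount of change for one pattern.

    The MAP is located on the quadrature grid and refined by bounded scalar
    optimisation between its neighbours; the expectation uses the same grid.
    Returns (map_amount, expected_amount, flat_flag).
    """
    grid = amount_grid(prior, n_grid)
    mu, sigma = model.predict(y)
    sn = np.asarray(sigma_n, float)
    log_like = log_likelihood_curve(dy, mu, sigma, sn, grid)
    log_post = prior.logpdf(grid) + log_like
    # flat likelihood: the amount is not informed by the data at all
    flat = bool(np.ptp(log_like) < 1e-6)
    i = int(np.argmax(log_post))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    map_amount = grid[i]
    best_val = log_post[i]
    if hi > lo and not flat:
        def neg(a):
            return -(prior.logpdf(a)
                     + log_likelihood_curve(dy, mu, sigma, sn, a)[0])

        # two-stage refinement: a fine sub-grid first, so that likelihoods
        # much narrower than the coarse grid spacing are not missed, then a
        # bounded scalar optimisation between the sub-grid neighbours
        sub = np.geomspace(lo, hi, 65)
        sub_val = prior.logpdf(sub) + log_likelihood_curve(dy, mu, sigma, sn,
                                                           sub)
        j = int(np.argmax(sub_val))
        if sub_val[j] > best_val:
            map_amount, best_val = float(sub[j]), float(sub_val[j])
        res = optimize.minimize_scalar(
            neg, bounds=(sub[max(j - 1, 0)], sub[min(j + 1, 64)]),
            method="bounded")
        if res.success and -res.fun >= best_val:
            map_amount = float(res.x)
    logw = _trapezoid_logweights(grid)
    log_norm = logsumexp(log_post + logw)
    expected = float(np.exp(logsumexp(log_post + logw + np.log(grid))
                            - log_norm))
    return float(map_amount), expected, flat


def posterior_over_models(dy, y, models, sigma_n, prior: AmountPrior,
                          n_grid: int = 128,
                          compute_amounts: bool = True) -> PosteriorResult:
    """Posterior probabilities over {no-change} + trained patterns.

    Uniform prior across models; the no-change likelihood is N(dy; 0,
    Sigma_n).  Probabilities are normalised in log space.
    """
    if len(models) == 0:
        raise ValueError("need at least one change model")
    dy = np.asarray(dy, dtype=float)
    sigma_n = np.asarray(sigma_n, dtype=float)
    names = [NO_CHANGE] + [m.pattern.name for m in models]
    logm = [gaussian_logpdf(dy, np.zeros_like(dy), sigma_n)]
    for m in models:
        logm.append(log_marginal_likelihood(dy, y, m, sigma_n, prior, n_grid))
    logm = np.asarray(logm, dtype=float)
    if not np.all(np.isfinite(logm)):
        raise FloatingPointError("non-finite log marginal likelihood")
    probs = np.exp(logm - logsumexp(logm))
    probs /= probs.sum()
    result = PosteriorResult(model_names=names, probabilities=probs,
                             log_marginals=logm)
    if compute_amounts:
        for m in models:
            a_map, a_exp, flat = infer_amount(dy, y, m, sigma_n, prior, n_grid)
            result.map_amounts[m.pattern.name] = a_map
            result.expected_amounts[m.pattern.name] = a_exp
            if flat:
                result.flags[m.pattern.name] = "flat_posterior"
    return result


def infer_voxelwise(y_map, dy_map, sigma_n_map, models, prior: AmountPrior,
                    mask=None, n_grid: int = 128) -> dict:
    """Independent per-voxel inference over a map of summary vectors.

    ``y_map`` and ``dy_map`` are (V, K); ``sigma_n_map`` is (V, K, K) or a
    single shared (K, K).  ``mask`` selects voxels (others yield NaN).
    Returns dict with 'model_names', 'probabilities' (V, n_models),
    'winner_index' (V,), 'map_amount' (V, n_patterns) and 'failures'.
    """
    y_map = np.asarray(y_map, dtype=float)
    dy_map = np.asarray(dy_map, dtype=float)
    v, k = y_map.shape
    sigma_n_map = np.asarray(sigma_n_map, dtype=float)
    if sigma_n_map.ndim == 2:
        sigma_n_map = np.broadcast_to(sigma_n_map, (v, k, k))
    if mask is None:
        mask = np.ones(v, dtype=bool)
    names = [NO_CHANGE] + [m.pattern.name for m in models]
    probs = np.full((v, len(names)), np.nan)
    winner = np.full(v, -1, dtype=int)
    map_amt = np.full((v, len(models)), np.nan)
    failures = {}
    for i in range(v):
        if not mask[i]:
            continue
        try:
            res = posterior_over_models(dy_map[i], y_map[i], models,
                                        sigma_n_map[i], prior, n_grid)
        except Exception as exc:  # per-voxel failures recorded, not fatal
            failures[i] = str(exc)
            continue
        probs[i] = res.probabilities
        winner[i] = int(np.argmax(res.probabilities))
        map_amt[i] = [res.map_amounts[m.pattern.name] for m in models]
    return {"model_names": names, "probabilities": probs,
            "winner_index": winner, "map_amount": map_amt,
            "failures": failures}
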