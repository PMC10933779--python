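"""Surrogate regression models for the derivative of the summary measures.

A *pattern of change* is a unit vector in the free-parameter space of the
forward model.  For each pattern we learn, from simulated data only, the
distribution of the directional derivative g of the summary vector y with
respect to that pattern, conditional on y itself:

    g | y  ~  N( F2(y) @ w_mu ,  T(F1(y) @ w_sigma) )

where F2 is a (default quadratic, with cross terms) polynomial design, F1 a
linear design, and T rebuilds a symmetric positive-definite covariance from
the regressed lower-triangular Cholesky factor whose diagonal is stored on a
log scale — any real regression output is a valid covariance.  Weights are
fitted by maximum likelihood: a least-squares warm start for the mean (with
the pooled residual covariance), joint BFGS refinement with an analytic
gradient, then a short Nelder–Mead polish.

Baselines are drawn from the sampling prior with signal fractions normalised
to sum to one, so the training baseline b0-mean is exactly 1; real data are
normalised to the same convention before prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .diffusion_model import (AcquisitionProtocol, StandardModel, as_rng)
from .summary_measures import summarize

__all__ = [
    "ChangePattern",
    "TrainingSet",
    "ChangeModel",
    "single_parameter_patterns",
    "directional_derivative",
    "build_training_set",
    "polynomial_design",
    "covariance_from_vector",
    "train_change_model",
    "predict_derivative_distribution",
    "train_pattern_set",
    "save_models",
    "load_models",
]


@dataclass(frozen=True)
class ChangePattern:
    """Unit direction in the model's free-parameter space."""

    name: str
    vector: np.ndarray
    param_names: tuple

    def __post_init__(self):
        v = np.asarray(self.vector, dtype=float).ravel()
        if v.shape[0] != len(self.param_names):
            raise ValueError("pattern vector length != number of parameters")
        nrm = np.linalg.norm(v)
        if not np.isclose(nrm, 1.0, atol=1e-8):
            raise ValueError("pattern vector must have unit norm")
        object.__setattr__(self, "vector", v)

    @classmethod
    def single(cls, param: str, param_names) -> "ChangePattern":
        param_names = tuple(param_names)
        v = np.zeros(len(param_names))
        v[param_names.index(param)] = 1.0
        return cls(name=param, vector=v, param_names=param_names)


def single_parameter_patterns(model: StandardModel) -> list:
    """One positive unit pattern per free parameter, in canonical order."""
    return [ChangePattern.single(p, model.param_names)
            for p in model.param_names]


@dataclass
class TrainingSet:
    """Paired noise-free summaries and directional derivatives."""

    y: np.ndarray          # (N, K) baseline summary vectors
    g: np.ndarray          # (N, K) derivative of summaries along the pattern
    pattern: ChangePattern
    protocol_hash: str = ""
    seed: int | None = None

    def __post_init__(self):
        if self.y.shape != self.g.shape:
            raise ValueError("y and g must have matching shapes")
        if not (np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.g))):
            raise ValueError("training pairs must be finite")


# --------------------------------------------------------------------------
# derivatives of the forward map
# --------------------------------------------------------------------------

def _perturbed(params: dict, pattern: ChangePattern, t) -> dict:
    out = dict(params)
    for name, comp in zip(pattern.param_names, pattern.vector):
        if comp != 0.0:
            out[name] = np.asarray(params[name], dtype=float) + t * comp
    return out


def _one_sided_steps(model, params, pattern, sign, t0, t_min, n):
    """Largest per-sample step <= t0 keeping v + sign*t valid; 0 if none."""
    t = np.full(n, t0)
    for _ in range(40):
        ok = model.is_valid(_perturbed(params, pattern, sign * t))
        if np.all(ok):
            break
        t = np.where(ok, t, t / 2.0)
        if np.all(t[~ok] < t_min):
            break
    t[~model.is_valid(_perturbed(params, pattern, sign * t))] = 0.0
    t[t < t_min] = 0.0
    return t


def directional_derivative(model: StandardModel, params: dict,
                           pattern: ChangePattern,
                           protocol: AcquisitionProtocol,
                           rel_step: float = 1e-4, l_max: int = 2):
    """Finite-difference derivative of the summary vector along a pattern.

    ``params`` maps parameter names to (N,) arrays (scalars are promoted).
    The step is ``rel_step`` times the pattern-weighted parameter scale,
    halved per sample where it would exit the valid ranges.  Interior samples
    use a central difference; samples on a range boundary (e.g. the prior's
    point mass at s_iso = 0) fall back to the valid one-sided difference.
    Samples with no valid step above 1e-8 of the scale are dropped.  Returns
    (y (N', K), g (N', K), kept-index array).
    """
    params = {k: np.atleast_1d(np.asarray(v, dtype=float))
              for k, v in params.items()}
    n = max(v.shape[0] for k, v in params.items() if k != "mu")
    for k, v in params.items():
        if k != "mu" and v.shape[0] != n:
            params[k] = np.broadcast_to(v, (n,)).copy()
    scales = model.scales()
    scale = float(np.linalg.norm(pattern.vector * scales))
    t0 = rel_step * scale
    t_min = 1e-8 * scale
    t_plus = _one_sided_steps(model, params, pattern, +1.0, t0, t_min, n)
    t_minus = _one_sided_steps(model, params, pattern, -1.0, t0, t_min, n)
    # central where both sides admit the same step; else one-sided
    both = (t_plus > 0) & (t_minus > 0)
    t_sym = np.minimum(t_plus, t_minus)
    t_plus = np.where(both, t_sym, t_plus)
    t_minus = np.where(both, t_sym, t_minus)
    keep = np.flatnonzero(t_plus + t_minus >= t_min)
    sub = {k: (v[keep] if k != "mu" else v) for k, v in params.items()}
    mu = params.get("mu")
    if mu is not None and np.asarray(mu).ndim == 2:
        sub["mu"] = np.asarray(mu)[keep]
    tp, tm = t_plus[keep], t_minus[keep]
    sig_plus = model.signals(_perturbed(sub, pattern, tp), protocol)
    sig_minus = model.signals(_perturbed(sub, pattern, -tm), protocol)
    y = summarize(model.signals(sub, protocol), protocol, l_max)
    g = (summarize(sig_plus, protocol, l_max)
         - summarize(sig_minus, protocol, l_max)) / (tp + tm)[:, None]
    return y, g, keep


def _conditioned_pairs(model, params, pattern, protocol, rel_step,
                       noise_sigma, rng, l_max=2):
    """(y, g) pairs with y observed the way inference will observe it.

    The derivative g is always computed from noise-free signals.  With
    ``noise_sigma > 0`` the baseline summary y is computed from a noisy
    realisation and the pair is b0-normalised exactly like test data, so the
    regression learns the derivative distribution conditional on the
    *observable* baseline rather than on the noise-free manifold (which for
    constrained models is lower-dimensional than the summary space).
    """
    y, g, keep = directional_derivative(model, params, pattern, protocol,
                                        rel_step=rel_step, l_max=l_max)
    if noise_sigma > 0:
        from .diffusion_model import add_noise
        from .summary_measures import log_coordinate_mask, summarize
        sub = {k: (np.atleast_1d(v)[keep] if k != "mu" else v)
               for k, v in params.items()}
        mu = params.get("mu")
        if mu is not None and np.ndim(mu) == 2:
            sub["mu"] = np.asarray(mu)[keep]
        signals = model.signals(sub, protocol)
        y_obs = summarize(add_noise(signals, noise_sigma, rng), protocol,
                          l_max)
        y, g = normalize_pair_training(y_obs, g,
                                       log_coordinate_mask(protocol))
    return y, g


def normalize_pair_training(y_obs, g, log_mask):
    from .summary_measures import normalize_pair
    return normalize_pair(y_obs, g, log_mask)


def build_training_set(model: StandardModel, pattern: ChangePattern,
                       protocol: AcquisitionProtocol, n: int = 100_000,
                       seed=None, rel_step: float = 1e-4,
                       noise_sigma: float = 0.0) -> TrainingSet:
    """Sample baselines from the prior and pair summaries with derivatives.

    Fractions are normalised to sum to one (baseline b0-mean = 1) and the
    fibre axis follows the prior's ``mu_mode``.  Derivatives are always
    noise-free; with ``noise_sigma > 0`` the baseline summaries are noisy,
    b0-normalised observations (matching the inference-time conditioning).
    """
    rng = as_rng(seed)
    params = model.sample_prior(n, rng)
    mu = params.pop("mu", None)
    if mu is not None and np.ndim(mu) == 2 and np.allclose(mu, mu[0]):
        mu = mu[0]
    params["mu"] = mu
    y, g = _conditioned_pairs(model, params, pattern, protocol, rel_step,
                              noise_sigma, rng)
    return TrainingSet(y=y, g=g, pattern=pattern,
                       protocol_hash=protocol.content_hash(),
                       seed=seed if isinstance(seed, int) else None)


# --------------------------------------------------------------------------
# designs and the Cholesky covariance map
# --------------------------------------------------------------------------

def polynomial_design(y: np.ndarray, degree: int) -> np.ndarray:
    """Polynomial design row(s) F(y): intercept, linear, and for degree 2 the
    full set of quadratic terms y_i*y_j (i <= j, cross terms included)."""
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n, k = y.shape
    cols = [np.ones((n, 1)), y]
    if degree == 2:
        iu, ju = np.triu_indices(k)
        cols.append(y[:, iu] * y[:, ju])
    return np.concatenate(cols, axis=1)


def n_design_columns(k: int, degree: int) -> int:
    return 1 + k + (k * (k + 1) // 2 if degree == 2 else 0)


def _tril_layout(d: int):
    rows, cols = np.tril_indices(d)
    diag = np.flatnonzero(rows == cols)
    return rows, cols, diag


def covariance_from_vector(theta: np.ndarray, d: int | None = None):
    """Rebuild SPD covariance(s) from packed Cholesky parameters.

    ``theta`` has shape (..., d(d+1)/2), laid out row-major over the lower
    triangle; diagonal entries are exponentiated.  Returns (..., d, d).
    """
    theta = np.asarray(theta, dtype=float)
    m = theta.shape[-1]
    if d is None:
        d = int(round((np.sqrt(8 * m + 1) - 1) / 2))
    if d * (d + 1) // 2 != m:
        raise ValueError("theta length must be d(d+1)/2")
    L = _chol_from_theta(theta, d)
    return L @ np.swapaxes(L, -1, -2)


def _chol_from_theta(theta: np.ndarray, d: int) -> np.ndarray:
    rows, cols, diag = _tril_layout(d)
    vals = theta.copy()
    vals[..., diag] = np.exp(np.clip(theta[..., diag], -40.0, 40.0))
    L = np.zeros(theta.shape[:-1] + (d, d))
    L[..., rows, cols] = vals
    return L


def _theta_from_cov(cov: np.ndarray) -> np.ndarray:
    d = cov.shape[-1]
    L = np.linalg.cholesky(cov)
    rows, cols, diag = _tril_layout(d)
    theta = L[..., rows, cols]
    theta[..., diag] = np.log(theta[..., diag])
    return theta


# --------------------------------------------------------------------------
# the trained model object
# --------------------------------------------------------------------------

@dataclass
class ChangeModel:
    """Per-pattern regression weights for the derivative distribution."""

    pattern: ChangePattern
    w_mu: np.ndarray               # (P2, K)
    w_sigma: np.ndarray            # (P1, K(K+1)/2)
    mean_degree: int = 2
    cov_degree: int = 1
    y_center: np.ndarray = None    # standardisation of y before the designs
    y_scale: np.ndarray = None
    theta_lo: np.ndarray = None    # training-range clip of the covariance
    theta_hi: np.ndarray = None    # regression (extrapolation guard)
    metadata: dict = field(default_factory=dict)

    @property
    def summary_dim(self) -> int:
        return self.w_mu.shape[1]

    def _standardize(self, y: np.ndarray) -> np.ndarray:
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if y.shape[1] != self.summary_dim:
            raise ValueError("summary vector has wrong dimension")
        return (y - self.y_center) / self.y_scale

    def predict(self, y: np.ndarray):
        """Return (mu (..., K), Sigma (..., K, K)) at baseline summaries y."""
        single = np.asarray(y).ndim == 1
        z = self._standardize(y)
        mu = polynomial_design(z, self.mean_degree) @ self.w_mu
        theta = polynomial_design(z, self.cov_degree) @ self.w_sigma
        if self.theta_lo is not None:
            theta = np.clip(theta, self.theta_lo, self.theta_hi)
        sigma = covariance_from_vector(theta, self.summary_dim)
        if single:
            return mu[0], sigma[0]
        return mu, sigma


def predict_derivative_distribution(model: ChangeModel, y: np.ndarray):
    """Functional alias for :meth:`ChangeModel.predict`."""
    return model.predict(y)


# --------------------------------------------------------------------------
# maximum-likelihood training
# --------------------------------------------------------------------------

def _nll_and_grad(w, F2, F1, g, d, diag_pos, ridge=0.0):
    """Penalised negative log likelihood and gradient, vectorised over samples.

    w packs w_mu (P2*d) then w_sigma (P1*m).  Constant 0.5*N*d*log(2*pi) terms
    are omitted.  ``ridge`` adds ridge*||w||^2 (excluding nothing): with
    standardised designs this suppresses the huge cancelling weights that
    collinear summary coordinates otherwise induce.
    """
    n, p2 = F2.shape
    p1 = F1.shape[1]
    m = d * (d + 1) // 2
    w_mu = w[: p2 * d].reshape(p2, d)
    w_sig = w[p2 * d:].reshape(p1, m)

    with np.errstate(over="ignore", invalid="ignore"):
        r = g - F2 @ w_mu                     # (N, d)
        theta = F1 @ w_sig                    # (N, m)
        L = _chol_from_theta(theta, d)        # (N, d, d)
        u = np.linalg.solve(L, r[..., None])[..., 0]          # L^-1 r
        sinv_r = np.linalg.solve(np.swapaxes(L, 1, 2), u[..., None])[..., 0]

        nll = np.sum(theta[:, diag_pos]) + 0.5 * np.sum(u * u)
        if not np.isfinite(nll):
            # line search wandered into overflow; report +inf, zero gradient
            return np.inf, np.zeros_like(w)

        grad_mu = -(F2.T @ sinv_r)            # (P2, d)

        # d(0.5 u'u)/dL = -(L^-T u) u^T restricted to the lower triangle
        linv_t_u = np.linalg.solve(np.swapaxes(L, 1, 2), u[..., None])[..., 0]
        rows, cols = np.tril_indices(d)
        dL = -(linv_t_u[:, rows] * u[:, cols])               # (N, m)
        dtheta = dL.copy()
        dtheta[:, diag_pos] *= L[:, rows[diag_pos], cols[diag_pos]]
        dtheta[:, diag_pos] += 1.0            # from the log-determinant term
        grad_sig = F1.T @ dtheta              # (P1, m)

        grad = np.concatenate([grad_mu.ravel(), grad_sig.ravel()])
    if not np.all(np.isfinite(grad)):
        return np.inf, np.zeros_like(w)
    if ridge > 0:
        nll = nll + ridge * float(w @ w)
        grad = grad + 2.0 * ridge * w
    return float(nll), grad


def train_change_model(samples: TrainingSet, mean_degree: int = 2,
                       cov_degree: int = 1, standardize: bool = True,
                       max_bfgs_iter: int = 400,
                       nelder_mead_fev: int = 200,
                       trim_iqr: float | None = 12.0,
                       ridge_per_sample: float = 1e-5) -> ChangeModel:
    """Fit the derivative-distribution weights by maximum likelihood.

    Stages: (1) ordinary least squares for the mean weights with the pooled
    residual covariance as a constant-covariance warm start; (2) joint BFGS on
    all weights with the analytic gradient; (3) a short Nelder–Mead polish.
    Each stage's result is kept only if it does not increase the negative log
    likelihood, so the NLL is non-increasing across stages.

    ``trim_iqr`` drops samples whose derivative lies more than that many
    interquartile ranges from the per-coordinate median before fitting.  The
    log-power summaries have unbounded derivatives for near-isotropic
    noise-free baselines, and the rare (<1%) extreme samples would otherwise
    dominate the Gaussian likelihood.

    ``ridge_per_sample`` scales an L2 weight penalty (total ridge = value * n)
    on the standardised designs.  Noise-free summaries of a constrained model
    live on a low-dimensional manifold with nearly collinear coordinates; the
    penalty prevents the regression from fitting huge mutually cancelling
    weights that explode once noisy measurements leave that manifold.
    """
    y, g = samples.y, samples.g
    if trim_iqr is not None:
        med = np.median(g, axis=0)
        iqr = np.maximum(np.subtract(*np.percentile(g, [75, 25], axis=0)),
                         1e-12)
        keep = np.all(np.abs(g - med) <= trim_iqr * iqr, axis=1)
        n_trimmed = int((~keep).sum())
        y, g = y[keep], g[keep]
    else:
        n_trimmed = 0
    n, d = y.shape
    m = d * (d + 1) // 2
    p2 = n_design_columns(d, mean_degree)
    p1 = n_design_columns(d, cov_degree)
    if n < 10 * (p2 * d + p1 * m):
        raise ValueError(
            f"need at least {10 * (p2 * d + p1 * m)} samples for "
            f"{p2 * d + p1 * m} weights; got {n}")

    if standardize:
        center = y.mean(axis=0)
        scale = y.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        center = np.zeros(d)
        scale = np.ones(d)
    z = (y - center) / scale
    F2 = polynomial_design(z, mean_degree)
    F1 = polynomial_design(z, cov_degree)
    _, _, diag_pos = _tril_layout(d)

    ridge = ridge_per_sample * n

    # stage 1: ridge-regularised OLS warm start, pooled residual covariance
    w_mu0 = np.linalg.solve(F2.T @ F2 + ridge * np.eye(p2), F2.T @ g)
    resid = g - F2 @ w_mu0
    pooled = np.atleast_2d(np.cov(resid, rowvar=False, ddof=0))
    pooled += 1e-12 * np.eye(d) * max(1.0, np.trace(pooled) / d)
    w_sig0 = np.zeros((p1, m))
    w_sig0[0] = _theta_from_cov(pooled)
    w0 = np.concatenate([w_mu0.ravel(), w_sig0.ravel()])

    args = (F2, F1, g, d, diag_pos, ridge)
    nll0, _ = _nll_and_grad(w0, *args)

    # stage 2: joint BFGS with analytic gradient
    res = optimize.minimize(_nll_and_grad, w0, args=args, jac=True,
                            method="BFGS",
                            options={"maxiter": max_bfgs_iter, "gtol": 1e-5})
    w_best, nll_best = (res.x, res.fun) if res.fun <= nll0 else (w0, nll0)

    # stage 3: short Nelder–Mead polish
    if nelder_mead_fev > 0:
        nm = optimize.minimize(lambda w: _nll_and_grad(w, *args)[0], w_best,
                               method="Nelder-Mead",
                               options={"maxfev": nelder_mead_fev,
                                        "xatol": 1e-8, "fatol": 1e-8})
        if nm.fun <= nll_best:
            w_best, nll_best = nm.x, nm.fun
    if not np.isfinite(nll_best):
        raise RuntimeError("change-model training failed to converge "
                           f"(nll={nll_best})")

    w_mu = w_best[: p2 * d].reshape(p2, d)
    w_sig = w_best[p2 * d:].reshape(p1, m)
    theta_train = F1 @ w_sig
    meta = {"n": int(n), "n_trimmed": n_trimmed, "seed": samples.seed,
            "protocol_hash": samples.protocol_hash,
            "nll_per_sample": nll_best / n,
            "stage_nll": [nll0 / n, float(res.fun) / n, nll_best / n]}
    return ChangeModel(pattern=samples.pattern, w_mu=w_mu, w_sigma=w_sig,
                       mean_degree=mean_degree, cov_degree=cov_degree,
                       y_center=center, y_scale=scale,
                       theta_lo=theta_train.min(axis=0),
                       theta_hi=theta_train.max(axis=0), metadata=meta)


def train_pattern_set(model: StandardModel, protocol: AcquisitionProtocol,
                      patterns=None, n: int = 100_000, seed: int = 0,
                      noise_sigma: float = 0.0, **train_kw) -> list:
    """Train one change model per pattern (default: one per free parameter).

    Baseline prior draws are shared across patterns; only the derivative
    evaluations differ.  ``noise_sigma`` is forwarded to the training-pair
    builder (noisy, b0-normalised baseline summaries).
    """
    if patterns is None:
        patterns = single_parameter_patterns(model)
    rng = as_rng(seed)
    params = model.sample_prior(n, rng)
    mu = params.pop("mu", None)
    if mu is not None and np.ndim(mu) == 2 and np.allclose(mu, mu[0]):
        mu = mu[0]
    params["mu"] = mu
    models = []
    for pattern in patterns:
        y, g = _conditioned_pairs(model, params, pattern, protocol, 1e-4,
                                  noise_sigma, rng)
        ts = TrainingSet(y=y, g=g, pattern=pattern,
                         protocol_hash=protocol.content_hash(), seed=seed)
        models.append(train_change_model(ts, **train_kw))
    return models


# --------------------------------------------------------------------------
# serialisation
# --------------------------------------------------------------------------

_FORMAT = "dmribench-change-models-v1"


def _model_payload(m: ChangeModel) -> dict:
    return {
        "pattern": {"name": m.pattern.name,
                    "vector": m.pattern.vector.tolist(),
                    "param_names": list(m.pattern.param_names)},
        "mean_degree": m.mean_degree,
        "cov_degree": m.cov_degree,
        "y_center": m.y_center.tolist(),
        "y_scale": m.y_scale.tolist(),
        "w_mu": m.w_mu.tolist(),
        "w_sigma": m.w_sigma.tolist(),
        "theta_lo": None if m.theta_lo is None else m.theta_lo.tolist(),
        "theta_hi": None if m.theta_hi is None else m.theta_hi.tolist(),
        "metadata": m.metadata,
    }


def _checksum(payload) -> str:
    import hashlib
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def save_models(models: list, path) -> None:
    """Write a pattern set as a single JSON archive (bit-exact round trip)."""
    payload = {"models": [_model_payload(m) for m in models]}
    doc = {"format": _FORMAT,
           "protocol_hash": models[0].metadata.get("protocol_hash", ""),
           "checksum": _checksum(payload), **payload}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_models(path, expected_protocol_hash: str | None = None) -> list:
    """Load a pattern set; verifies format, checksum and protocol hash."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except FileNotFoundError:
        raise FileNotFoundError(f"change-model archive not found: {path}")
    if doc.get("format") != _FORMAT:
        raise ValueError(f"{path} is not a change-model archive")
    if _checksum({"models": doc["models"]}) != doc.get("checksum"):
        raise ValueError(f"{path}: archive checksum mismatch (tampered or corrupt)")
    if (expected_protocol_hash is not None
            and doc.get("protocol_hash") != expected_protocol_hash):
        raise ValueError(
            f"{path}: archive was trained on a different protocol "
            f"({doc.get('protocol_hash')} != {expected_protocol_hash})")
    models = []
    for p in doc["models"]:
        pat = ChangePattern(name=p["pattern"]["name"],
                            vector=np.array(p["pattern"]["vector"]),
                            param_names=tuple(p["pattern"]["param_names"]))
        models.append(ChangeModel(
            pattern=pat, w_mu=np.array(p["w_mu"]),
            w_sigma=np.array(p["w_sigma"]), mean_degree=p["mean_degree"],
            cov_degree=p["cov_degree"], y_center=np.array(p["y_center"]),
            y_scale=np.array(p["y_scale"]),
            theta_lo=(None if p.get("theta_lo") is None
                      else np.array(p["theta_lo"])),
            theta_hi=(None if p.get("theta_hi") is None
                      else np.array(p["theta_hi"])),
            metadata=p["metadata"]))
    return models
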