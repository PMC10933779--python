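"""Simulation harness: test-pair generation, confusion matrices, sensitivity
and amount-recovery experiments, and the direct-inversion baseline.

Test pairs emulate a two-condition experiment: a baseline parameter setting is
drawn from the prior, at most one parameter is perturbed by a fixed effect
size, and i.i.d. Gaussian noise (default sigma = 0.01, SNR 100) is added to
both forward signals.  Two classifiers label each pair with the changed
parameter (or no-change): the inversion-free posterior over change patterns,
and — for the invertible 4-parameter constrained model — a maximum-a-posteriori
fit per signal followed by a Bonferroni-corrected z-test across the pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import inference as inf
from .diffusion_model import (AcquisitionProtocol, ConstrainedModel,
                              StandardModel, add_noise, as_rng, ODI_MIN,
                              ODI_MAX)
from .change_models import (ChangeModel, single_parameter_patterns,
                            train_pattern_set)
from .summary_measures import (estimate_noise_covariance, log_coordinate_mask,
                               normalize_covariance, normalize_pair, summarize)

__all__ = [
    "TestPairSet",
    "generate_test_pairs",
    "map_fit_constrained",
    "ztest_compare",
    "classify_pairs_bench",
    "classify_pairs_ztest",
    "confusion_matrix",
    "sensitivity_curves",
    "amount_recovery",
    "run_constrained_experiment",
    "run_full_experiment",
    "NO_CHANGE",
]

NO_CHANGE = inf.NO_CHANGE


@dataclass
class TestPairSet:
    """Balanced pairs of noisy signals with at most one changed parameter."""

    labels: np.ndarray            # (n,) changed-parameter name or NO_CHANGE
    baseline_params: dict         # name -> (n,) arrays (model free params)
    effect_size: float
    sigma: float
    clean_a: np.ndarray           # (n, M) noise-free baseline signals
    clean_b: np.ndarray           # (n, M) noise-free perturbed signals
    noisy_a: np.ndarray
    noisy_b: np.ndarray
    amounts: np.ndarray = None    # (n,) true amount per pair (0 for no-change)


def generate_test_pairs(model: StandardModel, protocol: AcquisitionProtocol,
                        effect_size: float = 0.1, sigma: float = 0.01,
                        n_per_class: int = 100, seed=None,
                        classes=None) -> TestPairSet:
    """Generate balanced test pairs over {each free parameter, no-change}.

    The changed parameter is increased by ``effect_size`` in its native units;
    baselines whose perturbation would leave the valid ranges are resampled.
    """
    if effect_size < 0:
        raise ValueError("effect size must be non-negative")
    rng = as_rng(seed)
    if classes is None:
        classes = list(model.param_names) + [NO_CHANGE]
    labels, base_list, amounts = [], [], []
    for cls in classes:
        count = 0
        while count < n_per_class:
            draw = model.sample_prior(n_per_class - count, rng)
            draw.pop("mu", None)
            if cls != NO_CHANGE and effect_size > 0:
                pert = dict(draw)
                pert[cls] = draw[cls] + effect_size
                ok = model.is_valid(pert)
            else:
                ok = np.ones(len(draw[model.param_names[0]]), bool)
            kept = {k: v[ok] for k, v in draw.items()}
            m = int(ok.sum())
            if m == 0:
                continue
            base_list.append(kept)
            labels += [cls] * m
            amounts += [effect_size if cls != NO_CHANGE else 0.0] * m
            count += m
    base = {k: np.concatenate([b[k] for b in base_list])
            for k in base_list[0]}
    labels = np.array(labels)
    amounts = np.array(amounts)

    clean_a = model.signals(base, protocol, mu=np.array([0.0, 0.0, 1.0]))
    pert = {k: v.copy() for k, v in base.items()}
    for cls in classes:
        if cls == NO_CHANGE:
            continue
        sel = labels == cls
        pert[cls][sel] += effect_size
    clean_b = model.signals(pert, protocol, mu=np.array([0.0, 0.0, 1.0]))
    return TestPairSet(labels=labels, baseline_params=base,
                       effect_size=effect_size, sigma=sigma,
                       clean_a=clean_a, clean_b=clean_b,
                       noisy_a=add_noise(clean_a, sigma, rng),
                       noisy_b=add_noise(clean_b, sigma, rng),
                       amounts=amounts)


# --------------------------------------------------------------------------
# direct-inversion baseline (constrained model)
# --------------------------------------------------------------------------

_FIT_BOUNDS_LO = np.array([0.0, 0.0, 0.0, ODI_MIN])
_FIT_BOUNDS_HI = np.array([1.0, 1.0, 1.0, ODI_MAX])
_FIT_STARTS = np.array([
    [0.1, 0.45, 0.45, 0.3],
    [0.05, 0.7, 0.25, 0.1],
    [0.4, 0.3, 0.3, 0.5],
    [0.0, 0.2, 0.8, 0.2],
])


def map_fit_constrained(signal: np.ndarray, protocol: AcquisitionProtocol,
                        sigma: float, model: ConstrainedModel | None = None):
    """MAP fit of the 4-parameter constrained model to one noisy signal.

    Bounded nonlinear least squares (flat priors inside the valid box) with
    multi-start; the estimate covariance is the Laplace approximation at the
    mode, sigma^2 (J'J)^-1 from the residual Jacobian.  Returns (estimates
    (4,), covariance (4, 4)) in the order (s_iso, s_in, s_ex, odi).
    """
    model = model or ConstrainedModel()
    signal = np.asarray(signal, dtype=float)

    def residuals(x):
        p = {"s_iso": x[0:1], "s_in": x[1:2], "s_ex": x[2:3], "odi": x[3:4]}
        return (model.signals(p, protocol,
                              mu=np.array([0.0, 0.0, 1.0]))[0] - signal)

    best = None
    for x0 in _FIT_STARTS:
        res = optimize.least_squares(residuals, x0,
                                     bounds=(_FIT_BOUNDS_LO, _FIT_BOUNDS_HI),
                                     method="trf", xtol=1e-10, ftol=1e-10)
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("constrained MAP fit failed for all starts")
    J = best.jac
    JtJ = J.T @ J
    # Laplace covariance; ridge keeps it PD when a bound pins a parameter
    cov = sigma ** 2 * np.linalg.inv(JtJ + 1e-10 * np.eye(4)
                                     * max(1.0, np.trace(JtJ) / 4))
    cov = 0.5 * (cov + cov.T)
    return best.x, cov


def ztest_compare(fit_a, fit_b, alpha: float = 0.05,
                  param_names=None) -> str:
    """Label a pair from two (estimate, covariance) fits via z-tests.

    Per-parameter z = (b - a) / sqrt(var_a + var_b); two-sided p-values are
    Bonferroni-corrected across parameters.  The minimum-p parameter is
    returned, or no-change when min corrected p > alpha.
    """
    (xa, ca), (xb, cb) = fit_a, fit_b
    param_names = list(param_names
                       or ("s_iso", "s_in", "s_ex", "odi")[:len(xa)])
    var = np.diag(ca) + np.diag(cb)
    z = (np.asarray(xb) - np.asarray(xa)) / np.sqrt(np.maximum(var, 1e-30))
    p = 2.0 * stats.norm.sf(np.abs(z))
    p_corr = np.minimum(p * len(param_names), 1.0)
    i = int(np.argmin(p_corr))
    return param_names[i] if p_corr[i] <= alpha else NO_CHANGE


def classify_pairs_ztest(pairs: TestPairSet, protocol: AcquisitionProtocol,
                         alpha: float = 0.05) -> np.ndarray:
    """Direct-inversion labels for every pair (constrained model only)."""
    model = ConstrainedModel()
    n = pairs.labels.shape[0]
    out = np.empty(n, dtype=object)
    for i in range(n):
        fa = map_fit_constrained(pairs.noisy_a[i], protocol, pairs.sigma, model)
        fb = map_fit_constrained(pairs.noisy_b[i], protocol, pairs.sigma, model)
        out[i] = ztest_compare(fa, fb, param_names=model.param_names)
    return out.astype(str)


# --------------------------------------------------------------------------
# inversion-free classification
# --------------------------------------------------------------------------

def classify_pairs_bench(pairs: TestPairSet, protocol: AcquisitionProtocol,
                         models: list, prior: inf.AmountPrior | None = None,
                         n_noise_rep: int = 100, seed=None,
                         return_posteriors: bool = False):
    """Label pairs with the maximum-posterior change model.

    The per-pair noise covariance is estimated from ``n_noise_rep`` noisy
    instances of the clean baseline signal; summaries and covariance are
    normalised by the baseline b0-mean before inference.
    """
    prior = prior or inf.AmountPrior()
    rng = as_rng(seed)
    log_mask = log_coordinate_mask(protocol)
    n = pairs.labels.shape[0]
    out = np.empty(n, dtype=object)
    results = []
    y_a = summarize(pairs.noisy_a, protocol)
    y_b = summarize(pairs.noisy_b, protocol)
    for i in range(n):
        sn = estimate_noise_covariance(pairs.clean_a[i], protocol,
                                       pairs.sigma, n_rep=n_noise_rep,
                                       seed=rng)
        y, dy = normalize_pair(y_a[i], y_b[i] - y_a[i], log_mask)
        sn = normalize_covariance(sn, y_a[i][0], log_mask)
        res = inf.posterior_over_models(dy, y, models, sn, prior,
                                        compute_amounts=return_posteriors)
        out[i] = res.winner
        if return_posteriors:
            results.append(res)
    labels = out.astype(str)
    return (labels, results) if return_posteriors else labels


def confusion_matrix(true_labels, predicted_labels, labels=None) -> pd.DataFrame:
    """Column-normalised percentage confusion matrix.

    Columns are true classes, rows predicted classes; every column sums to
    100.  Raises on predicted labels outside the class alphabet.
    """
    true_labels = np.asarray(true_labels, dtype=str)
    predicted_labels = np.asarray(predicted_labels, dtype=str)
    if labels is None:
        labels = list(dict.fromkeys(true_labels.tolist()))
    unseen = set(predicted_labels) - set(labels)
    if unseen:
        raise ValueError(f"predicted labels outside alphabet: {unseen}")
    mat = np.zeros((len(labels), len(labels)))
    index = {lab: k for k, lab in enumerate(labels)}
    for t, p in zip(true_labels, predicted_labels):
        mat[index[p], index[t]] += 1
    col_tot = mat.sum(axis=0)
    if np.any(col_tot == 0):
        raise ValueError("every true class must appear at least once")
    return pd.DataFrame(100.0 * mat / col_tot, index=labels, columns=labels)


# --------------------------------------------------------------------------
# experiment drivers
# --------------------------------------------------------------------------

def run_constrained_experiment(protocol: AcquisitionProtocol,
                               n_per_class: int = 100,
                               effect_size: float = 0.1, sigma: float = 0.01,
                               n_train: int = 20_000, seed: int = 0,
                               models: list | None = None) -> dict:
    """Both pipelines on the invertible 4-parameter model.

    Returns dict with 'confusion_bench', 'confusion_ztest' (DataFrames),
    the trained change models and the test pairs.
    """
    rng = np.random.SeedSequence(seed).spawn(3)
    model = ConstrainedModel()
    if models is None:
        models = train_pattern_set(model, protocol, n=n_train,
                                   seed=int(rng[0].generate_state(1)[0] % 2**31))
    pairs = generate_test_pairs(model, protocol, effect_size, sigma,
                                n_per_class,
                                seed=np.random.default_rng(rng[1]))
    labels = list(model.param_names) + [NO_CHANGE]
    pred_b = classify_pairs_bench(pairs, protocol, models,
                                  seed=np.random.default_rng(rng[2]))
    pred_z = classify_pairs_ztest(pairs, protocol)
    return {
        "confusion_bench": confusion_matrix(pairs.labels, pred_b, labels),
        "confusion_ztest": confusion_matrix(pairs.labels, pred_z, labels),
        "models": models,
        "pairs": pairs,
    }


def run_full_experiment(protocol: AcquisitionProtocol, n_per_class: int = 50,
                        effect_size: float = 0.1, sigma: float = 0.01,
                        n_train: int = 20_000, seed: int = 0,
                        models: list | None = None) -> dict:
    """Inversion-free pipeline on the degenerate 8-parameter model."""
    rng = np.random.SeedSequence(seed).spawn(3)
    model = StandardModel()
    if models is None:
        models = train_pattern_set(model, protocol, n=n_train,
                                   seed=int(rng[0].generate_state(1)[0] % 2**31))
    pairs = generate_test_pairs(model, protocol, effect_size, sigma,
                                n_per_class,
                                seed=np.random.default_rng(rng[1]))
    labels = list(model.param_names) + [NO_CHANGE]
    pred = classify_pairs_bench(pairs, protocol, models,
                                seed=np.random.default_rng(rng[2]))
    return {
        "confusion_bench": confusion_matrix(pairs.labels, pred, labels),
        "models": models,
        "pairs": pairs,
    }


def sensitivity_curves(model: StandardModel, protocol: AcquisitionProtocol,
                       models: list, effects=None, sigma: float = 0.01,
                       n_per_class: int = 20, seed: int = 0,
                       classes=None) -> pd.DataFrame:
    """Posterior of the true pattern (and MAP amount) versus effect size.

    Returns a tidy DataFrame with one row per (effect, class) giving the mean
    and 10-90 percentiles of the true pattern's posterior probability and of
    the MAP amount estimate.
    """
    if effects is None:
        effects = np.arange(0.0, 0.11, 0.01)
    classes = list(classes or model.param_names)
    prior = inf.AmountPrior()
    name_to_col = {m.pattern.name: j + 1 for j, m in enumerate(models)}
    rows = []
    rng = as_rng(seed)
    for effect in effects:
        pairs = generate_test_pairs(model, protocol, float(effect), sigma,
                                    n_per_class, seed=rng, classes=classes)
        pred, results = classify_pairs_bench(pairs, protocol, models,
                                             prior=prior, seed=rng,
                                             return_posteriors=True)
        for cls in classes:
            sel = np.flatnonzero(pairs.labels == cls)
            probs = np.array([results[i].probabilities[name_to_col[cls]]
                              for i in sel])
            amts = np.array([results[i].map_amounts[cls] for i in sel])
            p_nc = np.array([results[i].probabilities[0] for i in sel])
            rows.append({
                "effect": float(effect), "class": cls,
                "posterior_mean": probs.mean(),
                "posterior_p10": np.percentile(probs, 10),
                "posterior_p90": np.percentile(probs, 90),
                "no_change_mean": p_nc.mean(),
                "map_amount_median": float(np.median(amts)),
                "map_amount_p10": np.percentile(amts, 10),
                "map_amount_p90": np.percentile(amts, 90),
            })
    return pd.DataFrame(rows)


def amount_recovery(model: StandardModel, protocol: AcquisitionProtocol,
                    models: list, classes, effect_size: float = 0.1,
                    sigma: float = 0.01, n_per_class: int = 50,
                    seed: int = 0) -> pd.DataFrame:
    """Median MAP amount per class for a single true effect size."""
    df = sensitivity_curves(model, protocol, models,
                            effects=[effect_size], sigma=sigma,
                            n_per_class=n_per_class, seed=seed,
                            classes=classes)
    return df[["class", "effect", "map_amount_median",
               "map_amount_p10", "map_amount_p90"]]
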