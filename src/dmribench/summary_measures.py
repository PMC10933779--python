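"""Rotation-invariant per-shell summary measures of multi-shell dMRI signals.

Each nonzero shell is decomposed onto real, orthonormal, even-degree spherical
harmonics by least squares.  The degree-0 coefficient is calibrated to the
spherical mean signal; the degree-2 power y_2 = (1/5) sum_m C_{2,m}^2 is
rotation invariant and reported on a log scale, log(y_2 + eps), which brings
its distribution closer to Gaussian and increases sensitivity to small
changes.  For the two-shell UK-Biobank-like protocol this yields the 5-vector
[b0-mean, b1-mean, b1-l2, b2-mean, b2-l2].
"""

from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y

from .diffusion_model import AcquisitionProtocol, add_noise, as_rng

__all__ = [
    "real_sh_basis",
    "fit_sh_coefficients",
    "degree_power",
    "summarize",
    "summary_names",
    "log_coordinate_mask",
    "normalize_pair",
    "normalize_covariance",
    "estimate_noise_covariance",
    "LOG_EPS",
]

LOG_EPS = 1e-12  # floor inside log(y_2 + eps); noisy data never reaches it


def real_sh_basis(directions: np.ndarray, l_max: int):
    """Real orthonormal even-degree SH design matrix at unit ``directions``.

    Returns (basis, degrees): basis has shape (D, n_coef) and degrees labels
    each column with its l.  Uses a Condon–Shortley-free real convention; only
    even degrees appear because the dMRI signal is antipodally symmetric.
    """
    if l_max % 2 != 0:
        raise ValueError("l_max must be even")
    d = np.asarray(directions, dtype=float).reshape(-1, 3)
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))
    phi = np.arctan2(d[:, 1], d[:, 0])
    cols, degs = [], []
    for l in range(0, l_max + 1, 2):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m == 0:
                col = y.real
            elif m > 0:
                col = np.sqrt(2.0) * (-1.0) ** m * y.real
            else:
                col = np.sqrt(2.0) * (-1.0) ** m * y.imag
            cols.append(col)
            degs.append(l)
    return np.column_stack(cols), np.array(degs)


def fit_sh_coefficients(shell_signal: np.ndarray, shell_directions: np.ndarray,
                        l_max: int):
    """Least-squares even-degree SH coefficients of a single-shell signal.

    ``shell_signal`` may carry leading batch dimensions (..., D).  Returns
    (coefficients (..., n_coef), degrees).
    """
    basis, degs = real_sh_basis(shell_directions, l_max)
    n_dir, n_coef = basis.shape
    if n_dir < n_coef:
        raise ValueError(
            f"underdetermined SH fit: {n_dir} directions < {n_coef} basis "
            f"functions (l_max={l_max})")
    pinv = np.linalg.pinv(basis)
    sig = np.asarray(shell_signal, dtype=float)
    return sig @ pinv.T, degs


def degree_power(coefficients: np.ndarray, degrees: np.ndarray, l: int):
    """Rotation-invariant power y_l of one degree.

    For l > 0, y_l = (1/(2l+1)) sum_m C_{l,m}^2 (mean square of the 2l+1
    coefficients).  For l = 0 the single coefficient is rescaled so y_0 equals
    the spherical mean signal.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    sel = np.flatnonzero(degrees == l)
    if sel.size == 0:
        raise ValueError(f"no coefficients of degree {l}")
    c = coefficients[..., sel]
    if l == 0:
        return c[..., 0] / np.sqrt(4.0 * np.pi)
    return np.sum(c * c, axis=-1) / (2 * l + 1)


def summary_names(protocol: AcquisitionProtocol) -> list:
    """Coordinate names in fixed order: b0-mean, then per shell mean and l2."""
    names = ["b0_mean"]
    for b in sorted(protocol.nonzero_shells):
        tag = f"b{b:g}" if b != round(b) else f"b{int(round(b))}"
        names += [f"{tag}_mean", f"{tag}_l2"]
    return names


def log_coordinate_mask(protocol: AcquisitionProtocol) -> np.ndarray:
    """Boolean mask over summary coordinates: True for log-power entries."""
    return np.array([n.endswith("_l2") for n in summary_names(protocol)])


def summarize(signal: np.ndarray, protocol: AcquisitionProtocol,
              l_max: int = 2) -> np.ndarray:
    """Map per-measurement signal(s) to the rotation-invariant summary vector.

    ``signal`` has shape (..., M).  Returns (..., 1 + 2*n_shells): the b=0
    mean, then for each nonzero shell (ascending b) the spherical-mean
    invariant and log(y_2 + eps).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape[-1] != len(protocol):
        raise ValueError("signal length does not match protocol")
    parts = [np.mean(signal[..., protocol.b0_indices], axis=-1)]
    for b in sorted(protocol.nonzero_shells):
        idx = protocol.nonzero_shells[b]
        coeffs, degs = fit_sh_coefficients(signal[..., idx],
                                           protocol.bvecs[idx], l_max)
        parts.append(degree_power(coeffs, degs, 0))
        parts.append(np.log(degree_power(coeffs, degs, 2) + LOG_EPS))
    return np.stack(parts, axis=-1)


def normalize_pair(y: np.ndarray, dy: np.ndarray, log_mask: np.ndarray):
    """Normalise a (baseline, change) summary pair by the baseline b0-mean.

    Mean-type coordinates of both vectors are divided by the baseline b0-mean.
    Baseline log-power coordinates are shifted by -2*log(b0-mean) (the log of
    the squared scale); changes in log coordinates are scale invariant and
    pass through unchanged.  Supports leading batch dimensions.
    """
    y = np.asarray(y, dtype=float).copy()
    dy = np.asarray(dy, dtype=float).copy()
    log_mask = np.asarray(log_mask, bool)
    b0 = y[..., 0:1].copy()  # copy: the first mean coordinate is rescaled below
    if np.any(b0 <= 0):
        raise ValueError("baseline b0-mean must be positive")
    mean_mask = ~log_mask
    y[..., mean_mask] = y[..., mean_mask] / b0
    y[..., log_mask] = y[..., log_mask] - 2.0 * np.log(b0)
    dy[..., mean_mask] = dy[..., mean_mask] / b0
    return y, dy


def normalize_covariance(cov: np.ndarray, b0_mean, log_mask: np.ndarray):
    """Transform a summary-space covariance consistently with normalize_pair.

    The change vector is rescaled coordinate-wise by d = 1/b0 on mean-type and
    1 on log-type coordinates, so the covariance maps to D cov D.
    """
    cov = np.asarray(cov, dtype=float)
    log_mask = np.asarray(log_mask, bool)
    d = np.where(log_mask, 1.0, 1.0 / np.asarray(b0_mean, dtype=float)[..., None])
    return cov * d[..., :, None] * d[..., None, :]


def estimate_noise_covariance(clean_signal: np.ndarray,
                              protocol: AcquisitionProtocol,
                              sigma: float, n_rep: int = 100, seed=None,
                              l_max: int = 2) -> np.ndarray:
    """Monte-Carlo noise covariance of paired summary differences.

    Generates ``n_rep`` pairs of noisy realisations of ``clean_signal`` and
    returns the sample covariance of the difference between the two summary
    vectors in each pair — the covariance entering the no-change likelihood.
    """
    if n_rep < 2:
        raise ValueError("n_rep must be at least 2")
    rng = as_rng(seed)
    clean = np.asarray(clean_signal, dtype=float)
    a = add_noise(np.broadcast_to(clean, (n_rep, clean.size)), sigma, rng)
    b = add_noise(np.broadcast_to(clean, (n_rep, clean.size)), sigma, rng)
    diff = summarize(b, protocol, l_max) - summarize(a, protocol, l_max)
    return np.cov(diff, rowvar=False, ddof=1)
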