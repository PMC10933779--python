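"""Generative three-compartment "standard model" of white-matter diffusion MRI.

The signal is a sum of an isotropic free-water compartment, an intra-axonal
compartment of Watson-dispersed sticks (zero radial diffusivity) and an
extra-axonal compartment of Watson-dispersed zeppelins (radial diffusivity a
fixed fraction ``tau`` of the axial one).  Both anisotropic compartments share
one fibre-orientation distribution, a Watson density on the sphere whose
concentration is parameterised through the orientation dispersion index
ODI = (2/pi)·arctan(1/kappa).

The spherical convolutions are evaluated with a Funk–Hecke Legendre expansion:
both the Watson ODF and the response kernel exp(-beta t^2) are zonal, so the
convolution reduces to a 1-D Legendre series whose coefficients come from
Gauss–Legendre quadrature.  A dense product-quadrature evaluation over the
sphere (:func:`quadrature_attenuation`) is shipped as an independent reference
implementation for testing.

Units: b-values in ms/um^2, diffusivities in um^2/ms, so b*d is unitless.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy.spatial.transform import Rotation
from scipy.stats import truncnorm

__all__ = [
    "AcquisitionProtocol",
    "TissueParams",
    "PriorSpec",
    "StandardModel",
    "ConstrainedModel",
    "make_ukb_protocol",
    "kappa_from_odi",
    "odi_from_kappa",
    "attenuation_iso",
    "watson_stick_attenuation",
    "watson_zeppelin_attenuation",
    "watson_odf",
    "simulate_signal",
    "simulate_signals",
    "sample_prior",
    "add_noise",
    "quadrature_attenuation",
    "STANDARD_PARAM_NAMES",
    "CONSTRAINED_PARAM_NAMES",
    "PARAM_SCALES",
]

# Free parameters of the full model, in canonical order.
STANDARD_PARAM_NAMES = (
    "s_iso", "s_in", "s_ex", "d_iso", "d_in_a", "d_ex_a", "tau", "odi",
)
# Free parameters of the constrained (invertible, NODDI-style) variant.
CONSTRAINED_PARAM_NAMES = ("s_iso", "s_in", "s_ex", "odi")

# Characteristic scale of each parameter, used for relative finite-difference
# steps.  Fractions / tau / ODI are O(1); diffusivities sit near their priors.
PARAM_SCALES = {
    "s_iso": 1.0, "s_in": 1.0, "s_ex": 1.0,
    "d_iso": 3.0, "d_in_a": 1.7, "d_ex_a": 1.7,
    "tau": 1.0, "odi": 1.0,
}

# Valid ranges (inclusive unless noted); ODI is open at both ends and is kept
# inside [ODI_MIN, ODI_MAX] so the Legendre series stays within its accuracy
# contract (kappa(0.01) ~ 64).
ODI_MIN, ODI_MAX = 0.01, 0.99
PARAM_BOUNDS = {
    "s_iso": (0.0, 1.0), "s_in": (0.0, 1.0), "s_ex": (0.0, 1.0),
    "d_iso": (0.0, np.inf), "d_in_a": (0.0, np.inf), "d_ex_a": (0.0, np.inf),
    "tau": (0.0, 1.0), "odi": (ODI_MIN, ODI_MAX),
}

_SHELL_RESOLUTION = 0.1  # ms/um^2; b-values are grouped by rounding to this


def as_rng(seed) -> np.random.Generator:
    """Return a Generator from an int seed, a Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# acquisition protocol
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionProtocol:
    """Multi-shell acquisition: per-measurement b-value and gradient direction.

    ``bvals`` has shape (M,), in ms/um^2; ``bvecs`` has shape (M, 3) with unit
    rows wherever b > 0.  Shells are detected by rounding b to the nearest
    0.1 ms/um^2; b=0 forms its own group.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError("bvals and bvecs disagree on measurement count")
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        norms = np.linalg.norm(bvecs, axis=1)
        dwi = bvals > 0
        if np.any(np.abs(norms[dwi] - 1.0) > 1e-8):
            raise ValueError("b>0 gradient directions must have unit norm")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def shell_bs(self) -> np.ndarray:
        """Sorted unique rounded b-values (including 0 if present)."""
        return np.unique(np.round(self.bvals / _SHELL_RESOLUTION) * _SHELL_RESOLUTION)

    @property
    def shells(self) -> dict:
        """Mapping rounded-b -> integer index array. Every index in one shell."""
        rounded = np.round(self.bvals / _SHELL_RESOLUTION) * _SHELL_RESOLUTION
        return {b: np.flatnonzero(rounded == b) for b in self.shell_bs}

    @property
    def b0_indices(self) -> np.ndarray:
        return self.shells.get(0.0, np.array([], dtype=int))

    @property
    def nonzero_shells(self) -> dict:
        return {b: idx for b, idx in self.shells.items() if b > 0}

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.round(self.bvals, 6).tobytes())
        h.update(np.round(self.bvecs, 6).tobytes())
        return h.hexdigest()[:16]

    # -- FSL-style text serialisation -------------------------------------
    def to_files(self, bvals_path, bvecs_path) -> None:
        """Write FSL-dialect files: bvals one row, bvecs three rows (x/y/z)."""
        np.savetxt(bvals_path, self.bvals[None, :], fmt="%.17g")
        np.savetxt(bvecs_path, self.bvecs.T, fmt="%.17g")

    @classmethod
    def from_files(cls, bvals_path, bvecs_path) -> "AcquisitionProtocol":
        bvals = np.loadtxt(bvals_path).ravel()
        bvecs = np.loadtxt(bvecs_path)
        if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
            bvecs = bvecs.T
        norms = np.linalg.norm(bvecs, axis=1)
        fix = (bvals > 0) & (norms > 0) & (np.abs(norms - 1) > 1e-8)
        if np.any(fix):
            bvecs = bvecs.copy()
            bvecs[fix] /= norms[fix, None]
        return cls(bvals=bvals, bvecs=bvecs)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform spherical Fibonacci point set (n unit vectors)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + np.sqrt(5.0)) * i
    z = 1 - 2 * i / n
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_ukb_protocol(n_dir_per_shell: int = 50, n_b0: int = 5,
                      seed: int = 0) -> AcquisitionProtocol:
    """UK-Biobank-like two-shell protocol: b=1 and b=2 ms/um^2.

    Each shell carries ``n_dir_per_shell`` quasi-uniform directions (spherical
    Fibonacci set, independently rotated by a seed-controlled random rotation
    per shell) plus ``n_b0`` b=0 measurements.  Defaults give 105 measurements.
    """
    if n_dir_per_shell < 6:
        raise ValueError("need at least 6 directions per shell for an l=2 fit")
    rng = as_rng(seed)
    base = _fibonacci_sphere(n_dir_per_shell)
    bvals = [np.zeros(n_b0)]
    bvecs = [np.zeros((n_b0, 3))]
    for b in (1.0, 2.0):
        rot = Rotation.random(random_state=rng).as_matrix()
        dirs = base @ rot.T
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        bvals.append(np.full(n_dir_per_shell, b))
        bvecs.append(dirs)
    return AcquisitionProtocol(np.concatenate(bvals), np.vstack(bvecs))


# --------------------------------------------------------------------------
# tissue parameters
# --------------------------------------------------------------------------

@dataclass
class TissueParams:
    """The 8 free standard-model parameters plus the (nuisance) fibre axis."""

    s_iso: float
    s_in: float
    s_ex: float
    d_iso: float
    d_in_a: float
    d_ex_a: float
    tau: float
    odi: float
    mu: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        for name in ("s_iso", "s_in", "s_ex", "d_iso", "d_in_a", "d_ex_a"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must lie in [0, 1]")
        if not 0.0 < self.odi < 1.0:
            raise ValueError("odi must lie in (0, 1)")
        if abs(np.linalg.norm(self.mu) - 1.0) > 1e-8:
            raise ValueError("mu must be a unit vector")

    def free_values(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STANDARD_PARAM_NAMES])


# --------------------------------------------------------------------------
# Watson dispersion
# --------------------------------------------------------------------------

def kappa_from_odi(odi):
    """Watson concentration kappa = cot(pi*odi/2); inverse of odi_from_kappa."""
    odi = np.asarray(odi, dtype=float)
    if np.any(odi <= 0) or np.any(odi >= 1):
        raise ValueError("odi must lie strictly inside (0, 1)")
    return 1.0 / np.tan(np.pi * odi / 2.0)


def odi_from_kappa(kappa):
    """ODI = (2/pi)·arctan(1/kappa), mapping kappa in (0, inf) to (0, 1)."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa <= 0):
        raise ValueError("kappa must be positive")
    return (2.0 / np.pi) * np.arctan(1.0 / kappa)


def watson_odf(n, mu, odi):
    """Watson density exp(kappa (mu.n)^2)/c at unit vectors ``n`` (rows).

    Normalised so the density integrates to 1 over the unit sphere.
    """
    kappa = float(kappa_from_odi(odi))
    n = np.asarray(n, dtype=float).reshape(-1, 3)
    mu = np.asarray(mu, dtype=float).ravel()
    t2 = (n @ mu) ** 2
    # c = 2*pi * int_{-1}^{1} exp(kappa u^2) du, computed stably via exp(k(u^2-1))
    u, w = _GL_NODES, _GL_WEIGHTS
    c = 2 * np.pi * np.sum(w * np.exp(kappa * (u * u - 1.0)))
    return np.exp(kappa * (t2 - 1.0)) / c


# --- Funk–Hecke Legendre machinery ----------------------------------------

_GL_ORDER = 128
_LMAX = 60  # highest even Legendre degree retained
_GL_NODES, _GL_WEIGHTS = npleg.leggauss(_GL_ORDER)
_EVEN_L = np.arange(0, _LMAX + 1, 2)
# P_l(t_q) for even l at the quadrature nodes, pre-multiplied by the weights
_P_EVEN_AT_NODES = npleg.legvander(_GL_NODES, _LMAX)[:, _EVEN_L]  # (Q, L)
_WP = _GL_WEIGHTS[:, None] * _P_EVEN_AT_NODES  # (Q, L)


def _legvander_even(x: np.ndarray) -> np.ndarray:
    """Even-degree Legendre polynomials P_l(x), shape x.shape + (L,)."""
    return npleg.legvander(np.asarray(x, dtype=float), _LMAX)[..., _EVEN_L]


def _watson_even_moments(kappa: np.ndarray) -> np.ndarray:
    """Normalised even Legendre moments J_l/I of exp(kappa t^2) on [-1,1].

    Returns shape (N, L).  Computed with the overflow-safe factor
    exp(kappa (t^2-1)), which cancels in the ratio.
    """
    kappa = np.atleast_1d(np.asarray(kappa, dtype=float))
    e = np.exp(kappa[:, None] * (_GL_NODES[None, :] ** 2 - 1.0))  # (N, Q)
    J = e @ _WP                                                   # (N, L)
    I = e @ _GL_WEIGHTS                                           # (N,)
    return J / I[:, None]


def _kernel_even_moments(beta: np.ndarray) -> np.ndarray:
    """K_l = int_{-1}^{1} exp(-beta t^2) P_l(t) dt for even l; shape (N, L)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    e = np.exp(-beta[:, None] * _GL_NODES[None, :] ** 2)
    return e @ _WP


def attenuation_iso(b, d_iso):
    """Isotropic free-water attenuation exp(-b*d_iso)."""
    b = np.asarray(b, dtype=float)
    d_iso = np.asarray(d_iso, dtype=float)
    if np.any(b < 0) or np.any(d_iso < 0):
        raise ValueError("b and d_iso must be non-negative")
    return np.exp(-b * d_iso)


def _cos_gamma(protocol: AcquisitionProtocol, mu) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if mu.ndim == 1:
        return protocol.bvecs @ mu
    return mu @ protocol.bvecs.T  # (N, M)


def watson_stick_attenuation(protocol: AcquisitionProtocol, d_in_a, odi, mu):
    """Per-measurement attenuation of Watson-dispersed sticks.

    Spherical convolution of the stick response exp(-b d (g.n)^2) with the
    shared Watson fibre ODF.
    """
    if d_in_a < 0:
        raise ValueError("d_in_a must be non-negative")
    kappa = float(kappa_from_odi(odi))
    beta = protocol.bvals * d_in_a
    cg = _cos_gamma(protocol, mu)
    return _zonal_per_measurement(beta, kappa, cg)


def _zonal_per_measurement(beta: np.ndarray, kappa: float, cos_gamma: np.ndarray) -> np.ndarray:
    """Zonal convolution where beta and cos_gamma vary per measurement."""
    w = _watson_even_moments(np.array([kappa]))[0]        # (L,)
    K = _kernel_even_moments(beta)                        # (M, L)
    P = _legvander_even(cos_gamma)                        # (M, L)
    coef = 0.5 * (2 * _EVEN_L + 1) * w
    return np.einsum("l,ml,ml->m", coef, K, P)


def watson_zeppelin_attenuation(protocol: AcquisitionProtocol, d_ex_a, tau, odi, mu):
    """Per-measurement attenuation of Watson-dispersed zeppelins.

    The zeppelin response exp(-b d_a [(g.n)^2 + tau (1-(g.n)^2)]) factors into
    exp(-b d_a tau) times a stick response with effective diffusivity
    d_a (1 - tau), so the same zonal convolution applies.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    if d_ex_a < 0:
        raise ValueError("d_ex_a must be non-negative")
    kappa = kappa_from_odi(odi)
    beta = protocol.bvals * d_ex_a * (1.0 - tau)
    cg = _cos_gamma(protocol, mu)
    iso_factor = np.exp(-protocol.bvals * d_ex_a * tau)
    return iso_factor * _zonal_per_measurement(beta, kappa, cg)


def simulate_signal(params: TissueParams, protocol: AcquisitionProtocol) -> np.ndarray:
    """Noise-free signal S = s_iso A_iso + s_in A_in + s_ex A_ex."""
    a_iso = attenuation_iso(protocol.bvals, params.d_iso)
    a_in = watson_stick_attenuation(protocol, params.d_in_a, params.odi, params.mu)
    a_ex = watson_zeppelin_attenuation(protocol, params.d_ex_a, params.tau,
                                       params.odi, params.mu)
    return params.s_iso * a_iso + params.s_in * a_in + params.s_ex * a_ex


def simulate_signals(params: dict, protocol: AcquisitionProtocol,
                     mu=None) -> np.ndarray:
    """Vectorised forward model over N parameter settings.

    ``params`` maps each name in STANDARD_PARAM_NAMES to an (N,) array.  ``mu``
    is a single (3,) axis shared by all samples (default +z) or an (N, 3)
    array.  Returns signals of shape (N, M); exploits the shell structure so
    the Legendre coefficients are computed once per (sample, shell).
    """
    names = STANDARD_PARAM_NAMES
    arrs = {k: np.atleast_1d(np.asarray(params[k], dtype=float)) for k in names}
    n = max(a.shape[0] for a in arrs.values())
    for k, a in arrs.items():
        arrs[k] = np.broadcast_to(a, (n,))
    if mu is None:
        mu = np.array([0.0, 0.0, 1.0])
    mu = np.asarray(mu, dtype=float)
    kappa = kappa_from_odi(arrs["odi"])
    w = _watson_even_moments(kappa)                       # (N, L)
    coef_scale = 0.5 * (2 * _EVEN_L + 1)

    out = np.empty((n, len(protocol)))
    for b, idx in protocol.shells.items():
        dirs = protocol.bvecs[idx]
        if mu.ndim == 1:
            cg = dirs @ mu                                # (D,)
            P = _legvander_even(cg)                       # (D, L)
            contract = lambda coef: coef @ P.T            # noqa: E731
        else:
            cg = mu @ dirs.T                              # (N, D)
            P = _legvander_even(cg)                       # (N, D, L)
            contract = lambda coef: np.einsum("nl,ndl->nd", coef, P)  # noqa: E731
        if b == 0.0:
            sig = (arrs["s_iso"] + arrs["s_in"] + arrs["s_ex"])[:, None]
            out[:, idx] = np.broadcast_to(sig, (n, idx.size))
            continue
        a_iso = np.exp(-b * arrs["d_iso"])[:, None]
        K_in = _kernel_even_moments(b * arrs["d_in_a"])
        a_in = contract(coef_scale[None, :] * w * K_in)
        beta_ex = b * arrs["d_ex_a"] * (1.0 - arrs["tau"])
        K_ex = _kernel_even_moments(beta_ex)
        a_ex = np.exp(-b * arrs["d_ex_a"] * arrs["tau"])[:, None] * \
            contract(coef_scale[None, :] * w * K_ex)
        out[:, idx] = (arrs["s_iso"][:, None] * a_iso
                       + arrs["s_in"][:, None] * a_in
                       + arrs["s_ex"][:, None] * a_ex)
    return out


# --------------------------------------------------------------------------
# dense-quadrature reference
# --------------------------------------------------------------------------

def quadrature_attenuation(b, g, d_axial, tau, odi, mu,
                           n_theta: int = 128, n_phi: int = 256):
    """Reference dense spherical-quadrature convolution (test oracle).

    Evaluates A(b, g) = int_{S^2} exp(-b d_a [(g.n)^2 + tau (1-(g.n)^2)])
    Watson(n; mu, odi) dn with a Gauss–Legendre x trapezoid product rule.
    ``tau=0`` gives the stick compartment.  Slow but accurate; independent of
    the Legendre-series evaluation used by the forward model.
    """
    b = np.atleast_1d(np.asarray(b, dtype=float))
    g = np.asarray(g, dtype=float).reshape(-1, 3)
    mu = np.asarray(mu, dtype=float).ravel()
    kappa = float(kappa_from_odi(odi))

    ct, wt = npleg.leggauss(n_theta)           # cos(theta) nodes
    phi = np.arange(n_phi) * (2 * np.pi / n_phi)
    st = np.sqrt(1 - ct ** 2)
    nx = st[:, None] * np.cos(phi)[None, :]
    ny = st[:, None] * np.sin(phi)[None, :]
    nz = np.broadcast_to(ct[:, None], nx.shape)
    n_pts = np.stack([nx, ny, nz], axis=-1).reshape(-1, 3)
    w_pts = (wt[:, None] * np.full((1, n_phi), 2 * np.pi / n_phi)).ravel()

    mu_dot2 = (n_pts @ mu) ** 2
    watson_unnorm = np.exp(kappa * (mu_dot2 - 1.0))
    c = np.sum(w_pts * watson_unnorm)
    out = np.empty((b.shape[0],))
    for i in range(b.shape[0]):
        gd2 = (n_pts @ g[i % g.shape[0]]) ** 2
        kernel = np.exp(-b[i] * d_axial * (gd2 + tau * (1.0 - gd2)))
        out[i] = np.sum(w_pts * kernel * watson_unnorm) / c
    return out if out.size > 1 else float(out[0])


# --------------------------------------------------------------------------
# priors and noise
# --------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Sampling distributions for the standard-model parameters.

    Defaults encode the training prior: s_iso a 50/50 mixture of a point mass
    at 0 and U(0,1) (pure tissue vs. partial free-water volume), s_in and s_ex
    U(0,1), all three then renormalised to sum to 1; d_iso ~ N(3, 0.1) and the
    axial diffusivities ~ N(1.7, 0.3), truncated at 0; tau ~ U(0,1); ODI ~
    Beta(2, 5) clipped to [0.01, 0.99]; fibre axis fixed to +z (the summary
    measures are rotation invariant) or uniform on the sphere.
    """

    s_iso_delta_weight: float = 0.5
    normalize_fractions: bool = True
    d_iso_mean: float = 3.0
    d_iso_sd: float = 0.1
    d_axial_mean: float = 1.7
    d_axial_sd: float = 0.3
    odi_alpha: float = 2.0
    odi_beta: float = 5.0
    odi_clip: tuple = (ODI_MIN, ODI_MAX)
    mu_mode: str = "fixed"  # "fixed" (+z) or "uniform"

    def sample(self, n: int, seed=None) -> dict:
        return sample_prior(self, n, seed)


def _trunc_normal(rng, mean, sd, n):
    a = (0.0 - mean) / sd  # truncate at zero
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n,
                         random_state=rng)


def sample_prior(prior: PriorSpec, n: int, seed=None) -> dict:
    """Draw n parameter settings; returns dict of (N,) arrays plus 'mu' (N,3)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = as_rng(seed)
    s_iso = rng.uniform(0, 1, n)
    s_iso[rng.uniform(size=n) < prior.s_iso_delta_weight] = 0.0
    s_in = rng.uniform(0, 1, n)
    s_ex = rng.uniform(0, 1, n)
    total = s_iso + s_in + s_ex
    redo = total <= 0
    while np.any(redo):  # measure-zero corner: all three fractions zero
        s_in[redo] = rng.uniform(0, 1, int(redo.sum()))
        total = s_iso + s_in + s_ex
        redo = total <= 0
    if prior.normalize_fractions:
        s_iso, s_in, s_ex = s_iso / total, s_in / total, s_ex / total
    d_iso = _trunc_normal(rng, prior.d_iso_mean, prior.d_iso_sd, n)
    d_in_a = _trunc_normal(rng, prior.d_axial_mean, prior.d_axial_sd, n)
    d_ex_a = _trunc_normal(rng, prior.d_axial_mean, prior.d_axial_sd, n)
    tau = rng.uniform(0, 1, n)
    odi = np.clip(rng.beta(prior.odi_alpha, prior.odi_beta, n), *prior.odi_clip)
    if prior.mu_mode == "uniform":
        v = rng.normal(size=(n, 3))
        mu = v / np.linalg.norm(v, axis=1, keepdims=True)
    else:
        mu = np.broadcast_to(np.array([0.0, 0.0, 1.0]), (n, 3)).copy()
    return {"s_iso": s_iso, "s_in": s_in, "s_ex": s_ex, "d_iso": d_iso,
            "d_in_a": d_in_a, "d_ex_a": d_ex_a, "tau": tau, "odi": odi,
            "mu": mu}


def add_noise(signal, sigma: float, seed=None) -> np.ndarray:
    """Additive i.i.d. Gaussian measurement noise; sigma=0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    rng = as_rng(seed)
    return signal + rng.normal(0.0, sigma, size=signal.shape)


# --------------------------------------------------------------------------
# parameterised models (full and constrained)
# --------------------------------------------------------------------------

class StandardModel:
    """The full 8-parameter standard model as a named-parameter forward map."""

    param_names = STANDARD_PARAM_NAMES

    def __init__(self, prior: PriorSpec | None = None):
        self.prior = prior if prior is not None else PriorSpec()

    def scales(self) -> np.ndarray:
        return np.array([PARAM_SCALES[p] for p in self.param_names])

    def sample_prior(self, n: int, seed=None) -> dict:
        s = sample_prior(self.prior, n, seed)
        return {k: s[k] for k in (*self.param_names, "mu")}

    def is_valid(self, params: dict) -> np.ndarray:
        """Elementwise validity of an (N,)-array parameter dict."""
        ok = np.ones(np.atleast_1d(params[self.param_names[0]]).shape, bool)
        for name in self.param_names:
            lo, hi = PARAM_BOUNDS[name]
            v = np.atleast_1d(params[name])
            ok &= (v >= lo) & (v <= hi)
        return ok

    def signals(self, params: dict, protocol: AcquisitionProtocol,
                mu=None) -> np.ndarray:
        if mu is None:
            mu = params.get("mu")
        return simulate_signals(params, protocol, mu=mu)


class ConstrainedModel(StandardModel):
    """NODDI-style invertible variant with 4 free parameters.

    Diffusivities are fixed (d_iso = 3, d_in_a = d_ex_a = 1.7 um^2/ms) and the
    extra-axonal tortuosity follows the mean-field hindrance assumption
    d_ex_r = d_ex_a * (1 - v_ic), i.e. tau = s_ex / (s_in + s_ex): the denser
    the sticks, the more hindered the perpendicular diffusion.  This coupling
    is what renders the model invertible from two-shell data.
    """

    param_names = CONSTRAINED_PARAM_NAMES
    FIXED_D_ISO = 3.0
    FIXED_D_AXIAL = 1.7

    def expand(self, params: dict) -> dict:
        s_in = np.atleast_1d(np.asarray(params["s_in"], dtype=float))
        s_ex = np.atleast_1d(np.asarray(params["s_ex"], dtype=float))
        denom = np.where(s_in + s_ex > 0, s_in + s_ex, 1.0)
        full = {
            "s_iso": np.atleast_1d(np.asarray(params["s_iso"], dtype=float)),
            "s_in": s_in, "s_ex": s_ex,
            "d_iso": np.full_like(s_in, self.FIXED_D_ISO),
            "d_in_a": np.full_like(s_in, self.FIXED_D_AXIAL),
            "d_ex_a": np.full_like(s_in, self.FIXED_D_AXIAL),
            "tau": s_ex / denom,
            "odi": np.atleast_1d(np.asarray(params["odi"], dtype=float)),
        }
        if "mu" in params:
            full["mu"] = params["mu"]
        return full

    def sample_prior(self, n: int, seed=None) -> dict:
        s = sample_prior(self.prior, n, seed)
        return {k: s[k] for k in (*self.param_names, "mu")}

    def signals(self, params: dict, protocol: AcquisitionProtocol,
                mu=None) -> np.ndarray:
        full = self.expand(params)
        if mu is None:
            mu = full.get("mu")
        return simulate_signals(full, protocol, mu=mu)
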