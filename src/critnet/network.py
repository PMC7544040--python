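"""Random E/I connectivity and its eigenvalue theory.

The connectivity matrix ``J`` holds the synapse from neuron ``i`` to
neuron ``j`` in row ``j``, column ``i``.  The first ``(1 - alpha) * N``
neurons are excitatory (outgoing weights uniform on ``[0, w]``), the rest
inhibitory (outgoing weights uniform on ``[-g*w, 0]``); every off-diagonal
entry is present independently with probability ``p``.

For such a matrix the spectrum consists of a bulk of complex eigenvalues
filling a disc of radius

    R = sqrt( N * [ (1 - alpha) * sigma_E^2 + alpha * sigma_I^2 ] ),

where ``sigma_E^2 = (p/3 - p^2/4) w^2`` and
``sigma_I^2 = (p/3 - p^2/4) (g w)^2`` are the element variances of the
E and I sub-matrices, plus one real outlier set by the mean row sum,

    lambda_b = (w/2) N p (1 - alpha) - (g w / 2) N p alpha.

The largest eigenvalue is ``lambda_max = max(lambda_b, R)``; the network
sits on the boundary between runaway and decaying activity when
``lambda_max = 1``.  Which of the two expressions dominates depends only
on ``g``; the crossover ratio ``g*`` solves ``lambda_b(g) = R(g)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import ModelParams

__all__ = [
    "ConnectivityMatrix",
    "EigenTheory",
    "EigenSpectrum",
    "build_connectivity",
    "theoretical_eigen",
    "crossover_ratio",
    "crossover_ratio_large_n",
    "solve_boundary_weight",
    "empirical_spectrum",
]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Signed, weighted N x N coupling matrix with its E/I partition."""

    J: np.ndarray
    excitatory_ids: np.ndarray
    inhibitory_ids: np.ndarray
    params: ModelParams
    seed: int | None = None

    @property
    def N(self) -> int:
        return self.J.shape[0]


@dataclass(frozen=True)
class EigenTheory:
    """Closed-form spectral summary of a parameter point."""

    lambda_b: float
    R: float
    lambda_max: float
    sigma2_E: float
    sigma2_I: float


@dataclass(frozen=True)
class EigenSpectrum:
    """Numerically computed spectrum of one quenched connectivity draw."""

    eigenvalues: np.ndarray
    largest_modulus: float
    largest_real: float


def _as_rng(rng, fallback_seed=None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None:
        rng = fallback_seed
    return np.random.default_rng(rng)


def build_connectivity(params: ModelParams, rng=None) -> ConnectivityMatrix:
    """Draw one quenched connectivity matrix.

    Parameters
    ----------
    params : ModelParams
    rng : numpy Generator, int seed, or None
        ``None`` falls back to ``params.seed``.

    Self-connections are excluded (zero diagonal).  The draw is
    deterministic given the seed.
    """
    N = params.N
    seed = rng if isinstance(rng, (int, np.integer)) else params.seed
    gen = _as_rng(rng, fallback_seed=params.seed)

    n_exc = params.n_excitatory
    exc_ids = np.arange(n_exc)
    inh_ids = np.arange(n_exc, N)

    # Uniform magnitudes and the Bernoulli presence mask are drawn for the
    # full matrix so the stream layout is independent of alpha and g.
    magnitudes = gen.random((N, N))
    mask = gen.random((N, N)) < params.p

    col_scale = np.full(N, params.w)
    col_scale[inh_ids] = -params.g * params.w  # inhibitory columns in [-g*w, 0]

    J = np.where(mask, magnitudes, 0.0) * col_scale[np.newaxis, :]
    np.fill_diagonal(J, 0.0)
    return ConnectivityMatrix(
        J=J,
        excitatory_ids=exc_ids,
        inhibitory_ids=inh_ids,
        params=params,
        seed=None if isinstance(rng, np.random.Generator) else seed,
    )


def _element_variances(params: ModelParams) -> tuple[float, float]:
    v = (params.p / 3.0 - params.p**2 / 4.0)
    return v * params.w**2, v * (params.g * params.w) ** 2


def theoretical_eigen(params: ModelParams) -> EigenTheory:
    """Closed-form outlier, bulk radius and largest eigenvalue."""
    N, p, a, w, g = params.N, params.p, params.alpha, params.w, params.g
    lambda_b = (w / 2.0) * N * p * (1.0 - a) - (g * w / 2.0) * N * p * a
    s2_E, s2_I = _element_variances(params)
    R = math.sqrt(N * ((1.0 - a) * s2_E + a * s2_I))
    return EigenTheory(
        lambda_b=lambda_b,
        R=R,
        lambda_max=max(lambda_b, R),
        sigma2_E=s2_E,
        sigma2_I=s2_I,
    )


def crossover_ratio_large_n(alpha: float) -> float:
    """Large-N crossover ratio ``g* = (1 - alpha) / alpha``."""
    if alpha <= 0:
        raise ValueError("crossover ratio requires alpha > 0")
    return (1.0 - alpha) / alpha


def crossover_ratio(params: ModelParams, method: str = "closed_form") -> float:
    """I/E weight ratio ``g*`` at which the outlier meets the bulk radius.

    The condition ``lambda_b(g) = R(g)`` is independent of ``w``.  Squaring
    it yields a quadratic in ``g``; of its two roots only the one with
    ``lambda_b >= 0`` (i.e. ``g <= (1 - alpha)/alpha``) solves the original
    unsquared equation, and that root is returned.

    ``method='numeric'`` instead bisects ``lambda_b(g) - R(g)`` directly;
    the two routes agree to better than 1e-9 and are cross-checked in the
    test suite.
    """
    N, p, a = params.N, params.p, params.alpha
    if a <= 0:
        raise ValueError("crossover ratio requires alpha > 0")
    g_cap = (1.0 - a) / a

    if method == "numeric":
        def gap(g):
            q = params.with_(g=g, w=1.0)  # w-independent condition
            th = theoretical_eigen(q)
            return th.lambda_b - th.R

        if gap(0.0) <= 0:
            raise ValueError("no positive crossover: bulk dominates at g = 0")
        return brentq(gap, 0.0, g_cap, xtol=1e-14, rtol=1e-15)

    if method != "closed_form":
        raise ValueError(f"unknown method {method!r}")

    c = 4.0 / 3.0 - p
    A = p * a**2 - c * a / N
    B = p * a * (1.0 - a)
    C = p * (1.0 - a) ** 2 - c * (1.0 - a) / N
    disc = B**2 - A * C
    if disc < 0:
        if disc > -1e-15 * B**2:
            disc = 0.0  # degenerate double root (large-N limit)
        else:
            raise ValueError("no real crossover ratio for these parameters")
    roots = []
    sq = math.sqrt(disc)
    if A != 0.0:
        roots = [(B - sq) / A, (B + sq) / A]
    elif B != 0.0:
        roots = [C / (2.0 * B)]
    valid = [r for r in roots if 0.0 < r <= g_cap + 1e-12]
    if not valid:
        raise ValueError("no positive real crossover root exists")

    def residual(g):
        th = theoretical_eigen(params.with_(g=g, w=1.0))
        return abs(th.lambda_b - th.R)

    # squaring introduced a lambda_b = -R root; keep the genuine crossing
    return min(valid, key=residual)


def solve_boundary_weight(g: float, params: ModelParams) -> float:
    """Weight scale ``w*`` putting ``(g, w*)`` on the lambda_max = 1 boundary.

    For ``g <= g*`` the outlier branch applies:
    ``w* = 1 / [ (N p / 2) ((1 - alpha) - g alpha) ]``; beyond the
    crossover the bulk-radius branch applies:
    ``w* = 1 / sqrt( N (p/3 - p^2/4) ((1 - alpha) + alpha g^2) )``.
    At ``g = g*`` both coincide; the outlier branch is used by convention.
    """
    if g < 0:
        raise ValueError("g must be non-negative")
    N, p, a = params.N, params.p, params.alpha
    if a > 0:
        g_star = crossover_ratio(params)
    else:
        g_star = math.inf  # purely excitatory: outlier branch everywhere
    if g <= g_star:
        denom = (N * p / 2.0) * ((1.0 - a) - g * a)
        if denom <= 0:
            raise ValueError(f"outlier branch unbounded at g={g}")
        return 1.0 / denom
    denom = N * (p / 3.0 - p**2 / 4.0) * ((1.0 - a) + a * g**2)
    if denom <= 0:
        raise ValueError(f"bulk branch unbounded at g={g}")
    return 1.0 / math.sqrt(denom)


def empirical_spectrum(J) -> EigenSpectrum:
    """Full eigenvalue set of a sampled connectivity matrix.

    Accepts a :class:`ConnectivityMatrix` or a square array.  Raises
    ``numpy.linalg.LinAlgError`` if the QR iteration fails to converge.
    """
    M = J.J if isinstance(J, ConnectivityMatrix) else np.asarray(J, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"J must be square, got shape {M.shape}")
    ev = np.linalg.eigvals(M)
    return EigenSpectrum(
        eigenvalues=ev,
        largest_modulus=float(np.abs(ev).max()),
        largest_real=float(ev.real.max()),
    )
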