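"""Branching function, critical range and avalanche threshold.

The branching function ``Lambda(S) = E[S(t+1) | S(t) = S] / S`` measures
the expected one-step growth ratio of the active fraction.  A flat
stretch near ``Lambda = 1`` lets activity wander (criticality); a steep
crossing at some ``S*`` pins activity to a stable rate (asynchrony).

Two estimators are provided.  The empirical one imposes ``S(1) = k/N``
by activating a uniformly random subset of k neurons and averages
``S(2)/S(1)`` over one-step trials.  The semi-analytic one treats the
numbers of active presynaptic E and I neurons as Poisson variables with
means ``mu_E = N p (1-alpha) S`` and ``mu_I = N p alpha S``, replaces
every synapse by its average strength (``w/2`` and ``-g w/2``), and
evaluates

    Lambda(S) = (1/S) * sum_{n_E, n_I} P(n_E) P(n_I)
                sigma( (w/2) n_E - (g w / 2) n_I ),

with ``sigma`` the clamped-linear transfer.  The external drive is not
part of the one-step propagation and is excluded from both estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dynamics import transfer
from .network import ConnectivityMatrix
from .params import ModelParams

__all__ = [
    "BranchingCurve",
    "CriticalRange",
    "AvalancheThreshold",
    "default_S_grid",
    "empirical_branching",
    "semianalytic_branching",
    "critical_range",
    "avalanche_threshold",
]


@dataclass(frozen=True)
class BranchingCurve:
    """Lambda(S) on an ordered grid of activity fractions."""

    S_grid: np.ndarray
    Lambda: np.ndarray
    method: str  # "empirical" | "semianalytic"
    n_trials: int | None = None
    stderr: np.ndarray | None = None


@dataclass(frozen=True)
class CriticalRange:
    """Width of the S interval over which Lambda stays within [0.95, 1.05].

    ``S1`` is the downmost 1.05 crossing at largest S, ``S2`` the first
    0.95 crossing beyond it; when a level is never crossed the fallback
    endpoints are used and flagged.
    """

    S1: float
    S2: float
    rho: float
    s1_fallback: bool = False
    s2_fallback: bool = False


@dataclass(frozen=True)
class AvalancheThreshold:
    """Activity level S-dagger where Lambda(S) = 1.01, and its neuron count."""

    S_dagger: float
    count: int
    fallback: bool = False


def default_S_grid(N: int, s_max: float = 0.5) -> np.ndarray:
    """Grid of realizable activity fractions k/N for k = 1 .. s_max*N."""
    k_max = max(1, int(round(s_max * N)))
    return np.arange(1, k_max + 1) / N


def empirical_branching(
    conn: ConnectivityMatrix,
    S_grid: np.ndarray | None = None,
    n_trials: int = 200,
    rng=None,
) -> BranchingCurve:
    """Monte-Carlo branching function from one-step trials.

    For each grid value ``S = k/N``, ``n_trials`` trials each activate a
    fresh uniformly random set of k neurons, advance the model one step
    (Bernoulli draws on the clamped-linear probabilities, no external
    drive), and record ``S(2)/S(1)``.  The per-point standard error over
    trials is returned alongside the mean.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    N = conn.N
    J = conn.J
    if S_grid is None:
        S_grid = default_S_grid(N)
    S_grid = np.asarray(S_grid, dtype=float)
    ks = np.rint(S_grid * N).astype(int)
    if np.any(ks < 1) or np.any(ks > N):
        raise ValueError("S_grid values must be realizable as k/N, k >= 1")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    lam = np.empty(S_grid.shape)
    se = np.empty(S_grid.shape)
    for idx, k in enumerate(ks):
        # k distinct active neurons per trial, drawn column-wise
        scores = gen.random((n_trials, N))
        active = np.argpartition(scores, k - 1, axis=1)[:, :k]
        B = np.zeros((N, n_trials))
        B[active.T, np.arange(n_trials)[np.newaxis, :]] = 1.0
        p = transfer(J @ B)
        fired = gen.random(p.shape) < p
        ratios = fired.sum(axis=0) / k
        lam[idx] = ratios.mean()
        se[idx] = ratios.std(ddof=1) / math.sqrt(n_trials) if n_trials > 1 else np.inf
    return BranchingCurve(
        S_grid=S_grid, Lambda=lam, method="empirical", n_trials=n_trials, stderr=se
    )


def _poisson_support(mu: float, tail: float) -> np.ndarray:
    if mu <= 0:
        return np.array([0])
    hi = int(stats.poisson.isf(tail, mu)) + 1
    return np.arange(0, hi + 1)


def _mean_weight_lambda(params: ModelParams, S_grid: np.ndarray,
                        tail_mass: float) -> np.ndarray:
    """Poisson counts with every synapse at its average strength."""
    N, p, a, w, g = params.N, params.p, params.alpha, params.w, params.g
    lam = np.empty(S_grid.shape)
    for idx, S in enumerate(S_grid):
        mu_E = N * p * (1.0 - a) * S
        mu_I = N * p * a * S
        n_E = _poisson_support(mu_E, tail_mass)
        n_I = _poisson_support(mu_I, tail_mass)
        pmf_E = stats.poisson.pmf(n_E, mu_E) if mu_E > 0 else np.array([1.0])
        pmf_I = stats.poisson.pmf(n_I, mu_I) if mu_I > 0 else np.array([1.0])
        vals = transfer(
            (w / 2.0) * n_E[:, np.newaxis] - (g * w / 2.0) * n_I[np.newaxis, :]
        )
        lam[idx] = float(pmf_E @ vals @ pmf_I) / S
    return lam


def _triangular_histogram(values: np.ndarray, dx: float, M: int,
                          weight: float) -> np.ndarray:
    """Mass-preserving deposit of signed values onto the circular grid.

    Each value is split linearly between its two neighbouring bins, so
    the discretized distribution keeps the exact sample mean.
    """
    pmf = np.zeros(M)
    pos = values / dx
    lo = np.floor(pos).astype(np.int64)
    frac = pos - lo
    np.add.at(pmf, lo % M, weight * (1.0 - frac))
    np.add.at(pmf, (lo + 1) % M, weight * frac)
    return pmf


def _realized_jump_transforms(conn, dx: float, M: int):
    """Fourier transforms of the per-contribution input law of a drawn J.

    The jump distribution of one active presynaptic neuron is the pooled
    distribution of entries in its population's columns (zeros included,
    diagonal excluded) -- the realization-level analogue of
    Bernoulli(p) x Uniform.
    """
    J = conn.J
    N = J.shape[0]
    off = ~np.eye(N, dtype=bool)
    out = []
    for ids in (conn.excitatory_ids, conn.inhibitory_ids):
        if ids.size == 0:
            out.append(None)
            continue
        vals = J[:, ids][off[:, ids]]
        nz = vals[vals != 0.0]
        pmf = _triangular_histogram(nz, dx, M, 1.0 / vals.size)
        pmf[0] += 1.0 - nz.size / vals.size
        out.append(np.fft.rfft(pmf))
    return out


def _distribution_lambda(params: ModelParams, S_grid: np.ndarray,
                         conn=None) -> np.ndarray:
    """Full-weight-distribution one-step expectation.

    With ``k = S N`` imposed active neurons, the input to a neuron is a
    sum of k independent contributions, each present with probability p
    and then uniform on [0, w] (excitatory, probability 1 - alpha) or on
    [-g w, 0] (inhibitory, probability alpha).  The input density is
    obtained by an FFT convolution power of the single-contribution law
    on a signed grid, and ``Lambda = E[sigma(X)] / S`` follows by
    quadrature.  Retaining the weight (and count) dispersion matters in
    the strong-coupling regime, where the mean input cancels and firing
    is fluctuation-driven.

    When a drawn connectivity is supplied the per-contribution law is
    taken from its realized weights instead of the ensemble, giving the
    noise-free branching prediction for that quenched network.
    """
    N, p, a, w, g = params.N, params.p, params.alpha, params.w, params.g
    ks = np.rint(S_grid * N).astype(int)
    k_max = int(ks.max())

    dx = w / 64.0
    # grid half-width: worst-case mean +/- 14 sd of the compound sum
    m2 = p * ((1.0 - a) * w**2 / 3.0 + a * (g * w) ** 2 / 3.0)
    sd = math.sqrt(k_max * m2)
    mean = k_max * p * ((1.0 - a) * w / 2.0 - a * g * w / 2.0)
    L = max(1.5, abs(mean) + 14.0 * sd + (1.0 + g) * w)
    M = 1 << max(8, math.ceil(math.log2(2.0 * L / dx)))

    # signed circular grid: index j -> x = j*dx for j < M/2, (j - M)*dx above
    x = np.arange(M, dtype=float) * dx
    x[M // 2:] -= M * dx
    clip_x = transfer(x)

    if conn is not None:
        F_E, F_I = _realized_jump_transforms(conn, dx, M)
        frac_exc = conn.excitatory_ids.size / N
        F_1 = frac_exc * F_E
        if F_I is not None:
            F_1 = F_1 + (1.0 - frac_exc) * F_I
    else:
        # trapezoidal discretization of the uniform densities: exact mean
        b_E = max(1, int(round(w / dx)))
        j_E = np.zeros(M)
        j_E[0: b_E + 1] = 1.0 / b_E
        j_E[0] *= 0.5
        j_E[b_E] *= 0.5
        F_E = np.fft.rfft(j_E)
        if g > 0:
            b_I = max(1, int(round(g * w / dx)))
            j_I = np.zeros(M)
            j_I[M - b_I:] = 1.0 / b_I
            j_I[M - b_I] *= 0.5
            j_I[0] = 0.5 / b_I  # endpoint at weight 0
            F_I = np.fft.rfft(j_I)
        else:
            F_I = np.ones_like(F_E)  # zero-weight inhibitory synapses

        # one active neuron's contribution (E/I identity then presence)
        F_1 = (1.0 - a) * (1.0 - p + p * F_E) + a * (1.0 - p + p * F_I)

    lam = np.empty(S_grid.shape)
    cache: dict[int, float] = {}
    for idx, (S, k) in enumerate(zip(S_grid, ks)):
        if k not in cache:
            density = np.fft.irfft(F_1**k, M)
            cache[k] = float(np.sum(density * clip_x))
        lam[idx] = cache[k] / S
    return lam


def semianalytic_branching(
    params: ModelParams,
    S_grid: np.ndarray | None = None,
    weights: str = "distribution",
    tail_mass: float = 1e-12,
    conn=None,
) -> BranchingCurve:
    """Noise-free (semi-analytic) prediction of the branching function.

    ``weights='distribution'`` (default) propagates the full synaptic
    weight distribution through the one-step expectation and tracks the
    empirical branching function in every regime.
    ``weights='mean'`` replaces every synapse by its average strength
    (``w/2`` excitatory, ``-g w/2`` inhibitory) under Poisson presynaptic
    counts -- the classic simplification, accurate in the weak-coupling
    regime where the transfer stays linear but biased low when firing is
    fluctuation-driven.  Its double sum runs from ``n = 0`` (the
    zero-count terms carry Poisson mass even though the transfer
    vanishes there) and is truncated where the Poisson tail mass drops
    below ``tail_mass``.
    """
    N = params.N
    if S_grid is None:
        S_grid = default_S_grid(N)
    S_grid = np.asarray(S_grid, dtype=float)
    if np.any(S_grid <= 0):
        raise ValueError("S_grid must be strictly positive")

    if weights == "distribution":
        lam = _distribution_lambda(params, S_grid, conn=conn)
    elif weights == "mean":
        if conn is not None:
            raise ValueError("realized-weight curves require weights='distribution'")
        lam = _mean_weight_lambda(params, S_grid, tail_mass)
    else:
        raise ValueError(f"unknown weights mode {weights!r}")
    return BranchingCurve(S_grid=S_grid, Lambda=lam, method="semianalytic")


def _level_crossings(S: np.ndarray, L: np.ndarray, level: float) -> np.ndarray:
    """S positions where the piecewise-linear curve crosses ``level``."""
    out = []
    d = L - level
    exact = np.nonzero(d == 0)[0]
    out.extend(S[exact])
    sign_change = np.nonzero(d[:-1] * d[1:] < 0)[0]
    for i in sign_change:
        frac = d[i] / (d[i] - d[i + 1])
        out.append(S[i] + frac * (S[i + 1] - S[i]))
    return np.sort(np.array(out)) if out else np.array([])


def critical_range(curve: BranchingCurve) -> CriticalRange:
    """Critical range ``rho = S2 - S1`` between the 1.05 and 0.95 levels.

    All level crossings are located by linear interpolation between
    adjacent grid points.  With multiple 1.05 crossings the one at
    largest S is taken; S2 is then the first 0.95 crossing beyond S1.
    Fallbacks when a level is never crossed: S1 = smallest grid S,
    S2 = largest grid S with Lambda >= 0.95 (both flagged).
    """
    S, L = curve.S_grid, curve.Lambda
    if S.size < 2:
        raise ValueError("curve must cover at least two grid points")

    hi = _level_crossings(S, L, 1.05)
    if hi.size:
        S1, s1_fb = float(hi[-1]), False
    else:
        S1, s1_fb = float(S[0]), True

    lo = _level_crossings(S, L, 0.95)
    lo = lo[lo >= S1]
    if lo.size:
        S2, s2_fb = float(lo[0]), False
    else:
        ok = np.nonzero(L >= 0.95)[0]
        S2 = float(S[ok[-1]]) if ok.size else S1
        s2_fb = True
    return CriticalRange(S1=S1, S2=S2, rho=max(S2 - S1, 0.0),
                         s1_fallback=s1_fb, s2_fallback=s2_fb)


def avalanche_threshold_for(params: ModelParams, s_max: float = 0.8,
                            conn=None) -> AvalancheThreshold:
    """Avalanche threshold from the semi-analytic curve of ``params``.

    Supplying the drawn connectivity adapts the (still noise-free) curve
    to that realization, which keeps the threshold aligned with the
    realization's own fixed point.
    """
    curve = semianalytic_branching(params, default_S_grid(params.N, s_max=s_max),
                                   conn=conn)
    return avalanche_threshold(curve, params.N)


def avalanche_threshold(curve: BranchingCurve, N: int) -> AvalancheThreshold:
    """Avalanche threshold S-dagger where Lambda(S-dagger) = 1.01.

    The largest interpolated crossing of the 1.01 level is used.  When
    the curve never reaches 1.01 (flat, exactly critical curves) the
    single-neuron threshold ``S = 1/N`` is returned and flagged.
    """
    cr = _level_crossings(curve.S_grid, curve.Lambda, 1.01)
    if cr.size:
        s_dag = float(cr[-1])
        return AvalancheThreshold(
            S_dagger=s_dag, count=int(math.ceil(s_dag * N - 1e-9)), fallback=False
        )
    return AvalancheThreshold(S_dagger=1.0 / N, count=1, fallback=True)
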