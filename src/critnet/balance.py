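"""E/I input balance, input cross-correlograms, and spiking regularity.

The total synaptic input to a neuron splits into an excitatory stream
(positive weights only) and an inhibitory stream (negative weights only).
Three summary statistics characterize the asynchronous regime:

* E/I tension ``T_i = 1 - <I_i> / (<I_i^E> + <|I_i^I|>)`` measures how
  tightly inhibition cancels excitation in the time-averaged input
  (0 = no inhibition, 1 = exact mean cancellation).
* The asynchrony index ``eta = 1 - A_total / ((A_EE + A_II)/2)`` compares
  the area under the population-averaged cross-correlogram of total
  inputs with the E-only and I-only CCG areas; tight cancellation makes
  the total-input correlations vanish while the separate streams stay
  correlated, pushing ``eta`` toward 1.
* The coefficient of variation of inter-spike intervals, near 1 for
  Poisson-like firing and above 1 for bursty firing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import SpikeRaster
from .network import ConnectivityMatrix

__all__ = [
    "InputDecomposition",
    "TensionResult",
    "CCGSet",
    "ISIStats",
    "decompose_inputs",
    "tension",
    "tension_from_raster",
    "population_ccg",
    "eta",
    "isi_cv",
]


@dataclass(frozen=True)
class InputDecomposition:
    """Per-neuron E, I and total input time series.

    Row ``k`` corresponds to ``neuron_ids[k]``; column ``t`` holds the
    input generated by the population state at time ``t`` (i.e. the
    drive acting on step ``t + 1``).  ``I_E >= 0`` and ``I_I <= 0``
    elementwise, and ``I_total = I_E + I_I`` exactly.
    """

    I_E: np.ndarray
    I_I: np.ndarray
    neuron_ids: np.ndarray

    @property
    def I_total(self) -> np.ndarray:
        return self.I_E + self.I_I


@dataclass(frozen=True)
class TensionResult:
    T_i: np.ndarray
    T: float
    neuron_ids: np.ndarray
    n_excluded: int  # neurons with zero total drive


@dataclass(frozen=True)
class CCGSet:
    """Population-averaged input cross-correlograms over symmetric lags."""

    lags: np.ndarray
    ccg_total: np.ndarray
    ccg_EE: np.ndarray
    ccg_II: np.ndarray
    A_total: float
    A_EE: float
    A_II: float
    n_pairs: int


@dataclass(frozen=True)
class ISIStats:
    cv: np.ndarray
    neuron_ids: np.ndarray
    mean_cv: float
    n_excluded: int  # neurons with < min_spikes spikes


def decompose_inputs(
    conn: ConnectivityMatrix,
    raster: SpikeRaster,
    neurons=None,
    exclude_burn_in: bool = True,
) -> InputDecomposition:
    """Split the recurrent input of the given neurons into E and I streams.

    ``I^E`` uses ``J+ = max(J, 0)`` and ``I^I`` uses ``J- = min(J, 0)``,
    so the identity ``I = I^E + I^I`` holds exactly at every step.
    Restricting to a neuron subset keeps the dense output tractable for
    long runs.
    """
    if raster.N != conn.N:
        raise ValueError("raster and connectivity sizes differ")
    ids = np.arange(conn.N) if neurons is None else np.asarray(neurons, dtype=int)
    Jsub = conn.J[ids, :]
    Jp = np.clip(Jsub, 0.0, None)
    Jm = np.clip(Jsub, None, 0.0)
    S = raster.to_csc(exclude_burn_in=exclude_burn_in)
    I_E = np.asarray(Jp @ S)
    I_I = np.asarray(Jm @ S)
    return InputDecomposition(I_E=I_E, I_I=I_I, neuron_ids=ids)


def tension(decomp: InputDecomposition) -> TensionResult:
    """E/I tension per neuron and its network mean (time averages).

    Neurons whose total drive ``<I^E> + <|I^I|>`` is zero are excluded
    from the mean and counted.
    """
    mean_E = decomp.I_E.mean(axis=1)
    mean_absI = np.abs(decomp.I_I).mean(axis=1)
    return _tension_from_means(mean_E, mean_absI, decomp.neuron_ids)


def _tension_from_means(mean_E, mean_absI, neuron_ids) -> TensionResult:
    denom = mean_E + mean_absI
    ok = denom > 0
    T_i = np.full(denom.shape, np.nan)
    # <I> = <I^E> - <|I^I|> since I = I^E + I^I with I^I <= 0
    T_i[ok] = 1.0 - (mean_E[ok] - mean_absI[ok]) / denom[ok]
    if not ok.any():
        raise ValueError("no neuron receives any drive")
    return TensionResult(
        T_i=T_i,
        T=float(T_i[ok].mean()),
        neuron_ids=np.asarray(neuron_ids),
        n_excluded=int((~ok).sum()),
    )


def tension_from_raster(
    conn: ConnectivityMatrix, raster: SpikeRaster, exclude_burn_in: bool = True
) -> TensionResult:
    """Network tension via time-averaged states (no per-step input arrays).

    Time averaging commutes with the linear input maps, so
    ``<I^E> = J+ s_bar`` with ``s_bar`` the mean state vector; the result
    is identical to :func:`tension` applied to the full decomposition.
    """
    t0 = raster.burn_in if exclude_burn_in else 0
    T_window = raster.T_steps - t0
    if exclude_burn_in and raster.spike_counts is not None:
        s_bar = raster.spike_counts / T_window
    else:
        keep = raster.event_times >= t0
        s_bar = np.bincount(raster.event_ids[keep], minlength=raster.N) / T_window
    Jp = np.clip(conn.J, 0.0, None)
    Jm = np.clip(conn.J, None, 0.0)
    mean_E = Jp @ s_bar
    mean_absI = -(Jm @ s_bar)
    return _tension_from_means(mean_E, mean_absI, np.arange(conn.N))


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    valid = sd[:, 0] > 0
    Z = np.zeros_like(X)
    np.divide(X - mu, sd, out=Z, where=sd > 0)
    return Z, valid


def _pair_ccg(Z: np.ndarray, valid: np.ndarray, pairs_i, pairs_j, lags) -> np.ndarray:
    T = Z.shape[1]
    keep = valid[pairs_i] & valid[pairs_j]
    if not keep.any():
        raise ValueError("all sampled pairs have constant input series")
    pi, pj = pairs_i[keep], pairs_j[keep]
    out = np.empty(lags.shape)
    for n, lag in enumerate(lags):
        if lag >= 0:
            C = Z[:, : T - lag] @ Z[:, lag:].T / (T - lag)
        else:
            C = Z[:, -lag:] @ Z[:, : T + lag].T / (T + lag)
        out[n] = C[pi, pj].mean()
    return out


def population_ccg(
    decomp: InputDecomposition,
    max_lag: int = 20,
    n_pairs: int = 2000,
    rng=None,
) -> CCGSet:
    """Population-averaged lagged Pearson CCG of the input streams.

    For each sampled ordered neuron pair (i, j) the mean-subtracted,
    unit-variance input series are correlated at every lag in
    ``[-max_lag, max_lag]``; the population curve is the mean over pairs,
    computed for the total, E-only and I-only streams on the same pair
    sample.  Pairs involving a constant series are excluded.  Areas are
    plain sums over the lag axis (negative lobes subtract).
    """
    m, T = decomp.I_E.shape
    if m < 2:
        raise ValueError("need >= 2 neurons for a CCG")
    if T <= max_lag + 1:
        raise ValueError("series too short for the requested lags")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    all_pairs = m * (m - 1)
    if all_pairs <= n_pairs:
        flat = np.arange(m * m)
        flat = flat[flat // m != flat % m]
    else:
        flat = np.empty(0, dtype=int)
        seen = gen.choice(m * m, size=min(m * m, 3 * n_pairs), replace=False)
        flat = seen[seen // m != seen % m][:n_pairs]
    pairs_i, pairs_j = flat // m, flat % m

    lags = np.arange(-max_lag, max_lag + 1)
    Zt, vt = _standardize(decomp.I_total)
    Ze, ve = _standardize(decomp.I_E)
    Zi, vi = _standardize(decomp.I_I)
    ccg_t = _pair_ccg(Zt, vt, pairs_i, pairs_j, lags)
    ccg_e = _pair_ccg(Ze, ve, pairs_i, pairs_j, lags)
    ccg_i = _pair_ccg(Zi, vi, pairs_i, pairs_j, lags)
    return CCGSet(
        lags=lags,
        ccg_total=ccg_t,
        ccg_EE=ccg_e,
        ccg_II=ccg_i,
        A_total=float(ccg_t.sum()),
        A_EE=float(ccg_e.sum()),
        A_II=float(ccg_i.sum()),
        n_pairs=int(pairs_i.size),
    )


def eta(ccgs: CCGSet) -> float:
    """Asynchrony index ``eta = 1 - A_total / ((A_EE + A_II)/2)``."""
    denom = (ccgs.A_EE + ccgs.A_II) / 2.0
    if denom == 0:
        raise ValueError("degenerate CCG areas: A_EE + A_II = 0")
    return 1.0 - ccgs.A_total / denom


def isi_cv(raster: SpikeRaster, min_spikes: int = 3) -> ISIStats:
    """Per-neuron inter-spike-interval coefficient of variation.

    ISIs are differences of discrete spike times after the burn-in.
    Neurons with fewer than ``min_spikes`` spikes are excluded from the
    population mean and counted.

    Rasters produced by the simulator carry single-pass ISI moment
    accumulators; those are used directly so that saturated runs (~10^8
    events) never need a per-neuron sort.  Both paths compute the same
    statistic.
    """
    if raster.isi_moments is not None and raster.spike_counts is not None:
        n, s, ss = raster.isi_moments
        ok = raster.spike_counts >= min_spikes
        ids = np.nonzero(ok)[0]
        mean = s[ok] / n[ok]
        var = np.maximum(ss[ok] / n[ok] - mean**2, 0.0)
        cvs = np.where(mean > 0, np.sqrt(var) / mean, 0.0)
    else:
        trains = raster.spike_times_by_neuron(exclude_burn_in=True)
        cvs, ids = [], []
        for i, times in enumerate(trains):
            if times.size < min_spikes:
                continue
            isi = np.diff(times).astype(float)
            m = isi.mean()
            cvs.append(isi.std() / m if m > 0 else 0.0)
            ids.append(i)
        cvs, ids = np.array(cvs), np.array(ids, dtype=int)
    if len(cvs) == 0:
        raise ValueError("no neuron fired enough spikes for an ISI CV")
    return ISIStats(
        cv=np.asarray(cvs),
        neuron_ids=np.asarray(ids),
        mean_cv=float(np.asarray(cvs).mean()),
        n_excluded=int(raster.N - len(cvs)),
    )
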