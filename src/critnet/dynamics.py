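"""Probabilistic binary dynamics and spike rasters.

Each neuron is either active (1) or quiescent (0).  At every step the
recurrent input ``I_i = sum_j J_ij s_j(t-1)`` sets the recurrent firing
probability through the clamped-linear transfer

    p_i = 1        for I_i >= 1
    p_i = I_i      for 0 <= I_i < 1
    p_i = 0        for I_i < 0,

after which the external drive ``p_ext`` is applied as an independent
chance to fire, so the effective probability is
``1 - (1 - p_i)(1 - p_ext)``.  The whole population updates synchronously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from ._kernels import run_dynamics
from .network import ConnectivityMatrix
from .params import ModelParams, SimulationConfig

__all__ = [
    "SpikeRaster",
    "RateSeries",
    "synaptic_input",
    "transfer",
    "step",
    "simulate",
    "population_rate",
]


def transfer(I: np.ndarray) -> np.ndarray:
    """Clamped-linear transfer sigma(I): probability of firing from input I."""
    return np.clip(I, 0.0, 1.0)


def synaptic_input(J, state: np.ndarray) -> np.ndarray:
    """Total recurrent input ``I_i = sum_j J_ij s_j`` for one state vector."""
    M = J.J if isinstance(J, ConnectivityMatrix) else np.asarray(J, dtype=float)
    s = np.asarray(state)
    if s.shape != (M.shape[1],):
        raise ValueError(
            f"state length {s.shape} does not match J columns {M.shape[1]}"
        )
    return M @ s.astype(float)


def step(J, state: np.ndarray, p_ext: float, rng: np.random.Generator) -> np.ndarray:
    """One synchronous update; reference implementation of the map.

    The production path (:func:`simulate`) runs a compiled kernel with the
    same transfer and drive combination; this NumPy version is kept for
    small fixtures and deterministic checks.
    """
    I = synaptic_input(J, state)
    p = transfer(I)
    p_tot = p + (1.0 - p) * p_ext
    return (rng.random(p_tot.shape) < p_tot).astype(np.uint8)


@dataclass
class SpikeRaster:
    """Binary neurons x time activity, stored as a spike-event list.

    ``counts[t]`` is the number of active neurons at step ``t``; the
    event arrays list (time, neuron) pairs in time order.  Column 0 is
    the initial condition.  The first ``burn_in`` columns are a
    transient that analysis routines discard.
    """

    event_times: np.ndarray
    event_ids: np.ndarray
    counts: np.ndarray
    N: int
    T_steps: int
    burn_in: int = 0
    params: ModelParams | None = None
    config: SimulationConfig | None = None
    seed: int | None = None
    # kernel-accumulated post-burn-in per-neuron summaries (optional);
    # large saturated runs are analysed without re-sorting the event list
    spike_counts: np.ndarray | None = None
    isi_moments: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    @property
    def n_spikes(self) -> int:
        return int(self.event_times.shape[0])

    def counts_post_burn_in(self) -> np.ndarray:
        return self.counts[self.burn_in:]

    def to_dense(self, exclude_burn_in: bool = False) -> np.ndarray:
        """Dense binary (N, T) array; intended for small rasters."""
        dense = np.zeros((self.N, self.T_steps), dtype=np.uint8)
        dense[self.event_ids, self.event_times] = 1
        return dense[:, self.burn_in:] if exclude_burn_in else dense

    def to_csc(self, exclude_burn_in: bool = False) -> sparse.csc_matrix:
        """Sparse binary (N, T) matrix in CSC form (fast column slicing)."""
        t0 = self.burn_in if exclude_burn_in else 0
        keep = self.event_times >= t0
        mat = sparse.csc_matrix(
            (
                np.ones(int(keep.sum()), dtype=np.float64),
                (self.event_ids[keep], self.event_times[keep] - t0),
            ),
            shape=(self.N, self.T_steps - t0),
        )
        return mat

    def spike_times_by_neuron(self, exclude_burn_in: bool = True) -> list[np.ndarray]:
        """Per-neuron arrays of spike times (steps)."""
        t0 = self.burn_in if exclude_burn_in else 0
        keep = self.event_times >= t0
        ids = self.event_ids[keep]
        times = self.event_times[keep]
        order = np.argsort(ids, kind="stable")
        ids, times = ids[order], times[order]
        bounds = np.searchsorted(ids, np.arange(self.N + 1))
        return [times[bounds[i]: bounds[i + 1]] for i in range(self.N)]

    @classmethod
    def from_dense(cls, dense: np.ndarray, burn_in: int = 0, **kwargs) -> "SpikeRaster":
        dense = np.asarray(dense)
        if not np.isin(dense, (0, 1)).all():
            raise ValueError("raster entries must be binary")
        ids, times = np.nonzero(dense)
        order = np.argsort(times, kind="stable")
        return cls(
            event_times=times[order].astype(np.int32),
            event_ids=ids[order].astype(np.int32),
            counts=dense.sum(axis=0).astype(np.int64),
            N=dense.shape[0],
            T_steps=dense.shape[1],
            burn_in=burn_in,
            **kwargs,
        )


@dataclass(frozen=True)
class RateSeries:
    """Population activity fraction S(t) with its time mean and std."""

    S: np.ndarray
    mean_rate: float
    std_rate: float


def simulate(conn: ConnectivityMatrix, config: SimulationConfig) -> SpikeRaster:
    """Run the binary dynamics and return the spike raster.

    Deterministic given ``(conn.J, seed)``.  The seed comes from
    ``config.seed`` (falling back to ``conn.params.seed``); one stream
    picks the initial active set and an independent derived stream drives
    the kernel.
    """
    params = conn.params
    seed = config.seed if config.seed is not None else params.seed
    if seed is None:
        raise ValueError("simulate requires a seed (config.seed or params.seed)")

    ss = np.random.SeedSequence(int(seed))
    s_init, s_kernel = ss.generate_state(2)
    rng = np.random.default_rng(s_init)
    k = config.n_initial(params.N)
    init_ids = rng.choice(params.N, size=k, replace=False).astype(np.int64)

    JT = np.ascontiguousarray(conn.J.T)
    ev_t, ev_i, counts, spike_counts, isi_n, isi_s, isi_ss = run_dynamics(
        JT,
        int(config.T_steps),
        float(params.p_ext),
        int(s_kernel & 0x7FFFFFFF),
        init_ids,
        int(config.burn_in),
    )
    return SpikeRaster(
        event_times=ev_t,
        event_ids=ev_i,
        counts=counts,
        N=params.N,
        T_steps=config.T_steps,
        burn_in=config.burn_in,
        params=params,
        config=config,
        seed=int(seed),
        spike_counts=spike_counts,
        isi_moments=(isi_n, isi_s, isi_ss),
    )


def population_rate(raster, exclude_burn_in: bool = True) -> RateSeries:
    """Fraction of active neurons per step, with time mean and std.

    Accepts a :class:`SpikeRaster` or a dense binary (N, T) array (the
    latter is used as-is, with no burn-in handling).
    """
    if isinstance(raster, SpikeRaster):
        counts = (
            raster.counts_post_burn_in() if exclude_burn_in else raster.counts
        )
        if counts.size == 0:
            raise ValueError("empty raster after burn-in removal")
        S = counts / raster.N
    else:
        dense = np.asarray(raster)
        if dense.size == 0:
            raise ValueError("empty raster")
        if not np.isin(dense, (0, 1)).all():
            raise ValueError("raster entries must be binary")
        S = dense.mean(axis=0)
    return RateSeries(S=S, mean_rate=float(S.mean()), std_rate=float(S.std()))
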