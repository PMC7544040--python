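"""Numba kernel for the inner simulation loop.

The update is a synchronous discrete-time map: every neuron computes its
recurrent input from the previous population state, converts it to a
firing probability through the clamped-linear transfer, folds in the
external drive, and draws one Bernoulli variate.  The kernel walks the
transposed matrix so that each active presynaptic neuron contributes one
contiguous row, keeping the cost proportional to the number of active
neurons rather than N^2.

Besides the spike-event list the kernel accumulates, post burn-in,
per-neuron spike counts and inter-spike-interval moments in a single
pass; saturated runs can emit ~10^8 events, and the downstream
statistics should not have to sort them.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def run_dynamics(JT, T, p_ext, seed, init_ids, burn_in):  # pragma: no cover - jitted
    """Iterate the binary dynamics for T recorded steps.

    Parameters
    ----------
    JT : (N, N) float64, C-contiguous
        Transposed connectivity: row j holds the outgoing weights of
        neuron j (column j of J).
    T : int
        Number of recorded raster columns; column 0 is the initial state.
    p_ext : float
        Per-neuron external firing probability per step.
    seed : int
        Seed for the kernel RNG (31-bit).
    init_ids : int64 array
        Neurons active in the initial state.
    burn_in : int
        Steps excluded from the per-neuron spike-count and ISI moments.

    Returns
    -------
    (event_times, event_ids, counts, spike_counts,
     isi_count, isi_sum, isi_sumsq)
        Spike events in time order (int32), the active-neuron count per
        step, and the post-burn-in per-neuron accumulators.
    """
    N = JT.shape[0]
    np.random.seed(seed)

    state = np.zeros(N, np.uint8)
    for k in range(init_ids.shape[0]):
        state[init_ids[k]] = np.uint8(1)

    counts = np.zeros(T, np.int64)
    cap = 1 << 16
    ev_t = np.empty(cap, np.int32)
    ev_i = np.empty(cap, np.int32)
    ne = 0

    spike_counts = np.zeros(N, np.int64)
    last_spike = np.full(N, -1, np.int64)
    isi_count = np.zeros(N, np.int64)
    isi_sum = np.zeros(N, np.float64)
    isi_sumsq = np.zeros(N, np.float64)

    I = np.zeros(N, np.float64)

    for t in range(T):
        c = 0
        for i in range(N):
            if state[i] == 1:
                if ne >= cap:
                    cap *= 2
                    tmp_t = np.empty(cap, np.int32)
                    tmp_t[:ne] = ev_t[:ne]
                    ev_t = tmp_t
                    tmp_i = np.empty(cap, np.int32)
                    tmp_i[:ne] = ev_i[:ne]
                    ev_i = tmp_i
                ev_t[ne] = t
                ev_i[ne] = i
                ne += 1
                c += 1
                if t >= burn_in:
                    spike_counts[i] += 1
                    if last_spike[i] >= burn_in:
                        dt = float(t - last_spike[i])
                        isi_count[i] += 1
                        isi_sum[i] += dt
                        isi_sumsq[i] += dt * dt
                    last_spike[i] = t
        counts[t] = c
        if t == T - 1:
            break

        for i in range(N):
            I[i] = 0.0
        for j in range(N):
            if state[j] == 1:
                row = JT[j]
                for i in range(N):
                    I[i] += row[i]

        for i in range(N):
            pi = I[i]
            if pi >= 1.0:
                pf = 1.0
            elif pi <= 0.0:
                pf = p_ext
            else:
                # recurrent draw OR independent external draw
                pf = pi + (1.0 - pi) * p_ext
            if np.random.random() < pf:
                state[i] = np.uint8(1)
            else:
                state[i] = np.uint8(0)

    return (
        ev_t[:ne].copy(),
        ev_i[:ne].copy(),
        counts,
        spike_counts,
        isi_count,
        isi_sum,
        isi_sumsq,
    )
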