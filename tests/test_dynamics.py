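import numpy as np
import pytest
from hypothesis import given, strategies as st

import critnet as cn
from critnet import ModelParams, SimulationConfig
from critnet.network import ConnectivityMatrix


def _conn_from_matrix(J, alpha=0.0, p_ext=0.0, seed=0):
    N = J.shape[0]
    n_inh = int(round(alpha * N))
    params = ModelParams(N=N, p=0.5, alpha=n_inh / N, w=1.0, g=1.0,
                         p_ext=p_ext, seed=seed)
    return ConnectivityMatrix(
        J=np.asarray(J, dtype=float),
        excitatory_ids=np.arange(N - n_inh),
        inhibitory_ids=np.arange(N - n_inh, N),
        params=params,
        seed=seed,
    )


class TestSynapticInput:
    def test_zero_state_gives_zero_input(self, three_neuron_J):
        assert np.array_equal(
            cn.synaptic_input(three_neuron_J, np.zeros(3)), np.zeros(3)
        )

    def test_single_active_neuron_selects_its_column(self, three_neuron_J):
        state = np.array([0, 1, 0])
        assert np.array_equal(
            cn.synaptic_input(three_neuron_J, state), three_neuron_J[:, 1]
        )

    def test_hand_traced_two_active_neurons(self, three_neuron_J):
        # row sums over columns 1 and 2: [0.5, 0.3, 0.1+0.2]
        out = cn.synaptic_input(three_neuron_J, np.array([1, 1, 0]))
        assert np.allclose(out, [0.5, 0.3, 0.3])

    def test_dimension_mismatch_rejected(self, three_neuron_J):
        with pytest.raises(ValueError):
            cn.synaptic_input(three_neuron_J, np.zeros(4))


class TestStep:
    def test_saturated_input_fires_with_certainty(self):
        J = np.array([[0.0, 2.0], [2.0, 0.0]])
        rng = np.random.default_rng(0)
        nxt = cn.step(J, np.array([1, 1]), p_ext=0.0, rng=rng)
        assert nxt.tolist() == [1, 1]

    def test_negative_input_without_drive_is_silent(self):
        J = np.array([[0.0, -1.0], [-1.0, 0.0]])
        rng = np.random.default_rng(0)
        nxt = cn.step(J, np.array([1, 1]), p_ext=0.0, rng=rng)
        assert nxt.tolist() == [0, 0]

    def test_external_drive_rate_with_no_coupling(self):
        # J = 0: per-neuron firing probability is exactly p_ext
        N, T, p_ext = 200, 2000, 0.02
        J = np.zeros((N, N))
        rng = np.random.default_rng(1)
        state = np.zeros(N, dtype=np.uint8)
        total = 0
        for _ in range(T):
            state = cn.step(J, state, p_ext=p_ext, rng=rng)
            total += state.sum()
        expected = N * T * p_ext
        sd = np.sqrt(N * T * p_ext * (1 - p_ext))
        assert abs(total - expected) < 4 * sd


class TestSimulate:
    def test_quiescent_state_is_absorbing_without_drive(self):
        conn = _conn_from_matrix(np.zeros((4, 4)), p_ext=0.0)
        raster = cn.simulate(conn, SimulationConfig(T_steps=50, burn_in=0,
                                                    initial_active=0, seed=0))
        assert raster.n_spikes == 0
        assert raster.counts.sum() == 0

    def test_binary_closure_and_count_consistency(self):
        params = ModelParams(N=100, p=0.3, alpha=0.2, w=0.05, g=1.0, seed=3)
        conn = cn.build_connectivity(params)
        raster = cn.simulate(conn, SimulationConfig(T_steps=300, burn_in=0,
                                                    initial_active=10, seed=3))
        dense = raster.to_dense()
        assert set(np.unique(dense)) <= {0, 1}
        assert np.array_equal(dense.sum(axis=0), raster.counts)

    def test_bit_exact_seed_reproducibility(self):
        params = ModelParams(N=100, p=0.3, alpha=0.2, w=0.05, g=1.0)
        conn = cn.build_connectivity(params, rng=5)
        cfg = SimulationConfig(T_steps=500, burn_in=0, initial_active=5, seed=11)
        a = cn.simulate(conn, cfg)
        b = cn.simulate(conn, cfg)
        c = cn.simulate(conn, SimulationConfig(T_steps=500, burn_in=0,
                                               initial_active=5, seed=12))
        assert np.array_equal(a.event_times, b.event_times)
        assert np.array_equal(a.event_ids, b.event_ids)
        assert not (
            np.array_equal(a.event_times, c.event_times)
            and np.array_equal(a.event_ids, c.event_ids)
        )

    def test_kernel_matches_reference_map_on_deterministic_cascade(self):
        # ring of weight-2 synapses: saturated probabilities, no randomness
        N = 6
        J = np.zeros((N, N))
        for j in range(N):
            J[(j + 1) % N, j] = 2.0
        conn = _conn_from_matrix(J, p_ext=0.0)
        cfg = SimulationConfig(T_steps=10, burn_in=0, initial_active=1, seed=4)
        dense = cn.simulate(conn, cfg).to_dense()
        # iterate the NumPy reference map from the kernel's initial column
        state = dense[:, 0].copy()
        rng = np.random.default_rng(0)  # irrelevant: dynamics are saturated
        for t in range(1, 10):
            state = cn.step(J, state, 0.0, rng)
            assert np.array_equal(dense[:, t], state)
        assert np.array_equal(dense.sum(axis=0), np.ones(10))

    def test_requires_a_seed(self):
        conn = _conn_from_matrix(np.zeros((4, 4)))
        conn = ConnectivityMatrix(conn.J, conn.excitatory_ids, conn.inhibitory_ids,
                                  conn.params.with_(seed=None), None)
        with pytest.raises(ValueError):
            cn.simulate(conn, SimulationConfig(T_steps=10, burn_in=0, seed=None))


class TestPopulationRate:
    def test_all_active_raster(self):
        rs = cn.population_rate(np.ones((4, 6), dtype=np.uint8))
        assert rs.mean_rate == 1.0 and rs.std_rate == 0.0

    def test_alternating_population(self):
        dense = np.zeros((4, 6), dtype=np.uint8)
        dense[:, ::2] = 1
        rs = cn.population_rate(dense)
        assert rs.mean_rate == pytest.approx(0.5)
        assert rs.std_rate == pytest.approx(0.5)

    def test_hand_counted_fixture(self):
        dense = np.zeros((4, 3), dtype=np.uint8)
        dense[:2, 0] = 1       # 2 spikes
        dense[0, 1] = 1        # 1 spike
        dense[:3, 2] = 1       # 3 spikes
        rs = cn.population_rate(dense)
        assert np.allclose(rs.S, [0.5, 0.25, 0.75])

    def test_burn_in_excluded_from_raster_statistics(self):
        dense = np.zeros((2, 10), dtype=np.uint8)
        dense[:, :5] = 1  # activity only during burn-in
        raster = cn.SpikeRaster.from_dense(dense, burn_in=5)
        rs = cn.population_rate(raster)
        assert rs.mean_rate == 0.0


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_mean_drive_matches_p_ext_without_coupling(seed):
    """With J = 0 the per-neuron rate is p_ext (binomial tolerance)."""
    N, T, p_ext = 50, 400, 0.05
    conn = _conn_from_matrix(np.zeros((N, N)), p_ext=p_ext)
    raster = cn.simulate(
        conn, SimulationConfig(T_steps=T, burn_in=0, initial_active=0, seed=seed)
    )
    expected = N * (T - 1) * p_ext  # column 0 is the (empty) initial state
    sd = np.sqrt(N * (T - 1) * p_ext * (1 - p_ext))
    assert abs(raster.n_spikes - expected) < 5 * sd
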