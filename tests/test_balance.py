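import numpy as np
import pytest
from hypothesis import given, strategies as st

import critnet as cn
from critnet import CCGSet, InputDecomposition, ModelParams, SimulationConfig
from critnet.network import ConnectivityMatrix


def _small_run(g=1.0, N=60, T=400, seed=2):
    n_inh = int(0.2 * N)
    params = ModelParams(N=N, p=0.3, alpha=n_inh / N, w=0.08, g=g,
                         p_ext=0.01, seed=seed)
    conn = cn.build_connectivity(params)
    raster = cn.simulate(conn, SimulationConfig(T_steps=T, burn_in=50,
                                                initial_active=8, seed=seed))
    return conn, raster


class TestDecomposeInputs:
    def test_streams_sum_to_total_input_exactly(self):
        conn, raster = _small_run()
        decomp = cn.decompose_inputs(conn, raster, exclude_burn_in=False)
        dense = raster.to_dense().astype(float)
        assert np.allclose(decomp.I_total, conn.J @ dense)
        assert (decomp.I_E >= 0).all() and (decomp.I_I <= 0).all()

    def test_no_inhibition_means_no_inhibitory_stream(self):
        conn, raster = _small_run(g=0.0)
        decomp = cn.decompose_inputs(conn, raster)
        assert np.all(decomp.I_I == 0)

    def test_hand_traced_three_neuron_streams(self, three_neuron_J):
        params = ModelParams(N=3, p=0.9, alpha=1 / 3, w=1.0, g=1.0, seed=0)
        conn = ConnectivityMatrix(three_neuron_J, np.arange(2), np.array([2]), params)
        dense = np.array([[0], [1], [1]], dtype=np.uint8)
        raster = cn.SpikeRaster.from_dense(dense)
        decomp = cn.decompose_inputs(conn, raster, exclude_burn_in=False)
        assert np.allclose(decomp.I_E[:, 0], [0.5, 0.0, 0.2])
        assert np.allclose(decomp.I_I[:, 0], [-0.2, -0.4, 0.0])

    def test_quiescent_step_gives_zero_streams(self, three_neuron_J):
        params = ModelParams(N=3, p=0.9, alpha=1 / 3, w=1.0, g=1.0, seed=0)
        conn = ConnectivityMatrix(three_neuron_J, np.arange(2), np.array([2]), params)
        raster = cn.SpikeRaster.from_dense(np.zeros((3, 2), dtype=np.uint8))
        decomp = cn.decompose_inputs(conn, raster, exclude_burn_in=False)
        assert not decomp.I_E.any() and not decomp.I_I.any()


class TestTension:
    def test_zero_without_inhibition(self):
        conn, raster = _small_run(g=0.0)
        res = cn.tension(cn.decompose_inputs(conn, raster))
        assert res.T == pytest.approx(0.0, abs=1e-12)

    def test_one_under_exact_mean_cancellation(self):
        rng = np.random.default_rng(0)
        x = rng.random((5, 100)) + 0.1
        decomp = InputDecomposition(I_E=x, I_I=-x, neuron_ids=np.arange(5))
        assert cn.tension(decomp).T == pytest.approx(1.0)

    def test_time_averaged_path_matches_full_decomposition(self):
        conn, raster = _small_run(g=2.0)
        slow = cn.tension(cn.decompose_inputs(conn, raster))
        fast = cn.tension_from_raster(conn, raster)
        assert fast.T == pytest.approx(slow.T, abs=1e-12)
        assert np.allclose(fast.T_i, slow.T_i, equal_nan=True)

    def test_undriven_neurons_excluded_and_counted(self):
        I_E = np.array([[1.0, 1.0], [0.0, 0.0]])
        I_I = np.zeros((2, 2))
        res = cn.tension(InputDecomposition(I_E, I_I, np.arange(2)))
        assert res.n_excluded == 1
        assert np.isnan(res.T_i[1])

    @given(st.integers(min_value=0, max_value=10**6))
    def test_bounded_between_zero_and_two(self, seed):
        rng = np.random.default_rng(seed)
        I_E = rng.random((8, 50)) * rng.random()
        I_I = -rng.random((8, 50)) * rng.random()
        res = cn.tension(InputDecomposition(I_E, I_I, np.arange(8)))
        ok = ~np.isnan(res.T_i)
        assert ((res.T_i[ok] >= 0) & (res.T_i[ok] <= 2)).all()


class TestPopulationCCG:
    def test_identical_series_fully_correlated_at_zero_lag(self):
        t = np.sin(np.linspace(0, 20, 3000)) + np.random.default_rng(0).random(3000)
        X = np.tile(t, (4, 1))
        decomp = InputDecomposition(I_E=X, I_I=-0.5 * X, neuron_ids=np.arange(4))
        ccg = cn.population_ccg(decomp, max_lag=5, rng=0)
        mid = ccg.lags.tolist().index(0)
        assert ccg.ccg_total[mid] == pytest.approx(1.0)
        assert ccg.ccg_EE[mid] == pytest.approx(1.0)

    def test_independent_noise_decorrelates(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(16, 20_000))
        decomp = InputDecomposition(I_E=np.abs(X), I_I=X - np.abs(X),
                                    neuron_ids=np.arange(16))
        ccg = cn.population_ccg(decomp, max_lag=5, rng=1)
        assert np.abs(ccg.ccg_total).max() < 0.02

    def test_eta_invariant_under_positive_rescaling(self):
        conn, raster = _small_run(g=2.0, T=2000)
        ids = np.arange(20)
        d1 = cn.decompose_inputs(conn, raster, neurons=ids)
        d2 = InputDecomposition(I_E=3.7 * d1.I_E, I_I=3.7 * d1.I_I,
                                neuron_ids=ids)
        e1 = cn.eta(cn.population_ccg(d1, rng=5))
        e2 = cn.eta(cn.population_ccg(d2, rng=5))
        assert e1 == pytest.approx(e2, abs=1e-10)

    def test_too_short_series_rejected(self):
        decomp = InputDecomposition(I_E=np.ones((3, 10)), I_I=np.zeros((3, 10)),
                                    neuron_ids=np.arange(3))
        with pytest.raises(ValueError):
            cn.population_ccg(decomp, max_lag=20)


class TestEta:
    def _ccgs(self, a_tot, a_ee, a_ii):
        lags = np.arange(-2, 3)
        z = np.zeros(5)
        return CCGSet(lags, z, z, z, a_tot, a_ee, a_ii, n_pairs=10)

    def test_zero_when_total_area_matches_stream_mean(self):
        assert cn.eta(self._ccgs(1.0, 1.2, 0.8)) == pytest.approx(0.0)

    def test_one_when_total_input_decorrelates(self):
        assert cn.eta(self._ccgs(0.0, 1.0, 1.0)) == pytest.approx(1.0)

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ValueError):
            cn.eta(self._ccgs(0.5, 1.0, -1.0))


class TestISICV:
    def test_periodic_train_has_zero_cv(self):
        dense = np.zeros((3, 200), dtype=np.uint8)
        dense[:, ::10] = 1
        stats = cn.isi_cv(cn.SpikeRaster.from_dense(dense))
        assert np.allclose(stats.cv, 0.0)
        assert stats.mean_cv == 0.0

    def test_bernoulli_spiking_is_poisson_like(self):
        rng = np.random.default_rng(4)
        dense = (rng.random((20, 100_000)) < 0.01).astype(np.uint8)
        stats = cn.isi_cv(cn.SpikeRaster.from_dense(dense))
        # geometric ISIs: CV = sqrt(1 - p) ~ 0.995
        assert stats.mean_cv == pytest.approx(1.0, rel=0.05)

    def test_sparse_neurons_excluded_from_mean(self):
        dense = np.zeros((2, 100), dtype=np.uint8)
        dense[0, ::10] = 1
        dense[1, 3] = 1  # a single spike: no ISI
        stats = cn.isi_cv(cn.SpikeRaster.from_dense(dense))
        assert stats.n_excluded == 1
        assert stats.neuron_ids.tolist() == [0]

    def test_kernel_moment_path_matches_event_path(self):
        conn, raster = _small_run(g=1.0, T=3000)
        assert raster.isi_moments is not None
        fast = cn.isi_cv(raster)
        bare = cn.SpikeRaster(
            event_times=raster.event_times,
            event_ids=raster.event_ids,
            counts=raster.counts,
            N=raster.N,
            T_steps=raster.T_steps,
            burn_in=raster.burn_in,
        )
        slow = cn.isi_cv(bare)
        assert np.array_equal(fast.neuron_ids, slow.neuron_ids)
        assert np.allclose(fast.cv, slow.cv)
        assert fast.n_excluded == slow.n_excluded

    def test_silent_raster_rejected(self):
        with pytest.raises(ValueError):
            cn.isi_cv(cn.SpikeRaster.from_dense(np.zeros((4, 50), dtype=np.uint8)))
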