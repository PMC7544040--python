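"""Shared fixtures.

The heavy session-scoped fixtures run the boundary simulations once and
hand the derived statistics to every test that needs them.  Study
conditions: N = 1000 networks on the lambda_max = 1 boundary, 2x10^5
post-burn-in steps, five quenched realizations per point.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import critnet as cn

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

SEEDS = (1, 2, 3, 4, 5)
FULL_CONFIG = dict(T_steps=210_000, burn_in=10_000)  # 2e5 analysed steps
SHORT_CONFIG = dict(T_steps=60_000, burn_in=10_000)


@pytest.fixture(scope="session")
def base_params() -> cn.ModelParams:
    return cn.ModelParams()


def _regime_stats(g: float, seed: int, T_steps: int, burn_in: int,
                  base: cn.ModelParams) -> dict:
    """Simulate one boundary realization and derive the statistic set."""
    w = cn.solve_boundary_weight(g, base)
    params = base.with_(g=g, w=w)
    conn = cn.build_connectivity(params, rng=seed)
    raster = cn.simulate(conn, cn.SimulationConfig(T_steps=T_steps,
                                                   burn_in=burn_in, seed=seed))
    thr = cn.avalanche_threshold_for(params, conn=conn)
    cat = cn.detect_avalanches(raster.counts_post_burn_in(), thr.count)
    out = {
        "g": g,
        "w": w,
        "seed": seed,
        "threshold": thr.count,
        "threshold_fallback": thr.fallback,
        "sizes": cat.sizes,
        "durations": cat.durations,
        "n_avalanches": cat.n_avalanches,
        "mean_rate": float(raster.counts_post_burn_in().mean()) / params.N,
        "T": cn.tension_from_raster(conn, raster).T,
        "mean_CV": cn.isi_cv(raster).mean_cv,
        "kappa_size": np.nan,
        "kappa_duration": np.nan,
        "eta": np.nan,
    }
    if cat.n_avalanches >= 2 and cat.sizes.min() < cat.sizes.max():
        out["kappa_size"] = cn.kappa(cat.sizes, 1.5).kappa
        out["kappa_duration"] = cn.kappa(cat.durations, 1.7).kappa
    if params.g > 0:
        rng = np.random.default_rng(cn.spawn_seed(seed, 7))
        ids = rng.choice(params.N, size=64, replace=False)
        window = min(50_000, T_steps - burn_in)
        sub = cn.experiments.SpikeRasterWindow(raster, window).raster
        decomp = cn.decompose_inputs(conn, sub, neurons=ids)
        out["eta"] = cn.eta(cn.population_ccg(decomp, n_pairs=2000, rng=rng))
    return out


@pytest.fixture(scope="session")
def critical_runs(base_params) -> list[dict]:
    """Five realizations at g = 0, w = 0.0125 (critical end of the boundary)."""
    return [_regime_stats(0.0, s, base=base_params, **FULL_CONFIG) for s in SEEDS]


@pytest.fixture(scope="session")
def asynchronous_runs(base_params) -> list[dict]:
    """Five realizations at g = 4, w = w*(4) (asynchronous end)."""
    return [_regime_stats(4.0, s, base=base_params, **FULL_CONFIG) for s in SEEDS]


@pytest.fixture(scope="session")
def intermediate_runs(base_params) -> dict[float, list[dict]]:
    """Shorter runs at intermediate I/E ratios (the CCG uses a 50k-step
    window regardless of run length); two realizations suffice at g = 3,
    whose high-rate boundary state makes runs expensive."""
    out: dict[float, list[dict]] = {}
    for g, seeds in ((1.0, SEEDS), (2.0, SEEDS), (3.0, SEEDS[:2])):
        out[g] = [_regime_stats(g, s, base=base_params, **SHORT_CONFIG)
                  for s in seeds]
    return out


@pytest.fixture()
def three_neuron_J() -> np.ndarray:
    """Hand-traceable 3-neuron coupling (neuron 3 inhibitory)."""
    return np.array(
        [
            [0.0, 0.5, -0.2],
            [0.3, 0.0, -0.4],
            [0.1, 0.2, 0.0],
        ]
    )
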