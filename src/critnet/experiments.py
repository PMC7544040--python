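"""Parameter sweeps and boundary scans.

These orchestrators regenerate, at desk scale, the tables underlying the
model's phase diagrams (rate and fluctuation maps over the (g, w) plane)
and boundary scans (the full statistic suite along the lambda_max = 1
line).  One master seed deterministically spawns per-cell child seeds so
any cell can be recomputed in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .avalanches import detect_avalanches, fit_exponent, kappa, sample_zeta
from .balance import decompose_inputs, eta, isi_cv, population_ccg, tension_from_raster
from .branching import (
    avalanche_threshold_for,
    critical_range,
    default_S_grid,
    semianalytic_branching,
)
from .dynamics import population_rate, simulate
from .network import build_connectivity, solve_boundary_weight, theoretical_eigen
from .params import ModelParams, SimulationConfig
from .seeding import spawn_seed

__all__ = [
    "SweepSpec",
    "config_hash",
    "run_single_point",
    "run_phase_diagram",
    "run_boundary_scan",
    "make_fixtures",
]

log = logging.getLogger("critnet")


@dataclass(frozen=True)
class SweepSpec:
    """Grid or boundary sweep description."""

    g_values: tuple
    w_values: tuple | None = None  # None with on_boundary=True
    on_boundary: bool = False
    n_seeds: int = 5
    master_seed: int = 0
    params: ModelParams = field(default_factory=ModelParams)
    config: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if len(self.g_values) == 0:
            raise ValueError("g_values must be nonempty")
        if not self.on_boundary and (self.w_values is None or len(self.w_values) == 0):
            raise ValueError("w_values must be nonempty unless on_boundary is set")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")


def config_hash(*objs) -> str:
    """Short content hash of parameter objects, for output provenance."""
    payload = json.dumps(
        [dataclasses.asdict(o) if dataclasses.is_dataclass(o) else o for o in objs],
        sort_keys=True,
        default=str,
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def run_single_point(
    params: ModelParams,
    config: SimulationConfig,
    seed: int,
    full_stats: bool = True,
    eps_size: float = 1.5,
    eps_duration: float = 1.7,
    s_max: float = 0.8,
    ccg_window: int = 50_000,
    ccg_neurons: int = 64,
    ccg_pairs: int = 2000,
) -> dict:
    """One (g, w, seed) cell: simulate and compute the statistic suite.

    Light mode (``full_stats=False``) records only rates and the
    eigenvalue theory; full mode adds the branching-derived threshold
    and critical range, avalanche statistics, tension, asynchrony and
    ISI CV.  Statistics that cannot be computed (e.g. zero avalanches)
    are reported as NaN with a reason flag, never as silent zeros.
    """
    th = theoretical_eigen(params)
    conn = build_connectivity(params, rng=seed)
    raster = simulate(conn, replace(config, seed=seed))
    rates = population_rate(raster)
    rec = {
        "g": params.g,
        "w": params.w,
        "seed": seed,
        "mean_rate": rates.mean_rate,
        "std_rate": rates.std_rate,
        "lambda_b": th.lambda_b,
        "R": th.R,
        "lambda_max_theory": th.lambda_max,
        "n_spikes": raster.n_spikes,
        "flags": "",
    }
    if not full_stats:
        return rec

    flags = []
    curve = semianalytic_branching(params, default_S_grid(params.N, s_max=s_max))
    cr = critical_range(curve)
    # threshold from the realization-adapted (noise-free) curve
    thr = avalanche_threshold_for(params, s_max=s_max, conn=conn)
    rec.update(
        rho=cr.rho,
        S_dagger=thr.S_dagger,
        threshold=thr.count,
    )
    if thr.fallback:
        flags.append("threshold_fallback")

    cat = detect_avalanches(raster.counts_post_burn_in(), thr.count)
    rec["n_avalanches"] = cat.n_avalanches
    rec.update(
        kappa_size=np.nan,
        kappa_duration=np.nan,
        epsilon_hat_size=np.nan,
        epsilon_hat_duration=np.nan,
    )
    if cat.n_avalanches >= 2 and cat.sizes.min() < cat.sizes.max():
        rec["kappa_size"] = kappa(cat.sizes, eps_size).kappa
        rec["kappa_duration"] = kappa(cat.durations, eps_duration).kappa
        # support starts at the smallest attainable value (threshold-bound)
        fit_s = fit_exponent(cat.sizes, x_min=int(cat.sizes.min()))
        fit_d = fit_exponent(cat.durations, x_min=int(cat.durations.min()))
        rec["epsilon_hat_size"] = fit_s.epsilon
        rec["epsilon_hat_duration"] = fit_d.epsilon
        if fit_s.unreliable or fit_d.unreliable:
            flags.append("exponent_fit_unreliable")
    else:
        flags.append("no_avalanches")

    try:
        rec["T"] = tension_from_raster(conn, raster).T
    except ValueError:
        rec["T"] = np.nan
        flags.append("no_drive")

    rec["eta"] = np.nan
    rec["mean_CV"] = np.nan
    try:
        rng = np.random.default_rng(spawn_seed(seed, 7))
        ids = rng.choice(params.N, size=min(ccg_neurons, params.N), replace=False)
        window = min(ccg_window, raster.T_steps - raster.burn_in)
        sub = SpikeRasterWindow(raster, window)
        decomp = decompose_inputs(conn, sub.raster, neurons=ids)
        rec["eta"] = eta(population_ccg(decomp, n_pairs=ccg_pairs, rng=rng))
    except ValueError:
        flags.append("ccg_degenerate")
    try:
        rec["mean_CV"] = isi_cv(raster).mean_cv
    except ValueError:
        flags.append("all_silent")

    rec["flags"] = ";".join(flags)
    return rec


class SpikeRasterWindow:
    """View of the first ``window`` post-burn-in steps of a raster."""

    def __init__(self, raster, window: int):
        from .dynamics import SpikeRaster

        t0 = raster.burn_in
        t1 = t0 + window
        keep = (raster.event_times >= t0) & (raster.event_times < t1)
        self.raster = SpikeRaster(
            event_times=raster.event_times[keep] - t0,
            event_ids=raster.event_ids[keep],
            counts=raster.counts[t0:t1],
            N=raster.N,
            T_steps=window,
            burn_in=0,
            params=raster.params,
            config=raster.config,
            seed=raster.seed,
        )


def run_phase_diagram(spec: SweepSpec) -> pd.DataFrame:
    """Rate/fluctuation map over a (g, w) grid (light statistics).

    Per-cell failures are logged and the sweep continues; failed cells
    appear with NaN statistics and an error flag.
    """
    rows = []
    h = config_hash(spec.params, spec.config)
    for gi, g in enumerate(spec.g_values):
        w_list = (
            [solve_boundary_weight(g, spec.params)]
            if spec.on_boundary
            else spec.w_values
        )
        for wi, w in enumerate(w_list):
            params = spec.params.with_(g=g, w=w)
            for s in range(spec.n_seeds):
                seed = spawn_seed(spec.master_seed, gi, wi, s)
                try:
                    rec = run_single_point(params, spec.config, seed, full_stats=False)
                except Exception as exc:  # keep sweeping
                    log.warning("cell (g=%s, w=%s, seed=%s) failed: %s", g, w, seed, exc)
                    rec = {"g": g, "w": w, "seed": seed, "flags": f"error:{exc}"}
                rec["config_hash"] = h
                rows.append(rec)
    df = pd.DataFrame(rows)
    _maybe_write(df, spec, "phase_diagram.csv")
    return df


def run_boundary_scan(spec: SweepSpec) -> pd.DataFrame:
    """Full statistic suite at w = w*(g) for each g (one row per seed)."""
    rows = []
    h = config_hash(spec.params, spec.config)
    for gi, g in enumerate(spec.g_values):
        w = solve_boundary_weight(g, spec.params)
        params = spec.params.with_(g=g, w=w)
        for s in range(spec.n_seeds):
            seed = spawn_seed(spec.master_seed, gi, s)
            try:
                rec = run_single_point(params, spec.config, seed, full_stats=True)
            except Exception as exc:
                log.warning("boundary cell (g=%s, seed=%s) failed: %s", g, seed, exc)
                rec = {"g": g, "w": w, "seed": seed, "flags": f"error:{exc}"}
            rec["config_hash"] = h
            rows.append(rec)
    df = pd.DataFrame(rows)
    _maybe_write(df, spec, "boundary_scan.csv")
    return df


def _maybe_write(df: pd.DataFrame, spec: SweepSpec, name: str) -> None:
    if spec.out_dir:
        out = Path(spec.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / name, index=False)
        log.info("wrote %s (%d rows, config %s)", out / name, len(df),
                 config_hash(spec.params, spec.config))


def make_fixtures(out_dir, seed: int = 12345, power_law_n: int = 100_000) -> dict:
    """Write the hand-traceable fixture set used by the test suites.

    Produces a 3-neuron connectivity with hand-computed inputs, toy count
    series with their expected avalanche catalogs, discrete power-law
    samples at stated exponents, and periodic/Bernoulli rasters for ISI
    CV checks, plus a manifest listing every file with its expected
    statistics.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "files": {}}

    # 3-neuron connectivity with two active neurons: hand-traceable inputs.
    J3 = np.array(
        [
            [0.0, 0.5, -0.2],
            [0.3, 0.0, -0.4],
            [0.1, 0.2, 0.0],
        ]
    )
    state = np.array([1, 1, 0])
    np.savetxt(out / "three_neuron_J.csv", J3, delimiter=",")
    manifest["files"]["three_neuron_J.csv"] = {
        "state": state.tolist(),
        "expected_inputs": (J3 @ state).tolist(),
    }

    # Toy count series with manually traced avalanche catalogs.
    toys = {
        "counts_a.csv": {"counts": [0, 2, 3, 1, 0], "threshold": 1,
                         "durations": [2], "sizes": [5]},
        "counts_b.csv": {"counts": [0, 5, 0, 4, 4, 0], "threshold": 2,
                         "durations": [1, 2], "sizes": [5, 8]},
    }
    for name, t in toys.items():
        np.savetxt(out / name, np.asarray(t["counts"], dtype=int), fmt="%d")
        manifest["files"][name] = t

    # Discrete power-law samples for exponent-recovery checks.
    rng = np.random.default_rng(seed)
    for eps in (1.5, 2.0):
        name = f"power_law_eps{eps}.csv"
        samples = sample_zeta(eps, power_law_n, rng)
        np.savetxt(out / name, samples, fmt="%d")
        manifest["files"][name] = {"epsilon": eps, "n": power_law_n}

    # Periodic and Bernoulli rasters for CV tests.
    T = 2000
    periodic = np.zeros((2, T), dtype=np.uint8)
    periodic[:, ::10] = 1
    np.savetxt(out / "raster_periodic.csv", periodic, fmt="%d", delimiter=",")
    manifest["files"]["raster_periodic.csv"] = {"expected_cv": 0.0}
    bern = (rng.random((20, T)) < 0.05).astype(np.uint8)
    np.savetxt(out / "raster_bernoulli.csv", bern, fmt="%d", delimiter=",")
    manifest["files"]["raster_bernoulli.csv"] = {"rate": 0.05, "expected_cv": "approx 1"}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
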