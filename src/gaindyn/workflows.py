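"""Reusable study workflows shared by the analysis drivers and acceptance checks.

Each function runs one self-contained piece of the study at a stated problem
size and returns plain numbers/tables, so the numbered analysis scripts stay
thin and the same computations can be re-run from scratch elsewhere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import SweepConfig, run_sweep
from .connectome import Connectome
from .estimators import (
    EmbeddingSpec,
    active_memory_rate,
    collective_te_rate,
    conditional_te_rate,
    select_embedding,
    te_rate,
    te_significance,
)
from .simulator import SimConfig, simulate
from .synthetic import (
    SyntheticConnectomeSpec,
    generate_connectome,
    generate_var,
    random_stable_var,
)

LN2 = np.log(2.0)

__all__ = [
    "cmi_standard_error_bits",
    "oracle_comparison",
    "te_test_type1_rate",
    "desk_scale_config",
    "desk_scale_sweep",
    "sweep_summary",
    "embedding_selection_study",
]


def cmi_standard_error_bits(value_bits: float, df: int, n: int) -> float:
    """Asymptotic SE of a plug-in Gaussian CMI estimate.

    The deviance ``2 n ln2 * I_hat`` is noncentral chi-square with ``df``
    degrees of freedom and noncentrality ``2 n ln2 * I``; its variance
    ``2 df + 8 n ln2 * I`` converts back to bits.
    """
    lam = 2.0 * n * LN2 * max(value_bits, 0.0)
    return float(np.sqrt(2.0 * df + 4.0 * lam) / (2.0 * n * LN2))


def oracle_comparison(
    n_systems: int = 20, n: int = 50_000, seed: int = 0
) -> pd.DataFrame:
    """Estimate every information measure on random stable VARs vs analytic values.

    Returns one row per (system, measure) with the sample estimate, the
    analytic-covariance oracle value, the asymptotic SE, the plug-in bias
    ``df / (2 n ln2)``, and the bias-adjusted z-score.
    """
    rng = np.random.default_rng(seed)
    spec = EmbeddingSpec(k=3, tau_embed=1, u=1)
    dt = 0.5
    rows = []
    for s in range(n_systems):
        dim = int(rng.integers(2, 5))
        oracle = random_stable_var(dim, rng)
        x = generate_var(oracle, n, seed=int(rng.integers(2**31)))
        tgt, src = 0, 1
        others = [z for z in range(dim) if z not in (tgt, src)]

        dec = active_memory_rate(x[:, tgt], spec, dt)
        rows += [
            dict(system=s, dim=dim, measure="AIS", estimate=dec.ais.value,
                 analytic=oracle.ais(tgt, spec), df=spec.k, n=dec.ais.n_samples),
            dict(system=s, dim=dim, measure="IPC", estimate=dec.ipc.value,
                 analytic=oracle.instantaneous_predictive_capacity(tgt),
                 df=1, n=dec.ipc.n_samples),
            dict(system=s, dim=dim, measure="AM_rate",
                 estimate=dec.am_rate.bits_per_step,
                 analytic=oracle.memory_rate_bits_per_step(tgt, spec),
                 df=spec.k - 1, n=dec.am_rate.n_samples),
        ]
        te = te_rate(x[:, src], x[:, tgt], spec, dt)
        rows.append(dict(system=s, dim=dim, measure="TE", estimate=te.bits_per_step,
                         analytic=oracle.te_bits_per_step(src, tgt, spec),
                         df=1, n=te.n_samples))
        if others:
            cond = conditional_te_rate(
                x[:, src], x[:, tgt], [(x[:, z], 1) for z in others], spec, dt
            )
            rows.append(dict(
                system=s, dim=dim, measure="cond_TE", estimate=cond.bits_per_step,
                analytic=oracle.conditional_te_bits_per_step(
                    src, tgt, [(z, 1) for z in others], spec),
                df=1, n=cond.n_samples))
        srcs = [z for z in range(dim) if z != tgt]
        coll = collective_te_rate([(x[:, z], 1) for z in srcs], x[:, tgt], spec, dt)
        rows.append(dict(
            system=s, dim=dim, measure="coll_TE", estimate=coll.bits_per_step,
            analytic=oracle.collective_te_bits_per_step(
                [(z, 1) for z in srcs], tgt, spec),
            df=len(srcs), n=coll.n_samples))

    df = pd.DataFrame(rows)
    df["se"] = [
        cmi_standard_error_bits(a, d, int(n_))
        for a, d, n_ in zip(df.analytic, df.df, df.n)
    ]
    df["bias"] = df.df / (2.0 * df.n * LN2)
    df["z"] = (df.estimate - df.analytic - df.bias) / df.se
    return df


def te_test_type1_rate(
    n_reps: int = 1000, n: int = 1000, alpha: float = 0.05, seed: int = 1
) -> float:
    """Empirical rejection rate of the analytic TE test on independent pairs."""
    rng = np.random.default_rng(seed)
    spec = EmbeddingSpec(k=2, tau_embed=1, u=1)
    rejections = 0
    for _ in range(n_reps):
        x = rng.normal(size=n + 10)
        y = rng.normal(size=n + 10)
        est = te_rate(y, x, spec, 0.5)
        _, sig = te_significance(est, alpha=alpha, n_tests=1)
        rejections += sig
    return rejections / n_reps


def desk_scale_config(master_seed: int = 0) -> SweepConfig:
    """8x8 grid over [0,1]^2, 10 s analyzed per point at 0.5 ms sampling."""
    return SweepConfig(
        sigma_grid=tuple(np.round(np.linspace(0, 1, 8), 6)),
        gamma_grid=tuple(np.round(np.linspace(0, 1, 8), 6)),
        embedding=EmbeddingSpec(k=25, tau_embed=12),
        sim=SimConfig(duration=12_000.0, transient=2_000.0, dt=0.5),
        master_seed=master_seed,
    )


def desk_scale_sweep(seed: int = 0):
    """Run the scaled-down sweep: 10-region drive-preserving connectome, 8x8 grid."""
    c = generate_connectome(SyntheticConnectomeSpec.scaled_down(10, seed=seed))
    cfg = desk_scale_config(master_seed=seed)
    return c, cfg, run_sweep(c, cfg)


def sweep_summary(grid) -> dict[str, float]:
    """Headline phase-map numbers from a sweep result grid.

    The supercritical/subcritical split classifies grid points by the order
    parameter relative to the midpoint of its observed range.  Transition
    sharpness is the largest single-step rise in R along sigma, taken on the
    gamma line with the widest R range.
    """
    R = grid.order_param
    te = np.nanmean(grid.te_rate, axis=2)
    am = np.nanmean(grid.am_rate, axis=2)
    cte = np.nanmean(grid.cond_te_rate, axis=2)
    coll = np.nanmean(grid.coll_te_rate, axis=2)

    mid = 0.5 * (np.nanmin(R) + np.nanmax(R))
    hi = R > mid
    te_hi = float(np.nanmean(te[hi]))
    te_lo = float(np.nanmean(te[~hi]))

    amax = np.unravel_index(np.nanargmax(am), am.shape)
    ranges = np.nanmax(R, axis=0) - np.nanmin(R, axis=0)
    b = int(np.nanargmax(ranges))
    line = R[:, b]
    return {
        "te_ratio_super_over_sub": te_hi / te_lo,
        "te_mean_supercritical": te_hi,
        "te_mean_subcritical": te_lo,
        "am_argmax_sigma": float(grid.sigma_grid[amax[0]]),
        "am_argmax_gamma": float(grid.gamma_grid[amax[1]]),
        "am_peak_bits_per_s": float(np.nanmax(am)),
        "r_range_best_line": float(ranges[b]),
        "r_max_step_best_line": float(np.nanmax(np.diff(line))),
        "cond_te_mean_supercritical": float(np.nanmean(cte[hi])),
        "coll_te_mean_supercritical": float(np.nanmean(coll[hi])),
    }


def embedding_selection_study(
    seed: int = 0,
    sigma: float = 0.3,
    gamma: float = 0.5,
    n_samples: int = 10_000,
    regions: np.ndarray | None = None,
    k_max: int = 30,
    tau_max: int = 30,
) -> dict[str, float]:
    """Per-region embedding optimization on the 76-region synthetic network.

    Simulates the subcritical working point, then maximizes bias-corrected
    AIS over (k, tau) <= (k_max, tau_max) per region with the full-study
    sample count of 10000 values (5 s at 2 kHz).
    """
    c = generate_connectome(SyntheticConnectomeSpec(seed=seed))
    duration = n_samples * 0.5 + 2_000.0
    run = simulate(
        c, SimConfig(sigma=sigma, gamma=gamma, duration=duration,
                     transient=2_000.0, seed=seed + 1)
    )
    if regions is None:
        regions = np.arange(c.n_regions)
    ks, taus = [], []
    for i in regions:
        k, tau = select_embedding(run.V[int(i)][:n_samples], k_max, tau_max)
        ks.append(k)
        taus.append(tau)
    ks, taus = np.array(ks), np.array(taus)
    return {
        "mean_k": float(ks.mean()),
        "sd_k": float(ks.std()),
        "median_k": float(np.median(ks)),
        "mean_tau": float(taus.mean()),
        "sd_tau": float(taus.std()),
        "median_tau": float(np.median(taus)),
        "n_regions": int(len(ks)),
    }
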