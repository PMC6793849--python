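"""Sweep orchestration and derived whole-map analyses.

A sweep simulates the network at every (sigma, gamma) grid point and
estimates, per point: the phase-synchrony order parameter, per-region active
memory rates (with instantaneous predictive capacity), per-causal-edge
pairwise and complete-conditional transfer-entropy rates, per-target
collective TE rates, and all-directed-pairs TE significance flags
(Bonferroni-corrected over the tested pairs, for the inter-hemispheric
proportion analysis).

Sources for TE are restricted to causal parents — regions with a structural
edge into the target — at the discretized structural delay.  For the
all-pairs significance scan, structurally unconnected pairs have no tract
delay; they fall back to the connectome's mean non-self delay (flagged in the
result object), since a delay of some kind must be chosen and the mean tract
delay is the least-informative structural choice available without region
coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .connectome import Connectome, delay_steps_matrix
from .estimators import (
    EmbeddingSpec,
    active_memory_rate,
    collective_te_rate,
    conditional_te_rate,
    te_rate,
    te_significance,
)
from .simulator import (
    SimConfig,
    SimulationDivergenceError,
    order_parameter,
    simulate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SweepConfig",
    "InfoResultGrid",
    "point_seed",
    "run_sweep",
    "correlate_per_gridpoint",
    "interhemisphere_te_summary",
    "boundary_profile",
    "find_boundary",
]

ALL_MEASURES = ("storage", "te", "cond_te", "coll_te", "all_pairs")


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of a (sigma, gamma) sweep."""

    sigma_grid: tuple[float, ...] = tuple(np.round(np.linspace(0, 1, 8), 6))
    gamma_grid: tuple[float, ...] = tuple(np.round(np.linspace(0, 1, 8), 6))
    embedding: EmbeddingSpec = EmbeddingSpec()
    alpha: float = 0.05
    measures: tuple[str, ...] = ALL_MEASURES
    sim: SimConfig = SimConfig()
    master_seed: int = 0
    jitter: float = 1e-9

    def __post_init__(self):
        if not self.sigma_grid or not self.gamma_grid:
            raise ValueError("grids must be non-empty")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        unknown = set(self.measures) - set(ALL_MEASURES)
        if unknown:
            raise ValueError(f"unknown measures: {sorted(unknown)}")


@dataclass
class InfoResultGrid:
    """Arrays indexed by (i_sigma, i_gamma) plus region/edge axes."""

    sigma_grid: np.ndarray
    gamma_grid: np.ndarray
    edges: np.ndarray  # (m, 2) non-self causal (target, source) pairs
    order_param: np.ndarray  # (ns, ng)
    am_rate: np.ndarray  # (ns, ng, n) bits/s
    ipc: np.ndarray  # (ns, ng, n) bits
    te_rate: np.ndarray  # (ns, ng, m) bits/s
    cond_te_rate: np.ndarray  # (ns, ng, m)
    coll_te_rate: np.ndarray  # (ns, ng, n)
    te_pvalue: np.ndarray  # (ns, ng, m) raw p per causal edge
    all_pairs: np.ndarray  # (p, 2) directed non-self pairs tested
    all_pairs_te: np.ndarray  # (ns, ng, p) bits/s
    all_pairs_sig: np.ndarray  # (ns, ng, p) Bonferroni-corrected flags
    missing: np.ndarray  # (ns, ng) bool, failed grid points
    fallback_delay_pairs: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=int)
    )

    @property
    def shape(self) -> tuple[int, int]:
        return self.order_param.shape


def point_seed(master_seed: int, i_sigma: int, i_gamma: int) -> int:
    """Deterministic per-grid-point seed (< 2**31) from the master seed."""
    ss = np.random.SeedSequence([master_seed, i_sigma, i_gamma])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _nonself_edges(c: Connectome) -> np.ndarray:
    e = np.argwhere(c.A > 0)
    return e[e[:, 0] != e[:, 1]]


def run_sweep(c: Connectome, cfg: SweepConfig) -> InfoResultGrid:
    """Simulate and estimate over the full (sigma, gamma) grid.

    Failed grid points (divergence, degenerate series) are recorded in
    ``missing`` and left as NaN; the sweep continues.  Deterministic given
    the master seed and config.
    """
    n = c.n_regions
    ns, ng = len(cfg.sigma_grid), len(cfg.gamma_grid)
    edges = _nonself_edges(c)
    m = edges.shape[0]
    U = delay_steps_matrix(c.tau, cfg.sim.dt)

    pairs = np.array(
        [(i, j) for i in range(n) for j in range(n) if i != j], dtype=int
    )
    mean_delay = float(c.tau[tuple(edges.T)].mean()) if m else cfg.sim.dt
    edge_set = {tuple(e) for e in edges}
    fallback = np.array(
        [p for p in map(tuple, pairs) if p not in edge_set], dtype=int
    ).reshape(-1, 2)
    u_fallback = max(1, int(np.floor(mean_delay / cfg.sim.dt)) + 1)

    grid = InfoResultGrid(
        sigma_grid=np.asarray(cfg.sigma_grid, float),
        gamma_grid=np.asarray(cfg.gamma_grid, float),
        edges=edges,
        order_param=np.full((ns, ng), np.nan),
        am_rate=np.full((ns, ng, n), np.nan),
        ipc=np.full((ns, ng, n), np.nan),
        te_rate=np.full((ns, ng, m), np.nan),
        cond_te_rate=np.full((ns, ng, m), np.nan),
        coll_te_rate=np.full((ns, ng, n), np.nan),
        te_pvalue=np.full((ns, ng, m), np.nan),
        all_pairs=pairs,
        all_pairs_te=np.full((ns, ng, pairs.shape[0]), np.nan),
        all_pairs_sig=np.zeros((ns, ng, pairs.shape[0]), dtype=bool),
        missing=np.zeros((ns, ng), dtype=bool),
        fallback_delay_pairs=fallback,
    )

    parents = {i: c.causal_parents(i) for i in range(n)}

    for a, sigma in enumerate(cfg.sigma_grid):
        for b, gamma in enumerate(cfg.gamma_grid):
            sim_cfg = SimConfig(
                sigma=float(sigma),
                gamma=float(gamma),
                m=cfg.sim.m,
                dt=cfg.sim.dt,
                duration=cfg.sim.duration,
                transient=cfg.sim.transient,
                noise_scale=cfg.sim.noise_scale,
                seed=point_seed(cfg.master_seed, a, b),
                init_box=cfg.sim.init_box,
                divergence_guard=cfg.sim.divergence_guard,
                sub_steps=cfg.sim.sub_steps,
            )
            try:
                run = simulate(c, sim_cfg)
                _estimate_point(grid, a, b, run, c, cfg, U, u_fallback, parents)
            except (SimulationDivergenceError, ValueError, np.linalg.LinAlgError) as e:
                logger.warning(
                    "grid point (sigma=%.3f, gamma=%.3f) failed: %s", sigma, gamma, e
                )
                grid.missing[a, b] = True
    return grid


def _estimate_point(grid, a, b, run, c, cfg, U, u_fallback, parents):
    V = run.V
    dt = cfg.sim.dt
    spec = cfg.embedding
    jit = cfg.jitter
    try:
        grid.order_param[a, b] = order_parameter(run)
    except ValueError:
        pass

    if "storage" in cfg.measures:
        for i in range(c.n_regions):
            dec = active_memory_rate(V[i], spec, dt, jitter=jit)
            grid.am_rate[a, b, i] = dec.am_rate.value
            grid.ipc[a, b, i] = dec.ipc.value

    if "te" in cfg.measures:
        for e, (i, j) in enumerate(grid.edges):
            est = te_rate(V[j], V[i], spec.with_u(int(U[i, j])), dt, jitter=jit)
            grid.te_rate[a, b, e] = est.value
            p, _ = te_significance(est)
            grid.te_pvalue[a, b, e] = p

    if "cond_te" in cfg.measures:
        for e, (i, j) in enumerate(grid.edges):
            others = [
                (V[z], int(U[i, z])) for z in parents[i] if z != j
            ]
            est = conditional_te_rate(
                V[j], V[i], others, spec.with_u(int(U[i, j])), dt, jitter=jit
            )
            grid.cond_te_rate[a, b, e] = est.value

    if "coll_te" in cfg.measures:
        for i in range(c.n_regions):
            srcs = [(V[z], int(U[i, z])) for z in parents[i]]
            if not srcs:
                continue
            est = collective_te_rate(srcs, V[i], spec, dt, jitter=jit)
            grid.coll_te_rate[a, b, i] = est.value

    if "all_pairs" in cfg.measures:
        n_tests = grid.all_pairs.shape[0]
        edge_set = {tuple(e) for e in grid.edges}
        for q, (i, j) in enumerate(grid.all_pairs):
            u = int(U[i, j]) if (i, j) in edge_set else u_fallback
            est = te_rate(V[j], V[i], spec.with_u(u), dt, jitter=jit)
            grid.all_pairs_te[a, b, q] = est.value
            _, sig = te_significance(est, alpha=cfg.alpha, n_tests=n_tests)
            grid.all_pairs_sig[a, b, q] = sig


def correlate_per_gridpoint(values: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Pearson correlation of a per-region/per-edge measure with a covariate.

    ``values`` has shape (ns, ng, p) and ``covariate`` shape (p,); returns an
    (ns, ng) grid of product-moment correlations.  Grid points with fewer
    than 3 finite pairs or a zero-variance covariate come back NaN.
    """
    values = np.asarray(values, float)
    cov = np.asarray(covariate, float)
    if values.shape[-1] != cov.shape[0]:
        raise ValueError("values and covariate lengths differ")
    ns, ng, _ = values.shape
    out = np.full((ns, ng), np.nan)
    for a in range(ns):
        for b in range(ng):
            v = values[a, b]
            ok = np.isfinite(v) & np.isfinite(cov)
            if ok.sum() < 3:
                continue
            x, y = v[ok], cov[ok]
            if x.std() == 0 or y.std() == 0:
                continue
            out[a, b] = np.corrcoef(x, y)[0, 1]
    return out


def interhemisphere_te_summary(
    grid: InfoResultGrid, c: Connectome
) -> dict[str, np.ndarray]:
    """Mean TE over inter-hemispheric causal edges, and the significant-TE proportion.

    The proportion counts, among all-pairs TEs flagged significant at a grid
    point, the fraction whose source and target lie in different hemispheres;
    points with at most one significant pair are set to 0 (a proportion from
    a single pair is pure noise).
    """
    hemi = c.hemisphere
    edge_cross = hemi[grid.edges[:, 0]] != hemi[grid.edges[:, 1]]
    pair_cross = hemi[grid.all_pairs[:, 0]] != hemi[grid.all_pairs[:, 1]]

    if edge_cross.any():
        mean_te = np.nanmean(grid.te_rate[:, :, edge_cross], axis=2)
    else:
        mean_te = np.full(grid.shape, np.nan)

    n_sig = grid.all_pairs_sig.sum(axis=2)
    n_sig_cross = grid.all_pairs_sig[:, :, pair_cross].sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        proportion = np.where(n_sig > 1, n_sig_cross / np.maximum(n_sig, 1), 0.0)
    return {
        "mean_interhem_te": mean_te,
        "proportion_significant_interhem": proportion,
        "n_significant": n_sig,
    }


def find_boundary(order_param: np.ndarray, axis: int = 0) -> np.ndarray:
    """Per-line critical index where R first crosses its min/max midpoint.

    Scanning along ``axis`` (0: sigma varies within a line at fixed gamma),
    the boundary is the first index where R reaches the midpoint between the
    line's minimum and maximum.  Lines with no crossing (flat R, or all-NaN)
    return -1.
    """
    R = np.moveaxis(np.asarray(order_param, float), axis, 0)
    n_lines = R.shape[1]
    out = np.full(n_lines, -1, dtype=int)
    for b in range(n_lines):
        line = R[:, b]
        ok = np.isfinite(line)
        if ok.sum() < 2:
            continue
        lo, hi = np.nanmin(line), np.nanmax(line)
        if hi - lo <= 1e-12:
            continue
        thresh = 0.5 * (lo + hi)
        above = np.flatnonzero(ok & (line >= thresh))
        below_first = np.flatnonzero(ok & (line < thresh))
        if above.size == 0 or below_first.size == 0:
            continue
        # first index at-or-above threshold that has something below before it
        cand = above[above > below_first[0]]
        out[b] = int(cand[0]) if cand.size else int(above[0])
    return out


def boundary_profile(
    values: np.ndarray,
    order_param: np.ndarray,
    axis: int = 0,
    boundary: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Average a grid measure as a function of signed offset from the boundary.

    ``values`` and ``order_param`` are (ns, ng) grids; the boundary is found
    per line along ``axis`` (or supplied).  Returns ``(offsets, profile)``
    where offset 0 is the critical index of each line; lines without a
    detected boundary are excluded with a warning.
    """
    V = np.moveaxis(np.asarray(values, float), axis, 0)
    npts, n_lines = V.shape
    if boundary is None:
        boundary = find_boundary(order_param, axis=axis)
    keep = boundary >= 0
    if not keep.any():
        raise ValueError("no boundary crossing detected on any line")
    if not keep.all():
        logger.warning(
            "no boundary on %d of %d lines; excluded", (~keep).sum(), n_lines
        )
    offsets = np.arange(-(npts - 1), npts)
    acc = np.zeros(offsets.size)
    cnt = np.zeros(offsets.size)
    for b in np.flatnonzero(keep):
        for idx in range(npts):
            o = idx - boundary[b]
            v = V[idx, b]
            if np.isfinite(v):
                acc[o + npts - 1] += v
                cnt[o + npts - 1] += 1
    profile = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    used = cnt > 0
    return offsets[used], profile[used]
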