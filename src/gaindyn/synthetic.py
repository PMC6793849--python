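"""Synthetic fixtures: connectome generator and VAR oracles.

Two independent validation paths live here.

* :func:`generate_connectome` builds a two-hemisphere directed weighted
  connectome whose summary statistics (edge counts, self-loop count,
  inter-hemispheric link count, weight and delay moments, in-degree spread)
  match the macaque-derived 76-region network used in the whole-brain
  simulations this package reproduces.  It is a synthetic stand-in for that
  network: topology beyond the summary statistics (lobe structure, named
  regions) is not emulated.

* :class:`VAROracle` defines a stable first-order vector autoregression whose
  stationary lag covariances follow from a discrete Lyapunov equation.  Every
  information measure the estimators compute from *sample* covariances can be
  computed here from the *analytic* covariance instead, giving an
  implementation-independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .connectome import Connectome
from .estimators import EmbeddingSpec, gaussian_cmi_from_cov

__all__ = [
    "SyntheticConnectomeSpec",
    "generate_connectome",
    "write_connectome",
    "VAROracle",
    "random_stable_var",
    "generate_var",
]


@dataclass(frozen=True)
class SyntheticConnectomeSpec:
    """Targets for the synthetic connectome generator.

    Defaults reproduce the 76-region network's printed statistics: 1494
    non-self directed links (density 1494/(76*75)), 38 of them
    inter-hemispheric, 66 of 76 regions carrying self-loops, link weights
    with mean 1.91 / SD 0.63 overall and mean 1.07 / SD 0.86 on the
    inter-hemispheric subset, conduction delays with mean 19.8 ms / SD
    8.32 ms, and in-degree spread 19.7 +/- 7.65.
    """

    n_regions: int = 76
    density: float = 1494 / (76 * 75)
    interhem_fraction: float = 38 / 1494
    self_loop_fraction: float = 66 / 76
    weight_mean: float = 1.91
    weight_sd: float = 0.63
    interhem_weight_mean: float = 1.07
    interhem_weight_sd: float = 0.86
    delay_mean_ms: float = 19.8
    delay_sd_ms: float = 8.32
    in_degree_rel_sd: float = 7.65 / 19.7
    seed: int = 0

    @classmethod
    def scaled_down(
        cls, n_regions: int, seed: int = 0, density: float = 0.5
    ) -> "SyntheticConnectomeSpec":
        """Small-network stand-in preserving each region's total synaptic drive.

        Shrinking the network at fixed per-edge weights starves every region
        of input (expected in-weight falls from ~37.6 to a few units) and the
        synchronization transition disappears, so per-edge weights are scaled
        up by the ratio of expected in-degrees to keep
        ``density * (n - 1) * weight_mean`` at its 76-region value.  The
        weight coefficient of variation, the inter-hemispheric weight ratio
        and fraction, and the delay distribution are kept as in the full
        network.  In-degree dispersion is reduced (CV 0.2 instead of 0.39):
        at the full network's relative spread a 10-node graph routinely
        contains one-parent or parentless nodes, which decouple from the
        collective oscillation — a finite-size artifact, not a feature of
        the system being emulated.
        """
        ref = cls()
        ref_inweight = ref.density * (ref.n_regions - 1) * ref.weight_mean
        mean_k = density * (n_regions - 1)
        wm = ref_inweight / mean_k
        cv = ref.weight_sd / ref.weight_mean
        inter_ratio = ref.interhem_weight_mean / ref.weight_mean
        inter_cv = ref.interhem_weight_sd / ref.interhem_weight_mean
        return cls(
            n_regions=n_regions,
            density=density,
            weight_mean=wm,
            weight_sd=cv * wm,
            interhem_weight_mean=inter_ratio * wm,
            interhem_weight_sd=inter_cv * inter_ratio * wm,
            in_degree_rel_sd=0.2,
            seed=seed,
        )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a log-normal with the given mean and SD."""
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2, np.sqrt(s2)


def _draw_lognormal(rng: np.random.Generator, mean: float, sd: float, size: int):
    mu, sig = _lognormal_params(mean, sd)
    return rng.lognormal(mu, sig, size)


def _draw_delays(rng: np.random.Generator, mean: float, sd: float, size: int):
    """Positive-truncated normal delays whose truncated mean equals ``mean``.

    Plain redraw-truncation biases the mean upward (~0.2 ms at the default
    19.8/8.32), so the location is shifted by fixed-point iteration until the
    truncated distribution's mean lands on target.
    """
    from scipy.stats import truncnorm

    mu = mean
    for _ in range(20):
        mu_new = mu - (truncnorm(-mu / sd, np.inf, loc=mu, scale=sd).mean() - mean)
        if abs(mu_new - mu) < 1e-10:
            break
        mu = mu_new
    return truncnorm.rvs(-mu / sd, np.inf, loc=mu, scale=sd, size=size,
                         random_state=rng)


def generate_connectome(spec: SyntheticConnectomeSpec) -> Connectome:
    """Generate a two-hemisphere connectome hitting the requested edge counts exactly.

    Inter-hemispheric edges are placed first so their small count is exact;
    remaining edges are placed within hemispheres following a dispersed
    per-target in-degree sequence.  Weights are moment-matched log-normals
    (separately for inter-hemispheric and within-hemisphere links, so that
    both the subset and overall moments land on target); delays are truncated
    normals.  Deterministic for a given spec (including seed).
    """
    n = spec.n_regions
    rng = np.random.default_rng(spec.seed)
    n_left = n // 2
    hemi = np.where(np.arange(n) < n_left, "L", "R")
    hemi_size = np.where(hemi == "L", n_left, n - n_left)

    m_total = int(round(spec.density * n * (n - 1)))
    m_inter = int(round(spec.interhem_fraction * m_total))
    m_intra = m_total - m_inter
    n_cross = 2 * n_left * (n - n_left)
    if m_inter > n_cross:
        raise ValueError(
            f"infeasible spec: {m_inter} inter-hemispheric edges requested "
            f"but only {n_cross} cross pairs exist"
        )
    if m_total == 0:
        A = np.zeros((n, n))
        tau = np.zeros((n, n))
        names = np.array([f"region_{i:02d}" for i in range(n)])
        return Connectome(A=A, tau=tau, hemisphere=hemi, region_names=names)

    # dispersed in-degree sequence summing to m_total
    mean_k = m_total / n
    k = np.rint(rng.normal(mean_k, spec.in_degree_rel_sd * mean_k, n)).astype(int)
    k = np.clip(k, 0, n - 1)
    while k.sum() != m_total:  # rebalance one unit at a time
        if k.sum() < m_total:
            cand = np.flatnonzero(k < n - 1)
            k[rng.choice(cand)] += 1
        else:
            cand = np.flatnonzero(k > 0)
            k[rng.choice(cand)] -= 1

    edges = np.zeros((n, n), dtype=bool)  # [target, source]
    # inter-hemispheric edges first: choose targets ~ in-degree, sources across
    quota = k.copy()
    for _ in range(m_inter):
        p = quota.astype(float)
        p[p < 0] = 0
        targets = np.flatnonzero(p > 0)
        t = rng.choice(targets, p=p[targets] / p[targets].sum())
        sources = np.flatnonzero((hemi != hemi[t]) & ~edges[t])
        s = rng.choice(sources)
        edges[t, s] = True
        quota[t] -= 1
    # remaining edges within hemisphere
    for t in range(n):
        want = int(min(quota[t], hemi_size[t] - 1))
        if want <= 0:
            continue
        pool = np.flatnonzero((hemi == hemi[t]) & ~edges[t])
        pool = pool[pool != t]
        s = rng.choice(pool, size=min(want, pool.size), replace=False)
        edges[t, s] = True
    # top up if clipping lost edges; stay within hemispheres so the
    # inter-hemispheric count remains exact
    deficit = m_total - int(edges.sum())
    if deficit > 0:
        offdiag = ~np.eye(n, dtype=bool)
        same = hemi[:, None] == hemi[None, :]
        free_intra = np.argwhere(~edges & offdiag & same)
        free_cross = np.argwhere(~edges & offdiag & ~same)
        free = np.vstack([
            free_intra[rng.permutation(len(free_intra))],
            free_cross[rng.permutation(len(free_cross))],
        ])
        for t, s in free[:deficit]:
            edges[t, s] = True

    cross = hemi[:, None] != hemi[None, :]
    inter_mask = edges & cross
    intra_mask = edges & ~cross
    n_inter = int(inter_mask.sum())
    n_intra = int(intra_mask.sum())

    # within-hemisphere weight moments chosen so the pooled moments hit target
    p_int = n_inter / (n_inter + n_intra)
    mu_intra = (spec.weight_mean - p_int * spec.interhem_weight_mean) / (1 - p_int)
    ex2_total = spec.weight_sd**2 + spec.weight_mean**2
    ex2_inter = spec.interhem_weight_sd**2 + spec.interhem_weight_mean**2
    var_intra = (ex2_total - p_int * ex2_inter) / (1 - p_int) - mu_intra**2
    sd_intra = float(np.sqrt(max(var_intra, 1e-12)))

    A = np.zeros((n, n))
    A[inter_mask] = _draw_lognormal(
        rng, spec.interhem_weight_mean, spec.interhem_weight_sd, n_inter
    )
    A[intra_mask] = _draw_lognormal(rng, mu_intra, sd_intra, n_intra)

    # self-loops on a fixed-count subset; weights like within-hemisphere links
    n_self = int(round(spec.self_loop_fraction * n))
    loop_nodes = rng.choice(n, size=n_self, replace=False)
    A[loop_nodes, loop_nodes] = _draw_lognormal(rng, mu_intra, sd_intra, n_self)

    tau = np.zeros((n, n))
    tau[edges] = _draw_delays(rng, spec.delay_mean_ms, spec.delay_sd_ms, m_total)

    names = np.array([f"region_{i:02d}" for i in range(n)])
    return Connectome(A=A, tau=tau, hemisphere=hemi, region_names=names)


def write_connectome(c: Connectome, directory: str | Path) -> dict[str, Path]:
    """Write weights/delays/hemispheres in the delimited format the loader reads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "weights": directory / "weights.txt",
        "delays": directory / "delays.txt",
        "hemispheres": directory / "hemispheres.txt",
    }
    np.savetxt(paths["weights"], c.A)
    np.savetxt(paths["delays"], c.tau)
    with open(paths["hemispheres"], "w") as fh:
        for name, h in zip(c.region_names, c.hemisphere):
            fh.write(f"{name},{h}\n")
    return paths


# ---------------------------------------------------------------------------
# VAR oracle


@dataclass(frozen=True)
class VAROracle:
    """Stable VAR(1) process ``x_t = Phi x_{t-1} + eps_t, eps ~ N(0, Sigma)``.

    Stationary lag covariances ``Gamma_h = E[x_t x_{t-h}^T]`` satisfy
    ``Gamma_0 = Phi Gamma_0 Phi^T + Sigma`` (discrete Lyapunov) and
    ``Gamma_h = Phi Gamma_{h-1}`` for ``h >= 1``.  Any joint covariance of
    lagged coordinates is assembled from these, and the same Gaussian CMI
    formula used on data then yields exact information values.
    """

    Phi: np.ndarray
    Sigma: np.ndarray
    _gamma0: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        Phi = np.atleast_2d(np.asarray(self.Phi, float))
        Sigma = np.atleast_2d(np.asarray(self.Sigma, float))
        object.__setattr__(self, "Phi", Phi)
        object.__setattr__(self, "Sigma", Sigma)
        rho = np.max(np.abs(np.linalg.eigvals(Phi)))
        if rho >= 1:
            raise ValueError(f"unstable VAR: spectral radius {rho:.3f} >= 1")
        object.__setattr__(self, "_gamma0", solve_discrete_lyapunov(Phi, Sigma))

    @property
    def dim(self) -> int:
        return self.Phi.shape[0]

    def lag_cov(self, h: int) -> np.ndarray:
        """``E[x_t x_{t-h}^T]`` for any integer lag ``h``."""
        if h < 0:
            return self.lag_cov(-h).T
        return np.linalg.matrix_power(self.Phi, h) @ self._gamma0

    def joint_cov(self, variables: list[tuple[int, int]]) -> np.ndarray:
        """Covariance of the listed ``(coordinate, lag)`` pairs.

        Lags are relative to the prediction time: lag 0 is the next value
        ``x_{n+1}``, lag 1 is ``x_n``, lag ``1 + tau`` is ``x_{n - tau}``, etc.
        """
        p = len(variables)
        S = np.empty((p, p))
        for a, (ia, la) in enumerate(variables):
            for b, (ib, lb) in enumerate(variables):
                S[a, b] = self.lag_cov(lb - la)[ia, ib]
        return S

    # -- analytic information values -------------------------------------

    def _target_blocks(self, target: int, spec: EmbeddingSpec):
        nxt = [(target, 0)]
        past = [(target, 1 + j * spec.tau_embed) for j in range(spec.k)]
        return nxt, past

    def ais(self, target: int, spec: EmbeddingSpec) -> float:
        nxt, past = self._target_blocks(target, spec)
        S = self.joint_cov(nxt + past)
        return gaussian_cmi_from_cov(S, [0], list(range(1, 1 + spec.k)), [])

    def instantaneous_predictive_capacity(self, target: int) -> float:
        S = self.joint_cov([(target, 0), (target, 1)])
        return gaussian_cmi_from_cov(S, [0], [1], [])

    def memory_rate_bits_per_step(self, target: int, spec: EmbeddingSpec) -> float:
        if spec.k < 2:
            raise ValueError("memory rate needs k >= 2")
        nxt, past = self._target_blocks(target, spec)
        S = self.joint_cov(nxt + past)
        deeper = list(range(2, 1 + spec.k))
        return gaussian_cmi_from_cov(S, [0], deeper, [1])

    def te_bits_per_step(self, source: int, target: int, spec: EmbeddingSpec) -> float:
        nxt, past = self._target_blocks(target, spec)
        variables = nxt + past + [(source, spec.u)]
        S = self.joint_cov(variables)
        src = [1 + spec.k]
        return gaussian_cmi_from_cov(S, [0], src, list(range(1, 1 + spec.k)))

    def conditional_te_bits_per_step(
        self,
        source: int,
        target: int,
        conditionals: list[tuple[int, int]],
        spec: EmbeddingSpec,
    ) -> float:
        """Conditionals given as ``(coordinate, delay_steps)`` pairs."""
        nxt, past = self._target_blocks(target, spec)
        cond = [(z, uz) for z, uz in conditionals]
        variables = nxt + past + cond + [(source, spec.u)]
        S = self.joint_cov(variables)
        nz = len(cond)
        src = [1 + spec.k + nz]
        return gaussian_cmi_from_cov(S, [0], src, list(range(1, 1 + spec.k + nz)))

    def collective_te_bits_per_step(
        self,
        sources: list[tuple[int, int]],
        target: int,
        spec: EmbeddingSpec,
    ) -> float:
        nxt, past = self._target_blocks(target, spec)
        src = [(y, uy) for y, uy in sources]
        S = self.joint_cov(nxt + past + src)
        ns = len(src)
        return gaussian_cmi_from_cov(
            S,
            [0],
            list(range(1 + spec.k, 1 + spec.k + ns)),
            list(range(1, 1 + spec.k)),
        )


def random_stable_var(
    dim: int,
    rng: np.random.Generator,
    spectral_radius: float = 0.7,
) -> VAROracle:
    """Random VAR(1) rescaled to the requested spectral radius, unit-ish noise."""
    Phi = rng.normal(0, 1, (dim, dim))
    Phi *= spectral_radius / np.max(np.abs(np.linalg.eigvals(Phi)))
    L = rng.normal(0, 0.3, (dim, dim))
    Sigma = np.eye(dim) + L @ L.T
    return VAROracle(Phi=Phi, Sigma=Sigma)


def generate_var(
    oracle: VAROracle,
    n_samples: int,
    seed: int,
    burn_in: int = 1000,
) -> np.ndarray:
    """Simulate the VAR; returns an ``(n_samples, dim)`` stationary sample."""
    rng = np.random.default_rng(seed)
    d = oracle.dim
    L = np.linalg.cholesky(oracle.Sigma)
    eps = rng.normal(0, 1, (burn_in + n_samples, d)) @ L.T
    x = np.zeros(d)
    out = np.empty((burn_in + n_samples, d))
    Phi = oracle.Phi
    for t in range(burn_in + n_samples):
        x = Phi @ x + eps[t]
        out[t] = x
    return out[burn_in:]
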