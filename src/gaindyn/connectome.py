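"""Directed weighted connectomes with axonal conduction delays.

The matrices follow the row-equals-target convention used throughout the
package: ``A[i, j]`` is the weight of the directed edge *j -> i* and
``tau[i, j]`` the corresponding conduction delay in milliseconds.  Connectome
files found in the wild use either orientation, so every loader documents this
convention and :func:`load_connectome` records it in the returned object.

Self-loops live on the diagonal ``A[i, i]`` and represent synaptic coupling
between neurons within the same region; they are excluded from the edge
statistics (weight/delay moments, in-degree) exactly where the whole-brain
literature excludes them.
"""

from __future__ import annotations

import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Connectome",
    "NormalizedCoupling",
    "ConnectomeValidationError",
    "load_connectome",
    "connectome_stats",
    "delay_steps",
    "lengths_to_delays",
    "normalize_coupling",
    "local_network_support",
]


class ConnectomeValidationError(ValueError):
    """Raised when connectome inputs violate the structural contract."""


@dataclass(frozen=True)
class Connectome:
    """A directed, weighted, delayed whole-brain network.

    Attributes
    ----------
    A : (n, n) ndarray
        Coupling weights, ``A[i, j]`` = weight of edge ``j -> i`` (dimensionless).
    tau : (n, n) ndarray
        Conduction delays in ms, same orientation as ``A``.
    hemisphere : (n,) ndarray of str
        ``"L"`` or ``"R"`` per region; must form two non-empty groups.
    region_names : (n,) ndarray of str
    """

    A: np.ndarray
    tau: np.ndarray
    hemisphere: np.ndarray
    region_names: np.ndarray
    orientation: str = field(default="row=target", compare=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        tau = np.asarray(self.tau, dtype=float)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "hemisphere", np.asarray(self.hemisphere))
        object.__setattr__(self, "region_names", np.asarray(self.region_names))
        _validate(self)

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]

    @property
    def causal_edges(self) -> np.ndarray:
        """(m, 2) array of (target, source) index pairs with A > 0, incl. self-loops."""
        return np.argwhere(self.A > 0)

    @property
    def self_loop_weights(self) -> np.ndarray:
        return np.diag(self.A).copy()

    def causal_parents(self, i: int) -> np.ndarray:
        """Non-self structural sources of region ``i``."""
        parents = np.flatnonzero(self.A[i] > 0)
        return parents[parents != i]


def _validate(c: Connectome) -> None:
    A, tau = c.A, c.tau
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ConnectomeValidationError(f"weight matrix must be square, got {A.shape}")
    if tau.shape != A.shape:
        raise ConnectomeValidationError(
            f"dimension mismatch: weights {A.shape} vs delays {tau.shape}"
        )
    n = A.shape[0]
    if c.hemisphere.shape != (n,) or c.region_names.shape != (n,):
        raise ConnectomeValidationError(
            f"expected {n} hemisphere labels and region names, got "
            f"{c.hemisphere.shape[0]} and {c.region_names.shape[0]}"
        )
    for name, M in (("weights", A), ("delays", tau)):
        if not np.all(np.isfinite(M)):
            i, j = np.argwhere(~np.isfinite(M))[0]
            raise ConnectomeValidationError(f"non-finite {name} entry at ({i}, {j})")
        if np.any(M < 0):
            i, j = np.argwhere(M < 0)[0]
            raise ConnectomeValidationError(
                f"negative {name} entry at ({i}, {j}): {M[i, j]}"
            )
    off = ~np.eye(n, dtype=bool)
    bad = (A > 0) & (tau <= 0) & off
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ConnectomeValidationError(
            f"edge {j}->{i} has positive weight but zero delay"
        )
    groups = set(c.hemisphere.tolist())
    if len(groups) != 2:
        raise ConnectomeValidationError(
            f"hemisphere labels must form exactly two non-empty groups, got {groups}"
        )


def _read_matrix(path: str | Path) -> np.ndarray:
    """Whitespace- or comma-delimited numeric matrix, one row per target region."""
    text = Path(path).read_text()
    delim = "," if "," in text.splitlines()[0] else None
    M = np.loadtxt(Path(path), delimiter=delim, ndmin=2)
    return np.asarray(M, dtype=float)


def _read_hemispheres(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    if df.shape[1] == 1:  # labels only, no names
        labels = df.iloc[:, 0].astype(str).str.strip().str.upper()
        names = np.array([f"region_{i}" for i in range(len(labels))])
    else:
        names = df.iloc[:, 0].astype(str).str.strip().to_numpy()
        labels = df.iloc[:, 1].astype(str).str.strip().str.upper()
    lab = labels.to_numpy()
    if not set(lab) <= {"L", "R"}:
        raise ConnectomeValidationError(f"hemisphere labels must be L/R, got {set(lab)}")
    return names, lab


def load_connectome(
    weights_path: str | Path,
    delays_path: str | Path,
    hemisphere_path: str | Path,
) -> Connectome:
    """Load a connectome from delimited text matrices plus a hemisphere sidecar.

    Matrix files are whitespace- or comma-delimited, one row per *target*
    region (``A[i, j]`` = weight of ``j -> i``).  The hemisphere sidecar has
    one line per region: either ``name,L`` / ``name,R`` pairs or bare labels.
    """
    A = _read_matrix(weights_path)
    tau = _read_matrix(delays_path)
    names, hemi = _read_hemispheres(hemisphere_path)
    return Connectome(A=A, tau=tau, hemisphere=hemi, region_names=names)


def load_connectome_bundle(
    zip_path: str | Path,
    *,
    conduction_speed_mm_per_ms: float | None = None,
) -> Connectome:
    """Load from a connectivity zip bundle (weights / tract_lengths / centres files).

    Bundles ship tract lengths in mm rather than delays; a conduction speed
    (mm/ms) converts them.  The speed is a heuristic configuration value:
    published connectome bundles rarely state one, and the delay statistics
    are what matter downstream.
    """
    if conduction_speed_mm_per_ms is None:
        conduction_speed_mm_per_ms = 3.0  # common cortical white-matter figure
    with zipfile.ZipFile(zip_path) as z:
        members = {Path(m).stem.lower(): m for m in z.namelist()}

        def grab(stem: str) -> np.ndarray:
            with z.open(members[stem]) as fh:
                return np.loadtxt(fh, ndmin=2)

        A = grab("weights")
        lengths = grab("tract_lengths")
        with z.open(members["centres"]) as fh:
            names = np.array([ln.split()[0].decode() for ln in fh if ln.strip()])
    tau = lengths_to_delays(lengths, conduction_speed_mm_per_ms)
    # no hemisphere file in the bundle convention: split on name prefix if
    # possible, else first half left / second half right
    hemi = np.where(np.arange(A.shape[0]) < A.shape[0] // 2, "L", "R")
    return Connectome(A=A, tau=tau, hemisphere=hemi, region_names=names)


def lengths_to_delays(lengths_mm: np.ndarray, speed_mm_per_ms: float) -> np.ndarray:
    """Convert fiber tract lengths (mm) to conduction delays (ms)."""
    if speed_mm_per_ms <= 0:
        raise ValueError("conduction speed must be positive")
    return np.asarray(lengths_mm, dtype=float) / speed_mm_per_ms


def delay_steps(tau_ij: float, dt: float) -> int:
    """Discretize a delay: smallest integer u with ``u * dt`` strictly > ``tau_ij``.

    Always at least 1 step, so even zero-delay (self) edges act with a one-step
    lag in discrete time.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if tau_ij < 0:
        raise ValueError("delay must be non-negative")
    return max(1, int(np.floor(tau_ij / dt)) + 1)


def delay_steps_matrix(tau: np.ndarray, dt: float) -> np.ndarray:
    """Vectorized :func:`delay_steps` over a delay matrix."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return np.maximum(1, np.floor(np.asarray(tau, float) / dt).astype(np.int64) + 1)


def connectome_stats(c: Connectome) -> dict:
    """Summary statistics of the connectome.

    All weight/delay moments and degree counts exclude self-loops; in-degree
    counts non-self causal parents per target.
    """
    A, tau = c.A, c.tau
    n = c.n_regions
    off = ~np.eye(n, dtype=bool)
    edges = (A > 0) & off
    self_links = np.diag(A) > 0
    cross = c.hemisphere[:, None] != c.hemisphere[None, :]
    inter = edges & cross

    w = A[edges]
    d = tau[edges]
    w_inter = A[inter]
    in_degree = edges.sum(axis=1)
    return {
        "n_regions": n,
        "n_connections": int(edges.sum() + self_links.sum()),
        "n_self_links": int(self_links.sum()),
        "n_nonself_links": int(edges.sum()),
        "n_interhemispheric": int(inter.sum()),
        "weight_mean": float(w.mean()) if w.size else 0.0,
        "weight_sd": float(w.std(ddof=0)) if w.size else 0.0,
        "interhem_weight_mean": float(w_inter.mean()) if w_inter.size else 0.0,
        "interhem_weight_sd": float(w_inter.std(ddof=0)) if w_inter.size else 0.0,
        "delay_mean_ms": float(d.mean()) if d.size else 0.0,
        "delay_sd_ms": float(d.std(ddof=0)) if d.size else 0.0,
        "in_degree": in_degree,
        "in_degree_mean": float(in_degree.mean()),
        "in_degree_sd": float(in_degree.std(ddof=0)),
        "causal_parent_count": in_degree,
    }


@dataclass(frozen=True)
class NormalizedCoupling:
    """Incoming-weight-normalized coupling used by the motif heuristic.

    ``C = D^{-1} (A - diag(A))`` with ``d_i = sum_{j != i} A[i, j]``: each
    non-self in-edge weight divided by the target's total non-self in-weight,
    so every row with at least one in-edge sums to one.  ``F_diag[i] =
    A[i, i] / sum_j A[i, j]`` is the self-loop share of the total (self-
    inclusive) in-weight.
    """

    C: np.ndarray
    F_diag: np.ndarray


def normalize_coupling(c: Connectome) -> NormalizedCoupling:
    A = c.A
    n = c.n_regions
    off = A - np.diag(np.diag(A))
    d = off.sum(axis=1)
    C = np.zeros_like(A)
    nz = d > 0
    if not np.all(nz):
        logger.warning(
            "regions with no non-self in-edges get zero rows in C: %s",
            np.flatnonzero(~nz).tolist(),
        )
    C[nz] = off[nz] / d[nz, None]
    g = A.sum(axis=1)
    F_diag = np.zeros(n)
    gz = g > 0
    F_diag[gz] = np.diag(A)[gz] / g[gz]
    return NormalizedCoupling(C=C, F_diag=F_diag)


def local_network_support(nc: NormalizedCoupling) -> np.ndarray:
    """Weighted motif count Psi_a approximating network-supported storage.

    Sums, over the normalized coupling ``C``, the feedback loops through a
    node (2- and 3-cycles) and the feedforward loops terminating at it
    (2- and 3-step paths paralleled by a direct edge):

        Psi_a = sum_b C_ba C_ab + sum_bc C_ba C_cb C_ac
              + sum_bc C_bc C_ab C_ac + sum_bcd C_cd C_bc C_ab C_ad

    Index sums are unrestricted (weighted walks), which makes the expression
    identical to ``diag(C^2) + diag(C^3) + rowsum(C * C^2) + rowsum(C * C^3)``
    with ``*`` the entrywise product.  Longer motifs are omitted: the
    normalization makes their contribution decay with length.
    """
    C = nc.C
    C2 = C @ C
    C3 = C2 @ C
    return np.diag(C2) + np.diag(C3) + (C * C2).sum(axis=1) + (C * C3).sum(axis=1)
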