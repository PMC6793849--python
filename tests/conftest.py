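import numpy as np
import pytest

from gaindyn.connectome import Connectome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_connectome():
    """3 regions, 2 causal edges (1->0, 2->1), one self-loop on region 2."""
    A = np.array([[0.0, 2.0, 0.0], [0.0, 0.0, 1.5], [0.0, 0.0, 0.5]])
    tau = np.array([[0.0, 10.0, 0.0], [0.0, 0.0, 5.0], [0.0, 0.0, 0.0]])
    return Connectome(
        A=A,
        tau=tau,
        hemisphere=np.array(["L", "L", "R"]),
        region_names=np.array(["a", "b", "c"]),
    )


def random_connectome(n: int, rng: np.random.Generator, density: float = 0.4):
    """Random valid connectome for property tests."""
    edges = (rng.random((n, n)) < density) & ~np.eye(n, dtype=bool)
    A = np.where(edges, rng.lognormal(0.3, 0.4, (n, n)), 0.0)
    loops = rng.random(n) < 0.5
    A[np.diag_indices(n)] = np.where(loops, rng.lognormal(0.0, 0.3, n), 0.0)
    tau = np.where(edges, rng.uniform(1.0, 40.0, (n, n)), 0.0)
    hemi = np.where(np.arange(n) < n // 2, "L", "R")
    names = np.array([f"r{i}" for i in range(n)])
    return Connectome(A=A, tau=tau, hemisphere=hemi, region_names=names)
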