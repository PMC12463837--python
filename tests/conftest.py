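import numpy as np
import pytest

from lexstrat import DistanceMatrix, SimConfig, pairwise_ldn, simulate_wordlist


def random_distance_matrix(rng: np.random.Generator, n: int, scale: float = 1.0) -> DistanceMatrix:
    """A random valid symmetric nonnegative matrix with zero diagonal."""
    m = rng.uniform(0.05, scale, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    labels = [f"L{i:02d}" for i in range(n)]
    return DistanceMatrix(labels, m)


def euclidean_matrix(points: np.ndarray, labels=None) -> DistanceMatrix:
    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    labels = labels or [f"P{i:02d}" for i in range(len(points))]
    return DistanceMatrix(labels, d)


@pytest.fixture(scope="session")
def reference_sim():
    """One wordlist at the reference generator condition, with truth."""
    cfg = SimConfig(seed=11)
    w, tree, partition = simulate_wordlist(cfg)
    return cfg, w, tree, partition


@pytest.fixture(scope="session")
def reference_ldn(reference_sim):
    _, w, _, _ = reference_sim
    return pairwise_ldn(w)


@pytest.fixture(scope="session")
def hybrid_sim():
    """Two well-separated families plus a 50/50 hybrid variety."""
    cfg = SimConfig(
        n_families=2,
        varieties_per_family=4,
        hybrid_spec=("hybrid", ("fam1", "fam2"), 0.5),
        missing_rate=0.0,
        seed=23,
    )
    w, tree, partition = simulate_wordlist(cfg)
    return cfg, w, tree, partition
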