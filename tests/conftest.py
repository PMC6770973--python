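import numpy as np
import pytest

from dmapred import AssociationMatrix, Hyperparameters, SimilarityMatrix
from dmapred.knn import build_neighbor_graph


def random_similarity(rng, n, role="entity", prefix="e"):
    """Random symmetric similarity matrix with unit diagonal."""
    raw = rng.uniform(0, 1, (n, n))
    values = (raw + raw.T) / 2
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix([f"{prefix}{i}" for i in range(n)], values, role=role)


def random_problem(seed, nm=8, nd=6, density=0.25):
    """A small random (M, D, A) triple with aligned labels."""
    rng = np.random.default_rng(seed)
    M = random_similarity(rng, nm, role="mirna", prefix="m")
    D = random_similarity(rng, nd, role="disease", prefix="d")
    A_vals = (rng.uniform(size=(nm, nd)) < density).astype(float)
    A_vals[0, 0] = 1.0  # at least one positive
    A = AssociationMatrix(M.labels, D.labels, A_vals)
    return M, D, A


@pytest.fixture
def small_problem():
    return random_problem(seed=42)


@pytest.fixture
def small_params():
    return Hyperparameters(k_latent=4, k_neighbors=3, max_iter=50, rel_tol=0.0, seed=7)


@pytest.fixture
def small_graph(small_problem, small_params):
    M, _, _ = small_problem
    return build_neighbor_graph(M, small_params.k_neighbors)
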