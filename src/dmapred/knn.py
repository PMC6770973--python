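"""k-nearest-neighbor indicator graph over miRNAs and its Laplacian pieces.

The local-topology regularizer penalizes ``1/2 * sum_jl S_jl ||u_j - u_l||^2``,
which for a symmetric indicator ``S`` equals ``Tr(U.T @ (V - S) @ U)`` with
``V = diag(row sums of S)``.  Raw kNN selection is not symmetric, so ``S`` is
symmetrized as ``(S_raw + S_raw.T) / 2``; this keeps the Laplacian ``V - S``
positive semi-definite and makes the gradient exactly ``2 * (V - S) @ U``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .containers import SimilarityMatrix


@dataclasses.dataclass
class NeighborGraph:
    """Symmetrized kNN indicator ``S`` (entries in {0, 0.5, 1}) and degrees."""

    S: np.ndarray
    degrees: np.ndarray  # diagonal of V
    k_neighbors: int

    @property
    def V(self) -> np.ndarray:
        return np.diag(self.degrees)

    @property
    def laplacian(self) -> np.ndarray:
        return self.V - self.S

    def linked_pairs(self) -> np.ndarray:
        """Upper-triangular (j, l) index pairs with S[j, l] > 0."""
        ju, lu = np.triu_indices_from(self.S, k=1)
        keep = self.S[ju, lu] > 0
        return np.column_stack([ju[keep], lu[keep]])


def build_knn_indicator(M: SimilarityMatrix | np.ndarray, k_neighbors: int) -> np.ndarray:
    """Row-wise binary indicator of the k most similar other entities.

    ``S_raw[j, l] = 1`` iff ``l`` is among the ``k_neighbors`` largest
    similarities in row ``j``, self excluded.  Ties are broken toward the
    lower index so results are deterministic.
    """
    values = M.values if isinstance(M, SimilarityMatrix) else np.asarray(M, dtype=float)
    n = values.shape[0]
    if values.shape != (n, n):
        raise ValueError("similarity matrix must be square")
    if k_neighbors < 0:
        raise ValueError("k_neighbors must be >= 0")
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < number of entities ({n})")
    S_raw = np.zeros((n, n))
    work = values.copy()
    np.fill_diagonal(work, -np.inf)
    for j in range(n):
        # stable argsort on the negated row: lower index wins ties
        order = np.argsort(-work[j], kind="stable")
        S_raw[j, order[:k_neighbors]] = 1.0
    return S_raw


def symmetrize_and_degree(S_raw: np.ndarray, k_neighbors: int | None = None) -> NeighborGraph:
    """Symmetrize a raw kNN indicator and attach the degree diagonal."""
    S_raw = np.asarray(S_raw, dtype=float)
    if not np.isin(S_raw, (0.0, 1.0)).all():
        raise ValueError("raw kNN indicator must be binary")
    if np.any(np.diag(S_raw) != 0):
        raise ValueError("raw kNN indicator has a nonzero diagonal (self-neighbor)")
    S = (S_raw + S_raw.T) / 2.0
    if k_neighbors is None:
        k_neighbors = int(S_raw.sum(axis=1).max(initial=0))
    return NeighborGraph(S=S, degrees=S.sum(axis=1), k_neighbors=k_neighbors)


def build_neighbor_graph(M: SimilarityMatrix | np.ndarray, k_neighbors: int) -> NeighborGraph:
    """Convenience: kNN selection followed by symmetrization."""
    return symmetrize_and_degree(build_knn_indicator(M, k_neighbors), k_neighbors)
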