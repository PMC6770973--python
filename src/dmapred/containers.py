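"""Core data containers for the miRNA-disease heterogeneous network.

The method operates on three matrices: a miRNA-miRNA functional similarity
matrix ``M`` (Nm x Nm), a disease-disease semantic/phenotype similarity
matrix ``D`` (Nd x Nd), and a sparse binary association matrix ``A``
(Nm x Nd) whose 1-entries are experimentally confirmed miRNA-disease
associations.  The indicator mask ``Y`` equals ``A`` and restricts the
association-fit penalty to observed pairs; it is kept as a separate field
because cross-validation zeroes held-out entries in both.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

#: maximum tolerated asymmetry before a similarity matrix is rejected
SYMMETRY_TOL = 1e-6


def _check_unique(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        seen: set[str] = set()
        dup = next(x for x in labels if x in seen or seen.add(x))
        raise ValueError(f"duplicate {what} label: {dup!r}")
    return labels


@dataclasses.dataclass
class SimilarityMatrix:
    """A labeled square symmetric similarity matrix with entries in [0, 1].

    Parameters
    ----------
    labels
        Ordered entity names (miRNAs or diseases); row and column order.
    values
        Square array of pairwise similarities.  Inputs asymmetric by more
        than :data:`SYMMETRY_TOL` are rejected; smaller asymmetries are
        symmetrized as ``(X + X.T) / 2``.
    role
        Free-form tag, conventionally ``"mirna"`` or ``"disease"``.

    The diagonal is accepted as given: the k-nearest-neighbor graph step
    excludes self-neighbors explicitly, so the self-similarity convention
    (0 or 1) never changes downstream results.
    """

    labels: list[str]
    values: np.ndarray
    role: str = "entity"

    def __post_init__(self) -> None:
        self.labels = _check_unique(self.labels, self.role)
        values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"similarity matrix must be square, got shape {values.shape}")
        if values.shape[0] != n:
            raise ValueError(f"{n} labels but matrix of shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("similarity matrix contains non-finite entries")
        bad = np.argwhere((values < 0) | (values > 1))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"similarity out of [0,1] at ({self.labels[i]!r}, {self.labels[j]!r}): "
                f"{values[i, j]!r}"
            )
        asym = float(np.max(np.abs(values - values.T))) if n else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"asymmetric similarity matrix (max |Xij - Xji| = {asym:.3g})")
        self.values = (values + values.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclasses.dataclass
class AssociationMatrix:
    """Binary miRNA-disease association matrix ``A`` with indicator mask ``Y``.

    ``mask[i, j] == values[i, j]`` by definition; cross-validation produces
    training copies where held-out 1-entries are zeroed in both fields so
    the association-fit term carries zero weight on test pairs.
    """

    mirna_labels: list[str]
    disease_labels: list[str]
    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mirna_labels = _check_unique(self.mirna_labels, "miRNA")
        self.disease_labels = _check_unique(self.disease_labels, "disease")
        values = np.asarray(self.values, dtype=float)
        shape = (len(self.mirna_labels), len(self.disease_labels))
        if values.shape != shape:
            raise ValueError(f"association matrix shape {values.shape} != {shape}")
        if not np.isin(values, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.values = values
        if self.mask is None:
            self.mask = values.copy()
        else:
            mask = np.asarray(self.mask, dtype=float)
            if mask.shape != shape or not np.isin(mask, (0.0, 1.0)).all():
                raise ValueError("mask must be a binary matrix of the same shape")
            self.mask = mask

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_labels)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_labels)

    @property
    def n_positives(self) -> int:
        return int(self.values.sum())

    def positive_pairs(self) -> np.ndarray:
        """Row-major array of (miRNA index, disease index) for each 1-entry."""
        return np.argwhere(self.values == 1)

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            list(self.mirna_labels),
            list(self.disease_labels),
            self.values.copy(),
            self.mask.copy(),
        )


_MODES = ("consistent", "literal")

# config-file key -> attribute name ("lambda" is a Python keyword)
_ALIASES = {"lambda": "lam"}


@dataclasses.dataclass
class Hyperparameters:
    """Weights and optimizer settings for the factorization model.

    alpha, beta, lam, delta, eta
        Non-negative weights of the disease-reconstruction, association-fit,
        low-dimensional coupling, L1 sparsity and graph-regularization terms.
        Defaults are the values selected on the HMDD corpus.
    k_latent
        Latent dimension of the projections (default 100, sized for the
        490 x 326 corpus; scale down for small instances).
    k_neighbors
        Neighborhood size of the miRNA kNN graph.
    update_mode
        ``"consistent"`` derives every multiplicative rule from the stated
        objective (provably non-increasing); ``"literal"`` reproduces the
        published update formulas verbatim, which place the weight alpha on
        the miRNA-reconstruction term and drop beta, Y and delta from the
        U update.
    """

    alpha: float = 0.1
    beta: float = 0.1
    lam: float = 0.1
    delta: float = 1.0
    eta: float = 0.4
    k_latent: int = 100
    k_neighbors: int = 5
    max_iter: int = 1000
    rel_tol: float = 1e-6
    seed: int = 0
    update_mode: str = "consistent"

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "lam", "delta", "eta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.k_latent < 1:
            raise ValueError("k_latent must be >= 1")
        if self.k_neighbors < 0:
            raise ValueError("k_neighbors must be >= 0")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")
        if self.rel_tol < 0:
            raise ValueError("rel_tol must be >= 0")
        if self.update_mode not in _MODES:
            raise ValueError(f"update_mode must be one of {_MODES}")

    @classmethod
    def from_dict(cls, d: dict) -> "Hyperparameters":
        kwargs = {}
        valid = {f.name for f in dataclasses.fields(cls)}
        for key, value in d.items():
            name = _ALIASES.get(key, key)
            if name not in valid:
                raise ValueError(f"unknown hyperparameter {key!r}")
            kwargs[name] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lambda"] = d.pop("lam")
        return d

    def replace(self, **kwargs) -> "Hyperparameters":
        return dataclasses.replace(self, **kwargs)
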