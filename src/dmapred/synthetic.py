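"""Planted-structure synthetic instances of the miRNA-disease problem.

The generator emulates the statistical shape of the real inputs without
copying any data: non-negative latent loadings ``G_m`` (miRNAs) and ``G_d``
(diseases) produce a true score matrix ``T = G_m @ G_d.T`` whose top
``density`` fraction becomes the ground-truth association matrix, and the
similarity matrices are row-wise cosine similarities of the loadings plus
symmetric noise.  Because similar latent rows both share associations and
score as similar, the instances embody the assumption the model exploits:
similar miRNAs associate with similar diseases.  Hiding a fraction of the
true associations yields held-out pairs for recovery experiments.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .containers import AssociationMatrix, SimilarityMatrix
from .evaluation import roc_auc

#: background loading scale relative to the dominant-class loading
BACKGROUND_SCALE = 0.15


@dataclasses.dataclass
class PlantedInstance:
    """A complete synthetic problem with known hidden associations."""

    M: SimilarityMatrix
    D: SimilarityMatrix
    A_full: np.ndarray  # ground truth, including hidden pairs
    A_observed: AssociationMatrix
    hidden_pairs: np.ndarray  # (n_hidden, 2) index pairs present in A_full only
    latent: tuple[np.ndarray, np.ndarray]  # (G_m, G_d)
    seed: int


def _cosine_rows(G: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(G, axis=1, keepdims=True)
    norms = np.maximum(norms, 1e-300)
    sims = (G / norms) @ (G / norms).T
    return np.clip(sims, 0.0, 1.0)


def _latent_loadings(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Clustered non-negative loadings: a dominant class plus background.

    Each entity is assigned one of the ``k`` latent classes and receives a
    Gamma(2, 1) loading there on top of a small uniform background.  The
    resulting block-like community structure mirrors functional families of
    miRNAs (and disease categories): members of a family are mutually
    similar and share association partners, which is exactly the coupling
    the model assumes.
    """
    G = BACKGROUND_SCALE * rng.uniform(0.0, 1.0, (n, k))
    G[np.arange(n), rng.integers(0, k, n)] += rng.gamma(2.0, 1.0, n)
    return G


def _noisy_similarity(cos: np.ndarray, noise: float, rng: np.random.Generator) -> np.ndarray:
    if noise == 0:
        return cos
    n = cos.shape[0]
    E = noise * rng.standard_normal((n, n))
    E = (E + E.T) / 2.0
    np.fill_diagonal(E, 0.0)  # keep unit self-similarity exact
    return np.clip(cos + E, 0.0, 1.0)


def generate(
    nm: int,
    nd: int,
    k_true: int,
    density: float,
    hide_frac: float,
    noise: float,
    seed: int,
) -> PlantedInstance:
    """Draw a planted instance; deterministic for a given seed.

    Parameters
    ----------
    nm, nd
        Numbers of miRNAs and diseases.
    k_true
        Rank of the planted latent structure.
    density
        Fraction of the nm*nd pairs made true associations: exactly
        ``round(density * nm * nd)`` entries, the top-scoring ones under the
        latent model (stable tie-break), become 1s of ``A_full``.
    hide_frac
        Fraction of the true associations hidden from ``A_observed``.
    noise
        Scale of the symmetric Gaussian perturbation added to the cosine
        similarities (off-diagonal only; the result is clipped to [0, 1]).
    """
    if not 0 < density < 1:
        raise ValueError("density must be in (0, 1)")
    if not 0 <= hide_frac < 1:
        raise ValueError("hide_frac must be in [0, 1)")
    if k_true < 1:
        raise ValueError("k_true must be >= 1")
    if noise < 0:
        raise ValueError("noise must be >= 0")
    n_pos = round(density * nm * nd)
    if n_pos == 0:
        raise ValueError("density too low: no positive associations")

    rng = np.random.default_rng(seed)
    G_m = _latent_loadings(rng, nm, k_true)
    G_d = _latent_loadings(rng, nd, k_true)

    T = G_m @ G_d.T
    flat_order = np.argsort(-T.ravel(), kind="stable")
    A_full = np.zeros(nm * nd)
    A_full[flat_order[:n_pos]] = 1.0
    A_full = A_full.reshape(nm, nd)

    M_vals = _noisy_similarity(_cosine_rows(G_m), noise, rng)
    D_vals = _noisy_similarity(_cosine_rows(G_d), noise, rng)

    pos_pairs = np.argwhere(A_full == 1)
    n_hidden = round(hide_frac * n_pos)
    hidden_idx = rng.choice(n_pos, size=n_hidden, replace=False)
    hidden_pairs = pos_pairs[np.sort(hidden_idx)]

    A_obs = A_full.copy()
    A_obs[hidden_pairs[:, 0], hidden_pairs[:, 1]] = 0.0

    mirna_labels = [f"mir-{i + 1:04d}" for i in range(nm)]
    disease_labels = [f"disease-{j + 1:04d}" for j in range(nd)]
    return PlantedInstance(
        M=SimilarityMatrix(mirna_labels, M_vals, role="mirna"),
        D=SimilarityMatrix(disease_labels, D_vals, role="disease"),
        A_full=A_full,
        A_observed=AssociationMatrix(mirna_labels, disease_labels, A_obs),
        hidden_pairs=hidden_pairs,
        latent=(G_m, G_d),
        seed=seed,
    )


def identity_control(instance: PlantedInstance) -> PlantedInstance:
    """The same instance with all similarity signal removed (identity M, D).

    Serves as a negative control: any recovery advantage of the structured
    instance over this one is attributable to the similarity networks.
    """
    return dataclasses.replace(
        instance,
        M=SimilarityMatrix(instance.M.labels, np.eye(instance.M.n), role="mirna"),
        D=SimilarityMatrix(instance.D.labels, np.eye(instance.D.n), role="disease"),
    )


def recovery_auc(instance: PlantedInstance, U: np.ndarray) -> float:
    """AUC of the scores on hidden pairs versus never-associated pairs."""
    if len(instance.hidden_pairs) == 0:
        raise ValueError("instance has no hidden pairs")
    flat = np.asarray(U, dtype=float).ravel()
    nm, nd = instance.A_full.shape
    hidden_flat = instance.hidden_pairs[:, 0] * nd + instance.hidden_pairs[:, 1]
    negatives = np.nonzero(instance.A_full.ravel() == 0)[0]
    return roc_auc(flat, hidden_flat.tolist(), negatives.tolist())
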