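"""Graph-regularized sparse NMF model for miRNA-disease association scoring.

The score matrix ``U`` (Nm x Nd) is estimated by minimizing

    F = ||M - WH||_F^2  +  alpha * ||D - XC||_F^2
        + beta * ||Y . (A - U)||_F^2  +  lam * ||U - H.T C||_F^2
        + delta * ||U||_1  +  eta * Tr(U.T (V - S) U)

over non-negative factors U, W (Nm x k), H (k x Nm), X (Nd x k), C (k x Nd),
where ``.`` is the Hadamard product, Y the association indicator mask, S the
symmetrized miRNA kNN indicator with degree diagonal V, and the last term
equals the pairwise penalty ``1/2 * eta * sum_jl S_jl ||u_j - u_l||^2`` on
rows of U.  Each factor is optimized in turn by a multiplicative update that
preserves non-negativity; in ``consistent`` mode each rule is the exact
KKT/split-gradient rule of F, so F is non-increasing cycle over cycle.
``literal`` mode instead applies the published update formulas verbatim
(alpha moved onto the M term in the H update; beta, Y and delta dropped from
the U update); with the small weights used in practice the two iterate
sequences stay close, but only the consistent rules provably descend F.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .containers import AssociationMatrix, Hyperparameters, SimilarityMatrix
from .knn import NeighborGraph, build_neighbor_graph

logger = logging.getLogger(__name__)

#: multiplicative-update denominator guard; cells below it are left unchanged
EPS = 1e-12

#: convergence is judged on the objective decrease over this many cycles;
#: the per-cycle decrease of multiplicative updates shrinks much faster than
#: the distance to stationarity (sublinear tail), so a single-cycle check
#: stops prematurely
CONVERGENCE_WINDOW = 10

TERM_NAMES = (
    "mirna_reconstruction",
    "disease_reconstruction",
    "association_fit",
    "coupling",
    "sparsity",
    "graph",
)


@dataclasses.dataclass
class FactorSet:
    """The five non-negative factors of the model."""

    U: np.ndarray  # Nm x Nd association scores
    W: np.ndarray  # Nm x k miRNA basis
    H: np.ndarray  # k x Nm low-dimensional miRNA representations
    X: np.ndarray  # Nd x k disease basis
    C: np.ndarray  # k x Nd low-dimensional disease representations

    @property
    def k_latent(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "FactorSet":
        return FactorSet(*(Z.copy() for Z in (self.U, self.W, self.H, self.X, self.C)))


@dataclasses.dataclass
class FitTrace:
    """Objective diagnostics of one optimizer run."""

    objective_values: list[float]
    n_iter: int
    converged: bool
    term_breakdown: dict[str, float]


def _sim_values(M) -> np.ndarray:
    return M.values if isinstance(M, SimilarityMatrix) else np.asarray(M, dtype=float)


def _assoc_values(A) -> tuple[np.ndarray, np.ndarray]:
    """Return (A, Y); for a bare array the mask Y equals A by definition."""
    if isinstance(A, AssociationMatrix):
        return A.values, A.mask
    A = np.asarray(A, dtype=float)
    return A, A


def initialize_factors(nm: int, nd: int, k_latent: int, seed: int) -> FactorSet:
    """Seeded uniform(0.01, 1) initialization, strictly positive everywhere.

    Multiplicative updates cannot revive an exact zero, so the lower bound
    keeps every entry updatable.
    """
    if min(nm, nd, k_latent) < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    draw = lambda *shape: rng.uniform(0.01, 1.0, shape)
    return FactorSet(
        U=draw(nm, nd),
        W=draw(nm, k_latent),
        H=draw(k_latent, nm),
        X=draw(nd, k_latent),
        C=draw(k_latent, nd),
    )


def objective(
    f: FactorSet,
    M,
    D,
    A,
    g: NeighborGraph,
    p: Hyperparameters,
) -> tuple[float, dict[str, float]]:
    """Evaluate F and its per-term breakdown at the current factors."""
    Mv, Dv = _sim_values(M), _sim_values(D)
    Av, Y = _assoc_values(A)
    U = f.U
    terms = {
        "mirna_reconstruction": float(np.sum((Mv - f.W @ f.H) ** 2)),
        "disease_reconstruction": p.alpha * float(np.sum((Dv - f.X @ f.C) ** 2)),
        "association_fit": p.beta * float(np.sum((Y * (Av - U)) ** 2)),
        "coupling": p.lam * float(np.sum((U - f.H.T @ f.C) ** 2)),
        "sparsity": p.delta * float(np.sum(np.abs(U))),
        # Tr(U.T (V - S) U) via row sums; equals the half double-sum form
        "graph": p.eta
        * float(np.sum(g.degrees[:, None] * U * U) - np.sum(U * (g.S @ U))),
    }
    total = float(sum(terms.values()))
    if not np.isfinite(total):
        raise FloatingPointError("non-finite objective value")
    return total, terms


def objective_gradients(
    f: FactorSet, M, D, A, g: NeighborGraph, p: Hyperparameters
) -> dict[str, np.ndarray]:
    """Analytic gradients of F (consistent convention) w.r.t. each factor."""
    Mv, Dv = _sim_values(M), _sim_values(D)
    Av, Y = _assoc_values(A)
    U, W, H, X, C = f.U, f.W, f.H, f.X, f.C
    resU = U - H.T @ C
    return {
        "U": 2 * p.beta * Y * (U - Av)
        + 2 * p.lam * resU
        + p.delta * np.ones_like(U)
        + 2 * p.eta * (g.degrees[:, None] * U - g.S @ U),
        "W": 2 * (W @ H - Mv) @ H.T,
        "H": 2 * W.T @ (W @ H - Mv) - 2 * p.lam * C @ resU.T,
        "X": 2 * p.alpha * (X @ C - Dv) @ C.T,
        "C": 2 * p.alpha * X.T @ (X @ C - Dv) - 2 * p.lam * H @ resU,
    }


def _mul_update(Z: np.ndarray, num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Z * num/den with the guard: cells whose denominator underflows stay put."""
    out = Z * (num / np.maximum(den, EPS))
    return np.where(den < EPS, Z, out)


def update_U(f: FactorSet, A, g: NeighborGraph, p: Hyperparameters) -> np.ndarray:
    Av, Y = _assoc_values(A)
    U = f.U
    HtC = f.H.T @ f.C
    SU = g.S @ U
    VU = g.degrees[:, None] * U
    if p.update_mode == "literal":
        num = 2 * Av + 2 * p.lam * HtC + 2 * p.eta * SU
        den = 2 * U + 2 * p.lam * U + 2 * p.eta * VU
    else:
        num = 2 * p.beta * (Y * Av) + 2 * p.lam * HtC + 2 * p.eta * SU
        den = 2 * p.beta * (Y * U) + 2 * p.lam * U + 2 * p.eta * VU + p.delta
    return _mul_update(U, num, den)


def update_H(f: FactorSet, M, p: Hyperparameters) -> np.ndarray:
    Mv = _sim_values(M)
    W, H, C, U = f.W, f.H, f.C, f.U
    m_weight = p.alpha if p.update_mode == "literal" else 1.0
    num = 2 * m_weight * W.T @ Mv + 2 * p.lam * C @ U.T
    den = 2 * m_weight * W.T @ W @ H + 2 * p.lam * C @ C.T @ H
    return _mul_update(H, num, den)


def update_W(f: FactorSet, M) -> np.ndarray:
    Mv = _sim_values(M)
    W, H = f.W, f.H
    return _mul_update(W, 2 * Mv @ H.T, 2 * W @ H @ H.T)


def update_X(f: FactorSet, D) -> np.ndarray:
    Dv = _sim_values(D)
    X, C = f.X, f.C
    return _mul_update(X, 2 * Dv @ C.T, 2 * X @ C @ C.T)


def update_C(f: FactorSet, D, p: Hyperparameters) -> np.ndarray:
    Dv = _sim_values(D)
    X, C, H, U = f.X, f.C, f.H, f.U
    num = 2 * p.alpha * X.T @ Dv + 2 * p.lam * H @ U
    den = 2 * p.alpha * X.T @ X @ C + 2 * p.lam * H @ H.T @ C
    return _mul_update(C, num, den)


def update_cycle(f: FactorSet, M, D, A, g: NeighborGraph, p: Hyperparameters) -> FactorSet:
    """One alternating pass in the order U, H, W, X, C (in place)."""
    f.U = update_U(f, A, g, p)
    f.H = update_H(f, M, p)
    f.W = update_W(f, M)
    f.X = update_X(f, D)
    f.C = update_C(f, D, p)
    return f


def _check_alignment(M: SimilarityMatrix, D: SimilarityMatrix, A: AssociationMatrix) -> None:
    if A.mirna_labels != M.labels:
        raise ValueError("miRNA labels of the association matrix do not match M")
    if A.disease_labels != D.labels:
        raise ValueError("disease labels of the association matrix do not match D")


def fit(
    M: SimilarityMatrix,
    D: SimilarityMatrix,
    A: AssociationMatrix,
    p: Hyperparameters,
    graph: NeighborGraph | None = None,
) -> tuple[FactorSet, FitTrace]:
    """Run the alternating multiplicative optimizer to convergence.

    Builds the miRNA kNN graph from ``M`` (unless supplied), initializes the
    factors from ``p.seed`` and cycles U, H, W, X, C until the relative
    objective decrease over :data:`CONVERGENCE_WINDOW` consecutive cycles
    drops below ``p.rel_tol`` or ``p.max_iter`` is reached.  The trace
    records F at initialization and after every cycle.
    """
    _check_alignment(M, D, A)
    if graph is None:
        graph = build_neighbor_graph(M, p.k_neighbors)
    f = initialize_factors(M.n, D.n, p.k_latent, p.seed)
    F, terms = objective(f, M, D, A, graph, p)
    values = [F]
    converged = False
    for it in range(1, p.max_iter + 1):
        update_cycle(f, M, D, A, graph, p)
        try:
            F, terms = objective(f, M, D, A, graph, p)
        except FloatingPointError as exc:
            raise FloatingPointError(f"objective diverged at iteration {it}") from exc
        values.append(F)
        logger.debug("iteration %d: F = %.10g", it, F)
        if it % 50 == 0:
            logger.info("iteration %d: F = %.10g", it, F)
        if it >= CONVERGENCE_WINDOW:
            ref = values[-1 - CONVERGENCE_WINDOW]
            if abs(ref - F) <= p.rel_tol * abs(ref):
                converged = True
                break
    return f, FitTrace(
        objective_values=values,
        n_iter=len(values) - 1,
        converged=converged,
        term_breakdown=terms,
    )


def rank_candidates(
    U: np.ndarray,
    A: AssociationMatrix,
    disease: str,
    exclude_known: bool = True,
) -> list[tuple[str, float]]:
    """Rank miRNAs for one disease by descending association score.

    With ``exclude_known`` (the default), miRNAs already associated with the
    disease are removed so the list contains only novel candidates.  Ties are
    broken by the order of the miRNA label list.
    """
    try:
        j = A.disease_labels.index(disease)
    except ValueError:
        raise KeyError(f"unknown disease {disease!r}") from None
    scores = np.asarray(U, dtype=float)[:, j]
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    order = np.argsort(-scores, kind="stable")
    out = []
    for i in order:
        if exclude_known and A.values[i, j] == 1:
            continue
        out.append((A.mirna_labels[i], float(scores[i])))
    return out
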