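"""Fivefold cross-validation over known associations and ranking metrics.

The protocol hides one fold of the observed 1-entries of ``A`` at a time
(zeroing both the entry and its indicator mask, so the training objective
carries no weight on held-out pairs), refits the model, and evaluates the
recovered scores per disease: held-out associations are positives, miRNAs
never associated with the disease are negatives, and training positives are
excluded from the candidate pool entirely.  AUC uses the rank-sum
(Mann-Whitney) formulation with 0.5 credit for ties; AUPR is the
non-interpolated average precision over distinct-score thresholds.
Per-disease metrics are averaged over the folds in which the disease has
test positives, then macro-averaged (unweighted) over diseases.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AssociationMatrix, Hyperparameters, SimilarityMatrix
from . import model

logger = logging.getLogger(__name__)

DEFAULT_K_GRID = (30, 60, 90)


@dataclasses.dataclass
class CVSplit:
    """Fold assignment for each observed association (1-entry of A)."""

    pairs: np.ndarray  # (n_positives, 2) row-major (miRNA, disease) indices
    fold_of: np.ndarray  # fold index per pair
    n_folds: int
    seed: int

    def test_pairs(self, fold: int) -> np.ndarray:
        return self.pairs[self.fold_of == fold]


@dataclasses.dataclass
class EvaluationReport:
    """Per-disease and macro-averaged ranking metrics from cross-validation."""

    per_disease: pd.DataFrame  # index: disease; columns: auc, aupr, recall@k, n_folds
    macro: dict[str, float]
    diseases_evaluated: list[str]
    n_folds: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "macro": self.macro,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "n_diseases_evaluated": len(self.diseases_evaluated),
        }


def make_folds(A: AssociationMatrix, n_folds: int, seed: int) -> CVSplit:
    """Uniform random partition of the known associations into folds.

    Fold sizes differ by at most one; the assignment is deterministic for a
    given seed.
    """
    pairs = A.positive_pairs()
    n = len(pairs)
    if n < n_folds:
        raise ValueError(f"{n} known associations cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, n_folds)):
        fold_of[chunk] = fold
    return CVSplit(pairs=pairs, fold_of=fold_of, n_folds=n_folds, seed=seed)


def mask_test_fold(
    A: AssociationMatrix, split: CVSplit, fold: int
) -> tuple[AssociationMatrix, np.ndarray]:
    """Zero one fold's entries (values and mask) and return the held-out pairs."""
    if not 0 <= fold < split.n_folds:
        raise ValueError(f"fold {fold} out of range for {split.n_folds} folds")
    train = A.copy()
    held_out = split.test_pairs(fold)
    train.values[held_out[:, 0], held_out[:, 1]] = 0.0
    train.mask[held_out[:, 0], held_out[:, 1]] = 0.0
    return train, held_out


def _two_classes(scores, positives, negatives):
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(sorted(positives), dtype=int)
    neg = np.asarray(sorted(negatives), dtype=int)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    if np.intersect1d(pos, neg).size:
        raise ValueError("positive and negative index sets overlap")
    return scores, pos, neg


def roc_auc(scores, positives, negatives) -> float:
    """Area under the ROC curve (Mann-Whitney form, 0.5 credit for ties)."""
    scores, pos, neg = _two_classes(scores, positives, negatives)
    pooled = np.concatenate([scores[pos], scores[neg]])
    ranks = stats.rankdata(pooled)
    n_pos, n_neg = len(pos), len(neg)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def pr_aupr(scores, positives, negatives) -> float:
    """Area under the precision-recall curve (non-interpolated AP).

    The threshold sweeps the distinct score values in descending order; tied
    scores enter the predicted-positive set simultaneously.
    """
    scores, pos, neg = _two_classes(scores, positives, negatives)
    pooled = np.concatenate([scores[pos], scores[neg]])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    order = np.argsort(-pooled, kind="stable")
    s_sorted, y_sorted = pooled[order], labels[order]
    tp = np.cumsum(y_sorted)
    predicted = np.arange(1, len(pooled) + 1)
    # last position of each distinct score = one point on the curve
    boundary = np.r_[np.nonzero(np.diff(s_sorted))[0], len(pooled) - 1]
    precision = tp[boundary] / predicted[boundary]
    recall = tp[boundary] / len(pos)
    return float(np.sum(np.diff(np.r_[0.0, recall]) * precision))


def recall_at_k(ranking, test_positives, k_values) -> dict[int, float]:
    """Fraction of held-out positives found in the top-k of a ranking."""
    test_positives = set(test_positives)
    if not test_positives:
        raise ValueError("test_positives must be non-empty")
    ranking = list(ranking)
    out = {}
    for k in k_values:
        if k < 1:
            raise ValueError("k values must be positive")
        hits = sum(1 for item in ranking[:k] if item in test_positives)
        out[int(k)] = hits / len(test_positives)
    return out


def _evaluate_fold(U, A_full, train, held_out, k_grid):
    """Per-disease metrics of one fold; returns disease index -> metric dict."""
    results = {}
    by_disease: dict[int, list[int]] = {}
    for i, j in held_out:
        by_disease.setdefault(int(j), []).append(int(i))
    for j, test_pos in by_disease.items():
        # negatives: miRNAs never associated with j; training positives are
        # excluded from the pool (neither positive nor negative)
        never = np.nonzero(A_full.values[:, j] == 0)[0]
        if never.size == 0:
            logger.info("disease %s skipped: no negatives", A_full.disease_labels[j])
            continue
        scores = U[:, j]
        auc = roc_auc(scores, test_pos, never)
        aupr = pr_aupr(scores, test_pos, never)
        candidates = np.array(sorted(set(test_pos) | set(never.tolist())))
        order = candidates[np.argsort(-scores[candidates], kind="stable")]
        recalls = recall_at_k(order.tolist(), test_pos, k_grid)
        results[j] = {"auc": auc, "aupr": aupr, **{f"recall@{k}": v for k, v in recalls.items()}}
    return results


def cross_validate(
    M: SimilarityMatrix,
    D: SimilarityMatrix,
    A: AssociationMatrix,
    p: Hyperparameters,
    n_folds: int = 5,
    seed: int = 0,
    k_grid=DEFAULT_K_GRID,
) -> EvaluationReport:
    """Fivefold (by default) cross-validation of the full pipeline."""
    split = make_folds(A, n_folds, seed)
    collected: dict[int, list[dict]] = {}
    for fold in range(n_folds):
        train, held_out = mask_test_fold(A, split, fold)
        factors, trace = model.fit(M, D, train, p)
        logger.info(
            "fold %d: fit %s after %d iterations (F = %.6g)",
            fold,
            "converged" if trace.converged else "stopped",
            trace.n_iter,
            trace.objective_values[-1],
        )
        for j, metrics in _evaluate_fold(factors.U, A, train, held_out, k_grid).items():
            collected.setdefault(j, []).append(metrics)
    if not collected:
        raise ValueError("no disease had test positives in any fold")
    rows = {}
    for j, fold_metrics in sorted(collected.items()):
        df = pd.DataFrame(fold_metrics)
        rows[A.disease_labels[j]] = {**df.mean().to_dict(), "n_folds": len(fold_metrics)}
    per_disease = pd.DataFrame.from_dict(rows, orient="index")
    metric_cols = [c for c in per_disease.columns if c != "n_folds"]
    macro = {c: float(per_disease[c].mean()) for c in metric_cols}
    return EvaluationReport(
        per_disease=per_disease,
        macro=macro,
        diseases_evaluated=list(per_disease.index),
        n_folds=n_folds,
        seed=seed,
    )


def paired_ttest(metric_a, metric_b) -> tuple[float, float]:
    """Two-sided paired t-test on two per-disease metric vectors.

    Returns (t statistic, p-value).  Utility for comparing two methods'
    per-disease AUC or AUPR columns.
    """
    res = stats.ttest_rel(np.asarray(metric_a, float), np.asarray(metric_b, float))
    return float(res.statistic), float(res.pvalue)


def grid_search(
    M: SimilarityMatrix,
    D: SimilarityMatrix,
    A: AssociationMatrix,
    base: Hyperparameters,
    grid: dict[str, list[float]],
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Exhaustive cross-validated sweep over hyperparameter candidates.

    ``grid`` maps weight names (alpha, beta, lam, delta, eta, ...) to
    candidate lists; all combinations are evaluated and returned sorted by
    macro AUC, best first.
    """
    import itertools

    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must provide a non-empty candidate list per parameter")
    names = list(grid)
    rows = []
    for combo in itertools.product(*(grid[n] for n in names)):
        p = base.replace(**dict(zip(names, combo)))
        report = cross_validate(M, D, A, p, n_folds=n_folds, seed=seed)
        rows.append(
            {**dict(zip(names, combo)), "macro_auc": report.macro["auc"], "macro_aupr": report.macro["aupr"]}
        )
    return pd.DataFrame(rows).sort_values("macro_auc", ascending=False, ignore_index=True)
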