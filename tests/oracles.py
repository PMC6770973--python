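"""Independent brute-force oracles used by the unit and acceptance tests.

Every function here recomputes a quantity by literal loops, avoiding the
matrix identities and vectorized shortcuts of the package implementation.
"""

import numpy as np


def loop_objective(f, M, D, A, g, p):
    """Elementwise double-loop evaluation of the objective, term by term."""
    Mv = M.values if hasattr(M, "values") and not isinstance(M, np.ndarray) else np.asarray(M)
    Dv = D.values if hasattr(D, "values") and not isinstance(D, np.ndarray) else np.asarray(D)
    if isinstance(A, np.ndarray):
        Av, Y = A, A
    else:
        Av, Y = A.values, A.mask
    U, W, H, X, C = f.U, f.W, f.H, f.X, f.C
    nm, nd = U.shape
    k = W.shape[1]

    m_term = 0.0
    for i in range(nm):
        for j in range(nm):
            m_term += (Mv[i, j] - sum(W[i, r] * H[r, j] for r in range(k))) ** 2
    d_term = 0.0
    for i in range(nd):
        for j in range(nd):
            d_term += (Dv[i, j] - sum(X[i, r] * C[r, j] for r in range(k))) ** 2
    assoc = 0.0
    coupling = 0.0
    sparsity = 0.0
    for i in range(nm):
        for j in range(nd):
            assoc += (Y[i, j] * (Av[i, j] - U[i, j])) ** 2
            coupling += (U[i, j] - sum(H[r, i] * C[r, j] for r in range(k))) ** 2
            sparsity += abs(U[i, j])
    graph = 0.0
    for j in range(nm):
        for l in range(nm):
            graph += g.S[j, l] * sum((U[j, c] - U[l, c]) ** 2 for c in range(nd))
    graph *= 0.5
    return m_term + p.alpha * d_term + p.beta * assoc + p.lam * coupling + p.delta * sparsity + p.eta * graph


def pair_count_auc(scores, positives, negatives):
    """Mann-Whitney AUC by explicit pair counting with 0.5 tie credit."""
    total = 0.0
    for i in positives:
        for j in negatives:
            if scores[i] > scores[j]:
                total += 1.0
            elif scores[i] == scores[j]:
                total += 0.5
    return total / (len(positives) * len(negatives))


def loop_average_precision(scores, positives, negatives):
    """All-thresholds precision-recall loop; thresholds at distinct scores."""
    idx = list(positives) + list(negatives)
    labels = {i: 1 for i in positives}
    thresholds = sorted({scores[i] for i in idx}, reverse=True)
    ap = 0.0
    prev_recall = 0.0
    n_pos = len(positives)
    for t in thresholds:
        predicted = [i for i in idx if scores[i] >= t]
        tp = sum(labels.get(i, 0) for i in predicted)
        precision = tp / len(predicted)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def finite_difference_gradient(fun, Z, step=1e-6):
    """Central finite differences of a scalar function of one array."""
    grad = np.zeros_like(Z)
    it = np.nditer(Z, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = Z[idx]
        Z[idx] = orig + step
        up = fun()
        Z[idx] = orig - step
        down = fun()
        Z[idx] = orig
        grad[idx] = (up - down) / (2 * step)
    return grad
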