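"""Effect of the kNN graph regularizer on the score matrix.

The graph term eta * Tr(U'(V-S)U) pulls the score rows of kNN-linked
miRNAs together.  Sweeping eta shows the mean score-row distance between
linked miRNAs shrinking by orders of magnitude while hidden-association
recovery degrades only gently: smoothing trades score fidelity for
neighborhood coherence.
"""

import numpy as np

from dmapred import Hyperparameters, fit, generate, recovery_auc
from dmapred.knn import build_neighbor_graph

inst = generate(nm=60, nd=40, k_true=4, density=0.05, hide_frac=0.2, noise=0.05, seed=3)
graph = build_neighbor_graph(inst.M, 5)
pairs = graph.linked_pairs()
print(f"kNN graph: {len(pairs)} linked miRNA pairs\n")
print(f"{'eta':>6}  {'mean linked-row distance':>25}  {'hidden-pair AUC':>15}")
for eta in (0.0, 0.4, 4.0, 100.0):
    params = Hyperparameters(eta=eta, k_latent=10, max_iter=600, rel_tol=1e-6,
                             update_mode="literal", seed=3)
    factors, _ = fit(inst.M, inst.D, inst.A_observed, params)
    dist = float(np.mean(np.linalg.norm(factors.U[pairs[:, 0]] - factors.U[pairs[:, 1]],
                                        axis=1)))
    print(f"{eta:6.1f}  {dist:25.4f}  {recovery_auc(inst, factors.U):15.4f}")
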