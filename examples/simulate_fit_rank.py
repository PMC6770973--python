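"""Fit the model on a planted instance and rank candidate miRNAs.

Generates a synthetic miRNA-disease problem with known hidden associations,
fits the factorization, and prints the top candidates for one disease.
Candidates marked [hidden truth] are associations the generator removed
from the training data: a good fit ranks them near the top.
"""

from dmapred import Hyperparameters, fit, generate, rank_candidates

inst = generate(nm=60, nd=40, k_true=4, density=0.05, hide_frac=0.2, noise=0.05, seed=0)
print(f"instance: {inst.A_observed.n_positives} observed associations, "
      f"{len(inst.hidden_pairs)} hidden")

params = Hyperparameters(k_latent=10, max_iter=600, rel_tol=1e-6,
                         update_mode="literal", seed=0)
factors, trace = fit(inst.M, inst.D, inst.A_observed, params)
print(f"fit {'converged' if trace.converged else 'stopped'} after {trace.n_iter} "
      f"cycles; objective {trace.objective_values[0]:.1f} -> {trace.objective_values[-1]:.3f}")

disease = inst.D.labels[int(inst.hidden_pairs[0][1])]  # a disease with a hidden pair
hidden_here = {inst.M.labels[i] for i, j in inst.hidden_pairs
               if inst.D.labels[j] == disease}
print(f"\ntop 10 novel candidates for {disease} "
      f"({len(hidden_here)} hidden true association(s)):")
for rank, (mirna, score) in enumerate(rank_candidates(factors.U, inst.A_observed,
                                                      disease)[:10], start=1):
    tag = "  [hidden truth]" if mirna in hidden_here else ""
    print(f"  {rank:2d}. {mirna}  score={score:.4f}{tag}")
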