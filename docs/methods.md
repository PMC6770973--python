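# Methods

## Model

The package predicts miRNA–disease associations by completing a sparse
binary matrix `A` (`Nm × Nd`) with the help of two similarity networks: a
miRNA functional-similarity matrix `M` and a disease semantic/phenotype
similarity matrix `D`, both symmetric with entries in [0, 1]. These
similarities are inputs; computing them (e.g., by Wang's functional
similarity from shared disease sets, or from MeSH semantic structure) is out
of scope.

The score matrix `U ≥ 0` and the projection factors `W, H` (for `M ≈ WH`)
and `X, C` (for `D ≈ XC`) minimize

```
F = ‖M − WH‖²_F + α‖D − XC‖²_F + β‖Y ⊙ (A − U)‖²_F
  + λ‖U − HᵀC‖²_F + δ‖U‖₁ + η Tr(Uᵀ(V − S)U)
```

subject to non-negativity of all five factors. `Y = A` is the indicator
mask, so the `β` term penalizes only deviations on observed associations.
`S` is the k-nearest-neighbor indicator of the miRNA network after
symmetrization `S ← (S_raw + S_rawᵀ)/2`, and `V` the diagonal of its row
sums; the trace form equals the pairwise penalty
`½η Σ_{jl} S_{jl}‖u_j − u_l‖²` (verified as a property test) and its
gradient is `2η(V − S)U`. Symmetrizing by averaging rather than by `max`
keeps the Laplacian `V − S` positive semi-definite, which the descent
argument for the multiplicative updates needs.

## Optimization

The problem is split into five sub-problems solved cyclically
(`U → H → W → X → C`) by multiplicative updates, e.g. in consistent mode

```
U ← U ⊙ (2β(Y⊙A) + 2λHᵀC + 2ηSU) / (2β(Y⊙U) + 2λU + 2ηVU + δB)
```

with `B` the all-ones matrix, and analogous rules for the other factors
(the `W` and `X` rules are the classical Lee–Seung updates for `M ≈ WH`
and `D ≈ XC`). Denominators are guarded at 1e-12; cells whose denominator
underflows are left unchanged, and no entry is ever clipped to exact zero
(a multiplicative scheme cannot revive an exact zero, which is also why
initialization draws uniformly from (0.01, 1)).

### Two update modes

`update_mode` selects between:

- **consistent** (default): every rule is the exact split-gradient/KKT rule
  of `F` as written above. Each update is non-increasing in `F`
  (majorization argument as in graph-regularized and sparse NMF), so the
  per-cycle objective trace is monotone, gradients match finite
  differences, and converged factors satisfy complementary slackness
  `Z ⊙ ∂F/∂Z = 0`. These three guarantees are enforced by the test suite.
- **literal**: the update formulas as published for this model family:
  the `H` rule carries weight `α` on the `M`-reconstruction part (whereas
  `F` as stated puts unit weight there), and the `U` rule is
  `U ← U ⊙ (2A + 2λHᵀC + 2ηSU)/(2U + 2λU + 2ηVU)`, i.e. without `β`, `Y`
  or `δ`. This corresponds to minimizing a *different* association term —
  fully observed, unit weight, no L1.

### Why predictive runs use the literal rules

With the published weights (`β = 0.1`, `δ = 1`) the consistent objective is
degenerate: for any entry of `U`, the L1 subgradient `δ = 1` exceeds the
largest possible pull of the association term `2β = 0.2`, so `F` is
minimized by `U ≡ 0` and the consistent updates duly drive every entry of
`U` below 1e-200 — a correct optimizer of a miscalibrated objective, and
useless for ranking. The literal rules do not collapse and reproduce the
intended behavior of the method; they are therefore the mode used in the
recovery and cross-validation experiments, while the consistent mode is the
reference implementation of the stated objective and the subject of the
descent/gradient/KKT guarantees. Consistent mode with a small `δ` (below
`2β`) is non-degenerate, but the package does not silently re-weight; the
choice is the user's.

The two modes coincide exactly when `α = 1`, `β = 1`, `δ = 0` and every
pair is observed (`Y` all ones); the suite checks bit-level agreement of
the iterates under those conditions.

## Parameters

| name | default | meaning |
|---|---|---|
| `alpha` | 0.1 | weight of the disease-network reconstruction `‖D − XC‖²` |
| `beta` | 0.1 | weight of the observed-association fit `‖Y⊙(A−U)‖²` |
| `lam` | 0.1 | coupling of `U` to the low-dimensional product `HᵀC` |
| `delta` | 1.0 | L1 sparsity pressure on `U` |
| `eta` | 0.4 | graph-Laplacian smoothing across kNN-linked miRNAs |
| `k_latent` | 100 | latent dimension; sized for the ~490×326 HMDD corpus, scale to ~`min(Nm,Nd)/4` for small instances |
| `k_neighbors` | 5 | kNN neighborhood of the miRNA graph (ties broken toward lower index for determinism) |
| `max_iter` | 1000 | cycle cap |
| `rel_tol` | 1e-6 | convergence threshold, see below |
| `seed` | 0 | initialization seed |

The weights are unitless; all default values are the ones selected for this
model family on the HMDD corpus out of the candidate set
{0.1, 0.4, 0.8, 1, 4, 8} (a cross-validated sweep over that set is available
as `grid_search` / `dmapred grid`).

### Convergence

Convergence is declared when the objective decrease over a window of 10
consecutive cycles falls below `rel_tol · |F|`. A single-cycle check stops
systematically too early for multiplicative updates: their per-cycle
decrease shrinks much faster than the distance to stationarity (sublinear
tail), and empirically leaves the elementwise KKT residual
`|Z ⊙ ∂F/∂Z|/|F|` around 1e-5 at a per-cycle threshold of 1e-8, versus
~5e-6 with the windowed check at the same threshold.

## Synthetic data

Real inputs (an HMDD association dump plus precomputed similarity matrices)
require external downloads, so all tests and the acceptance script run on
planted instances from `dmapred.synthetic.generate`:

- Latent loadings: each miRNA (and disease) is assigned one of `k_true`
  latent classes and receives a Gamma(2, 1) loading there, on top of a
  0.15·U(0, 1) background. The class structure mimics functional families —
  members are mutually similar and share association partners — which is
  precisely the coupling the model assumes, and it gives heterogeneous
  similarities rather than the uniformly high cosines of unstructured
  non-negative draws.
- Associations: the top `density` fraction of `G_m G_dᵀ` is thresholded to
  1 (exact positive counts, deterministic ties) rather than sampled
  per-entry, so tests are reproducible.
- Similarities: row-wise cosine of the loadings plus symmetric Gaussian
  noise of scale `noise`, clipped to [0, 1], unit diagonal kept exact.
- A `hide_frac` fraction of true associations is removed from the observed
  matrix; recovery experiments score these hidden pairs against
  never-associated pairs.

What the generator does **not** emulate: HMDD's empirical degree
distribution, disease-ontology hierarchy, literature-driven reporting
biases, or similarity matrices estimated from noisy annotation sets.
Passing recovery tests therefore shows that the optimizer exploits
planted low-rank-plus-network structure, not that a particular real-world
AUC will be attained.

The identity-similarity control (`identity_control`) replaces `M` and `D`
with identity matrices, removing all network signal while keeping the
associations; the margin of the structured instance over this control
isolates the contribution of the similarity networks beyond plain low-rank
completion.

## Evaluation protocol

Fivefold cross-validation partitions the observed 1-entries uniformly at
random (fold sizes within one of each other). Held-out entries are zeroed
in both `A` and `Y` of the training copy, so the association term carries
zero weight on them — leakage is structurally impossible and asserted in
tests. Per disease: held-out miRNAs are positives, never-associated miRNAs
negatives, training positives excluded from the pool. AUC is the rank-sum
(Mann–Whitney) statistic with 0.5 tie credit; AUPR is non-interpolated
average precision with thresholds at distinct scores (tied scores enter
simultaneously); recall@k counts held-out positives in the top-k of the
candidate ranking. Diseases without test positives in a fold are skipped
for that fold; per-disease values are averaged over evaluated folds and
then macro-averaged without weighting.

## Problem sizes used in the shipped experiments

The acceptance script runs fivefold CV on a 100×60 instance (rank 5,
density 0.05, `k_latent` 12) and the recovery experiment on 60×40 instances
(rank 4, density 0.05, 20% hidden, `k_latent` 10) over ten seeds, both with
the default weights and literal updates, 600-cycle cap. These sizes retain
the qualitative behavior of the method (similarity-driven recovery, skewed
per-disease difficulty) at desk scale.

## Integration with real data

Given a user-supplied HMDD snapshot with Wang-method miRNA similarities and
semantic/phenotype disease similarities (490 miRNAs, 326 diseases, 5088
associations), `dmapred evaluate` runs the same fivefold protocol at full
scale with `k_latent=100`; macro AUC on that corpus is expected in the
vicinity of 0.93 for this model family. This is an integration experiment —
the package ships no real data and the claim is not machine-checked here.

## Known limitations

- The literal update rules do not guarantee monotone descent of the stated
  objective (they descend a neighboring one); traces are monotone in
  practice but only the consistent mode is covered by the descent proof.
- `W`/`H` (and `X`/`C`) carry a multiplicative scale freedom; KKT residuals
  along that flat direction converge slowly, hence the windowed stopping
  rule.
- Multiplicative updates cannot introduce exact zeros, so "sparsity" under
  `δ` manifests as geometric decay toward zero rather than exact support
  selection.
- Diseases whose every positive lands in a single fold are evaluated in
  that fold only; with very sparse columns the per-disease averages rest on
  few folds.
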