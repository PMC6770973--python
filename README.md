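# dmapred

Graph-regularized, sparsity-constrained non-negative matrix factorization for
predicting disease-associated miRNA candidates.

## The problem

Experimentally confirmed miRNA–disease associations (e.g., from HMDD) cover a
small fraction of the plausible pairs. Because miRNAs with similar functions
tend to be associated with similar diseases, the missing entries of the
association matrix can be inferred by combining three heterogeneous inputs:

- `M` — an `Nm × Nm` miRNA functional-similarity matrix (values in [0, 1]),
- `D` — an `Nd × Nd` disease semantic/phenotype-similarity matrix,
- `A` — the sparse binary `Nm × Nd` association matrix, with indicator mask
  `Y = A`.

`dmapred` estimates a non-negative score matrix `U ∈ R^{Nm×Nd}` whose column
`U[:, j]` ranks every miRNA as a candidate for disease `j`.

## The model

`U` is found jointly with low-dimensional projections of both similarity
networks — `M ≈ WH`, `D ≈ XC` with `W ∈ R^{Nm×k}`, `H ∈ R^{k×Nm}`,
`X ∈ R^{Nd×k}`, `C ∈ R^{k×Nd}` — by minimizing

```
F(U, W, H, X, C) = ‖M − WH‖²_F + α‖D − XC‖²_F + β‖Y ⊙ (A − U)‖²_F
                 + λ‖U − HᵀC‖²_F + δ‖U‖₁ + η Tr(Uᵀ(V − S)U),
```

over non-negative factors, where `S` is the symmetrized k-nearest-neighbor
indicator of the miRNA network, `V = diag(S·1)` its degree matrix, and
`η Tr(Uᵀ(V−S)U) = ½η Σ_{jl} S_{jl}‖u_j − u_l‖²` pulls the score rows of
similar miRNAs together. The `λ` term couples the scores to the product of
the two low-dimensional representations; the `δ` term encodes the sparsity
of true associations. Default weights are `α = β = λ = 0.1`, `δ = 1`,
`η = 0.4`.

Each factor is optimized in turn by multiplicative updates. Two rule sets
are provided (`update_mode`):

- `consistent` (default) — every rule is derived from `F` exactly, so the
  objective is provably non-increasing and converges to a KKT point;
- `literal` — the update formulas as published (`α` moved onto the `M` term
  in the `H` update; `β`, `Y` and `δ` absent from the `U` update).

The distinction matters: under the consistent rules with `δ = 1` the L1
penalty dominates the association term and drives `U` to the degenerate
optimum `U ≡ 0`, so predictive runs use the literal rules. See
`docs/methods.md` for the full analysis.

## Worked example

```sh
python examples/simulate_fit_rank.py
```

```
instance: 96 observed associations, 24 hidden
fit stopped after 600 cycles; objective 23491.4 -> 114.954

top 10 novel candidates for disease-0024 (2 hidden true association(s)):
   1. mir-0045  score=0.2876
   2. mir-0019  score=0.2775  [hidden truth]
   3. mir-0007  score=0.2736
   ...
   5. mir-0001  score=0.2602  [hidden truth]
```

A planted synthetic instance (60 miRNAs × 40 diseases, rank-4 latent
structure, 20% of true associations hidden) is generated, the model is
fitted on the observed associations only, and candidates for one disease are
ranked by `U[:, j]`. Both associations that the generator hid for this
disease surface in the top 5 of 60 candidates — the factorization recovers
them from the similarity structure alone. The other examples run fivefold
cross-validation (`examples/cross_validation.py`) and sweep the graph
regularizer `η` (`examples/graph_regularization.py`).

The same workflow is scriptable from a shell:

```sh
dmapred simulate --nm 60 --nd 40 --outdir run/
dmapred fit --m run/M.tsv --d run/D.tsv --associations run/associations.tsv \
        --update-mode literal --k-latent 10 --outdir run/fit/
dmapred predict --scores run/fit/scores.tsv --associations run/associations.tsv \
        --disease disease-0024 --top 10 --out run/candidates.tsv
dmapred evaluate --m run/M.tsv --d run/D.tsv --associations run/associations.tsv \
        --update-mode literal --k-latent 10 --outdir run/cv/
```

All formats are plain delimited text: labeled square matrices for `M`/`D`,
a two-column edge list for `A`.

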