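# flatrank

Flattenings of Markov models on phylogenetic trees: exact ranks, parsimony
cuts, split scores, and tree-rearrangement distances.

## The problem

Under the general Markov model of sequence evolution, a rooted tree `T`
with root distribution `π_ρ` and a row-stochastic `r × r` transition matrix
`P_uv` on every edge determines a probability for each *pattern* — each
assignment of states to the `n` taxa:

```
π(X_V = F) = π_ρ(F(ρ)) · ∏_{(u,v)} P_uv(F(u), F(v)),
```

marginalized over internal vertices.  The `r^n` pattern probabilities form
a tensor; arranging them into a matrix whose rows are indexed by the state
assignments to one vertex set `A` and columns by assignments to a disjoint
set `B` gives the **flattening** `flat_{A|B}`, the tensor unfolding along
the bipartition `A|B`.

The rank of this matrix ties the algebra of the model to the combinatorics
of the tree.  Under mild regularity conditions —

* **C1** every `P_uv` nonsingular,
* **C2** `π_ρ` strictly positive,
* **C3** `P_uv` strictly positive on internal edges —

the rank is exactly

```
rank(flat_{A|B}) = r^{ν_T(A|B)},
```

where `ν_T(A|B)` is the minimum number of vertices whose removal separates
`A` from `B` (equivalently, by Menger's theorem, the maximum number of
vertex-disjoint `A`–`B` paths).  On binary trees with `A, B` sets of
leaves, `ν` coincides with the parsimony length `ℓ_T(A|B)` of the binary
character that is 0 on `A` and 1 on `B`; and for a bipartition of the taxa,
`ν − 1` equals the SPR (and TBR) rearrangement distance from `T` to the
nearest binary tree that contains the split `A|B`.  In particular an edge
split has rank `r` (which is why SVD-based split scores work), any
non-split has rank at least `r²`, and none of C1–C3 can be dropped:
zeroing a single root or internal-edge entry collapses the non-split rank
below `r²`.

This package is for people who want to *compute and check* these objects:
flattenings of arbitrary vertex subsets (internal vertices included), exact
certified ranks via rational arithmetic, cut sizes with max-flow/min-cut
certificates, split scores of model or alignment flattenings, and
exhaustive SPR/TBR searches that certify the distance formula on small
trees.

## Worked example

Generate the four-taxon, two-state worked quartet (tree `((1,2),(3,4))`
with seeded generic parameters), then interrogate the split `{1,3}|{2,4}`
— which is *not* a split of the tree:

```
$ flatrank fixture --kind worked_quartet --seed 5 --out-dir demo
$ flatrank verify --tree demo/tree.nwk --params demo/params.yaml --A 1,3 --B 2,4
{
  "n_leaves": 4,
  "A": [0, 3],
  "B": [1, 4],
  "r": 2,
  "nu": 2,
  "ell": 2,
  "predicted_rank": 4,
  "numerical_rank": 4,
  "agree": true,
  "spectrum": [0.3240722899220158, 0.14807420960200263,
               0.05004494294639941, 0.005472186636707966],
  "tolerance": 3.240722899220158e-10
}
```

Reading: separating `{1,3}` from `{2,4}` requires deleting `ν = 2`
vertices, so the flattening must have rank `2² = 4` — and its singular
spectrum indeed has four values far above tolerance (`agree: true`).  The
cut and its dual certificate:

```
$ flatrank nu --tree demo/tree.nwk --A 1,3 --B 2,4
{
  "nu": 2,
  "witness_cut": [1, 4],
  "witness_paths": [[0, 2, 1], [3, 5, 4]]
}
```

two vertex-disjoint paths, and a two-vertex separator.  The rearrangement
reading — one SPR move suffices to reach a tree containing the split, as
certified by exhaustive search:

```
$ flatrank splitdist --tree demo/tree.nwk --A 1,3 --B 2,4 --certify
{
  "nu": 2,
  "spr_distance": 1,
  "tbr_distance": 1,
  "bfs_spr_distance": 1,
  "bfs_tbr_distance": 1,
  "certified": true,
  "spr_witness": "(2,4,(1,3));"
}
```

Other subcommands: `simulate` (iid sites to FASTA), `flatten` (model or
empirical flattening as TSV), `rank`, `score`, `parsimony`, `degeneracy`
(rank collapse under a zeroed entry), and `suite` (the full verification
harness; exit code 2 on any disagreement).  All randomized commands are
reproducible under `--seed`.

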