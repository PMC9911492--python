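# Methods

This note records the models, algorithms, numerical choices, and design
decisions behind `flatrank`, in the order the data flows through the
package.

## Trees and addressing

A phylogeny is stored as an undirected connected acyclic graph whose
degree-one vertices carry unique taxon labels.  Internal vertices are
deliberately first-class: the vertex subsets `A`, `B` that index
flattenings and cuts may contain them, so every vertex is addressable — by
taxon label, by Newick internal label, by its deterministic post-order
integer id, or by the collision-proof form `#id`.  Rooting is an
annotation only; the undirected edge set never changes, and any algorithm
needing an orientation reroots explicitly.  This reflects the model-level
fact that root placement does not affect leaf pattern probabilities
(re-rooting updates parameters by Bayes reversal and leaves the joint
distribution unchanged, which the tests verify to 1e−12 in floating point
and exactly in rational mode).

Newick dialect: internal labels are kept, branch lengths are parsed and
discarded (edges carry transition matrices, not lengths).  An unlabeled
basal bifurcation is suppressed by default, so `((1,2),(3,4));` is the
six-vertex unrooted quartet; `rooted=True` keeps the outermost vertex.
Degree-two vertices are storable (rearrangements create them transiently)
and a suppression utility removes them.

## Cuts and parsimony

`ell(T, A, B)` is the parsimony length of the two-state indicator
character (0 on `A`, 1 on `B`): the minimum number of edges whose deletion
leaves no component meeting both sets.  It is computed two ways that must
agree: unit-cost Sankoff dynamic programming with clamped domain vertices
(Fitch's set rule is not used because the domain may include internal
vertices and the state count is arbitrary), and unit-capacity max flow,
which also yields the Menger certificate pair — a separating edge cut and
an edge-disjoint path system of the same cardinality.

`nu(T, A, B)` is the vertex analogue, computed by the standard
vertex-splitting flow reduction with the terminals' internal arcs also at
capacity one, so the optimal cut may contain members of `A ∪ B` — required
for correctness of the rank formula with internal-vertex subsets.  Both
functions validate their certificates internally (paths disjoint, cut
separating, cardinalities equal) before returning.  Trees here are tiny,
so no attempt is made at asymptotically optimal flow; any augmenting-path
scheme is adequate.

Exhaustive oracles (`brute_force_ell` over all `r^{|V∖dom|}` extensions,
`brute_force_nu` over vertex subsets in increasing size) guard the fast
paths in tests, with size guards of 15 free vertices and 18 vertices
respectively.

The efficient flow reduction covers only the two-block indicator case
`A|B` used by the rank formula; the general multistate vertex cut of an
arbitrary character is exposed only through the brute-force oracle, since
no efficient algorithm for it is implemented here.

## The Markov model

States are 0-based integers `0..r−1`; alphabet maps (`RY`, `ACGT`, letters)
apply only at I/O boundaries.  Parameters are a root distribution plus one
row-stochastic matrix per directed edge.  Marginals of arbitrary partial
assignments are computed by one upward message-passing pass with queried
vertices clamped; full leaf-pattern tensors use a message-tensor variant
costing `O(r^{n+1})`, appropriate for the desk-scale trees this package
targets (a dense-size guard of 2^24 entries refuses larger flattenings).

**Exact mode.** Rank is discontinuous, so numerical rank claims near
threshold are unconvincing.  When parameters are `fractions.Fraction`
(either user-supplied as `"p/q"` strings in YAML or generated with
`exact=True`), every probability, flattening entry, re-rooted parameter,
and rank is computed in exact rational arithmetic; exact rank uses
Gaussian elimination with normalized pivots over the rationals.  The test
suite cross-checks this elimination against an independent computer-algebra
rank on random low-rank rational matrices.

**Condition checking.** C1 (nonsingularity, per edge), C2 (positive root
distribution), C3 (positivity on internal edges only — pendant edges may
legitimately contain zeros) are evaluated independently with witnesses and
never silently repaired.  Floating-point singularity uses a 1e−12
determinant threshold; exact mode decides exactly.

**Parameter generation.** Rows and the root distribution are flat
Dirichlet draws, resampled (budget 1000) until `|det| ≥ 1e−6` per matrix
and entries `≥ 1e−3` where positivity is structurally required (root and
internal edges).  These guards keep generic singular spectra well
separated on trees of ≤ 12 leaves, so numerical and exact ranks agree in
practice.  Exact mode rounds each draw to a fraction with denominator
≤ 1000 and renormalizes exactly — the bounded denominators keep exact
elimination fast while remaining generic (a zero determinant after
rounding would be resampled; it has not been observed).

## Flattenings

Row index of an assignment is base-`r` with the **last listed vertex
varying fastest**, so the row order of a two-part flattening reads like a
lexicographic pattern table; the convention is part of the stored value
and tested positionally against the pattern tensor.  Two construction
routes — reshaping the full leaf tensor (when `A ∪ B` are leaves) and
per-entry clamped marginals (always) — are both exposed and must agree.

Numerical rank counts singular values above `1e−9 · σ_max` by default.
The tolerance is deliberately loose relative to machine precision: true
ranks here are powers of `r` with large spectral gaps for generic
parameters, and the report includes the largest relative gap as a
diagnostic for borderline spectra.  Exact mode is the arbiter in tests.
The split score is `(Σ_{i>r^k} σ_i) / (Σ_i σ_i)` with the conventional
`k = 1` default, generalized to `k` because larger blocks are meaningful
for multi-vertex sides.  For empirically estimated flattenings no hard
rank is reported — sampling noise makes every singular value positive —
only the spectrum and score.

## Rearrangements and distances

SPR removes an edge and reconnects one endpoint to a point of the opposite
component; TBR removes an edge and joins arbitrary points of the two
components; degree-two vertices are suppressed afterwards.  Neighborhoods
are enumerated exhaustively, deduplicated by the canonical nontrivial
split set (binary leaf-labeled trees are isomorphic iff their split sets
coincide), and exclude the starting topology.  The SPR neighborhood count
matches the closed form `2(n−3)(2n−7)`, and a hand-derived pure-TBR
topology on the six-leaf caterpillar is verified to lie in the TBR but not
the SPR neighborhood.

The distance from a binary tree to the nearest tree containing a given
taxon bipartition is reported as `ν − 1`; on trees of at most 7 leaves a
breadth-first search over the one-move graph certifies it (and returns a
witness tree).  Larger trees fall back to the formula with a warning — the
neighborhood graph grows too fast for exhaustive search to stay honest.
Neighborhoods are memoized by topology key, which makes whole-space
certification on 6 leaves cheap.

## Degeneracy of the conditions

`degeneracy_demo` zeroes one root entry or one internal-edge entry and
renormalizes the affected row (the zeroed object must remain a probability
distribution; renormalization preserves the zero pattern that drives the
collapse).  For a quartet, gathering terms of the joint probability around
the internal edge `(u,v)` factors the non-split flattening as `U D V` with
diagonal `D_{ij} = π(i) P_uv(i,j)`, so the rank equals the number of
nonzero diagonal entries when `U`, `V` are generic: zeroing a root entry
removes `r` of them, an edge entry removes one, and either pushes the rank
strictly below `r²`.  The demo reports both the predicted count and the
exact rank.

## Scale of the shipped verification runs

The test suite and `scripts/acceptance.py` run the harnesses at these
sizes, chosen so every stochastic claim has enough replicates while the
whole suite stays interactive: 50 exact-arithmetic rank-formula instances
on trees of 4–10 leaves (binary and multifurcating, `r ∈ {2,3}`, subsets
of up to 3 vertices per side, internal vertices included); 200 binary
trees for cut equality; 200 instances per oracle-equivalence family
(extension enumeration capped at 6-leaf trees so the brute-force side
stays exhaustive); all 310 bipartitions of ten 6-leaf trees for
BFS-certified distances.  The synthetic generator is the study condition
here: what passing shows is that the implementation realizes the theory on
generic seeded instances, not anything about a particular empirical
dataset — the one data-facing claim (empirical split scores of simulated
alignments falling with site count) is exercised separately at 50 000
sites.

## Known limitations

* Flattenings are dense; genome-scale `r^{|A|}` is out of scope.
* No tree inference: split scores are computed, never optimized over
  quartets or assemblies.
* `d_SPR`/`d_TBR` between two arbitrary trees is not computed (NP-hard);
  only the distance to the nearest tree containing a given split, which
  the cut formula supplies directly.
* Continuous-time rate matrices and likelihood fitting are out of scope;
  the model is parameterized directly by stochastic matrices.
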