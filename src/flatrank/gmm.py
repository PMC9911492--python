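"""General Markov model on a tree: parameters, probabilities, simulation.

The model attaches a root distribution ``pi`` to a chosen root vertex and a
row-stochastic ``r x r`` transition matrix to every edge directed away from
the root.  The joint probability of a full state assignment ``F`` is

    pi(F(root)) * prod over directed edges (u, v) of P_uv(F(u), F(v)),

and marginals over arbitrary vertex subsets (leaves or internal) follow by
summation — computed here by message passing along the tree with the
queried vertices clamped.

Three regularity conditions govern the rank results downstream:

* C1 — every transition matrix is nonsingular;
* C2 — the root distribution is strictly positive;
* C3 — transition matrices on internal edges are strictly positive.

``check_conditions`` evaluates each independently and reports witnesses;
nothing is ever silently repaired.

All probability computations run in either floating point or exact rational
arithmetic: when parameters are :class:`fractions.Fraction`, every joint,
marginal, flattening entry, and re-rooted parameter is exact, which lets
matrix ranks be certified without numerical tolerances.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cutsets import Character
from .trees import Phylogeny, VertexRef

__all__ = [
    "GMMParams",
    "ConditionReport",
    "Alignment",
    "GenerationError",
    "DegenerateModelError",
    "check_conditions",
    "joint_probability",
    "marginal",
    "vertex_marginals",
    "pairwise_joint",
    "pairwise_transition",
    "reroot_params",
    "pattern_tensor",
    "random_generic_params",
    "simulate_alignment",
    "load_params",
    "save_params",
    "default_alphabet",
    "exact_det",
]


class GenerationError(RuntimeError):
    """Random parameter generation exhausted its resampling budget."""


class DegenerateModelError(ValueError):
    """An operation required conditions C1-C3 and they do not hold."""


def _is_exact(arr: np.ndarray) -> bool:
    return arr.dtype == object


def exact_det(M: np.ndarray) -> Fraction:
    """Determinant by exact fraction Gaussian elimination (small r)."""
    A = [[Fraction(x) for x in row] for row in np.asarray(M, dtype=object)]
    n = len(A)
    det = Fraction(1)
    for col in range(n):
        pivot = next((i for i in range(col, n) if A[i][col] != 0), None)
        if pivot is None:
            return Fraction(0)
        if pivot != col:
            A[col], A[pivot] = A[pivot], A[col]
            det = -det
        det *= A[col][col]
        inv = 1 / A[col][col]
        for i in range(col + 1, n):
            factor = A[i][col] * inv
            if factor:
                A[i] = [a - factor * b for a, b in zip(A[i], A[col])]
    return det


@dataclass
class GMMParams:
    """Root distribution plus per-directed-edge transition matrices.

    ``edge_matrices`` is keyed by ``(parent, child)`` pairs in the
    orientation away from ``root``.  Exact mode is inferred from the dtype:
    object arrays of :class:`fractions.Fraction` trigger exact arithmetic
    throughout the package.
    """

    r: int
    root: int
    root_dist: np.ndarray
    edge_matrices: dict[tuple[int, int], np.ndarray]

    def __post_init__(self) -> None:
        self.root_dist = np.asarray(self.root_dist)
        self.edge_matrices = {
            (int(u), int(v)): np.asarray(P) for (u, v), P in self.edge_matrices.items()
        }

    @property
    def exact(self) -> bool:
        return _is_exact(self.root_dist)

    def zero(self):
        return Fraction(0) if self.exact else 0.0

    def one(self):
        return Fraction(1) if self.exact else 1.0

    def validate(self, tree: Phylogeny, atol: float = 1e-12) -> None:
        """Structural validity: stochasticity and edge coverage.

        This is *not* the C1-C3 check — degenerate but well-formed
        parameters are storable on purpose (see ``degeneracy_demo``).
        """
        if self.root_dist.shape != (self.r,):
            raise ValueError("root distribution has wrong length")
        if set(self.edge_matrices) != set(tree.directed_edges(self.root)):
            raise ValueError("edge matrices do not cover the rooted edge set")
        def close(x, y):
            return abs(float(x - y)) <= atol
        if not close(sum(self.root_dist), 1):
            raise ValueError("root distribution does not sum to 1")
        if any(float(x) < -atol for x in self.root_dist):
            raise ValueError("negative root probability")
        for (u, v), P in self.edge_matrices.items():
            if P.shape != (self.r, self.r):
                raise ValueError(f"matrix on edge ({u},{v}) has wrong shape")
            for i in range(self.r):
                if not close(sum(P[i]), 1):
                    raise ValueError(f"row {i} of edge ({u},{v}) does not sum to 1")
                if any(float(x) < -atol for x in P[i]):
                    raise ValueError(f"negative entry in edge ({u},{v}) row {i}")

    def topological_edges(self) -> list[tuple[int, int]]:
        """Directed edges ordered parents-first from the root, regardless
        of the insertion order of ``edge_matrices`` (e.g. file order)."""
        children: dict[int, list[int]] = {}
        for (u, v) in self.edge_matrices:
            children.setdefault(u, []).append(v)
        order: list[tuple[int, int]] = []
        frontier = [self.root]
        while frontier:
            u = frontier.pop()
            for v in sorted(children.get(u, [])):
                order.append((u, v))
                frontier.append(v)
        if len(order) != len(self.edge_matrices):
            raise ValueError("edge matrices are not a tree rooted at the root")
        return order

    def copy(self) -> "GMMParams":
        return GMMParams(
            self.r,
            self.root,
            self.root_dist.copy(),
            {e: P.copy() for e, P in self.edge_matrices.items()},
        )


@dataclass(frozen=True)
class ConditionReport:
    """Outcome of the C1-C3 check, with a witness for each failure."""

    c1: bool
    c1_witness: Optional[str]
    c2: bool
    c2_witness: Optional[str]
    c3: bool
    c3_witness: Optional[str]

    @property
    def ok(self) -> bool:
        return self.c1 and self.c2 and self.c3

    def as_dict(self) -> dict:
        return {
            "C1": {"pass": self.c1, "witness": self.c1_witness},
            "C2": {"pass": self.c2, "witness": self.c2_witness},
            "C3": {"pass": self.c3, "witness": self.c3_witness},
        }


def check_conditions(
    tree: Phylogeny, params: GMMParams, singular_tol: float = 1e-12
) -> ConditionReport:
    """Evaluate C1 (nonsingular matrices), C2 (positive root distribution),
    C3 (positive entries on internal edges) independently.

    Violations are reported with the offending edge or entry; nothing is
    fixed.  In exact mode singularity and positivity are decided exactly.
    """
    c1, w1 = True, None
    c2, w2 = True, None
    c3, w3 = True, None
    for (u, v), P in sorted(params.edge_matrices.items()):
        if params.exact:
            singular = exact_det(P) == 0
        else:
            singular = abs(np.linalg.det(P.astype(float))) <= singular_tol
        if singular and c1:
            c1, w1 = False, f"edge ({u},{v}) matrix is singular"
        internal = not tree.is_leaf(u) and not tree.is_leaf(v)
        if internal and c3:
            for i, j in itertools.product(range(params.r), repeat=2):
                if not P[i][j] > 0:
                    c3, w3 = False, f"edge ({u},{v}) entry ({i},{j}) = 0"
                    break
    for i in range(params.r):
        if not params.root_dist[i] > 0:
            c2, w2 = False, f"root distribution entry i={i} is not positive"
            break
    return ConditionReport(c1, w1, c2, w2, c3, w3)


# ---------------------------------------------------------------------------
# Probabilities
# ---------------------------------------------------------------------------


def joint_probability(tree: Phylogeny, params: GMMParams, F: Mapping[VertexRef, int]):
    """Probability of a full assignment: the product over directed edges."""
    full = {tree.resolve(v): s for v, s in F.items()}
    missing = set(tree.vertices) - set(full)
    if missing:
        raise ValueError(f"assignment missing vertices {sorted(missing)}")
    p = params.root_dist[full[params.root]]
    for (u, v), P in params.edge_matrices.items():
        p = p * P[full[u]][full[v]]
    return p


def marginal(tree: Phylogeny, params: GMMParams, char: Character):
    """Marginal probability of a partial assignment.

    One upward pass of message passing from the leaves to the model root:
    vertices in the character's domain are clamped, all others summed out.
    Exact when the parameters are rational.
    """
    if char.r != params.r:
        raise ValueError("character state count does not match the model")
    char.validate_on(tree)
    clamp = {tree.resolve(v): s for v, s in char.assignment.items()}
    r = params.r
    root = params.root
    parent = tree.parent_map(root)
    one, zero = params.one(), params.zero()
    msgs: dict[int, np.ndarray] = {}
    for v in tree.postorder(root):
        vec = np.full(r, one, dtype=object if params.exact else float)
        if v in clamp:
            ind = np.full(r, zero, dtype=vec.dtype)
            ind[clamp[v]] = one
            vec = vec * ind
        for u in tree.neighbors(v):
            if parent.get(u) == v:
                vec = vec * (params.edge_matrices[(v, u)] @ msgs[u])
        msgs[v] = vec
    total = params.root_dist @ msgs[root]
    return total


def vertex_marginals(tree: Phylogeny, params: GMMParams) -> dict[int, np.ndarray]:
    """Marginal state distribution at every vertex, by forward propagation."""
    mu = {params.root: params.root_dist.copy()}
    for u, v in params.topological_edges():
        mu[v] = mu[u] @ params.edge_matrices[(u, v)]
    return mu


def pairwise_joint(tree: Phylogeny, params: GMMParams, u: VertexRef, v: VertexRef):
    """The r x r matrix M with M[i, j] = P(X_u = i, X_v = j).

    Nonsingular whenever C1-C3 hold, for any pair of vertices.
    """
    u, v = tree.resolve(u), tree.resolve(v)
    r = params.r
    M = np.empty((r, r), dtype=object if params.exact else float)
    for i, j in itertools.product(range(r), repeat=2):
        M[i, j] = marginal(tree, params, Character(r, {u: i, v: j}))
    return M


def pairwise_transition(tree: Phylogeny, params: GMMParams, u: VertexRef, v: VertexRef):
    """Conditional matrix P(X_v = j | X_u = i) for arbitrary u, v.

    Derived as the pairwise joint divided by the marginal at ``u``; exposed
    for the nonsingularity property, not used by the core computations.
    """
    u, v = tree.resolve(u), tree.resolve(v)
    M = pairwise_joint(tree, params, u, v)
    mu = vertex_marginals(tree, params)[u]
    out = np.empty_like(M)
    for i in range(params.r):
        if not mu[i] > 0:
            raise DegenerateModelError(f"P(X_{u} = {i}) = 0; conditional undefined")
        out[i] = M[i] / mu[i] if not params.exact else np.array(
            [x / mu[i] for x in M[i]], dtype=object
        )
    return out


def reroot_params(tree: Phylogeny, params: GMMParams, new_root: VertexRef) -> GMMParams:
    """Move the model root, preserving the joint distribution exactly.

    The new root distribution is the marginal at the new root; every edge
    whose orientation flips receives the Bayes-reversed matrix
    ``P'(i, j) = mu_v(j) P_vu(j, i) / mu_u(i)``.  Requires the vertex
    marginals involved to be positive, which C1 + C2 guarantee.
    """
    nr = tree.resolve(new_root)
    if nr == params.root:
        return params.copy()
    mu = vertex_marginals(tree, params)
    new_edges: dict[tuple[int, int], np.ndarray] = {}
    for (u, v) in tree.directed_edges(nr):
        if (u, v) in params.edge_matrices:
            new_edges[(u, v)] = params.edge_matrices[(u, v)].copy()
        else:
            Q = params.edge_matrices[(v, u)]  # old orientation v -> u
            P = np.empty((params.r, params.r), dtype=Q.dtype)
            for i in range(params.r):
                if not mu[u][i] > 0:
                    raise DegenerateModelError(
                        f"cannot reverse edge ({v},{u}): P(X_{u} = {i}) = 0"
                    )
                for j in range(params.r):
                    P[i, j] = mu[v][j] * Q[j][i] / mu[u][i]
            new_edges[(u, v)] = P
    return GMMParams(params.r, nr, mu[nr].copy(), new_edges)


# ---------------------------------------------------------------------------
# Pattern tensors
# ---------------------------------------------------------------------------


def _full_leaf_tensor(tree: Phylogeny, params: GMMParams, leaf_order: Sequence[int]):
    """Joint tensor over all leaves, axes in ``leaf_order``.

    Message-tensor dynamic programming: the message at a vertex is an array
    over (own state, patterns of leaves beneath), combined across children
    by outer products after pushing each child message through its edge
    matrix.  Cost is O(r^(n+1)) — fine for the desk-scale trees this
    package targets.
    """
    r = params.r
    root = params.root
    parent = tree.parent_map(root)
    dtype = object if params.exact else float
    msgs: dict[int, np.ndarray] = {}
    below: dict[int, list[int]] = {}
    for v in tree.postorder(root):
        if tree.is_leaf(v):
            acc = np.eye(r, dtype=dtype)
            if params.exact:
                acc = np.array(
                    [[Fraction(int(x)) for x in row] for row in np.eye(r, dtype=int)],
                    dtype=object,
                )
            leaves_here = [v]
        else:
            acc = np.full((r, 1), params.one(), dtype=dtype)
            leaves_here = []
        for u in tree.neighbors(v):
            if parent.get(u) == v:
                pushed = params.edge_matrices[(v, u)] @ msgs[u]
                acc = (acc[:, :, None] * pushed[:, None, :]).reshape(r, -1)
                leaves_here = leaves_here + below[u]
        msgs[v] = acc
        below[v] = leaves_here
    flat = params.root_dist @ msgs[root]
    tensor = flat.reshape((r,) * len(below[root]))
    perm = [below[root].index(v) for v in leaf_order]
    return np.transpose(tensor, axes=perm)


def pattern_tensor(
    tree: Phylogeny,
    params: GMMParams,
    vertices: Optional[Sequence[VertexRef]] = None,
):
    """Joint probability tensor over an ordered vertex list.

    Defaults to the leaves in taxon-label order.  When the query is a set
    of leaves the full leaf tensor is computed once and marginalized by
    axis summation; otherwise each entry is a clamped marginal.
    """
    if vertices is None:
        verts = tuple(tree.leaves())
    else:
        verts = tree.resolve_all(vertices)
    if len(set(verts)) != len(verts):
        raise ValueError("vertex list contains repeats")
    leaves = tree.leaves()
    if set(verts) <= set(leaves):
        full = _full_leaf_tensor(tree, params, leaves)
        drop = tuple(i for i, v in enumerate(leaves) if v not in verts)
        if drop:
            full = full.sum(axis=drop)
        kept = [v for v in leaves if v in verts]
        perm = [kept.index(v) for v in verts]
        return np.transpose(full, axes=perm)
    r = params.r
    out = np.empty((r,) * len(verts), dtype=object if params.exact else float)
    for states in itertools.product(range(r), repeat=len(verts)):
        out[states] = marginal(tree, params, Character(r, dict(zip(verts, states))))
    return out


# ---------------------------------------------------------------------------
# Seeded parameter generation
# ---------------------------------------------------------------------------


def random_generic_params(
    tree: Phylogeny,
    r: int,
    seed,
    min_entry: float = 1e-3,
    min_det: float = 1e-6,
    exact: bool = False,
    denominator_limit: int = 1000,
    max_tries: int = 1000,
    root: Optional[VertexRef] = None,
) -> GMMParams:
    """Generic parameters satisfying C1-C3, drawn from flat Dirichlets.

    Rows (and the root distribution) are resampled until every determinant
    clears ``min_det`` and every guarded entry clears ``min_entry`` — the
    guards keep generic ranks numerically unambiguous on small trees.
    With ``exact=True`` the draws are rounded to nearby fractions (bounded
    denominators) and renormalized exactly, so downstream arithmetic is
    certified.  Deterministic for a fixed seed.
    """
    if r < 2:
        raise ValueError("need at least two states")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    root_v = tree.resolve(root) if root is not None else tree.reference_vertex
    budget = [max_tries]

    def draw_simplex() -> np.ndarray:
        while True:
            if budget[0] <= 0:
                raise GenerationError("resampling budget exhausted")
            budget[0] -= 1
            row = rng.dirichlet(np.ones(r))
            if row.min() >= min_entry:
                return row

    def rationalize(row: np.ndarray) -> np.ndarray:
        fr = [Fraction(float(x)).limit_denominator(denominator_limit) for x in row]
        total = sum(fr)
        return np.array([x / total for x in fr], dtype=object)

    def draw_matrix(guard_entries: bool) -> np.ndarray:
        while True:
            if budget[0] <= 0:
                raise GenerationError("resampling budget exhausted")
            budget[0] -= 1
            M = np.stack([rng.dirichlet(np.ones(r)) for _ in range(r)])
            if guard_entries and M.min() < min_entry:
                continue
            if not guard_entries and M.min() <= 0:
                continue
            if abs(np.linalg.det(M)) < min_det:
                continue
            if exact:
                Q = np.stack([rationalize(row) for row in M]).astype(object)
                if exact_det(Q) == 0:
                    continue
                return Q
            return M

    pi = draw_simplex()
    pi = rationalize(pi) if exact else pi
    edges = {}
    for (u, v) in tree.directed_edges(root_v):
        internal = not tree.is_leaf(u) and not tree.is_leaf(v)
        edges[(u, v)] = draw_matrix(guard_entries=internal)
    params = GMMParams(r, root_v, pi, edges)
    params.validate(tree)
    return params


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


def default_alphabet(r: int) -> str:
    """State-to-letter map used at I/O boundaries: RY for two states,
    nucleotides for four, otherwise consecutive uppercase letters."""
    if r == 2:
        return "RY"
    if r == 4:
        return "ACGT"
    if r > 26:
        raise ValueError("no default alphabet beyond 26 states")
    return "ABCDEFGHIJKLMNOPQRSTUVWXYZ"[:r]


@dataclass
class Alignment:
    """Matrix of iid site patterns: one row per taxon, one column per site."""

    taxa: tuple[str, ...]
    data: np.ndarray  # shape (n_taxa, n_sites), integer states
    r: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int64)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValueError("alignment shape does not match taxa")
        if self.data.size and (self.data.min() < 0 or self.data.max() >= self.r):
            raise ValueError("state out of range in alignment")

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def column(self, j: int) -> tuple[int, ...]:
        return tuple(int(x) for x in self.data[:, j])

    def to_fasta(self, path, alphabet: Optional[str] = None) -> None:
        alpha = alphabet or default_alphabet(self.r)
        records = [
            SeqRecord(
                Seq("".join(alpha[s] for s in row)), id=taxon, description=""
            )
            for taxon, row in zip(self.taxa, self.data)
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path, r: int, alphabet: Optional[str] = None) -> "Alignment":
        alpha = alphabet or default_alphabet(r)
        index = {c: i for i, c in enumerate(alpha)}
        taxa, rows = [], []
        for rec in SeqIO.parse(path, "fasta"):
            taxa.append(rec.id)
            try:
                rows.append([index[c] for c in str(rec.seq).upper()])
            except KeyError as exc:
                raise ValueError(f"symbol {exc} not in alphabet {alpha!r}") from None
        if not taxa:
            raise ValueError("no sequences in FASTA input")
        lengths = {len(row) for row in rows}
        if len(lengths) > 1:
            raise ValueError("ragged alignment: unequal sequence lengths")
        return cls(tuple(taxa), np.array(rows, dtype=np.int64).reshape(len(taxa), -1), r)


def simulate_alignment(
    tree: Phylogeny, params: GMMParams, n_sites: int, seed
) -> Alignment:
    """Draw iid sites by root-to-leaf sampling; deterministic under seed."""
    if n_sites < 0:
        raise ValueError("n_sites must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pi = params.root_dist.astype(float)
    states = {params.root: _sample_categorical(pi[None, :].repeat(max(n_sites, 1), 0), rng)[:n_sites]}
    for (u, v) in params.topological_edges():
        P = params.edge_matrices[(u, v)]
        rows = P.astype(float)[states[u]] if n_sites else np.zeros((0, params.r))
        states[v] = _sample_categorical(rows, rng)
    leaves = tree.leaves()
    taxa = tuple(tree.leaf_labels[v] for v in leaves)
    data = (
        np.stack([states[v] for v in leaves])
        if n_sites
        else np.zeros((len(leaves), 0), dtype=np.int64)
    )
    return Alignment(taxa, data, params.r)


def _sample_categorical(rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One draw per row of a matrix of probability rows (vectorized)."""
    if rows.shape[0] == 0:
        return np.zeros(0, dtype=np.int64)
    cum = np.cumsum(rows, axis=1)
    u = rng.random(rows.shape[0])
    return (u[:, None] > cum).sum(axis=1).astype(np.int64)


# ---------------------------------------------------------------------------
# Parameter file I/O (YAML)
# ---------------------------------------------------------------------------


def _coerce_number(x):
    if isinstance(x, str):
        return Fraction(x)
    return x


def load_params(source, tree: Phylogeny) -> GMMParams:
    """Read parameters from YAML.

    Expected keys: ``r``, ``root`` (label or id), ``root_dist`` (list), and
    ``edges`` mapping ``"parent>child"`` (labels or ids) to row-stochastic
    matrices.  Entries written as strings like ``"1/3"`` switch the whole
    parameter set to exact rational mode.
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    r = int(doc["r"])
    root = tree.resolve(doc["root"])
    raw_pi = [_coerce_number(x) for x in doc["root_dist"]]
    raw_edges = {}
    for key, mat in doc["edges"].items():
        u_ref, v_ref = str(key).split(">")
        u, v = tree.resolve(u_ref.strip()), tree.resolve(v_ref.strip())
        raw_edges[(u, v)] = [[_coerce_number(x) for x in row] for row in mat]
    exact = any(isinstance(x, Fraction) for x in raw_pi) or any(
        isinstance(x, Fraction) for mat in raw_edges.values() for row in mat for x in row
    )
    if exact:
        pi = np.array([Fraction(x) for x in raw_pi], dtype=object)
        edges = {
            e: np.array([[Fraction(x) for x in row] for row in mat], dtype=object)
            for e, mat in raw_edges.items()
        }
    else:
        pi = np.array(raw_pi, dtype=float)
        edges = {e: np.array(mat, dtype=float) for e, mat in raw_edges.items()}
    params = GMMParams(r, root, pi, edges)
    params.validate(tree)
    return params


def save_params(params: GMMParams, tree: Phylogeny, path) -> None:
    """Write parameters to YAML; exact fractions are kept as strings."""

    def fmt(x):
        return str(x) if isinstance(x, Fraction) else float(x)

    def name(v: int) -> str:
        lab = tree.label_of(v)
        return lab if lab is not None else f"#{v}"

    doc = {
        "r": params.r,
        "root": name(params.root),
        "root_dist": [fmt(x) for x in params.root_dist],
        "edges": {
            f"{name(u)}>{name(v)}": [[fmt(x) for x in row] for row in P]
            for (u, v), P in sorted(params.edge_matrices.items())
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
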