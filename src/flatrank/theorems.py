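"""Harnesses tying the algebra of flattenings to tree combinatorics.

Three families of checks live here:

* :func:`verify_rank_formula` — for a tree, generic parameters, and a
  vertex bipartition ``A | B``, compare the (exact or numerical) rank of
  the flattening with the prediction ``r ** nu(A|B)``, where ``nu`` is the
  minimum vertex cut separating the two sets.  On binary trees with leaf
  subsets the cut size also equals the parsimony length of the indicator
  character, and the harness checks that equality too.

* :func:`split_distance` — the rank exponent has a rearrangement reading:
  for a leaf bipartition of a binary tree, ``nu - 1`` equals the SPR (and
  TBR) distance from the tree to the nearest binary tree that *contains*
  the split.  Small instances can be certified by exhaustive breadth-first
  search over one-move neighborhoods (:func:`spr_neighbors`,
  :func:`tbr_neighbors`).

* :func:`degeneracy_demo` — the regularity conditions C1-C3 are not
  decorative: zeroing a single root-distribution entry or a single
  internal-edge entry makes the rank of the non-split quartet flattening
  drop strictly below ``r^2``.  The drop is predicted by the diagonal
  factor ``D[ij] = pi(i) * P_uv(i, j)`` of the quartet's UDV decomposition
  and certified in exact arithmetic.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import numpy as np

from . import cutsets
from .cutsets import CutResult
from .flatten import Flattening, RankReport, build_flattening, numerical_rank, rational_rank
from .gmm import DegenerateModelError, GMMParams, check_conditions
from .trees import Phylogeny, SplitSpec, VertexRef, suppress_degree_two

__all__ = [
    "VerificationReport",
    "DistanceReport",
    "DegeneracyReport",
    "verify_rank_formula",
    "split_distance",
    "spr_neighbors",
    "tbr_neighbors",
    "degeneracy_demo",
    "bfs_distance_to_split",
]

BFS_LEAF_GUARD = 7  # exhaustive neighborhood search refuses larger trees


@dataclass
class VerificationReport:
    """Side-by-side record of combinatorial prediction and algebraic rank."""

    n_leaves: int
    n_vertices: int
    split: SplitSpec
    r: int
    nu: int
    ell: int
    predicted_rank: int
    numerical_rank: int
    exact_rank: Optional[int]
    agree: bool
    cut_equality: Optional[bool]  # ell == nu, asserted for binary leaf splits
    spectrum: np.ndarray
    tolerance: float

    @property
    def rank(self) -> int:
        return self.exact_rank if self.exact_rank is not None else self.numerical_rank

    def as_dict(self) -> dict:
        return {
            "n_leaves": self.n_leaves,
            "A": list(self.split.A),
            "B": list(self.split.B),
            "r": self.r,
            "nu": self.nu,
            "ell": self.ell,
            "predicted_rank": self.predicted_rank,
            "numerical_rank": self.numerical_rank,
            "exact_rank": self.exact_rank,
            "agree": self.agree,
            "spectrum": [float(s) for s in self.spectrum],
            "tolerance": self.tolerance,
        }


def verify_rank_formula(
    tree: Phylogeny,
    params: GMMParams,
    split: Union[SplitSpec, tuple],
    rel_tol: float = 1e-9,
) -> VerificationReport:
    """Compare rank(flattening of A|B) against ``r ** nu(A|B)``.

    Refuses parameters violating C1-C3 — the formula provably fails there;
    see :func:`degeneracy_demo` for what happens instead.  Exact rank is
    certified automatically in rational mode.
    """
    if not isinstance(split, SplitSpec):
        split = tree.split(*split)
    report = check_conditions(tree, params)
    if not report.ok:
        failed = [k for k, v in report.as_dict().items() if not v["pass"]]
        raise DegenerateModelError(
            f"parameter conditions {failed} violated; the rank formula does not "
            "apply (degeneracy_demo explores such cases)"
        )
    nu_res = cutsets.nu(tree, split.A, split.B)
    ell_res = cutsets.ell(tree, split.A, split.B)
    flat = build_flattening(tree, params, split)
    rank_rep = numerical_rank(flat, rel_tol=rel_tol)
    predicted = params.r ** nu_res.size
    rank_rep.predicted_rank = predicted
    leaves = set(tree.leaves())
    cut_equality = None
    if tree.is_binary() and set(split.vertices) <= leaves:
        cut_equality = ell_res.size == nu_res.size
    return VerificationReport(
        n_leaves=len(leaves),
        n_vertices=len(tree.vertices),
        split=split,
        r=params.r,
        nu=nu_res.size,
        ell=ell_res.size,
        predicted_rank=predicted,
        numerical_rank=rank_rep.numerical_rank,
        exact_rank=rank_rep.exact_rank,
        agree=rank_rep.rank == predicted,
        cut_equality=cut_equality,
        spectrum=rank_rep.singular_values,
        tolerance=rank_rep.tolerance,
    )


# ---------------------------------------------------------------------------
# Tree rearrangements
# ---------------------------------------------------------------------------


def _new_id(graph: nx.Graph) -> int:
    return max(graph.nodes) + 1


def _attachment_points(graph: nx.Graph, component: set) -> list:
    """Edges of the component (subdivision targets), or the lone vertex."""
    if len(component) == 1:
        return [("vertex", next(iter(component)))]
    return [
        ("edge", tuple(sorted((u, v))))
        for u, v in graph.edges
        if u in component and v in component
    ]


def _attach(graph: nx.Graph, point, anchor: int) -> None:
    """Connect ``anchor`` to an attachment point, subdividing if needed."""
    kind, target = point
    if kind == "vertex":
        graph.add_edge(anchor, target)
    else:
        u, v = target
        mid = _new_id(graph)
        graph.remove_edge(u, v)
        graph.add_edges_from([(u, mid), (mid, v), (mid, anchor)])


def _finish(graph: nx.Graph, template: Phylogeny) -> Phylogeny:
    t = Phylogeny(graph, template.leaf_labels, internal_labels={}, root=None)
    return suppress_degree_two(t)


def _require_rearrangeable(tree: Phylogeny) -> Phylogeny:
    if len(tree.leaf_labels) < 4:
        raise ValueError("rearrangements need at least 4 leaves")
    t = tree.unrooted()
    if not t.is_binary():
        raise ValueError("rearrangements are defined on binary trees")
    return t


def spr_neighbors(tree: Phylogeny) -> list[Phylogeny]:
    """Distinct topologies one subtree-prune-and-regraft move away.

    An edge is removed and one of its endpoints is reconnected to a point
    in the opposite component; degree-two vertices are suppressed.  The
    original topology is not included in the result.
    """
    t = _require_rearrangeable(tree)
    own = t.topology_key()
    found: dict = {}
    for e in t.edges():
        u, v = tuple(sorted(e))
        for keep, other in ((u, v), (v, u)):
            g = nx.Graph(t.graph)
            g.remove_edge(u, v)
            opposite = nx.node_connected_component(g, other)
            # the dangling endpoint in the opposite component goes away
            if g.degree(other) == 2:
                a, b = g.neighbors(other)
                g.remove_node(other)
                g.add_edge(a, b)
                opposite = (opposite - {other})
            for point in _attachment_points(g, opposite):
                h = nx.Graph(g)
                _attach(h, point, keep)
                neigh = _finish(h, t)
                key = neigh.topology_key()
                if key != own:
                    found.setdefault(key, neigh)
    return list(found.values())


def tbr_neighbors(tree: Phylogeny) -> list[Phylogeny]:
    """Distinct topologies one tree-bisection-and-reconnection move away.

    An edge is removed and a brand-new edge joins arbitrary points of the
    two components; degree-two vertices are suppressed.  Every SPR move is
    a TBR move, so the SPR neighborhood is a subset of this one.
    """
    t = _require_rearrangeable(tree)
    own = t.topology_key()
    found: dict = {}
    for e in t.edges():
        u, v = tuple(sorted(e))
        g = nx.Graph(t.graph)
        g.remove_edge(u, v)
        sides = []
        for endpoint in (u, v):
            comp = nx.node_connected_component(g, endpoint)
            if g.degree(endpoint) == 2:
                a, b = g.neighbors(endpoint)
                g.remove_node(endpoint)
                g.add_edge(a, b)
                comp = comp - {endpoint}
            sides.append(comp)
        for p1 in _attachment_points(g, sides[0]):
            for p2 in _attachment_points(g, sides[1]):
                h = nx.Graph(g)
                if p1[0] == "vertex" and p2[0] == "vertex":
                    h.add_edge(p1[1], p2[1])
                else:
                    anchor = _new_id(h)
                    first, second = (p1, p2) if p1[0] == "edge" else (p2, p1)
                    fu, fv = first[1]
                    h.remove_edge(fu, fv)
                    h.add_edges_from([(fu, anchor), (anchor, fv)])
                    _attach(h, second, anchor)
                neigh = _finish(h, t)
                key = neigh.topology_key()
                if key != own:
                    found.setdefault(key, neigh)
    return list(found.values())


# ---------------------------------------------------------------------------
# Distance to the nearest tree containing a split
# ---------------------------------------------------------------------------

_NEIGHBOR_CACHE: dict = {}


def _cached_neighbors(tree: Phylogeny, move: str) -> list[Phylogeny]:
    key = (tree.topology_key(), move)
    if key not in _NEIGHBOR_CACHE:
        fn = spr_neighbors if move == "spr" else tbr_neighbors
        _NEIGHBOR_CACHE[key] = fn(tree)
    return _NEIGHBOR_CACHE[key]


def bfs_distance_to_split(
    tree: Phylogeny,
    A_labels: Iterable[str],
    B_labels: Iterable[str],
    move: str = "spr",
    max_depth: int = 10,
) -> tuple[int, Phylogeny]:
    """Breadth-first certified distance to a tree containing ``A | B``.

    Explores the one-move neighborhood graph layer by layer until a
    topology whose split set contains the target bipartition appears.
    Returns the distance and one witness tree.  Exhaustive and therefore
    restricted to small trees (guard: more than 7 leaves is refused).
    """
    if len(tree.leaf_labels) > BFS_LEAF_GUARD:
        raise ValueError(
            f"exhaustive search refuses more than {BFS_LEAF_GUARD} leaves"
        )
    target = frozenset({frozenset(A_labels), frozenset(B_labels)})
    if target & {frozenset()}:
        raise ValueError("split parts must be non-empty")
    start = tree.unrooted()
    if target in start.splits():
        return 0, start
    seen = {start.topology_key()}
    frontier = [start]
    for depth in range(1, max_depth + 1):
        nxt = []
        for t in frontier:
            for neigh in _cached_neighbors(t, move):
                key = neigh.topology_key()
                if key in seen:
                    continue
                seen.add(key)
                if target in neigh.splits():
                    return depth, neigh
                nxt.append(neigh)
        frontier = nxt
        if not frontier:
            break
    raise RuntimeError("no tree containing the split found within max_depth")


@dataclass
class DistanceReport:
    """Rearrangement-distance reading of the rank exponent for a split."""

    split: tuple[tuple[str, ...], tuple[str, ...]]
    nu: int
    claimed_spr_distance: int
    claimed_tbr_distance: int
    bfs_spr_distance: Optional[int] = None
    bfs_tbr_distance: Optional[int] = None
    spr_witness: Optional[Phylogeny] = None
    tbr_witness: Optional[Phylogeny] = None

    @property
    def certified(self) -> Optional[bool]:
        if self.bfs_spr_distance is None:
            return None
        return (
            self.bfs_spr_distance == self.claimed_spr_distance
            and self.bfs_tbr_distance == self.claimed_tbr_distance
        )


def split_distance(
    tree: Phylogeny,
    A_labels: Iterable[str],
    B_labels: Iterable[str],
    certify: bool = False,
) -> DistanceReport:
    """Distance from a binary tree to the nearest tree containing a split.

    For a bipartition ``A | B`` of the taxa, the distance (under SPR, and
    equally under TBR) to the closest binary tree containing the split is
    ``nu(A|B) - 1`` — zero exactly when the split is already in the tree.
    With ``certify=True`` the formula is checked by exhaustive BFS on trees
    of at most 7 leaves (larger trees fall back to the formula with a
    warning).
    """
    t = tree.unrooted()
    if not t.is_binary():
        raise ValueError("split distances are defined for binary trees")
    A = tuple(A_labels)
    B = tuple(B_labels)
    if set(A) | set(B) != set(t.taxa()) or set(A) & set(B) or not A or not B:
        raise ValueError("A | B must bipartition the taxon set")
    a_vertices = [t.resolve(x) for x in A]
    b_vertices = [t.resolve(x) for x in B]
    nu_res = cutsets.nu(t, a_vertices, b_vertices)
    claimed = nu_res.size - 1
    report = DistanceReport(
        split=(A, B),
        nu=nu_res.size,
        claimed_spr_distance=claimed,
        claimed_tbr_distance=claimed,
    )
    if certify:
        if len(t.leaf_labels) > BFS_LEAF_GUARD:
            warnings.warn(
                "tree too large for exhaustive certification; reporting the "
                "cut formula only",
                stacklevel=2,
            )
            return report
        d_spr, w_spr = bfs_distance_to_split(t, A, B, move="spr")
        d_tbr, w_tbr = bfs_distance_to_split(t, A, B, move="tbr")
        report.bfs_spr_distance = d_spr
        report.bfs_tbr_distance = d_tbr
        report.spr_witness = w_spr
        report.tbr_witness = w_tbr
    return report


# ---------------------------------------------------------------------------
# Degeneracy of the parameter conditions
# ---------------------------------------------------------------------------


@dataclass
class DegeneracyReport:
    """Rank of the non-split flattening after zeroing one parameter entry."""

    zeroed: Optional[tuple]
    A: tuple
    B: tuple
    r: int
    rank: int
    full_rank: int  # r ** 2, the generic non-split value
    rank_dropped: bool
    predicted_rank: Optional[int]  # nonzero diagonal count, quartets only
    message: str


def _nonsplit_pairing(tree: Phylogeny, edge) -> tuple[tuple, tuple]:
    """Cross the two sides of an internal edge to get a non-split A | B."""
    s = tree.induced_split(edge)
    if len(s.A) < 2 or len(s.B) < 2:
        raise ValueError("need at least two leaves on each side of the edge")
    return (s.A[0], s.B[0]), (s.A[1], s.B[1])


def degeneracy_demo(
    tree: Phylogeny,
    params: GMMParams,
    zero: Optional[tuple] = None,
    rel_tol: float = 1e-9,
) -> DegeneracyReport:
    """Show how zeroing one parameter entry collapses the non-split rank.

    ``zero`` is ``("root", i)`` to zero a root-distribution entry or
    ``("edge", (u, v), (i, j))`` to zero a transition entry on an internal
    edge; the affected row (or the root vector) is renormalized so the
    object stays a probability distribution while keeping the zero that
    drives the rank drop.  ``zero=None`` is the control case: generic
    parameters keep the full non-split rank ``r^2``.

    For a quartet the report also carries the predicted rank — the number
    of nonzero entries of the diagonal factor ``pi(i) * P_uv(i, j)``.
    """
    r = params.r
    internal_edges = [e for e in tree.edges() if tree.is_internal_edge(e)]
    if not internal_edges:
        raise ValueError("tree has no internal edge")
    modified = params.copy()
    zero_norm: Optional[tuple] = None
    target_edge = internal_edges[0]

    if zero is not None:
        kind = zero[0]
        if kind == "root":
            i = int(zero[1])
            if not 0 <= i < r:
                raise ValueError(f"root entry {i} out of range")
            pi = modified.root_dist.copy()
            pi[i] = params.zero()
            total = sum(pi)
            if not total > 0:
                raise ValueError("cannot renormalize: all mass removed")
            modified.root_dist = np.array([x / total for x in pi], dtype=pi.dtype)
            zero_norm = ("root", i)
        elif kind == "edge":
            (u_ref, v_ref), (i, j) = zero[1], zero[2]
            u, v = tree.resolve(u_ref), tree.resolve(v_ref)
            key = (u, v) if (u, v) in modified.edge_matrices else (v, u)
            if key not in modified.edge_matrices:
                raise ValueError(f"no edge ({u_ref},{v_ref}) in the model")
            if not (0 <= i < r and 0 <= j < r):
                raise ValueError(f"entry ({i},{j}) out of range")
            P = modified.edge_matrices[key].copy()
            P[i, j] = params.zero()
            total = sum(P[i])
            if not total > 0:
                raise ValueError("cannot renormalize: all mass removed from row")
            for col in range(r):
                P[i, col] = P[i, col] / total
            modified.edge_matrices[key] = P
            zero_norm = ("edge", key, (i, j))
            if tree.is_internal_edge(key):
                target_edge = frozenset(key)
        else:
            raise ValueError(f"unknown zero kind {zero[0]!r}")

    A, B = _nonsplit_pairing(tree, target_edge)
    flat = build_flattening(tree, modified, (A, B))
    if modified.exact:
        rank = rational_rank(flat.matrix)
    else:
        rank = numerical_rank(flat, rel_tol=rel_tol).numerical_rank

    predicted = None
    if len(tree.leaf_labels) == 4:
        u, v = tuple(target_edge)
        key = (u, v) if (u, v) in modified.edge_matrices else (v, u)
        P = modified.edge_matrices[key]
        # root distribution seen from the internal edge: marginal at its tail
        from .gmm import vertex_marginals

        mu = vertex_marginals(tree, modified)[key[0]]
        predicted = sum(
            1
            for i, j in itertools.product(range(r), repeat=2)
            if mu[i] * P[i][j] > 0
        )

    full = r ** 2
    dropped = rank < full
    if zero_norm is None:
        message = "no degeneracy: generic parameters give the full non-split rank"
    else:
        message = (
            f"zeroed {zero_norm}: non-split rank {rank} < {full}"
            if dropped
            else f"zeroed {zero_norm}: rank did not drop (rank {rank})"
        )
    return DegeneracyReport(
        zeroed=zero_norm,
        A=A,
        B=B,
        r=r,
        rank=rank,
        full_rank=full,
        rank_dropped=dropped,
        predicted_rank=predicted,
        message=message,
    )
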