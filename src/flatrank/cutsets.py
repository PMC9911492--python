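"""Parsimony lengths, vertex cuts, and disjoint-path certificates.

This module carries the combinatorial half of the rank formula.  For
disjoint vertex sets ``A`` and ``B`` of a tree:

* ``ell(T, A, B)`` — the parsimony length of the two-state indicator
  character (0 on A, 1 on B): the minimum number of edges whose deletion
  leaves no component meeting both sets.  By Menger's theorem it equals the
  maximum number of pairwise edge-disjoint A–B paths.
* ``nu(T, A, B)`` — the minimum number of *vertices* whose deletion leaves
  no component meeting both ``A`` and ``B`` (the cut may include members of
  ``A ∪ B``); equals the maximum number of vertex-disjoint A–B paths.

``nu <= ell`` always; on binary trees with ``A, B`` restricted to leaves the
two coincide, and the exponent of the flattening rank is ``nu``.

Both quantities come with max-flow/min-cut *certificates*: a separating cut
and a disjoint path system of equal cardinality, so every answer can be
re-validated independently of the flow computation.  Exhaustive brute-force
oracles are provided for testing on small trees.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import networkx as nx

from .trees import Phylogeny, VertexRef

__all__ = [
    "Character",
    "CutResult",
    "indicator_character",
    "parsimony_length",
    "ell",
    "nu",
    "brute_force_ell",
    "brute_force_nu",
    "is_vertex_separator",
    "is_edge_separator",
]

_INF = float("inf")


@dataclass(frozen=True)
class Character:
    """A partial assignment of states ``{0..r-1}`` to tree vertices.

    The domain may be any non-empty vertex subset — leaves, internal
    vertices, or a mixture.  A full alignment column is the special case
    where the domain is the leaf set.
    """

    r: int
    assignment: Mapping[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", dict(self.assignment))
        if self.r < 2:
            raise ValueError("need at least two states")
        if not self.assignment:
            raise ValueError("character domain must be non-empty")
        for v, s in self.assignment.items():
            if not 0 <= s < self.r:
                raise ValueError(f"state {s} at vertex {v} outside 0..{self.r - 1}")

    @property
    def domain(self) -> frozenset:
        return frozenset(self.assignment)

    def validate_on(self, tree: Phylogeny) -> None:
        for v in self.assignment:
            tree.resolve(v)


@dataclass(frozen=True)
class CutResult:
    """A cut size together with its max-flow/min-cut certificate pair.

    ``witness_cut`` is a frozenset of edges (for the edge version) or of
    vertices (for the vertex version); ``witness_paths`` is a tuple of
    vertex sequences, pairwise disjoint in the corresponding sense, each
    running from ``A`` to ``B``.  Both certificates have cardinality
    ``size`` — LP duality on the tree guarantees they match.
    """

    size: int
    witness_cut: frozenset
    witness_paths: tuple[tuple[int, ...], ...]


def indicator_character(
    tree: Phylogeny, A: Iterable[VertexRef], B: Iterable[VertexRef]
) -> Character:
    """Two-state character: 0 on ``A``, 1 on ``B``; domain ``A ∪ B``."""
    a = tree.resolve_all(A)
    b = tree.resolve_all(B)
    if not a or not b:
        raise ValueError("A and B must be non-empty")
    if set(a) & set(b):
        raise ValueError("A and B must be disjoint")
    return Character(2, {**{v: 0 for v in a}, **{v: 1 for v in b}})


# ---------------------------------------------------------------------------
# Parsimony length (unit-cost Sankoff dynamic programming)
# ---------------------------------------------------------------------------


def parsimony_length(tree: Phylogeny, char: Character) -> int:
    """Minimum number of state-changing edges over all full extensions.

    Unit-cost Sankoff dynamic programming with the vertices in the
    character's domain clamped to their assigned states.  The Fitch set
    rule would not do here: the domain may include internal vertices and
    the state count is arbitrary.
    """
    char.validate_on(tree)
    clamp = {tree.resolve(v): s for v, s in char.assignment.items()}
    r = char.r
    root = tree.reference_vertex
    parent = tree.parent_map(root)
    cost: dict[int, list[float]] = {}
    for v in tree.postorder(root):
        base = [0.0] * r
        if v in clamp:
            base = [0.0 if s == clamp[v] else _INF for s in range(r)]
        for u in tree.neighbors(v):
            if parent.get(u) == v:
                child = cost[u]
                cheapest = min(child)
                for s in range(r):
                    # staying equal costs child[s]; switching costs cheapest+1
                    base[s] += min(child[s], cheapest + 1)
        cost[v] = base
    best = min(cost[root])
    assert best < _INF
    return int(best)


def brute_force_ell(tree: Phylogeny, char: Character) -> int:
    """Exhaustive minimum over all ``r^{|V \\ dom|}`` extensions.

    Test oracle only; refuses more than 15 free vertices.
    """
    char.validate_on(tree)
    clamp = {tree.resolve(v): s for v, s in char.assignment.items()}
    free = [v for v in tree.vertices if v not in clamp]
    if len(free) > 15:
        raise ValueError(f"{len(free)} free vertices exceeds brute-force guard (15)")
    edges = [tuple(e) for e in tree.edges()]
    best = len(edges)
    for combo in itertools.product(range(char.r), repeat=len(free)):
        F = dict(clamp)
        F.update(zip(free, combo))
        length = sum(1 for u, v in edges if F[u] != F[v])
        best = min(best, length)
    return best


# ---------------------------------------------------------------------------
# Edge version: ell(A|B) with certificates
# ---------------------------------------------------------------------------

_S, _T = "__source__", "__sink__"


def _check_sets(tree, A, B) -> tuple[tuple[int, ...], tuple[int, ...]]:
    a = tree.resolve_all(A)
    b = tree.resolve_all(B)
    if not a or not b:
        raise ValueError("A and B must be non-empty")
    if set(a) & set(b):
        raise ValueError("A and B must be disjoint")
    return a, b


def ell(tree: Phylogeny, A: Iterable[VertexRef], B: Iterable[VertexRef]) -> CutResult:
    """Minimum separating edge cut = maximum edge-disjoint A–B paths.

    Unit-capacity max flow on the (bidirected) tree.  The returned size
    equals ``parsimony_length`` of the indicator character of ``A | B``.
    """
    a, b = _check_sets(tree, A, B)
    big = tree.graph.number_of_edges() + 1
    D = nx.DiGraph()
    for e in tree.edges():
        u, v = tuple(e)
        D.add_edge(u, v, capacity=1)
        D.add_edge(v, u, capacity=1)
    for x in a:
        D.add_edge(_S, x, capacity=big)
    for y in b:
        D.add_edge(y, _T, capacity=big)
    value, flow = nx.maximum_flow(D, _S, _T)
    cut_value, (side_s, _) = nx.minimum_cut(D, _S, _T)
    assert cut_value == value
    witness_cut = frozenset(
        frozenset(e) for e in tree.edges() if len(set(e) & side_s) == 1
    )
    paths = _decompose(flow, value)
    result = CutResult(int(value), witness_cut, paths)
    _validate_edge_result(tree, a, b, result)
    return result


def nu(tree: Phylogeny, A: Iterable[VertexRef], B: Iterable[VertexRef]) -> CutResult:
    """Minimum separating vertex cut = maximum vertex-disjoint A–B paths.

    Standard vertex-splitting reduction: each vertex becomes an internal
    arc of capacity one — terminals included, so the optimal cut is free to
    contain members of ``A ∪ B``.  Tree edges get effectively infinite
    capacity, hence every minimum cut consists of internal arcs only and
    reads back as a vertex set.
    """
    a, b = _check_sets(tree, A, B)
    big = tree.graph.number_of_nodes() + 1
    D = nx.DiGraph()
    for v in tree.vertices:
        D.add_edge(("in", v), ("out", v), capacity=1)
    for e in tree.edges():
        u, v = tuple(e)
        D.add_edge(("out", u), ("in", v), capacity=big)
        D.add_edge(("out", v), ("in", u), capacity=big)
    for x in a:
        D.add_edge(_S, ("in", x), capacity=big)
    for y in b:
        D.add_edge(("out", y), _T, capacity=big)
    value, flow = nx.maximum_flow(D, _S, _T)
    cut_value, (side_s, _) = nx.minimum_cut(D, _S, _T)
    assert cut_value == value
    witness_cut = frozenset(
        v for v in tree.vertices if ("in", v) in side_s and ("out", v) not in side_s
    )
    raw_paths = _decompose(flow, value)
    paths = tuple(
        tuple(node[1] for node in p if node[0] == "in") for p in raw_paths
    )
    result = CutResult(int(value), witness_cut, paths)
    _validate_vertex_result(tree, a, b, result)
    return result


def _decompose(flow: dict, value: int) -> tuple[tuple, ...]:
    """Decompose an integral s-t flow into ``value`` unit paths."""
    net: dict = {}
    for u, nbrs in flow.items():
        for v, f in nbrs.items():
            if f <= 0:
                continue
            back = flow.get(v, {}).get(u, 0)
            net.setdefault(u, {})[v] = max(0, f - min(f, back))
    # antiparallel cancellation must be symmetric
    for u in list(net):
        for v in list(net[u]):
            if net.get(v, {}).get(u, 0) and net[u][v]:
                c = min(net[u][v], net[v][u])
                net[u][v] -= c
                net[v][u] -= c
    paths = []
    for _ in range(value):
        path = [_S]
        cur = _S
        while cur != _T:
            nxt = next(
                v
                for v, f in sorted(net.get(cur, {}).items(), key=lambda kv: str(kv[0]))
                if f >= 1
            )
            net[cur][nxt] -= 1
            path.append(nxt)
            cur = nxt
        paths.append(tuple(path[1:-1]))
    return tuple(paths)


# ---------------------------------------------------------------------------
# Certificate validation and brute-force oracles
# ---------------------------------------------------------------------------


def is_edge_separator(tree: Phylogeny, A, B, cut_edges) -> bool:
    """Does deleting ``cut_edges`` leave no component meeting both sets?"""
    a, b = _check_sets(tree, A, B)
    g = nx.restricted_view(tree.graph, [], [tuple(e) for e in cut_edges])
    for comp in nx.connected_components(g):
        if comp & set(a) and comp & set(b):
            return False
    return True


def is_vertex_separator(tree: Phylogeny, A, B, cut_vertices) -> bool:
    """Does deleting ``cut_vertices`` leave no component meeting both
    ``A \\ cut`` and ``B \\ cut``?"""
    a, b = _check_sets(tree, A, B)
    cut = {tree.resolve(v) for v in cut_vertices}
    g = nx.restricted_view(tree.graph, cut, [])
    rest_a, rest_b = set(a) - cut, set(b) - cut
    for comp in nx.connected_components(g):
        if comp & rest_a and comp & rest_b:
            return False
    return True


def _validate_edge_result(tree, a, b, res: CutResult) -> None:
    assert len(res.witness_paths) == res.size == len(res.witness_cut)
    assert is_edge_separator(tree, a, b, res.witness_cut)
    used: set = set()
    for p in res.witness_paths:
        assert p[0] in a and p[-1] in b
        for u, v in zip(p, p[1:]):
            e = frozenset((u, v))
            assert e not in used, "paths share an edge"
            used.add(e)


def _validate_vertex_result(tree, a, b, res: CutResult) -> None:
    assert len(res.witness_paths) == res.size == len(res.witness_cut)
    assert is_vertex_separator(tree, a, b, res.witness_cut)
    used: set = set()
    for p in res.witness_paths:
        assert p[0] in a and p[-1] in b
        for v in p:
            assert v not in used, "paths share a vertex"
            used.add(v)


def brute_force_nu(tree: Phylogeny, A, B) -> int:
    """Exhaustive minimum vertex cut by subset enumeration, smallest first.

    Test oracle only; refuses trees with more than 18 vertices.  On a
    connected tree with both sets non-empty the minimum is at least one.
    """
    a, b = _check_sets(tree, A, B)
    verts = tree.vertices
    if len(verts) > 18:
        raise ValueError("tree too large for brute-force vertex-cut enumeration")
    for k in range(len(verts) + 1):
        for cut in itertools.combinations(verts, k):
            if is_vertex_separator(tree, a, b, cut):
                return k
    raise AssertionError("unreachable: deleting V separates everything")
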