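"""Phylogenetic tree container, Newick I/O and structural utilities.

A :class:`Phylogeny` is an undirected acyclic connected graph whose
degree-one vertices (the leaves) carry unique taxon labels.  Internal
vertices are first-class citizens here: they may carry Newick labels and can
be referenced anywhere a vertex is expected, because the vertex subsets used
for flattenings and cuts may contain internal vertices, not just taxa.

Vertex identifiers are small integers assigned in deterministic post-order
during parsing, so even an unlabeled internal vertex can be addressed
reproducibly.  Rooting is a lightweight annotation: the undirected edge set
never changes, only the orientation implied by the chosen root.  Algorithms
that need a rooted view call :meth:`Phylogeny.directed_edges` (or
:meth:`Phylogeny.reroot`) explicitly, since for the Markov models treated in
this package root placement is statistically immaterial.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import dendropy
import networkx as nx
import numpy as np

__all__ = [
    "NewickParseError",
    "UnknownVertexError",
    "SplitSpec",
    "Phylogeny",
    "parse_newick",
    "write_newick",
    "suppress_degree_two",
    "random_binary_tree",
    "random_tree",
    "same_topology",
]

VertexRef = Union[int, str]


class NewickParseError(ValueError):
    """Raised when Newick text cannot be turned into a valid phylogeny."""


class UnknownVertexError(KeyError):
    """Raised when a vertex reference does not resolve to a tree vertex."""


@dataclass(frozen=True)
class SplitSpec:
    """An ordered pair ``A | B`` of disjoint vertex sets.

    The order of vertices *within* each part is significant: it fixes the
    row and column enumeration of any flattening built on this split.
    """

    A: tuple[int, ...]
    B: tuple[int, ...]

    def __post_init__(self) -> None:
        a, b = tuple(self.A), tuple(self.B)
        object.__setattr__(self, "A", a)
        object.__setattr__(self, "B", b)
        if not a or not b:
            raise ValueError("both parts of a split must be non-empty")
        if len(set(a)) != len(a) or len(set(b)) != len(b):
            raise ValueError("split parts must not repeat vertices")
        if set(a) & set(b):
            raise ValueError(f"split parts overlap: {sorted(set(a) & set(b))}")

    @property
    def vertices(self) -> tuple[int, ...]:
        return self.A + self.B


class Phylogeny:
    """Undirected leaf-labeled tree with optional root and internal labels.

    Parameters
    ----------
    graph:
        Connected acyclic :class:`networkx.Graph`; node ids are integers.
    leaf_labels:
        Bijection between the degree-one vertices and taxon names.
    internal_labels:
        Optional partial map from internal vertices to names.
    root:
        Optional vertex id; when set, edges are oriented away from it.
    """

    def __init__(
        self,
        graph: nx.Graph,
        leaf_labels: Mapping[int, str],
        internal_labels: Optional[Mapping[int, str]] = None,
        root: Optional[int] = None,
    ) -> None:
        self.graph = nx.Graph(graph)
        self.leaf_labels = dict(leaf_labels)
        self.internal_labels = dict(internal_labels or {})
        self.root = root
        self._validate()
        self._label_to_vertex = {}
        for v, lab in itertools.chain(
            self.leaf_labels.items(), self.internal_labels.items()
        ):
            if lab in self._label_to_vertex:
                raise ValueError(f"duplicate label {lab!r}")
            self._label_to_vertex[lab] = v

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        g = self.graph
        n = g.number_of_nodes()
        if n == 0:
            raise ValueError("empty tree")
        if g.number_of_edges() != n - 1 or not nx.is_connected(g):
            raise ValueError("graph is not a tree (must be connected, acyclic)")
        leaves = {v for v in g if g.degree(v) == 1} if n > 1 else set(g)
        if set(self.leaf_labels) != leaves:
            missing = leaves - set(self.leaf_labels)
            extra = set(self.leaf_labels) - leaves
            raise ValueError(
                f"leaf labeling mismatch (unlabeled leaves {sorted(missing)}, "
                f"labels on non-leaves {sorted(extra)})"
            )
        if len(set(self.leaf_labels.values())) != len(self.leaf_labels):
            raise ValueError("duplicate taxon labels")
        if self.root is not None and self.root not in g:
            raise UnknownVertexError(self.root)
        bad = set(self.internal_labels) - (set(g) - leaves)
        if bad:
            raise ValueError(f"internal labels on non-internal vertices {sorted(bad)}")

    # -- basic accessors -------------------------------------------------

    @property
    def vertices(self) -> list[int]:
        return sorted(self.graph.nodes)

    def edges(self) -> list[frozenset]:
        return sorted(
            (frozenset(e) for e in self.graph.edges), key=lambda e: tuple(sorted(e))
        )

    def degree(self, v: int) -> int:
        return self.graph.degree(v)

    def is_leaf(self, v: int) -> bool:
        return v in self.leaf_labels

    def leaves(self) -> list[int]:
        """Leaf vertex ids sorted by taxon label."""
        return sorted(self.leaf_labels, key=lambda v: self.leaf_labels[v])

    def internal_vertices(self) -> list[int]:
        return sorted(set(self.graph) - set(self.leaf_labels))

    def taxa(self) -> list[str]:
        return sorted(self.leaf_labels.values())

    def label_of(self, v: int) -> Optional[str]:
        return self.leaf_labels.get(v, self.internal_labels.get(v))

    def neighbors(self, v: int) -> list[int]:
        return sorted(self.graph.neighbors(v))

    # -- vertex resolution -----------------------------------------------

    def resolve(self, ref: VertexRef) -> int:
        """Resolve a vertex reference: an integer id, a taxon label, an
        internal-vertex label, the decimal string of an id, or ``#id``
        (raw id, immune to label collisions)."""
        if isinstance(ref, (int, np.integer)):
            v = int(ref)
            if v not in self.graph:
                raise UnknownVertexError(ref)
            return v
        if isinstance(ref, str) and ref.startswith("#"):
            try:
                v = int(ref[1:])
            except ValueError:
                raise UnknownVertexError(ref) from None
            if v in self.graph:
                return v
            raise UnknownVertexError(ref)
        if ref in self._label_to_vertex:
            return self._label_to_vertex[ref]
        try:
            v = int(ref)
        except (TypeError, ValueError):
            raise UnknownVertexError(ref) from None
        if v in self.graph:
            return v
        raise UnknownVertexError(ref)

    def resolve_all(self, refs: Iterable[VertexRef]) -> tuple[int, ...]:
        return tuple(self.resolve(x) for x in refs)

    def split(self, A: Iterable[VertexRef], B: Iterable[VertexRef]) -> SplitSpec:
        """Build a validated :class:`SplitSpec` from vertex references."""
        return SplitSpec(self.resolve_all(A), self.resolve_all(B))

    # -- orientation -----------------------------------------------------

    @property
    def reference_vertex(self) -> int:
        """Deterministic fallback orientation root: the root if set, else
        the smallest internal vertex id, else the smallest vertex id."""
        if self.root is not None:
            return self.root
        internal = self.internal_vertices()
        return internal[0] if internal else self.vertices[0]

    def directed_edges(self, root: Optional[VertexRef] = None) -> list[tuple[int, int]]:
        """Edges as (parent, child) pairs oriented away from ``root``,
        in deterministic BFS order."""
        r = self.reference_vertex if root is None else self.resolve(root)
        out: list[tuple[int, int]] = []
        seen = {r}
        frontier = [r]
        while frontier:
            nxt: list[int] = []
            for u in frontier:
                for v in self.neighbors(u):
                    if v not in seen:
                        seen.add(v)
                        out.append((u, v))
                        nxt.append(v)
            frontier = nxt
        return out

    def parent_map(self, root: Optional[VertexRef] = None) -> dict[int, int]:
        return {v: u for u, v in self.directed_edges(root)}

    def postorder(self, root: Optional[VertexRef] = None) -> list[int]:
        """Vertices in post-order (children before parents) from ``root``."""
        r = self.reference_vertex if root is None else self.resolve(root)
        order: list[int] = []
        stack: list[tuple[int, Optional[int]]] = [(r, None)]
        while stack:
            v, parent = stack.pop()
            order.append(v)
            for u in self.neighbors(v):
                if u != parent:
                    stack.append((u, v))
        order.reverse()
        return order

    # -- structural predicates and transforms ----------------------------

    def is_binary(self) -> bool:
        """True for fully resolved trees.

        Unrooted: every internal vertex has degree three.  Rooted: the root
        has two children and every other internal vertex has out-degree two
        (total degree three).
        """
        if len(self.graph) <= 2:
            return False
        if self.root is None:
            return all(
                self.degree(v) == 3 for v in self.graph if not self.is_leaf(v)
            )
        for v in self.graph:
            if self.is_leaf(v):
                continue
            want = 2 if v == self.root else 3
            if self.degree(v) != want:
                return False
        return True

    def induced_split(self, edge) -> SplitSpec:
        """The bipartition of the taxa induced by deleting ``edge``.

        The part containing the lexicographically smallest taxon-label tuple
        comes first; within each part, leaves are ordered by label.
        """
        u, v = self._resolve_edge(edge)
        g = nx.restricted_view(self.graph, [], [(u, v)])
        side_u = nx.node_connected_component(g, u)
        part_u = sorted(
            (w for w in side_u if self.is_leaf(w)), key=lambda w: self.leaf_labels[w]
        )
        part_v = sorted(
            (w for w in self.graph if w not in side_u and self.is_leaf(w)),
            key=lambda w: self.leaf_labels[w],
        )
        key_u = tuple(self.leaf_labels[w] for w in part_u)
        key_v = tuple(self.leaf_labels[w] for w in part_v)
        first, second = (part_u, part_v) if key_u <= key_v else (part_v, part_u)
        return SplitSpec(tuple(first), tuple(second))

    def _resolve_edge(self, edge) -> tuple[int, int]:
        u, v = tuple(edge)
        u, v = self.resolve(u), self.resolve(v)
        if not self.graph.has_edge(u, v):
            raise UnknownVertexError(f"no edge {{{u},{v}}} in tree")
        return u, v

    def is_internal_edge(self, edge) -> bool:
        u, v = self._resolve_edge(edge)
        return not self.is_leaf(u) and not self.is_leaf(v)

    def reroot(self, new_root: VertexRef) -> "Phylogeny":
        """Same undirected tree, re-oriented away from ``new_root``."""
        r = self.resolve(new_root)
        return Phylogeny(self.graph, self.leaf_labels, self.internal_labels, root=r)

    def unrooted(self) -> "Phylogeny":
        return Phylogeny(self.graph, self.leaf_labels, self.internal_labels, root=None)

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.graph, self.leaf_labels, self.internal_labels, self.root)

    # -- topology identity ------------------------------------------------

    def leaf_split_of_edge(self, edge) -> frozenset:
        """Unordered leaf-label bipartition induced by an edge."""
        s = self.induced_split(edge)
        return frozenset(
            {
                frozenset(self.leaf_labels[v] for v in s.A),
                frozenset(self.leaf_labels[v] for v in s.B),
            }
        )

    def splits(self, nontrivial_only: bool = False) -> set:
        """All leaf-label bipartitions induced by edges.

        Single post-order pass: the leaf set below each directed edge is
        accumulated bottom-up, and its complement is the other side.
        """
        all_taxa = frozenset(self.leaf_labels.values())
        root = self.reference_vertex
        parent = self.parent_map(root)
        below: dict[int, frozenset] = {}
        out = set()
        for v in self.postorder(root):
            if self.is_leaf(v):
                acc = frozenset({self.leaf_labels[v]})
            else:
                acc = frozenset()
            for u in self.neighbors(v):
                if parent.get(u) == v:
                    acc = acc | below[u]
            below[v] = acc
            if v != root:
                if nontrivial_only and min(len(acc), len(all_taxa - acc)) < 2:
                    continue
                if acc and acc != all_taxa:
                    out.add(frozenset({acc, all_taxa - acc}))
        return out

    def topology_key(self):
        """Canonical key for the unrooted leaf-labeled topology.

        Two binary phylogenies on the same taxa are isomorphic iff their
        nontrivial split sets coincide.
        """
        return (frozenset(self.taxa()), frozenset(self.splits(nontrivial_only=True)))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Phylogeny({len(self.leaf_labels)} leaves, "
            f"{self.graph.number_of_nodes()} vertices"
            + (f", root={self.root}" if self.root is not None else "")
            + ")"
        )


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def parse_newick(text: str, rooted: Optional[bool] = None) -> Phylogeny:
    """Parse Newick text into a :class:`Phylogeny`.

    Branch lengths are accepted and discarded (the models carried by this
    package attach transition matrices to edges, not lengths).  Internal
    node labels are preserved and make those vertices addressable by name.

    The ``rooted`` flag controls how a basal bifurcation is treated:

    * ``rooted=True`` — keep the outermost vertex as a root.
    * ``rooted=False`` — never set a root; an *unlabeled* degree-two
      outermost vertex is suppressed.
    * ``rooted=None`` (default) — treat the tree as rooted exactly when the
      outermost vertex carries a label; an unlabeled basal bifurcation is
      suppressed, so ``((1,2),(3,4));`` yields the six-vertex unrooted
      quartet.
    """
    if text is None or not str(text).strip():
        raise NewickParseError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=str(text),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed Newick: {exc}") from None

    nodes = list(dtree.postorder_node_iter())
    ids = {id(node): i for i, node in enumerate(nodes)}
    graph = nx.Graph()
    leaf_labels: dict[int, str] = {}
    internal_labels: dict[int, str] = {}
    for node in nodes:
        i = ids[id(node)]
        graph.add_node(i)
        if node.is_leaf():
            label = node.taxon.label if node.taxon is not None else node.label
            if label is None or not str(label).strip():
                raise NewickParseError("unlabeled leaf in Newick input")
            leaf_labels[i] = str(label)
        elif node.label is not None and str(node.label).strip():
            internal_labels[i] = str(node.label)
        for child in node.child_nodes():
            graph.add_edge(i, ids[id(child)])

    labels = list(leaf_labels.values())
    dup = {x for x in labels if labels.count(x) > 1}
    if dup:
        raise NewickParseError(f"duplicate taxon label {sorted(dup)[0]!r}")

    seed = ids[id(dtree.seed_node)]
    seed_labeled = seed in internal_labels
    root: Optional[int] = None
    if rooted is True:
        root = seed
    else:
        if graph.degree(seed) == 2 and not seed_labeled and seed not in leaf_labels:
            a, b = graph.neighbors(seed)
            graph.remove_node(seed)
            graph.add_edge(a, b)
        elif rooted is None and seed_labeled:
            root = seed

    # renumber to consecutive post-order positions
    remap = {old: new for new, old in enumerate(sorted(graph.nodes))}
    graph = nx.relabel_nodes(graph, remap)
    leaf_labels = {remap[v]: s for v, s in leaf_labels.items() if v in remap}
    internal_labels = {remap[v]: s for v, s in internal_labels.items() if v in remap}
    root = remap[root] if root is not None else None
    return Phylogeny(graph, leaf_labels, internal_labels, root)


def write_newick(tree: Phylogeny) -> str:
    """Serialize to Newick; inverse of :func:`parse_newick` up to
    whitespace, child order, and (for unrooted trees) orientation."""
    start = tree.reference_vertex

    def emit(v: int, parent: Optional[int]) -> str:
        children = [u for u in tree.neighbors(v) if u != parent]
        name = tree.label_of(v) or ""
        if not children:
            return name
        inner = ",".join(emit(c, v) for c in children)
        return f"({inner}){name}"

    return emit(start, None) + ";"


def suppress_degree_two(tree: Phylogeny) -> Phylogeny:
    """Remove every internal degree-two vertex, joining its neighbors.

    Tree rearrangements create such vertices transiently; labels on
    suppressed vertices are dropped.  The root annotation is discarded.
    """
    g = nx.Graph(tree.graph)
    internal_labels = dict(tree.internal_labels)
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            if g.degree(v) == 2 and v not in tree.leaf_labels:
                a, b = g.neighbors(v)
                g.remove_node(v)
                g.add_edge(a, b)
                internal_labels.pop(v, None)
                changed = True
    return Phylogeny(g, tree.leaf_labels, internal_labels, root=None)


# ---------------------------------------------------------------------------
# Seeded random trees
# ---------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_binary_tree(
    n_leaves: int, seed, labels: Optional[Sequence[str]] = None
) -> Phylogeny:
    """Uniformly grown unrooted binary tree with ``n_leaves`` taxa.

    Starts from the three-leaf star and repeatedly attaches a new leaf to a
    uniformly chosen edge.  Deterministic for a fixed seed.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves for an unrooted binary tree")
    rng = _as_rng(seed)
    if labels is None:
        labels = [str(i + 1) for i in range(n_leaves)]
    if len(set(labels)) != n_leaves:
        raise ValueError("labels must be unique and match n_leaves")
    g = nx.Graph()
    center = n_leaves  # internal ids start after leaf ids
    g.add_edges_from((i, center) for i in range(3))
    next_id = n_leaves + 1
    for leaf in range(3, n_leaves):
        edges = sorted(tuple(sorted(e)) for e in g.edges)
        u, v = edges[rng.integers(len(edges))]
        g.remove_edge(u, v)
        mid = next_id
        next_id += 1
        g.add_edges_from([(u, mid), (mid, v), (mid, leaf)])
    leaf_labels = {i: labels[i] for i in range(n_leaves)}
    return Phylogeny(g, leaf_labels)


def random_tree(
    n_leaves: int,
    seed,
    contract_prob: float = 0.0,
    labels: Optional[Sequence[str]] = None,
) -> Phylogeny:
    """Seeded random tree, optionally multifurcating.

    A binary tree is grown first; each internal edge is then contracted
    independently with probability ``contract_prob``, producing vertices of
    degree four or more while keeping the taxa fixed.
    """
    rng = _as_rng(seed)
    t = random_binary_tree(n_leaves, rng, labels=labels)
    if contract_prob <= 0:
        return t
    g = nx.Graph(t.graph)
    for e in t.edges():
        u, v = tuple(sorted(e))
        if t.is_leaf(u) or t.is_leaf(v):
            continue
        if g.has_edge(u, v) and rng.random() < contract_prob:
            if g.number_of_nodes() - len(t.leaf_labels) <= 1:
                break
            g = nx.contracted_edge(g, (u, v), self_loops=False)
    return Phylogeny(g, t.leaf_labels)


def same_topology(t1: Phylogeny, t2: Phylogeny) -> bool:
    """Leaf-labeled topological isomorphism via split-set comparison."""
    return (
        set(t1.taxa()) == set(t2.taxa())
        and t1.splits() == t2.splits()
        and sorted(t1.internal_labels.values()) == sorted(t2.internal_labels.values())
    )
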