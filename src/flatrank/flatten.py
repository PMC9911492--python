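"""Flattening matrices of pattern distributions, ranks, and split scores.

A flattening arranges the joint pattern probabilities of a tree model into
a matrix: rows are indexed by the ``r^|A|`` state assignments to an ordered
vertex list ``A``, columns by the ``r^|B|`` assignments to ``B``, and each
entry is the marginal probability of the combined partial assignment (all
other vertices summed out).  It is the matrix unfolding of the pattern
probability tensor along the bipartition ``A | B``.

Index convention: assignments enumerate in base ``r`` with the *last listed
vertex varying fastest*, so for two-state data on four taxa the row order of
``flat_{1,2|3,4}`` reads 00, 01, 10, 11 — the usual lexicographic pattern
table order.  The convention is part of the :class:`Flattening` value and is
tested positionally.

The rank of a flattening is the algebraically meaningful quantity — for
generic parameters it equals ``r`` to the power of the minimum vertex cut
separating ``A`` from ``B``.  Ranks are reported two ways: numerically from
the singular spectrum with a relative tolerance, and exactly (certified) by
rational Gaussian elimination when the parameters are rational.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import scipy.linalg

from .cutsets import Character
from .gmm import Alignment, GMMParams, marginal, pattern_tensor
from .trees import Phylogeny, SplitSpec, VertexRef

__all__ = [
    "Flattening",
    "RankReport",
    "build_flattening",
    "numerical_rank",
    "rational_rank",
    "exact_rank",
    "split_score",
    "empirical_flattening",
    "marginalization_operator",
]

_ENTRY_GUARD = 2 ** 24  # refuse dense flattenings beyond this many entries


@dataclass(frozen=True)
class Flattening:
    """A flattening matrix plus the ordered index metadata defining it.

    ``row_vertices`` and ``col_vertices`` are the ordered vertex lists (or
    taxon labels, for empirical flattenings); ``matrix`` has shape
    ``(r^len(rows), r^len(cols))``, is entrywise non-negative and sums to 1.
    """

    r: int
    row_vertices: tuple
    col_vertices: tuple
    matrix: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def exact(self) -> bool:
        return self.matrix.dtype == object

    def row_index(self, assignment: Sequence[int]) -> int:
        """Base-r index of a row assignment (last vertex fastest)."""
        return _mixed_index(assignment, self.r, len(self.row_vertices))

    def col_index(self, assignment: Sequence[int]) -> int:
        return _mixed_index(assignment, self.r, len(self.col_vertices))

    def row_assignment(self, index: int) -> tuple[int, ...]:
        return _index_assignment(index, self.r, len(self.row_vertices))

    def col_assignment(self, index: int) -> tuple[int, ...]:
        return _index_assignment(index, self.r, len(self.col_vertices))


def _mixed_index(assignment: Sequence[int], r: int, n: int) -> int:
    if len(assignment) != n:
        raise ValueError("assignment length does not match vertex list")
    idx = 0
    for s in assignment:
        if not 0 <= s < r:
            raise ValueError(f"state {s} out of range")
        idx = idx * r + s
    return idx


def _index_assignment(index: int, r: int, n: int) -> tuple[int, ...]:
    out = []
    for _ in range(n):
        index, s = divmod(index, r)
        out.append(s)
    return tuple(reversed(out))


@dataclass
class RankReport:
    """Singular spectrum of a flattening with derived rank diagnostics.

    ``numerical_rank`` counts singular values above ``tolerance``;
    ``exact_rank`` is set when rational arithmetic was available;
    ``spectral_gap`` is the largest ratio between consecutive singular
    values and its position — true ranks here are powers of ``r``, so a
    clean answer shows one dominant gap.  ``predicted_rank`` is filled by
    the verification harness when a cut size is known.
    """

    singular_values: np.ndarray
    tolerance: float
    numerical_rank: int
    exact_rank: Optional[int] = None
    predicted_rank: Optional[int] = None
    split_score: Optional[float] = None
    spectral_gap: Optional[tuple[int, float]] = None

    @property
    def rank(self) -> int:
        """Exact rank when certified, numerical rank otherwise."""
        return self.exact_rank if self.exact_rank is not None else self.numerical_rank


def build_flattening(
    tree: Phylogeny,
    params: GMMParams,
    split: Union[SplitSpec, tuple],
    method: str = "auto",
) -> Flattening:
    """Flattening of the model distribution for a vertex bipartition.

    ``split`` may be a :class:`SplitSpec` or an ``(A, B)`` pair of vertex
    reference lists; the listed order fixes the row/column enumeration.
    Vertices outside ``A ∪ B`` — internal or leaf — are marginalized out.

    ``method`` selects the computation: ``"tensor"`` reshapes the full leaf
    pattern tensor (only when ``A ∪ B`` are leaves), ``"marginal"``
    evaluates each entry as a clamped marginal (always applicable), and
    ``"auto"`` picks whichever fits.  Both routes agree to floating-point
    resolution and exactly in rational mode.
    """
    if not isinstance(split, SplitSpec):
        A, B = split
        split = tree.split(A, B)
    A, B = split.A, split.B
    r = params.r
    if r ** (len(A) + len(B)) > _ENTRY_GUARD:
        raise ValueError(
            f"flattening would have r^{len(A) + len(B)} > {_ENTRY_GUARD} entries"
        )
    leaves = set(tree.leaves())
    leaf_query = set(A) | set(B) <= leaves
    if method == "auto":
        method = "tensor" if leaf_query else "marginal"
    if method == "tensor":
        if not leaf_query:
            raise ValueError("tensor method requires A and B to be leaves")
        tensor = pattern_tensor(tree, params, A + B)
        matrix = tensor.reshape(r ** len(A), r ** len(B))
    elif method == "marginal":
        matrix = np.empty(
            (r ** len(A), r ** len(B)), dtype=object if params.exact else float
        )
        for fa in itertools.product(range(r), repeat=len(A)):
            i = _mixed_index(fa, r, len(A))
            for fb in itertools.product(range(r), repeat=len(B)):
                j = _mixed_index(fb, r, len(B))
                char = Character(r, {**dict(zip(A, fa)), **dict(zip(B, fb))})
                matrix[i, j] = marginal(tree, params, char)
    else:
        raise ValueError(f"unknown method {method!r}")
    return Flattening(r, A, B, matrix)


# ---------------------------------------------------------------------------
# Rank
# ---------------------------------------------------------------------------


def rational_rank(matrix: np.ndarray) -> int:
    """Exact rank over the rationals by Gaussian elimination with
    normalized pivots.  Certified: no tolerances involved."""
    rows = [[Fraction(x) for x in row] for row in np.asarray(matrix, dtype=object)]
    nrows = len(rows)
    ncols = len(rows[0]) if nrows else 0
    rank = 0
    for col in range(ncols):
        pivot = next((i for i in range(rank, nrows) if rows[i][col] != 0), None)
        if pivot is None:
            continue
        rows[rank], rows[pivot] = rows[pivot], rows[rank]
        inv = 1 / rows[rank][col]
        rows[rank] = [x * inv for x in rows[rank]]
        for i in range(rank + 1, nrows):
            f = rows[i][col]
            if f:
                rows[i] = [a - f * b for a, b in zip(rows[i], rows[rank])]
        rank += 1
        if rank == nrows:
            break
    return rank


def exact_rank(flat: Flattening) -> int:
    """Certified rank of an exact-mode flattening."""
    if not flat.exact:
        raise ValueError("exact rank requires rational-mode parameters")
    return rational_rank(flat.matrix)


def numerical_rank(
    flat: Flattening,
    rel_tol: float = 1e-9,
    tol: Optional[float] = None,
    k: int = 1,
) -> RankReport:
    """SVD-based rank report.

    The default tolerance is ``rel_tol`` times the largest singular value —
    generous because true ranks are powers of ``r`` with large spectral
    gaps for generic parameters on small trees.  The largest relative gap
    is reported as a diagnostic for borderline spectra, and exact rank is
    appended automatically in rational mode.
    """
    M = flat.matrix
    if M.size == 0:
        raise ValueError("empty flattening matrix")
    svals = scipy.linalg.svdvals(M.astype(float))
    smax = float(svals[0]) if len(svals) else 0.0
    if tol is None:
        tol = smax * rel_tol
    num_rank = int(np.sum(svals > tol))
    gap = None
    positive = svals[svals > 0]
    if len(positive) >= 2:
        ratios = positive[:-1] / positive[1:]
        j = int(np.argmax(ratios))
        gap = (j + 1, float(ratios[j]))
    elif len(svals) >= 2 and len(positive) >= 1:
        gap = (len(positive), float("inf"))
    score = None
    if flat.r ** k <= min(M.shape):
        score = _score_from_svals(svals, flat.r ** k)
    return RankReport(
        singular_values=svals,
        tolerance=float(tol),
        numerical_rank=num_rank,
        exact_rank=exact_rank(flat) if flat.exact else None,
        split_score=score,
        spectral_gap=gap,
    )


def _score_from_svals(svals: np.ndarray, keep: int) -> float:
    total = float(svals.sum())
    if total == 0:
        return 0.0
    return float(svals[keep:].sum()) / total


def split_score(flat: Flattening, k: int = 1) -> float:
    """Sum of singular values beyond the largest ``r^k``, over their total.

    Zero exactly when the flattening has rank at most ``r^k`` — in
    particular for exact probabilities of a split present in the tree with
    the conventional ``k = 1``.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if flat.r ** k > min(flat.shape):
        raise ValueError(
            f"r^k = {flat.r ** k} exceeds the smaller flattening dimension"
        )
    svals = scipy.linalg.svdvals(flat.matrix.astype(float))
    return _score_from_svals(svals, flat.r ** k)


# ---------------------------------------------------------------------------
# Empirical flattenings from alignments
# ---------------------------------------------------------------------------


def empirical_flattening(
    alignment: Alignment,
    A: Sequence[str],
    B: Sequence[str],
) -> Flattening:
    """Pattern-frequency flattening of an alignment for taxon lists A | B.

    The data-facing analogue of :func:`build_flattening`: entries are
    relative frequencies of the observed joint patterns, so the matrix sums
    to one and converges to the model flattening as sites accumulate.
    """
    index = {t: i for i, t in enumerate(alignment.taxa)}
    for t in tuple(A) + tuple(B):
        if t not in index:
            raise ValueError(f"unknown taxon {t!r}")
    if set(A) & set(B):
        raise ValueError("A and B must be disjoint")
    if not A or not B:
        raise ValueError("A and B must be non-empty")
    if alignment.n_sites == 0:
        raise ValueError("empty alignment")
    r = alignment.r
    rows_a = alignment.data[[index[t] for t in A], :]
    rows_b = alignment.data[[index[t] for t in B], :]
    ia = np.zeros(alignment.n_sites, dtype=np.int64)
    for row in rows_a:
        ia = ia * r + row
    ib = np.zeros(alignment.n_sites, dtype=np.int64)
    for row in rows_b:
        ib = ib * r + row
    matrix = np.zeros((r ** len(A), r ** len(B)))
    np.add.at(matrix, (ia, ib), 1.0)
    matrix /= alignment.n_sites
    return Flattening(r, tuple(A), tuple(B), matrix)


# ---------------------------------------------------------------------------
# Marginalization operators (0-1 matrices)
# ---------------------------------------------------------------------------


def marginalization_operator(
    r: int, sub: Sequence, full: Sequence, exact: bool = False
) -> np.ndarray:
    """The 0-1 matrix U with ``flat_{A'|B'} = U_A flat_{A|B} U_B^T``.

    ``U[i, j] = 1`` iff the full assignment with index ``j`` restricts on
    ``sub`` to the assignment with index ``i``.  Summing a flattening
    against these operators marginalizes vertices out of a part, which can
    only lower the rank.
    """
    sub = tuple(sub)
    full = tuple(full)
    if not set(sub) <= set(full):
        raise ValueError("sub must be a subset of full")
    positions = [full.index(v) for v in sub]
    U = np.zeros((r ** len(sub), r ** len(full)), dtype=object if exact else float)
    one = Fraction(1) if exact else 1.0
    if exact:
        U[:] = Fraction(0)
    for j, g in enumerate(itertools.product(range(r), repeat=len(full))):
        restricted = tuple(g[p] for p in positions)
        i = _mixed_index(restricted, r, len(sub))
        U[i, j] = one
    return U
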