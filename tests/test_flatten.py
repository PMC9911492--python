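"""Flattening construction, index layout, ranks, scores, factorizations."""
import itertools
from fractions import Fraction

import numpy as np
import pytest

import flatrank as fr
from flatrank import flatten as fl
from flatrank import cutsets, gmm
from flatrank.flatten import (
    Flattening,
    build_flattening,
    empirical_flattening,
    exact_rank,
    marginalization_operator,
    numerical_rank,
    rational_rank,
    split_score,
)
from flatrank.gmm import GMMParams, pattern_tensor, random_generic_params, simulate_alignment
from flatrank.trees import random_binary_tree

from conftest import random_disjoint_vertex_subsets


def test_positional_layout_matches_pattern_vector(quartet):
    """Rows of flat_{1,2|3,4} enumerate states of taxa 1,2 (last fastest),
    columns of taxa 3,4 — entry (0,1) is the probability of pattern 0001."""
    p = random_generic_params(quartet, 2, seed=1)
    tensor = pattern_tensor(quartet, p)  # axes in taxon order 1,2,3,4
    flat = build_flattening(quartet, p, (["1", "2"], ["3", "4"]))
    assert flat.shape == (4, 4)
    for i1, i2, i3, i4 in itertools.product(range(2), repeat=4):
        row = flat.row_index((i1, i2))
        col = flat.col_index((i3, i4))
        assert flat.matrix[row, col] == pytest.approx(
            float(tensor[i1, i2, i3, i4]), abs=1e-15
        )
    assert flat.row_index((0, 1)) == 1  # last listed vertex varies fastest


def test_single_taxon_flattening_layout(quartet):
    p = random_generic_params(quartet, 2, seed=2)
    tensor = pattern_tensor(quartet, p)
    flat = build_flattening(quartet, p, (["1"], ["2", "3", "4"]))
    assert flat.shape == (2, 8)
    for states in itertools.product(range(2), repeat=4):
        assert flat.matrix[states[0], flat.col_index(states[1:])] == pytest.approx(
            float(tensor[states]), abs=1e-15
        )


def test_identity_model_flattening_is_scaled_permutation(quartet):
    """With identity transitions and a uniform root all leaves share the
    root state: exactly r entries, each 1/r, on the 'diagonal'."""
    r = 3
    root = quartet.reference_vertex
    p = GMMParams(
        r,
        root,
        np.full(r, 1.0 / r),
        {e: np.eye(r) for e in quartet.directed_edges(root)},
    )
    flat = build_flattening(quartet, p, (["1", "2"], ["3", "4"]))
    nonzero = np.argwhere(flat.matrix > 0)
    assert len(nonzero) == r
    assert np.allclose(flat.matrix[flat.matrix > 0], 1.0 / r)
    assert numerical_rank(flat).numerical_rank == r


@pytest.mark.parametrize("r", [2, 3])
def test_generic_quartet_ranks(quartet, r):
    p = random_generic_params(quartet, r, seed=3)
    split_flat = build_flattening(quartet, p, (["1", "2"], ["3", "4"]))
    cross_flat = build_flattening(quartet, p, (["1", "3"], ["2", "4"]))
    assert numerical_rank(split_flat).numerical_rank == r
    assert numerical_rank(cross_flat).numerical_rank == r * r
    pe = random_generic_params(quartet, r, seed=3, exact=True)
    assert exact_rank(build_flattening(quartet, pe, (["1", "2"], ["3", "4"]))) == r
    assert exact_rank(build_flattening(quartet, pe, (["1", "3"], ["2", "4"]))) == r * r


def test_methods_agree(quartet):
    p = random_generic_params(quartet, 2, seed=4)
    a = build_flattening(quartet, p, (["1", "2"], ["3", "4"]), method="tensor")
    b = build_flattening(quartet, p, (["1", "2"], ["3", "4"]), method="marginal")
    assert np.abs(a.matrix - b.matrix).max() <= 1e-12
    pe = random_generic_params(quartet, 2, seed=4, exact=True)
    ae = build_flattening(quartet, pe, (["1", "2"], ["3", "4"]), method="tensor")
    be = build_flattening(quartet, pe, (["1", "2"], ["3", "4"]), method="marginal")
    assert (ae.matrix == be.matrix).all()


def test_internal_vertices_in_split(quartet):
    """Flattenings are defined for vertex subsets, not just taxa."""
    p = random_generic_params(quartet, 2, seed=5)
    u, v = quartet.internal_vertices()
    flat = build_flattening(quartet, p, ([u], [v]))
    assert flat.shape == (2, 2)
    assert flat.matrix.sum() == pytest.approx(1.0, abs=1e-12)
    assert numerical_rank(flat).numerical_rank == 2


def test_entries_positive_and_sum_to_one(quartet):
    p = random_generic_params(quartet, 2, seed=6)
    flat = build_flattening(quartet, p, (["1", "4"], ["2", "3"]))
    assert (flat.matrix > 0).all()
    assert flat.matrix.sum() == pytest.approx(1.0, abs=1e-12)


def test_split_scores(quartet):
    p = random_generic_params(quartet, 2, seed=7)
    true_split = build_flattening(quartet, p, (["1", "2"], ["3", "4"]))
    assert split_score(true_split) <= 1e-9
    cross = build_flattening(quartet, p, (["1", "3"], ["2", "4"]))
    assert split_score(cross) > 1e-6
    # rank-one outer product scores zero for any k >= 0
    u = np.array([0.1, 0.2, 0.3, 0.4])
    rank1 = Flattening(2, ("a", "b"), ("c", "d"), np.outer(u, u) / np.outer(u, u).sum())
    assert split_score(rank1, k=1) == pytest.approx(0.0, abs=1e-15)
    assert split_score(true_split, k=2) == pytest.approx(0.0)  # r^2 = min dim
    with pytest.raises(ValueError):
        split_score(true_split, k=3)  # r^3 = 8 exceeds the 4x4 shape


def test_rank_invariant_under_within_part_reordering(quartet):
    p = random_generic_params(quartet, 2, seed=8)
    a = build_flattening(quartet, p, (["1", "3"], ["2", "4"]))
    b = build_flattening(quartet, p, (["3", "1"], ["4", "2"]))
    assert numerical_rank(a).numerical_rank == numerical_rank(b).numerical_rank
    assert not np.array_equal(a.matrix, b.matrix)  # layout did change


@pytest.mark.parametrize("seed", range(10))
def test_marginalization_factorization(seed):
    """Summing vertices out of a part is multiplication by a 0-1 operator,
    so the smaller flattening's rank never exceeds the larger one's."""
    rng = np.random.default_rng(seed)
    t = random_binary_tree(int(rng.integers(4, 8)), rng)
    r = 2
    p = random_generic_params(t, r, rng)
    A, B = random_disjoint_vertex_subsets(t, rng, max_part=3, leaves_only=True)
    if len(A) < 2 or len(B) < 2:
        A, B = t.leaves()[:2], t.leaves()[2:4]
    sub_a = tuple(A[: max(1, len(A) - 1)])
    sub_b = tuple(B[: max(1, len(B) - 1)])
    big = build_flattening(t, p, (A, B))
    small = build_flattening(t, p, (sub_a, sub_b))
    UA = marginalization_operator(r, sub_a, tuple(A))
    UB = marginalization_operator(r, sub_b, tuple(B))
    assert np.abs(UA @ big.matrix @ UB.T - small.matrix).max() <= 1e-12
    assert (
        numerical_rank(small).numerical_rank <= numerical_rank(big).numerical_rank
    )


@pytest.mark.parametrize("seed", range(10))
def test_cut_conditional_factorization(seed):
    """flat_{A|B} = R S through a minimum vertex cut C: R holds the
    conditionals P(X_A | X_C), S the joints P(X_B, X_C)."""
    rng = np.random.default_rng(100 + seed)
    for _ in range(50):  # draw until the optimal cut avoids the terminals
        t = random_binary_tree(int(rng.integers(4, 8)), rng)
        p = random_generic_params(t, 2, rng)
        A, B = random_disjoint_vertex_subsets(t, rng, max_part=2, leaves_only=True)
        cut = sorted(cutsets.nu(t, A, B).witness_cut)
        if not set(cut) & (set(A) | set(B)):
            break
    else:
        pytest.fail("no terminal-free minimum cut found in 50 draws")
    flat_ab = build_flattening(t, p, (A, B))
    flat_ac = build_flattening(t, p, (A, cut))
    flat_cb = build_flattening(t, p, (cut, B))
    pc = flat_ac.matrix.sum(axis=0)  # marginal of X_C
    R = flat_ac.matrix / pc[None, :]
    assert np.abs(R @ flat_cb.matrix - flat_ab.matrix).max() <= 1e-12


def test_rational_rank_agrees_with_sympy():
    """Independent cross-check of the exact elimination on random
    low-rank rational matrices."""
    sympy = pytest.importorskip("sympy")
    rng = np.random.default_rng(0)
    for _ in range(10):
        m, n, k = rng.integers(2, 7, size=3)
        L = rng.integers(-5, 6, size=(m, k))
        R = rng.integers(-5, 6, size=(k, n))
        M = (L @ R).astype(object)
        M = np.array([[Fraction(int(x), 7) for x in row] for row in M], dtype=object)
        assert rational_rank(M) == sympy.Matrix(M.tolist()).rank()


def test_empirical_flattening_basics(quartet):
    taxa = ("1", "2", "3", "4")
    single = gmm.Alignment(taxa, np.zeros((4, 1), dtype=int), 2)
    flat = empirical_flattening(single, ["1", "2"], ["3", "4"])
    assert flat.matrix[0, 0] == 1.0 and flat.matrix.sum() == 1.0
    # one column of every pattern -> uniform matrix of rank one
    cols = np.array(list(itertools.product(range(2), repeat=4))).T
    every = gmm.Alignment(taxa, cols, 2)
    flat = empirical_flattening(every, ["1", "2"], ["3", "4"])
    assert np.allclose(flat.matrix, 1 / 16)
    assert numerical_rank(flat).numerical_rank == 1
    with pytest.raises(ValueError):
        empirical_flattening(single, ["1", "x"], ["3"])


def test_simulated_true_split_scores_low(quartet):
    p = random_generic_params(quartet, 2, seed=9)
    aln = simulate_alignment(quartet, p, 50_000, seed=10)
    flat = empirical_flattening(aln, ["1", "2"], ["3", "4"])
    assert split_score(flat) < 0.05


def test_flattening_guards(quartet):
    p = random_generic_params(quartet, 2, seed=11)
    with pytest.raises(ValueError):
        build_flattening(quartet, p, (["1", "2"], ["2", "3"]))
    big = random_binary_tree(30, 0)
    pbig = random_generic_params(big, 4, seed=0)
    with pytest.raises(ValueError):
        build_flattening(big, pbig, (big.leaves()[:7], big.leaves()[7:14]))
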