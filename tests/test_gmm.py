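"""Model probabilities, conditions, rerooting, generation, and simulation."""
import itertools
from fractions import Fraction

import numpy as np
import pytest

import flatrank as fr
from flatrank import gmm
from flatrank.cutsets import Character
from flatrank.gmm import (
    GMMParams,
    check_conditions,
    joint_probability,
    load_params,
    marginal,
    pairwise_joint,
    pattern_tensor,
    random_generic_params,
    reroot_params,
    save_params,
    simulate_alignment,
    vertex_marginals,
)
from flatrank.trees import random_tree


def _two_leaf_tree():
    return fr.parse_newick("(a,b);")


def _identity_params(tree, r=2):
    root = tree.reference_vertex
    pi = np.full(r, 1.0 / r)
    edges = {e: np.eye(r) for e in tree.directed_edges(root)}
    return GMMParams(r, root, pi, edges)


def test_joint_single_edge_identity():
    t = _two_leaf_tree()
    p = _identity_params(t)
    F = {v: 0 for v in t.vertices}
    assert joint_probability(t, p, F) == pytest.approx(0.5)
    # identity annihilates mixed assignments
    F[t.resolve("b")] = 1
    assert joint_probability(t, p, F) == 0.0


def test_joint_sums_to_one_exhaustively(quartet):
    p = random_generic_params(quartet, 2, seed=3)
    total = sum(
        joint_probability(quartet, p, dict(zip(quartet.vertices, F)))
        for F in itertools.product(range(2), repeat=6)
    )
    assert total == pytest.approx(1.0, abs=1e-12)


def test_marginal_of_full_domain_is_joint(quartet):
    p = random_generic_params(quartet, 2, seed=4)
    F = {v: (v * 7) % 2 for v in quartet.vertices}
    m = marginal(quartet, p, Character(2, F))
    assert m == pytest.approx(joint_probability(quartet, p, F), abs=1e-15)


@pytest.mark.parametrize("seed", range(40))
def test_elimination_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 6))
    t = random_tree(n, rng, contract_prob=0.3 if seed % 2 else 0.0)
    r = int(rng.choice([2, 3]))
    p = random_generic_params(t, r, rng)
    verts = t.vertices
    dom_size = int(rng.integers(1, len(verts) + 1))
    dom = [verts[i] for i in rng.permutation(len(verts))[:dom_size]]
    char = Character(r, {v: int(rng.integers(r)) for v in dom})
    fast = marginal(t, p, char)
    slow = sum(
        joint_probability(t, p, dict(zip(verts, F)))
        for F in itertools.product(range(r), repeat=len(verts))
        if all(F[verts.index(v)] == s for v, s in char.assignment.items())
    )
    assert abs(fast - slow) <= 1e-12


def test_leaf_marginals_positive_under_conditions(quartet):
    p = random_generic_params(quartet, 3, seed=5)
    for v in quartet.vertices:
        for i in range(3):
            assert marginal(quartet, p, Character(3, {v: i})) > 0


@pytest.mark.parametrize("seed", range(10))
def test_pairwise_joint_nonsingular(seed):
    rng = np.random.default_rng(seed)
    t = random_tree(int(rng.integers(4, 7)), rng)
    r = int(rng.choice([2, 3]))
    p = random_generic_params(t, r, rng)
    verts = t.vertices
    u, v = (verts[i] for i in rng.permutation(len(verts))[:2])
    M = pairwise_joint(t, p, u, v)
    assert abs(np.linalg.det(M.astype(float))) > 1e-12


def test_pattern_tensor_sums_to_one(quartet):
    p = random_generic_params(quartet, 2, seed=6)
    assert pattern_tensor(quartet, p).sum() == pytest.approx(1.0, abs=1e-10)
    pe = random_generic_params(quartet, 2, seed=6, exact=True)
    assert pattern_tensor(quartet, pe).sum() == Fraction(1)


def test_pattern_tensor_internal_vertices(quartet):
    """Tensors over mixed leaf/internal vertex lists marginalize correctly."""
    p = random_generic_params(quartet, 2, seed=8)
    internal = quartet.internal_vertices()[0]
    tens = pattern_tensor(quartet, p, [internal, quartet.resolve("1")])
    assert tens.shape == (2, 2)
    assert tens.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(tens.sum(axis=0), pattern_tensor(quartet, p, [quartet.resolve("1")]))


def test_reroot_identity_and_tensor_preservation(quartet):
    p = random_generic_params(quartet, 2, seed=9)
    assert reroot_params(quartet, p, p.root).root == p.root
    base = pattern_tensor(quartet, p)
    for target in quartet.vertices:
        p2 = reroot_params(quartet, p, target)
        p2.validate(quartet)
        assert check_conditions(quartet, p2).ok
        assert np.abs(pattern_tensor(quartet, p2) - base).max() <= 1e-12
    # round trip restores the distribution exactly in rational mode
    pe = random_generic_params(quartet, 2, seed=9, exact=True)
    base_e = pattern_tensor(quartet, pe)
    back = reroot_params(quartet, reroot_params(quartet, pe, quartet.resolve("3")), pe.root)
    assert (pattern_tensor(quartet, back) == base_e).all()


def test_check_conditions_witnesses(quartet):
    root = quartet.reference_vertex
    directed = quartet.directed_edges(root)
    ok = {e: np.array([[0.8, 0.2], [0.3, 0.7]]) for e in directed}

    bad_root = GMMParams(2, root, np.array([0.0, 1.0]), ok)
    rep = check_conditions(quartet, bad_root)
    assert not rep.c2 and "i=0" in rep.c2_witness and rep.c1 and rep.c3

    pendant = next(e for e in directed if quartet.is_leaf(e[1]))
    with_identity = dict(ok)
    with_identity[pendant] = np.eye(2)
    rep = check_conditions(quartet, GMMParams(2, root, np.array([0.5, 0.5]), with_identity))
    assert rep.c1 and rep.c3  # C3 does not apply to pendant edges

    internal = next(e for e in directed if not quartet.is_leaf(e[1]))
    singular = dict(ok)
    singular[internal] = np.array([[0.5, 0.5], [0.5, 0.5]])
    rep = check_conditions(quartet, GMMParams(2, root, np.array([0.5, 0.5]), singular))
    assert not rep.c1 and str(internal[0]) in rep.c1_witness


def test_generator_deterministic_and_conditional(quartet):
    a = random_generic_params(quartet, 3, seed=11)
    b = random_generic_params(quartet, 3, seed=11)
    assert np.array_equal(a.root_dist, b.root_dist)
    for e in a.edge_matrices:
        assert np.array_equal(a.edge_matrices[e], b.edge_matrices[e])
    for seed in range(30):
        p = random_generic_params(quartet, 2, seed=seed)
        p.validate(quartet)
        assert check_conditions(quartet, p).ok


def test_generator_exact_mode_is_exactly_stochastic(quartet):
    p = random_generic_params(quartet, 2, seed=12, exact=True)
    assert sum(p.root_dist) == Fraction(1)
    for P in p.edge_matrices.values():
        for row in P:
            assert sum(row) == Fraction(1)
    assert check_conditions(quartet, p).ok


def test_generation_error_when_unsatisfiable(quartet):
    with pytest.raises(gmm.GenerationError):
        random_generic_params(quartet, 2, seed=0, min_entry=0.6, max_tries=50)


def test_simulate_empty_and_deterministic(quartet):
    p = random_generic_params(quartet, 2, seed=13)
    assert simulate_alignment(quartet, p, 0, seed=1).n_sites == 0
    with pytest.raises(ValueError):
        simulate_alignment(quartet, p, -1, seed=1)
    a = simulate_alignment(quartet, p, 100, seed=2)
    b = simulate_alignment(quartet, p, 100, seed=2)
    assert np.array_equal(a.data, b.data)


def test_identity_model_gives_constant_columns(quartet):
    p = _identity_params(quartet)
    aln = simulate_alignment(quartet, p, 200, seed=3)
    assert (aln.data == aln.data[0]).all()


def test_empirical_frequencies_concentrate(quartet):
    """Empirical pattern frequencies match exact probabilities within
    three binomial standard errors for nearly all of the 16 patterns."""
    p = random_generic_params(quartet, 2, seed=14)
    n = 50_000
    aln = simulate_alignment(quartet, p, n, seed=15)
    tensor = pattern_tensor(quartet, p)
    counts = np.zeros((2,) * 4)
    for j in range(n):
        counts[aln.column(j)] += 1
    within = 0
    for states in itertools.product(range(2), repeat=4):
        prob = float(tensor[states])
        se = (prob * (1 - prob) / n) ** 0.5
        if abs(counts[states] / n - prob) <= 3 * se:
            within += 1
    assert within >= 15


def test_params_yaml_roundtrip(tmp_path, quartet):
    p = random_generic_params(quartet, 2, seed=16)
    path = tmp_path / "params.yaml"
    save_params(p, quartet, path)
    q = load_params(path, quartet)
    assert q.root == p.root and not q.exact
    assert np.allclose(q.root_dist, p.root_dist)
    pe = random_generic_params(quartet, 2, seed=16, exact=True)
    save_params(pe, quartet, path)
    qe = load_params(path, quartet)
    assert qe.exact
    assert (qe.root_dist == pe.root_dist).all()
    for e in pe.edge_matrices:
        assert (qe.edge_matrices[e] == pe.edge_matrices[e]).all()


def test_alignment_fasta_roundtrip(tmp_path, quartet):
    p = random_generic_params(quartet, 4, seed=17)
    aln = simulate_alignment(quartet, p, 25, seed=18)
    path = tmp_path / "sim.fasta"
    aln.to_fasta(path)
    back = gmm.Alignment.from_fasta(path, 4)
    assert back.taxa == aln.taxa
    assert np.array_equal(back.data, aln.data)


def test_vertex_marginals_consistent(quartet):
    p = random_generic_params(quartet, 3, seed=19)
    mu = vertex_marginals(quartet, p)
    for v in quartet.vertices:
        for i in range(3):
            assert mu[v][i] == pytest.approx(
                marginal(quartet, p, Character(3, {v: i})), abs=1e-12
            )
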