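"""Tree profile learning and interface scoring."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coevnet import (
    AlignedSequencePair,
    ContactMap,
    InterfaceProfilePair,
    TreePGM,
    build_negative_samples,
    learn_tree,
    learn_tree_from_matrix,
    mutual_information,
    score_interface,
    tree_loglik,
)
from coevnet.alphabet import ALPHABET, AMINO_ACIDS, N_SYMBOLS, decode
from coevnet.interface import InterfaceAssignment
from coevnet.tree import mi_from_counts

from _oracles import all_spanning_trees, brute_force_mi

A = AMINO_ACIDS.index("A")
V = AMINO_ACIDS.index("V")


def random_tree(nodes, rng, gap_mass=True) -> TreePGM:
    """A TreePGM with random (Dirichlet) marginal and CPTs and random structure."""
    nodes = sorted(nodes)
    n = len(nodes)
    marginal = rng.dirichlet(np.ones(N_SYMBOLS))
    edges = []
    cpts = {}
    for k in range(1, n):
        parent = nodes[rng.integers(0, k)]
        edges.append((parent, nodes[k]))
        cpts[(parent, nodes[k])] = rng.dirichlet(np.ones(N_SYMBOLS), size=N_SYMBOLS)
    return TreePGM(tuple(nodes), nodes[0], tuple(edges), marginal, cpts)


def pairs_from_matrix(matrix, nodes, length_a, length_b):
    """Embed a node-symbol matrix into full-length aligned pairs ('A' elsewhere)."""
    out = []
    for row in matrix:
        a = np.zeros(length_a, dtype=np.int8)
        b = np.zeros(length_b, dtype=np.int8)
        for sym, (tag, col) in zip(row, nodes):
            (a if tag == "A" else b)[col - 1] = sym
        out.append(AlignedSequencePair(decode(a), decode(b)))
    return out


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------


class TestMutualInformation:
    def test_independent_columns_near_zero(self):
        # plug-in MI has an O((k-1)^2 / 2N ln 2) upward bias and uniform
        # smoothing over the full 21x21 table adds a mixture artifact when the
        # data live on a sub-alphabet, so "near zero" is checked above a small
        # pseudocount floor
        rng = np.random.default_rng(0)
        matrix = rng.integers(0, 4, size=(10_000, 2)).astype(np.int8)
        pairs = pairs_from_matrix(matrix, [("A", 1), ("B", 1)], 1, 1)
        mi = mutual_information(pairs, ("A", 1), ("B", 1), pseudocount=0.01)
        assert mi < 0.01
        # full 20-letter alphabet: still small, bounded by the bias term
        matrix20 = rng.integers(0, 20, size=(10_000, 2)).astype(np.int8)
        pairs20 = pairs_from_matrix(matrix20, [("A", 1), ("B", 1)], 1, 1)
        assert mutual_information(pairs20, ("A", 1), ("B", 1), pseudocount=0.01) < 0.05

    def test_copied_two_symbol_column_is_one_bit(self):
        rng = np.random.default_rng(1)
        x = rng.choice([A, V], size=10_000).astype(np.int8)
        matrix = np.stack([x, x], axis=1)
        pairs = pairs_from_matrix(matrix, [("A", 1), ("B", 1)], 1, 1)
        mi = mutual_information(pairs, ("A", 1), ("B", 1), pseudocount=1e-9)
        assert mi == pytest.approx(1.0, abs=0.02)

    def test_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 21, size=50)
        y = rng.integers(0, 21, size=50)
        matrix = np.stack([x, y], axis=1).astype(np.int8)
        pairs = pairs_from_matrix(matrix, [("A", 1), ("B", 1)], 1, 1)
        for pc in (0.1, 0.5, 2.0):
            mi = mutual_information(pairs, ("A", 1), ("B", 1), pseudocount=pc)
            assert mi == pytest.approx(brute_force_mi(x, y, pc), abs=1e-12)

    def test_unknown_node_rejected(self):
        pairs = [AlignedSequencePair("AC", "DE")]
        with pytest.raises(ValueError, match="unknown node"):
            mutual_information(pairs, ("A", 1), ("B", 9))


# ---------------------------------------------------------------------------
# structure learning
# ---------------------------------------------------------------------------


class TestLearnTree:
    def test_two_nodes_forced_edge_and_cpt(self):
        rng = np.random.default_rng(3)
        matrix = rng.integers(0, 5, size=(40, 2)).astype(np.int8)
        nodes = [("A", 1), ("B", 1)]
        tree = learn_tree_from_matrix(matrix, nodes, pseudocount=0.5)
        assert tree.edges == ((("A", 1), ("B", 1)),)
        joint = np.full((N_SYMBOLS, N_SYMBOLS), 0.5)
        for a, b in matrix:
            joint[a, b] += 1
        expected_cpt = joint / joint.sum(axis=1, keepdims=True)
        assert np.allclose(tree.edge_cpt[(("A", 1), ("B", 1))], expected_cpt)

    def test_chain_recovery_single_replicate(self):
        rng = np.random.default_rng(4)
        nodes = [("A", 1), ("A", 2), ("B", 1), ("B", 2)]
        chain = make_chain_tree(nodes, stay=0.8, rng=rng)
        matrix = chain.sample(4000, rng)
        learned = learn_tree_from_matrix(matrix, nodes, pseudocount=0.5)
        assert learned.undirected_edges == chain.undirected_edges

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(5)
        matrix = rng.integers(0, 21, size=(200, 3)).astype(np.int8)
        nodes = [("A", 1), ("A", 2), ("B", 1)]
        t1 = learn_tree_from_matrix(matrix, nodes, 0.5)
        t2 = learn_tree_from_matrix(matrix[::-1].copy(), nodes, 0.5)
        assert t1.edges == t2.edges
        assert np.array_equal(t1.node_marginal, t2.node_marginal)
        for e in t1.edges:
            assert np.array_equal(t1.edge_cpt[e], t2.edge_cpt[e])

    def test_chow_liu_weight_is_maximal_over_all_spanning_trees(self):
        rng = np.random.default_rng(6)
        for n in (3, 4, 5):
            nodes = [("A", c) for c in range(1, n + 1)]
            matrix = rng.integers(0, 4, size=(60, n)).astype(np.int8)
            # correlate a random pair to give structure
            matrix[:, 1] = np.where(rng.random(60) < 0.7, matrix[:, 0], matrix[:, 1])
            pc = 0.5
            tree = learn_tree_from_matrix(matrix, nodes, pc)

            def weight(edge_idx_set):
                total = 0.0
                for i, j in edge_idx_set:
                    counts = np.zeros((N_SYMBOLS, N_SYMBOLS))
                    for row in matrix:
                        counts[row[i], row[j]] += 1
                    total += mi_from_counts(counts, pc)
                return total

            best = max(weight(t) for t in all_spanning_trees(n))
            got = weight(
                {(nodes.index(u), nodes.index(v)) for u, v in tree.edges}
            )
            assert got == pytest.approx(best, abs=1e-9)

    def test_single_node_degenerate_tree(self):
        matrix = np.array([[A], [V], [A]], dtype=np.int8)
        tree = learn_tree_from_matrix(matrix, [("A", 3)], pseudocount=0.5)
        assert tree.edges == ()
        assert tree.node_marginal.sum() == pytest.approx(1.0)

    def test_zero_nodes_rejected(self):
        with pytest.raises(ValueError):
            learn_tree([AlignedSequencePair("A", "A")] * 2, ContactMap(frozenset(), 1, 1))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_learned_tree_satisfies_normalization_invariants(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        matrix = rng.integers(0, 21, size=(30, n)).astype(np.int8)
        nodes = [("A", c) for c in range(1, n + 1)]
        tree = learn_tree_from_matrix(matrix, nodes, pseudocount=0.5)
        assert len(tree.edges) == n - 1
        assert tree.node_marginal.sum() == pytest.approx(1.0, abs=1e-9)
        for cpt in tree.edge_cpt.values():
            assert np.allclose(cpt.sum(axis=1), 1.0, atol=1e-9)


def make_chain_tree(nodes, stay, rng) -> TreePGM:
    """Chain tree over sorted nodes with sticky CPTs (P(child=parent) = stay)."""
    nodes = sorted(nodes)
    marginal = np.full(N_SYMBOLS, 1.0 / N_SYMBOLS)
    cpt = np.full((N_SYMBOLS, N_SYMBOLS), (1.0 - stay) / (N_SYMBOLS - 1))
    np.fill_diagonal(cpt, stay)
    edges = tuple((nodes[k], nodes[k + 1]) for k in range(len(nodes) - 1))
    return TreePGM(tuple(nodes), nodes[0], edges, marginal, {e: cpt.copy() for e in edges})


# ---------------------------------------------------------------------------
# negative samples
# ---------------------------------------------------------------------------


class TestNegativeSamples:
    def test_two_samples_swap(self):
        pairs = [AlignedSequencePair("AA", "CC"), AlignedSequencePair("DD", "EE")]
        rng = np.random.default_rng(0)
        out = build_negative_samples(pairs, rng)
        assert out[0].seq_b == "EE" and out[1].seq_b == "CC"
        assert out[0].seq_a == "AA" and out[1].seq_a == "DD"

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            build_negative_samples([AlignedSequencePair("A", "C")], np.random.default_rng(0))

    def test_marginals_preserved(self):
        rng = np.random.default_rng(1)
        matrix = rng.integers(0, 20, size=(50, 2)).astype(np.int8)
        pairs = pairs_from_matrix(matrix, [("A", 1), ("B", 1)], 2, 2)
        shuffled = build_negative_samples(pairs, rng)
        assert sorted(p.seq_a for p in pairs) == sorted(p.seq_a for p in shuffled)
        assert sorted(p.seq_b for p in pairs) == sorted(p.seq_b for p in shuffled)

    def test_derangement_destroys_contact_mi(self):
        rng = np.random.default_rng(2)
        x = rng.choice([A, V], size=4000).astype(np.int8)
        noise = rng.choice([A, V], size=4000).astype(np.int8)
        y = np.where(rng.random(4000) < 0.95, x, noise)
        pairs = pairs_from_matrix(np.stack([x, y], axis=1), [("A", 1), ("B", 1)], 1, 1)
        # pseudocount small enough that the uniform smoothing mass (which is
        # itself a mixture component with spurious MI) stays negligible
        before = mutual_information(pairs, ("A", 1), ("B", 1), pseudocount=0.01)
        after = mutual_information(
            build_negative_samples(pairs, rng), ("A", 1), ("B", 1), pseudocount=0.01
        )
        assert before > 0.5
        assert after < 0.02


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


class TestTreeLoglik:
    def test_single_node_uniform_marginal(self):
        marginal = np.zeros(N_SYMBOLS)
        marginal[:20] = 1.0 / 20
        tree = TreePGM((("A", 1),), ("A", 1), (), marginal, {})
        ll = tree_loglik(InterfaceAssignment({("A", 1): "W"}), tree)
        assert ll == pytest.approx(math.log2(1 / 20), abs=1e-12)

    def test_factorization_matches_enumeration(self):
        rng = np.random.default_rng(7)
        nodes = [("A", 1), ("B", 1), ("B", 2)]
        tree = random_tree(nodes, rng)
        pos = {n: k for k, n in enumerate(tree.nodes)}
        # spot-check a random subset of the 21^3 assignments exactly
        for _ in range(500):
            syms = rng.integers(0, N_SYMBOLS, size=3)
            assignment = InterfaceAssignment(
                {n: ALPHABET[syms[pos[n]]] for n in tree.nodes}
            )
            expected = tree.node_marginal[syms[pos[tree.root]]]
            for (p, c), cpt in tree.edge_cpt.items():
                expected *= cpt[syms[pos[p]], syms[pos[c]]]
            assert math.exp2(tree_loglik(assignment, tree)) == pytest.approx(
                expected, abs=1e-12
            )

    def test_total_probability_sums_to_one(self):
        rng = np.random.default_rng(8)
        for n in (1, 2, 3):
            nodes = [("A", c) for c in range(1, n + 1)]
            tree = random_tree(nodes, rng)
            total = 0.0
            for combo in itertools.product(range(N_SYMBOLS), repeat=n):
                assignment = InterfaceAssignment(
                    {node: ALPHABET[s] for node, s in zip(tree.nodes, combo)}
                )
                total += math.exp2(tree_loglik(assignment, tree))
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_rerooting_leaves_loglik_unchanged(self):
        # two rootings of the same 2-node joint must give identical likelihoods
        rng = np.random.default_rng(9)
        joint = rng.dirichlet(np.ones(N_SYMBOLS * N_SYMBOLS)).reshape(
            N_SYMBOLS, N_SYMBOLS
        )
        nodes = (("A", 1), ("B", 1))
        t_a = TreePGM(
            nodes, ("A", 1), ((("A", 1), ("B", 1)),),
            joint.sum(axis=1), {(("A", 1), ("B", 1)): joint / joint.sum(axis=1, keepdims=True)},
        )
        t_b = TreePGM(
            nodes, ("B", 1), ((("B", 1), ("A", 1)),),
            joint.sum(axis=0), {(("B", 1), ("A", 1)): joint.T / joint.T.sum(axis=1, keepdims=True)},
        )
        for _ in range(200):
            sa, sb = rng.integers(0, N_SYMBOLS, size=2)
            assignment = InterfaceAssignment(
                {("A", 1): ALPHABET[sa], ("B", 1): ALPHABET[sb]}
            )
            assert tree_loglik(assignment, t_a) == pytest.approx(
                tree_loglik(assignment, t_b), abs=1e-9
            )

    def test_symbol_coverage_enforced(self):
        rng = np.random.default_rng(10)
        tree = random_tree([("A", 1), ("B", 1)], rng)
        with pytest.raises(ValueError):
            tree_loglik(InterfaceAssignment({("A", 1): "A"}), tree)

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        tree = random_tree([("A", 1), ("A", 2), ("B", 3)], rng)
        pair = InterfaceProfilePair(tree, random_tree(tree.nodes, rng), "fam")
        path = tmp_path / "profile.json"
        pair.save(path)
        loaded = InterfaceProfilePair.load(path)
        assignment = InterfaceAssignment({n: "A" for n in tree.nodes})
        assert score_interface(assignment, loaded) == pytest.approx(
            score_interface(assignment, pair), abs=1e-12
        )


class TestScoreInterface:
    def test_identical_trees_give_equal_scores(self):
        rng = np.random.default_rng(12)
        tree = random_tree([("A", 1), ("B", 2)], rng)
        pair = InterfaceProfilePair(tree, tree, "fam")
        for _ in range(20):
            syms = rng.integers(0, N_SYMBOLS, size=2)
            assignment = InterfaceAssignment(
                {n: ALPHABET[s] for n, s in zip(tree.nodes, syms)}
            )
            l_plus, l_minus = score_interface(assignment, pair)
            assert l_plus == l_minus

    def test_positive_samples_score_higher_under_positive_tree(self):
        rng = np.random.default_rng(13)
        nodes = [("A", 1), ("B", 1)]
        positive = make_chain_tree(nodes, stay=0.8, rng=rng)
        # independent negative: product of uniform marginals
        uniform = np.full(N_SYMBOLS, 1.0 / N_SYMBOLS)
        negative = TreePGM(
            tuple(nodes), nodes[0], ((nodes[0], nodes[1]),),
            uniform, {(nodes[0], nodes[1]): np.tile(uniform, (N_SYMBOLS, 1))},
        )
        pair = InterfaceProfilePair(positive, negative, "fam")
        draws = positive.sample(1000, rng)
        diffs = []
        for row in draws:
            assignment = InterfaceAssignment(
                {n: ALPHABET[s] for n, s in zip(positive.nodes, row)}
            )
            l_plus, l_minus = score_interface(assignment, pair)
            diffs.append(l_plus - l_minus)
        assert np.mean(diffs) > 0

    def test_all_gap_assignment_is_finite(self):
        rng = np.random.default_rng(14)
        matrix = rng.integers(0, 21, size=(30, 2)).astype(np.int8)
        nodes = [("A", 1), ("B", 1)]
        tree = learn_tree_from_matrix(matrix, nodes, pseudocount=0.5)
        pair = InterfaceProfilePair(tree, tree, "fam")
        assignment = InterfaceAssignment({n: "-" for n in nodes})
        l_plus, l_minus = score_interface(assignment, pair)
        assert math.isfinite(l_plus) and math.isfinite(l_minus)

    def test_node_set_mismatch_rejected(self):
        rng = np.random.default_rng(15)
        with pytest.raises(ValueError):
            InterfaceProfilePair(
                random_tree([("A", 1)], rng), random_tree([("B", 1)], rng), "fam"
            )
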