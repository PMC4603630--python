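"""Inside/outside likelihoods, posteriors, and the batched evaluator,
checked against independent oracles."""

import numpy as np
import pytest

from adjevo import trees as T
from adjevo.adjacencies import Adjacency, AdjacencyClass
from adjevo.adjtree import (DUP, LEAF, SPEC, AdjNode, assign_leaf_states,
                            build_adjacency_forest)
from adjevo.likelihood import (LEAF_TABLES, BatchedPruner, KernelCache,
                               ModelParams, downward_likelihood,
                               dup1_child_table, dup2_child_table,
                               dup_likelihood_patterns, forest_loglik,
                               posterior_presence, tree_loglik,
                               upward_likelihood)
from adjevo.simulate import simulate_adjacency_evolution, \
    simulate_reconciled_family, random_species_tree

from oracles import (enumeration_tree, random_adjacency_tree,
                     textbook_pruning_loglik)

PARAMS = ModelParams(1.4, 0.55)


def leaf(state, t=0.3):
    from adjevo.trees import SpeciesNode
    return AdjNode(kind=LEAF, species=SpeciesNode(name="s"), t=t, state=state)


def _count_internal(root):
    stack, n = [root], 0
    while stack:
        node = stack.pop()
        if node.kind in (SPEC, DUP):
            n += 1
        stack.extend(node.children)
    return n


def _random_trees(rng, n, max_internal=8):
    out = []
    while len(out) < n:
        root = random_adjacency_tree(rng, max_internal=max_internal)
        if _count_internal(root) <= 10:
            out.append(root)
    return out


class TestChildTables:
    def test_tables_are_stochastic(self):
        for kappa, t in [(0.5, 0.2), (1.5, 1.0), (3.0, 2.5)]:
            T1 = dup1_child_table(kappa, t)
            T2 = dup2_child_table(kappa, t)
            assert np.allclose(T1.reshape(2, -1).sum(axis=1), 1.0)
            assert np.allclose(T2.reshape(2, -1).sum(axis=1), 1.0)
            assert T1.min() >= 0 and T2.min() >= 0

    def test_dup1_table_symmetric_in_children(self):
        T1 = dup1_child_table(1.5, 0.7)
        assert np.abs(T1 - np.swapaxes(T1, 1, 2)).max() < 1e-15

    def test_dup2_table_symmetric_under_copy_relabelling(self):
        # children ordered ((0,0),(0,1),(1,0),(1,1)): relabelling the two
        # copies of either gene permutes children without changing the law
        T2 = dup2_child_table(1.5, 0.7)
        gene1_swap = np.transpose(T2, (0, 3, 4, 1, 2))
        gene2_swap = np.transpose(T2, (0, 2, 1, 4, 3))
        assert np.abs(T2 - gene1_swap).max() < 1e-14
        assert np.abs(T2 - gene2_swap).max() < 1e-14

    def test_pattern_factorisation_equals_enumeration(self, rng):
        """The pattern/weight formulation over the exchangeable
        second-duplication slots reproduces the plain state enumeration."""
        from adjevo import kernels as K
        for _ in range(10):
            kappa = 10 ** rng.uniform(-0.5, 0.5)
            t = rng.uniform(0.05, 2.0)
            P = K.transition_matrix(kappa, t)
            R = K.dup11_row(kappa, t)
            Ls = [rng.uniform(0.1, 1.0, size=2) for _ in range(4)]
            plain = np.einsum("xa,buv,a,b,u,v->x", P, R, *Ls)
            via_patterns = dup_likelihood_patterns(Ls, P, R)
            assert np.abs(plain - via_patterns).max() < 1e-12


class TestUpward:
    def test_all_undetermined_likelihood_one(self):
        from adjevo.trees import SpeciesNode
        root = AdjNode(kind=SPEC, species=SpeciesNode(name="r"), t=None)
        for _ in range(2):
            c = leaf(None)
            c.parent = root
            root.children.append(c)
        assert tree_loglik(root, PARAMS) == pytest.approx(0.0, abs=1e-14)

    def test_duplication_free_matches_textbook_pruning(self, rng):
        for _ in range(30):
            root = random_adjacency_tree(rng, max_internal=6, p_dup=0.0)
            ours = tree_loglik(root, PARAMS)
            ref = textbook_pruning_loglik(root, PARAMS.kappa, PARAMS.prior)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_matches_enumeration(self, rng):
        cache = KernelCache(PARAMS.kappa)
        for root in _random_trees(rng, 40):
            total, _ = enumeration_tree(root, PARAMS, cache)
            assert tree_loglik(root, PARAMS, cache) == \
                pytest.approx(np.log(total), rel=1e-10)

    def test_scaling_does_not_change_result(self, rng):
        cache = KernelCache(PARAMS.kappa)
        for root in _random_trees(rng, 10):
            up1, ls1 = upward_likelihood(root, PARAMS, cache, scale=True)
            up2, ls2 = upward_likelihood(root, PARAMS, cache, scale=False)
            l1 = np.log(PARAMS.prior @ up1[id(root)]) + ls1
            l2 = np.log(PARAMS.prior @ up2[id(root)]) + ls2
            assert l1 == pytest.approx(l2, rel=1e-12)

    def test_forest_additivity_and_permutation(self, rng):
        roots = _random_trees(rng, 6)

        class F:
            def __init__(self, roots):
                self.roots = roots

        ll = forest_loglik([F(roots)], PARAMS)
        ll_twice = forest_loglik([F(roots), F(roots)], PARAMS)
        assert ll_twice == pytest.approx(2 * ll, rel=1e-12)
        perm = [roots[i] for i in rng.permutation(len(roots))]
        assert forest_loglik([F(perm)], PARAMS) == pytest.approx(ll, rel=1e-12)

    def test_empty_forest_rejected(self):
        with pytest.raises(ValueError):
            forest_loglik([], PARAMS)


class TestPosteriors:
    def test_match_enumeration(self, rng):
        cache = KernelCache(PARAMS.kappa)
        for root in _random_trees(rng, 40):
            _, expected = enumeration_tree(root, PARAMS, cache)
            post = posterior_presence(root, PARAMS, cache)
            for nid, want in expected.items():
                assert post[nid] == pytest.approx(want, abs=1e-10)

    def test_observed_leaf_posterior_is_indicator(self, rng):
        for root in _random_trees(rng, 10):
            post = posterior_presence(root, PARAMS)
            for node in _iter(root):
                if node.kind == LEAF and node.state is not None:
                    assert post[id(node)] == pytest.approx(node.state,
                                                           abs=1e-12)

    def test_inside_outside_consistency(self, rng):
        """sum_state inside*outside is the same (the total likelihood) at
        every node when no rescaling is applied."""
        cache = KernelCache(PARAMS.kappa)
        for root in _random_trees(rng, 15):
            up, _ = upward_likelihood(root, PARAMS, cache, scale=False)
            out = downward_likelihood(root, PARAMS, up, cache)
            total = float(PARAMS.prior @ up[id(root)])
            for node in _iter(root):
                val = float(out[id(node)] @ up[id(node)])
                assert val == pytest.approx(total, rel=1e-9)

    def test_mirror_symmetry(self):
        from adjevo.trees import SpeciesNode
        root = AdjNode(kind=SPEC, species=SpeciesNode(name="r"), t=None)
        for _ in range(2):
            mid = AdjNode(kind=SPEC, species=SpeciesNode(name="m"), t=0.4,
                          parent=root)
            for st in (1, 0):
                c = leaf(st, 0.2)
                c.parent = mid
                mid.children.append(c)
            root.children.append(mid)
        post = posterior_presence(root, PARAMS)
        a, b = root.children
        assert post[id(a)] == pytest.approx(post[id(b)], rel=1e-12)

    def test_all_present_short_branches_high_root_posterior(self):
        from adjevo.trees import SpeciesNode
        root = AdjNode(kind=SPEC, species=SpeciesNode(name="r"), t=None)
        mid = AdjNode(kind=SPEC, species=SpeciesNode(name="m"), t=0.01,
                      parent=root)
        for _ in range(2):
            c = leaf(1, 0.01)
            c.parent = mid
            mid.children.append(c)
        root.children.append(mid)
        c = leaf(1, 0.01)
        c.parent = root
        root.children.append(c)
        cache = KernelCache(PARAMS.kappa)
        _, expected = enumeration_tree(root, PARAMS, cache)
        post = posterior_presence(root, PARAMS, cache)
        assert post[id(root)] > 0.99
        assert post[id(root)] == pytest.approx(expected[id(root)], abs=1e-10)


class TestBatchedPruner:
    def test_equals_recursive(self, rng):
        sp = random_species_tree(6, rng)
        roots = []
        for i in range(25):
            t1, _ = simulate_reconciled_family(sp, 0.0, 0.2, rng, name=f"A{i}")
            t2, _ = simulate_reconciled_family(sp, 0.0, 0.2, rng, name=f"B{i}")
            truth = simulate_adjacency_evolution(t1, t2, 1.4, 0.55, rng)
            roots.extend(truth.forest.roots)
        lengths = np.zeros(len(list(sp.postorder())))
        for n in sp.postorder():
            if n.parent is not None:
                lengths[n.index] = n.length
        pruner = BatchedPruner(roots, len(lengths))
        batched = pruner.loglik(PARAMS, lengths)
        cache = KernelCache(PARAMS.kappa)
        recursive = sum(tree_loglik(r, PARAMS, cache, lengths)
                        for r in roots)
        assert batched == pytest.approx(recursive, rel=1e-12)

    def test_rejects_duplication_trees(self, rng):
        root = None
        while root is None:
            cand = random_adjacency_tree(rng, p_dup=0.9)
            if any(n.kind == DUP for n in _iter(cand)):
                root = cand
        with pytest.raises(ValueError):
            BatchedPruner([root], 4)


def _iter(root):
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)
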