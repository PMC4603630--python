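"""Independent oracles used by the test suite.

These deliberately avoid the package's pruning/outside algorithms: a
textbook binary-character pruning built on ``scipy.linalg.expm``, a
brute-force enumeration of all ancestral state assignments, and a random
generator of adjacency-tree shapes.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm

from adjevo.adjtree import DUP, LEAF, SPEC, AdjNode
from adjevo.likelihood import LEAF_TABLES, KernelCache, ModelParams
from adjevo.trees import SpeciesNode


def _subtree(root):
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def textbook_pruning_loglik(root: AdjNode, kappa: float,
                            prior: np.ndarray) -> float:
    """Plain Felsenstein pruning for duplication-free trees, with the
    transition matrix obtained by matrix exponentiation."""
    a = (kappa + 1.0) / 2.0
    b = (kappa + 1.0) / (2.0 * kappa)
    Q = np.array([[-a, a], [b, -b]])

    def rec(node: AdjNode) -> np.ndarray:
        if node.kind == LEAF:
            return LEAF_TABLES[node.state]
        assert node.kind == SPEC
        L = np.ones(2)
        for c in node.children:
            L = L * (expm(Q * c.t) @ rec(c))
        return L

    lik = prior @ rec(root)
    return float(np.log(lik))


def enumeration_tree(root: AdjNode, params: ModelParams,
                     cache: KernelCache | None = None
                     ) -> tuple[float, dict[int, float]]:
    """Total likelihood and posteriors of presence by brute-force summation
    over all internal (speciation + duplication) state assignments."""
    cache = cache or KernelCache(params.kappa)
    internals = [n for n in _subtree(root) if n.kind in (SPEC, DUP)]
    prior = params.prior
    total = 0.0
    marg = {id(n): 0.0 for n in internals}

    from adjevo.likelihood import _dup_children_in_order

    for assign in itertools.product((0, 1), repeat=len(internals)):
        st = {id(n): s for n, s in zip(internals, assign)}
        p = prior[st[id(root)]]
        for n in internals:
            if p == 0.0:
                break
            x = st[id(n)]
            if n.kind == SPEC:
                for c in n.children:
                    if c.kind == DUP:
                        if st[id(c)] != x:
                            p = 0.0
                    elif c.kind == LEAF:
                        p *= cache.P(c.t)[x] @ LEAF_TABLES[c.state]
                    else:
                        p *= cache.P(c.t)[x, st[id(c)]]
            else:  # DUP: joint factor over its children
                slots = _dup_children_in_order(n)
                vecs = []
                for ch in slots:
                    if ch is None:
                        vecs.append(np.ones(2))
                    elif ch.kind == LEAF:
                        vecs.append(LEAF_TABLES[ch.state])
                    else:
                        v = np.zeros(2)
                        v[st[id(ch)]] = 1.0
                        vecs.append(v)
                T = cache.dup1(n.t) if n.n_dup == 1 else cache.dup2(n.t)
                sub = T[x]
                for v in reversed(vecs):
                    sub = sub @ v
                p *= float(sub)
        total += p
        for n in internals:
            if st[id(n)] == 1:
                marg[id(n)] += p
    post = {k: v / total for k, v in marg.items()}
    return float(total), post


def random_adjacency_tree(rng: np.random.Generator,
                          max_internal: int = 10,
                          p_dup: float = 0.35,
                          p_missing_quartet_child: float = 0.2) -> AdjNode:
    """Random adjacency-tree shape mixing speciation nodes, 2- and 4-child
    duplication nodes, observed leaves and undetermined leaves."""
    counter = itertools.count()
    budget = [int(rng.integers(2, max_internal + 1))]

    def species() -> SpeciesNode:
        return SpeciesNode(name=f"s{next(counter)}")

    def t() -> float:
        return float(rng.uniform(0.05, 2.0))

    def leaf(dur: float) -> AdjNode:
        state = [0, 1, None][int(rng.integers(3))]
        return AdjNode(kind=LEAF, species=species(), t=dur, state=state)

    def grow(dur: float | None) -> AdjNode:
        if budget[0] <= 0:
            return leaf(dur if dur is not None else t())
        budget[0] -= 1
        if rng.random() < p_dup:
            n_dup = 1 if rng.random() < 0.5 else 2
            dt = t()
            node = AdjNode(kind=DUP, species=species(), t=dt, n_dup=n_dup)
            pairs = [(0, 0), (0, 1)] if n_dup == 1 else \
                [(0, 0), (0, 1), (1, 0), (1, 1)]
            if n_dup == 2 and rng.random() < p_missing_quartet_child:
                pairs = pairs[:3]  # a copy pair without representative
            for ci in pairs:
                child = grow(dt) if rng.random() < 0.5 else leaf(dt)
                child.copy_index = ci
                child.parent = node
                node.children.append(child)
            # a duplication must hang under a speciation node
            top = AdjNode(kind=SPEC, species=species(), t=dur)
            node.parent = top
            sib = leaf(t())
            sib.parent = top
            top.children.extend([node, sib])
            return top
        node = AdjNode(kind=SPEC, species=species(), t=dur)
        for _ in range(2):
            child = grow(t()) if rng.random() < 0.6 else leaf(t())
            child.parent = node
            node.children.append(child)
        return node

    root = grow(None)
    if root.kind == LEAF:  # ensure at least one internal node
        top = AdjNode(kind=SPEC, species=species(), t=None)
        root.parent = top
        sib = leaf(t())
        sib.parent = top
        top.children.extend([root, sib])
        root = top
    return root
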