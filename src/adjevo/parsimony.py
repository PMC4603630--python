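"""Parsimony baseline for ancestral adjacencies and model comparison.

A DeCo-style minimum-change assignment of presence/absence on the same
trees of possible adjacencies: Sankoff dynamic programming with unit cost
for every gain or breakage on every edge (including the bookkeeping edge
into a duplication node, which lets a single change before the duplication
cover all descendant copy-pairs, as a parsimony method would count it).
Undetermined ("?") leaves cost nothing in either state.  Ties are broken
toward absence at the root, then toward the parent's state.

The comparison with the probabilistic model records, for every ancestral
adjacency present in the parsimony reconstruction, its posterior
probability of presence — the parsimony reconstruction is restricted to the
nodes a last-common-ancestor method covers, while the model also scores
possible adjacencies above that point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adjtree import LEAF, SPEC, AdjacencyForest, AdjNode

__all__ = [
    "ParsimonyAssignment",
    "parsimony_ancestral_states",
    "compare_parsimony_posterior",
]

_INF = float("inf")


@dataclass
class ParsimonyAssignment:
    """Minimum-change states (``id(node) -> 0/1``) and the total number of
    gains plus breakages."""

    states: dict[int, int]
    cost: float


def _leaf_cost(node: AdjNode) -> list[float]:
    if node.state is None:
        return [0.0, 0.0]
    return [0.0 if node.state == 0 else _INF,
            0.0 if node.state == 1 else _INF]


def parsimony_ancestral_states(root: AdjNode) -> ParsimonyAssignment:
    """Sankoff minimum-change assignment on one tree of possible adjacencies."""
    cost: dict[int, list[float]] = {}
    for node in _postorder(root):
        if node.kind == LEAF:
            cost[id(node)] = _leaf_cost(node)
            continue
        c = [0.0, 0.0]
        for x in (0, 1):
            for child in node.children:
                cc = cost[id(child)]
                c[x] += min(cc[y] + (1 if x != y else 0) for y in (0, 1))
        cost[id(node)] = c

    states: dict[int, int] = {}
    rc = cost[id(root)]
    states[id(root)] = 0 if rc[0] <= rc[1] else 1
    for node in _preorder(root):
        x = states[id(node)]
        for child in node.children:
            cc = cost[id(child)]
            vals = [cc[y] + (1 if x != y else 0) for y in (0, 1)]
            best = min(vals)
            cands = [y for y in (0, 1) if vals[y] == best]
            states[id(child)] = x if x in cands else cands[0]
    return ParsimonyAssignment(states=states, cost=min(rc))


def _coverage(root: AdjNode) -> set[int] | None:
    """Nodes below (and including) the LCA of the PRESENT leaves — the part
    of the tree a last-common-ancestor parsimony method reconstructs.
    None when no leaf is present."""
    present = [n for n in _postorder(root)
               if n.kind == LEAF and n.state == 1]
    if not present:
        return None
    paths = []
    for leaf in present:
        path, n = [], leaf
        while n is not None:
            path.append(n)
            n = n.parent
        paths.append(list(reversed(path)))
    lca = None
    for nodes in zip(*paths):
        if all(n is nodes[0] for n in nodes):
            lca = nodes[0]
        else:
            break
    return {id(n) for n in _subtree(lca)}


def compare_parsimony_posterior(forests, posteriors_by_node,
                                threshold_hi: float = 0.9,
                                threshold_lo: float = 0.5,
                                n_bins: int = 20,
                                restrict_to_lca: bool = True) -> dict:
    """Support of parsimony-reconstructed ancestral adjacencies under the
    model.

    Parameters
    ----------
    forests:
        The adjacency forests.
    posteriors_by_node:
        ``id(spec node) -> posterior of presence`` over all forests.

    Returns a dict with the per-adjacency ``table`` (class, species, genes,
    parsimony state, posterior), a ``histogram`` frame over all possible
    adjacencies versus the parsimony subset, and the fractions of
    parsimony adjacencies with posterior above/below the thresholds
    (``None`` when parsimony reconstructs nothing).
    """
    rows = []
    for fi, forest in enumerate(forests):
        cid = forest.cls.id if forest.cls is not None else fi
        for root in forest.roots:
            pars = parsimony_ancestral_states(root)
            cover = _coverage(root) if restrict_to_lca else \
                {id(n) for n in _subtree(root)}
            for node in _subtree(root):
                if node.kind != SPEC:
                    continue
                in_cover = cover is not None and id(node) in cover
                g = node.genes
                rows.append({
                    "class_id": cid,
                    "species": node.species.name,
                    "gene1": g[0].name if g else "",
                    "gene2": g[1].name if g else "",
                    "parsimony_state": int(pars.states[id(node)])
                    if in_cover else 0,
                    "in_coverage": in_cover,
                    "posterior": posteriors_by_node[id(node)],
                })
    table = pd.DataFrame(
        rows, columns=["class_id", "species", "gene1", "gene2",
                       "parsimony_state", "in_coverage", "posterior"])

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    all_counts, _ = np.histogram(table["posterior"], bins=edges)
    par = table[table["parsimony_state"] == 1]
    par_counts, _ = np.histogram(par["posterior"], bins=edges)
    hist = pd.DataFrame({
        "bin_low": edges[:-1], "bin_high": edges[1:],
        "count_all": all_counts, "count_parsimony": par_counts,
    })

    n_par = len(par)
    frac_hi = float((par["posterior"] > threshold_hi).mean()) if n_par else None
    frac_lo = float((par["posterior"] < threshold_lo).mean()) if n_par else None
    return {
        "table": table,
        "histogram": hist,
        "n_parsimony": n_par,
        "frac_above": frac_hi,
        "frac_below": frac_lo,
    }


def _postorder(root: AdjNode):
    stack, out = [root], []
    while stack:
        node = stack.pop()
        out.append(node)
        stack.extend(node.children)
    return reversed(out)


def _preorder(root: AdjNode):
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(node.children))


def _subtree(root: AdjNode):
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(node.children)
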