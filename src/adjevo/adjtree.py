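"""Trees of possible adjacencies.

For one adjacency class spanned by two reconciled (loss-annotated) gene
trees, the *tree of possible adjacencies* has one node per pair of
same-species speciation/leaf nodes taken one from each gene tree under the
class roots.  A speciation pair connects to the pairs in each species child,
either directly (no duplication on the branch) or through a *duplication
node* spawning 2-4 descendant pairs (one or both genes duplicated on the
branch).  A branch on which one or both gene lineages are lost ends in a
loss leaf whose state is undetermined ("?").  Extant pairs are leaves whose
binary state records whether the adjacency is observed.

The model restriction of at most one duplication per gene lineage between
two speciations is enforced here: classes that violate it raise
:class:`UnsupportedInstanceError` and are meant to be reported and skipped.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .adjacencies import Adjacency, AdjacencyClass
from .trees import (DUPLICATION, EXTANT_LEAF, LOSS_LEAF, SPECIATION,
                    GeneNode, ReconciledGeneTree, SpeciesNode, SpeciesTree)

__all__ = [
    "SPEC", "DUP", "LEAF",
    "AdjNode", "AdjacencyForest", "UnsupportedInstanceError",
    "build_adjacency_forest", "assign_leaf_states",
]

SPEC = "spec"
DUP = "dup"
LEAF = "leaf"

PRESENT = 1
ABSENT = 0
UNDETERMINED = None


class UnsupportedInstanceError(ValueError):
    """Raised for classes with two duplications between consecutive
    speciations (filtered out by the model)."""


@dataclass(eq=False)
class AdjNode:
    """Node of a tree of possible adjacencies.

    ``t`` is the duration of the incoming edge in species branch-length
    units: the branch length of ``species`` for speciation and leaf nodes,
    and for a duplication node the length of the species branch its children
    span (its own incoming edge from the parent speciation pair has duration
    zero).  Roots have ``t is None``.
    """

    kind: str
    species: SpeciesNode
    t: float | None = None
    genes: tuple[GeneNode, GeneNode] | None = None
    state: int | None = None
    parent: "AdjNode | None" = None
    children: list["AdjNode"] = field(default_factory=list)
    #: for children of a duplication node: (copy index in gene 1, in gene 2)
    copy_index: tuple[int, int] | None = None
    #: for duplication nodes: how many of the two genes duplicated (1 or 2)
    n_dup: int = 0
    index: int = -1

    @property
    def is_leaf(self) -> bool:
        return self.kind == LEAF

    @property
    def label(self) -> str:
        if self.kind == DUP:
            return f"dup@{self.species.name}"
        g = f"{self.genes[0].name}--{self.genes[1].name}" if self.genes else "?"
        return f"{g}@{self.species.name}"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<AdjNode {self.kind} {self.label} state={self.state}>"


class AdjacencyForest:
    """The rooted component(s) of possible adjacencies of one class."""

    def __init__(self, roots: list[AdjNode],
                 cls: AdjacencyClass | None = None):
        if not roots:
            raise ValueError("adjacency forest has no roots")
        self.roots = roots
        self.cls = cls
        self._postorder: list[AdjNode] = []
        for root in roots:
            self._postorder.extend(_postorder(root))
        for i, node in enumerate(self._postorder):
            node.index = i

    def postorder(self) -> Iterator[AdjNode]:
        return iter(self._postorder)

    def __len__(self) -> int:
        return len(self._postorder)

    @property
    def spec_nodes(self) -> list[AdjNode]:
        return [n for n in self._postorder if n.kind == SPEC]

    @property
    def dup_nodes(self) -> list[AdjNode]:
        return [n for n in self._postorder if n.kind == DUP]

    @property
    def leaves(self) -> list[AdjNode]:
        return [n for n in self._postorder if n.kind == LEAF]

    @property
    def has_duplications(self) -> bool:
        return any(n.kind == DUP for n in self._postorder)

    def dump(self) -> str:
        """Debug/golden-file text rendering (one Newick-like line per root)."""
        out = io.StringIO()
        for root in self.roots:
            _dump(out, root)
            out.write(";\n")
        return out.getvalue()


def _dump(out, node: AdjNode) -> None:
    if node.children:
        out.write("(")
        for i, child in enumerate(node.children):
            if i:
                out.write(",")
            _dump(out, child)
        out.write(")")
    state = {PRESENT: "1", ABSENT: "0", UNDETERMINED: "?"}[node.state] \
        if node.kind == LEAF else ""
    out.write(f"{node.kind}|{node.label}"
              + (f"|{state}" if node.kind == LEAF else ""))


def _postorder(root: AdjNode):
    stack, out = [root], []
    while stack:
        node = stack.pop()
        out.append(node)
        stack.extend(node.children)
    return reversed(out)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_adjacency_forest(cls: AdjacencyClass,
                           species_tree: SpeciesTree) -> AdjacencyForest:
    """Construct the tree (or forest) of possible adjacencies of a class.

    Both gene trees must be loss-annotated (strict reconciliation
    invariants).  If the class roots lie in different species, the result is
    a forest whose roots are the maximal same-species pairs.
    """
    pairs = _same_species_pairs(cls.root1, cls.root2)
    root_pairs = [(j1, j2) for (j1, j2) in pairs
                  if not _has_generating_parent(j1, j2, cls.root1, cls.root2)]
    roots = [_build_pair(j1, j2, None, species_tree)
             for (j1, j2) in sorted(
                 root_pairs, key=lambda p: (p[0].index, p[1].index))]
    forest = AdjacencyForest(roots, cls=cls)
    n_spec_like = sum(1 for n in forest.postorder()
                      if n.kind in (SPEC, LEAF) and n.genes is not None)
    if n_spec_like != len(pairs):
        raise AssertionError(
            "construction did not cover all same-species pairs")
    return forest


def _pairable(node: GeneNode) -> bool:
    return node.event in (SPECIATION, EXTANT_LEAF)


def _same_species_pairs(root1: GeneNode, root2: GeneNode):
    nodes1: dict[SpeciesNode, list[GeneNode]] = {}
    for n in _gene_subtree(root1):
        if _pairable(n):
            nodes1.setdefault(n.species, []).append(n)
    pairs = []
    for m in _gene_subtree(root2):
        if _pairable(m):
            for n in nodes1.get(m.species, ()):
                if n is not m:
                    pairs.append((n, m))
    return pairs


def _gene_subtree(root: GeneNode):
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(node.children)


def _spec_parent_within(node: GeneNode, top: GeneNode) -> GeneNode | None:
    """Nearest strict ancestor with a speciation event, not above ``top``."""
    while node is not top:
        node = node.parent
        if node is None:
            return None
        if node.event == SPECIATION:
            return node
    return None


def _has_generating_parent(j1: GeneNode, j2: GeneNode,
                           top1: GeneNode, top2: GeneNode) -> bool:
    a1 = _spec_parent_within(j1, top1)
    a2 = _spec_parent_within(j2, top2)
    return a1 is not None and a2 is not None and a1.species is a2.species


def _child_toward(node: GeneNode, side: SpeciesNode) -> GeneNode:
    for child in node.children:
        if child.species is side:
            return child
    raise AssertionError(
        f"node {node.name!r} has no child in species {side.name!r}; "
        f"is the tree loss-annotated?"
    )


def _build_pair(j1: GeneNode, j2: GeneNode, t: float | None,
                species_tree: SpeciesTree) -> AdjNode:
    s = j1.species
    if j1.event == EXTANT_LEAF:
        return AdjNode(kind=LEAF, species=s, t=t, genes=(j1, j2))
    node = AdjNode(kind=SPEC, species=s, t=t, genes=(j1, j2))
    for side in s.children:
        c1 = _child_toward(j1, side)
        c2 = _child_toward(j2, side)
        child = _build_branch(c1, c2, side, species_tree)
        child.parent = node
        node.children.append(child)
    return node


def _build_branch(c1: GeneNode, c2: GeneNode, side: SpeciesNode,
                  species_tree: SpeciesTree) -> AdjNode:
    t = side.length if side.length is not None else 0.0
    if c1.event == LOSS_LEAF or c2.event == LOSS_LEAF:
        return AdjNode(kind=LEAF, species=side, t=t, state=UNDETERMINED)
    dup1 = c1.event == DUPLICATION
    dup2 = c2.event == DUPLICATION
    if not dup1 and not dup2:
        return _build_pair(c1, c2, t, species_tree)
    copies1 = _dup_copies(c1) if dup1 else [c1]
    copies2 = _dup_copies(c2) if dup2 else [c2]
    dup = AdjNode(kind=DUP, species=side, t=t, n_dup=int(dup1) + int(dup2))
    for i, x in enumerate(copies1):
        for j, y in enumerate(copies2):
            if x.event == LOSS_LEAF or y.event == LOSS_LEAF:
                child = AdjNode(kind=LEAF, species=side, t=t,
                                state=UNDETERMINED)
            else:
                child = _build_pair(x, y, t, species_tree)
            child.copy_index = (i, j)
            child.parent = dup
            dup.children.append(child)
    return dup


def _dup_copies(dup_node: GeneNode) -> list[GeneNode]:
    copies = list(dup_node.children)
    for c in copies:
        if c.event == DUPLICATION and c.species is dup_node.species:
            raise UnsupportedInstanceError(
                f"two duplications on the species branch to "
                f"{dup_node.species.name!r} (gene node {dup_node.name!r})"
            )
    return copies


# ---------------------------------------------------------------------------
# leaf states
# ---------------------------------------------------------------------------

def assign_leaf_states(forest: AdjacencyForest,
                       adjacencies: Iterable[Adjacency]) -> AdjacencyForest:
    """Set extant leaf states from the observed adjacency set (in place).

    An extant pair is PRESENT (1) iff its gene pair is an observed adjacency
    and ABSENT (0) otherwise; loss leaves stay UNDETERMINED.
    """
    observed = set(adjacencies)
    for node in forest.postorder():
        if node.kind == LEAF and node.genes is not None:
            g1, g2 = node.genes
            adj = Adjacency.make(node.species.name, g1.name, g2.name)
            node.state = PRESENT if adj in observed else ABSENT
    return forest
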