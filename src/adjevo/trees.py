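"""Species trees and reconciled gene trees.

A reconciled gene tree is a rooted gene phylogeny in which every node carries
the species it belongs to and the evolutionary event at its bifurcation:
speciation, duplication, an extant leaf, or a loss leaf marking a lineage
that died out.  Reconciled trees are the bridge between sequence-level gene
families and the species-level adjacency model: they determine which
ancestral genes existed in which ancestral species.

File formats: species trees are plain Newick; reconciled gene trees use the
NHX dialect with ``[&&NHX:S=<species>:D=<Y|N>]`` node comments, loss leaves
being leaves named ``*LOSS*`` whose ``S`` tag is the species in which the
lineage was lost.  Reading goes through dendropy; writing uses exact float
round-tripping so that write-then-parse is the identity.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Callable, Iterator, Mapping

import dendropy

__all__ = [
    "EXTANT_LEAF",
    "SPECIATION",
    "DUPLICATION",
    "LOSS_LEAF",
    "LOSS_NAME",
    "TreeStructureError",
    "ReconciliationError",
    "SpeciesNode",
    "SpeciesTree",
    "GeneNode",
    "ReconciledGeneTree",
    "parse_species_tree",
    "parse_reconciled_gene_tree",
    "parse_gene_tree",
    "lca_reconcile",
    "insert_loss_leaves",
    "check_single_dup_constraint",
]

EXTANT_LEAF = "extant"
SPECIATION = "speciation"
DUPLICATION = "duplication"
LOSS_LEAF = "loss"

#: reserved leaf name marking a loss leaf in NHX files
LOSS_NAME = "*LOSS*"

_FORBIDDEN = set("()[]{},;:= \t\n'\"")


class TreeStructureError(ValueError):
    """Raised when a tree violates a structural invariant."""


class ReconciliationError(ValueError):
    """Raised when species/event annotations are inconsistent."""


def _check_name(name: str) -> str:
    if name != LOSS_NAME and (not name or set(name) & _FORBIDDEN):
        raise TreeStructureError(f"illegal node name {name!r}")
    return name


def _fmt_len(x: float) -> str:
    return repr(float(x))


# ---------------------------------------------------------------------------
# species trees
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class SpeciesNode:
    name: str | None = None
    length: float | None = None
    parent: "SpeciesNode | None" = None
    children: list["SpeciesNode"] = field(default_factory=list)
    depth: int = 0
    index: int = -1  # postorder index

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<SpeciesNode {self.name}>"


class SpeciesTree:
    """Rooted binary species phylogeny with branch lengths.

    Branch lengths are expected numbers of adjacency gain/loss events per
    adjacency per branch (the unit induced by the normalised generator of
    :mod:`adjevo.kernels`).  Unnamed internal nodes are auto-named
    ``ANC1..ANCk`` in postorder so that runs are reproducible.
    """

    def __init__(self, root: SpeciesNode):
        self.root = root
        self._postorder: list[SpeciesNode] = []
        self._by_name: dict[str, SpeciesNode] = {}
        self._finalize()

    # -- construction ------------------------------------------------------

    def _finalize(self) -> None:
        self._postorder = list(_postorder(self.root))
        n_anc = 0
        for node in self._postorder:
            if not node.is_leaf:
                if len(node.children) != 2:
                    raise TreeStructureError(
                        f"species node {node.name!r} has "
                        f"{len(node.children)} children; the tree must be binary"
                    )
                if node.name is None:
                    n_anc += 1
                    node.name = f"ANC{n_anc}"
            elif node.name is None:
                raise TreeStructureError("species leaves must be named")
            _check_name(node.name)
            if node.name in self._by_name:
                raise TreeStructureError(f"duplicate species name {node.name!r}")
            self._by_name[node.name] = node
            if node.length is not None and node.length < 0:
                raise TreeStructureError(
                    f"negative branch length on species {node.name!r}"
                )
        for i, node in enumerate(self._postorder):
            node.index = i
        self.root.depth = 0
        for node in _preorder(self.root):
            for child in node.children:
                child.depth = node.depth + 1

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        root = _dendropy_to_nodes(text, SpeciesNode)
        return cls(root)

    def to_newick(self) -> str:
        out = io.StringIO()
        _write_newick(out, self.root, _species_label)
        out.write(";")
        return out.getvalue()

    # -- queries -----------------------------------------------------------

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> SpeciesNode:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown species {name!r}") from None

    def postorder(self) -> Iterator[SpeciesNode]:
        return iter(self._postorder)

    @property
    def leaves(self) -> list[SpeciesNode]:
        return [n for n in self._postorder if n.is_leaf]

    @property
    def internal_nodes(self) -> list[SpeciesNode]:
        return [n for n in self._postorder if not n.is_leaf]

    def branches(self) -> list[SpeciesNode]:
        """Non-root nodes; each identifies the branch to its parent."""
        return [n for n in self._postorder if n.parent is not None]

    def lca(self, a: SpeciesNode, b: SpeciesNode) -> SpeciesNode:
        while a is not b:
            if a.depth >= b.depth:
                a = a.parent
            else:
                b = b.parent
        return a

    def is_ancestor_or_self(self, anc: SpeciesNode, desc: SpeciesNode) -> bool:
        while desc.depth > anc.depth:
            desc = desc.parent
        return desc is anc

    def path_down(self, anc: SpeciesNode, desc: SpeciesNode) -> list[SpeciesNode]:
        """Species on the path ``anc -> desc``, both ends included."""
        path = [desc]
        node = desc
        while node is not anc:
            node = node.parent
            if node is None:
                raise TreeStructureError(
                    f"{anc.name!r} is not an ancestor of {desc.name!r}"
                )
            path.append(node)
        path.reverse()
        return path


def _species_label(node: SpeciesNode) -> str:
    lab = node.name or ""
    if node.length is not None:
        lab += ":" + _fmt_len(node.length)
    return lab


def parse_species_tree(text: str) -> SpeciesTree:
    """Parse a rooted binary Newick species tree."""
    return SpeciesTree.from_newick(text)


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class GeneNode:
    name: str | None = None
    length: float | None = None
    species: SpeciesNode | None = None
    event: str | None = None
    parent: "GeneNode | None" = None
    children: list["GeneNode"] = field(default_factory=list)
    index: int = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        sp = self.species.name if self.species else None
        return f"<GeneNode {self.name} {self.event} S={sp}>"


class ReconciledGeneTree:
    """Gene tree in which every node carries a species and an event label."""

    def __init__(self, root: GeneNode, species_tree: SpeciesTree,
                 name: str | None = None, strict: bool = False):
        self.root = root
        self.species_tree = species_tree
        self.name = name
        self._postorder: list[GeneNode] = []
        self._finalize(strict=strict)

    def _finalize(self, strict: bool) -> None:
        self._postorder = list(_postorder(self.root))
        taken = {n.name for n in self._postorder if n.name is not None}
        n_auto = 0
        seen: set[str] = set()
        for node in self._postorder:
            if node.name is None:
                n_auto += 1
                while f"g{n_auto}" in taken:
                    n_auto += 1
                node.name = f"g{n_auto}"
                taken.add(node.name)
            _check_name(node.name)
            if node.name != LOSS_NAME:
                if node.name in seen:
                    raise TreeStructureError(f"duplicate gene name {node.name!r}")
                seen.add(node.name)
            # events left open by an NHX file without D= tags: a node is a
            # duplication iff it maps to the same species as one of its children
            if node.event is None and not node.is_leaf and node.species is not None:
                node.event = (DUPLICATION
                              if any(c.species is node.species
                                     for c in node.children)
                              else SPECIATION)
        for i, node in enumerate(self._postorder):
            node.index = i
        self.validate(strict=strict)

    # -- validation --------------------------------------------------------

    def validate(self, strict: bool = False) -> None:
        """Check reconciliation invariants.

        In non-strict mode, edges may still skip intermediate species (the
        state before :func:`insert_loss_leaves`); strict mode additionally
        requires every speciation node's children to map to the two species
        children and every duplication's children to its own species.
        """
        sp = self.species_tree
        for node in self._postorder:
            if node.species is None or node.event is None:
                raise ReconciliationError(
                    f"gene node {node.name!r} lacks species or event annotation"
                )
            if node.is_leaf:
                if node.event == EXTANT_LEAF and not node.species.is_leaf:
                    raise ReconciliationError(
                        f"extant gene {node.name!r} mapped to ancestral "
                        f"species {node.species.name!r}"
                    )
                if node.event not in (EXTANT_LEAF, LOSS_LEAF):
                    raise ReconciliationError(
                        f"leaf {node.name!r} has internal event {node.event!r}"
                    )
            else:
                if len(node.children) != 2:
                    raise TreeStructureError(
                        f"gene node {node.name!r} is not binary"
                    )
                if node.event not in (SPECIATION, DUPLICATION):
                    raise ReconciliationError(
                        f"internal node {node.name!r} has event {node.event!r}"
                    )
                for child in node.children:
                    if not sp.is_ancestor_or_self(node.species, child.species):
                        raise ReconciliationError(
                            f"species {child.species.name!r} of {child.name!r} "
                            f"is not within {node.species.name!r} of its parent"
                        )
                if node.event == SPECIATION:
                    if node.species.is_leaf:
                        raise ReconciliationError(
                            f"speciation {node.name!r} mapped to extant species"
                        )
                    if strict:
                        got = {c.species for c in node.children}
                        want = set(node.species.children)
                        if got != want:
                            raise ReconciliationError(
                                f"speciation {node.name!r} at "
                                f"{node.species.name!r} has children in "
                                f"{sorted(s.name for s in got)}"
                            )
                elif strict:  # duplication
                    for child in node.children:
                        if child.species is not node.species:
                            raise ReconciliationError(
                                f"duplication {node.name!r} child "
                                f"{child.name!r} not in species "
                                f"{node.species.name!r}"
                            )

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_nhx(cls, text: str, species_tree: SpeciesTree,
                 name: str | None = None) -> "ReconciledGeneTree":
        root = _dendropy_to_nodes(text, GeneNode, species_tree=species_tree)
        return cls(root, species_tree, name=name)

    def to_nhx(self) -> str:
        def label(node: GeneNode) -> str:
            lab = LOSS_NAME if node.event == LOSS_LEAF else (node.name or "")
            if node.length is not None:
                lab += ":" + _fmt_len(node.length)
            dflag = "Y" if node.event == DUPLICATION else "N"
            lab += f"[&&NHX:S={node.species.name}:D={dflag}]"
            return lab

        out = io.StringIO()
        _write_newick(out, self.root, label)
        out.write(";")
        return out.getvalue()

    # -- queries -----------------------------------------------------------

    def postorder(self) -> Iterator[GeneNode]:
        return iter(self._postorder)

    def __len__(self) -> int:
        return len(self._postorder)

    @property
    def extant_leaves(self) -> list[GeneNode]:
        return [n for n in self._postorder if n.event == EXTANT_LEAF]

    def copy(self) -> "ReconciledGeneTree":
        def rec(node: GeneNode) -> GeneNode:
            new = GeneNode(name=node.name, length=node.length,
                           species=node.species, event=node.event)
            for child in node.children:
                c = rec(child)
                c.parent = new
                new.children.append(c)
            return new

        return ReconciledGeneTree(rec(self.root), self.species_tree,
                                  name=self.name)


def parse_reconciled_gene_tree(text: str, species_tree: SpeciesTree,
                               name: str | None = None) -> ReconciledGeneTree:
    """Parse an NHX reconciled gene tree against a species tree."""
    return ReconciledGeneTree.from_nhx(text, species_tree, name=name)


def parse_gene_tree(text: str) -> GeneNode:
    """Parse a gene-tree topology without requiring reconciliation tags."""
    return _dendropy_to_nodes(text, GeneNode, species_tree=None)


# ---------------------------------------------------------------------------
# reconciliation operations
# ---------------------------------------------------------------------------

def lca_reconcile(root: GeneNode | str, species_tree: SpeciesTree,
                  leaf_species: Mapping[str, str] | Callable[[str], str]
                  | None = None,
                  name: str | None = None) -> ReconciledGeneTree:
    """Standard LCA (most parsimonious) reconciliation of a rooted gene tree.

    Every leaf must resolve to an extant species: either it already carries a
    species annotation, or ``leaf_species`` maps/derives the species from the
    leaf name (default: the part after the last ``__`` of the name).  Each
    internal node is mapped to the LCA of its children's species and labelled
    a duplication iff it maps to the same species as one of its children;
    this minimises duplications for the given rooted topology.  The result is
    loss-annotated via :func:`insert_loss_leaves`.
    """
    if isinstance(root, str):
        root = parse_gene_tree(root)

    def species_of(leaf: GeneNode) -> SpeciesNode:
        if leaf.species is not None:
            return leaf.species
        if callable(leaf_species):
            sname = leaf_species(leaf.name)
        elif leaf_species is not None:
            sname = leaf_species.get(leaf.name)
        else:
            _, _, sname = (leaf.name or "").rpartition("__")
        if not sname or sname not in species_tree:
            raise ReconciliationError(
                f"cannot resolve species of gene leaf {leaf.name!r}"
            )
        return species_tree[sname]

    for node in _postorder(root):
        if node.is_leaf:
            node.species = species_of(node)
            if not node.species.is_leaf:
                raise ReconciliationError(
                    f"leaf {node.name!r} mapped to ancestral species "
                    f"{node.species.name!r}"
                )
            node.event = EXTANT_LEAF
        else:
            if len(node.children) != 2:
                raise TreeStructureError(f"gene node {node.name!r} not binary")
            a, b = node.children
            node.species = species_tree.lca(a.species, b.species)
            node.event = (DUPLICATION
                          if node.species in (a.species, b.species)
                          else SPECIATION)
    tree = ReconciledGeneTree(root, species_tree, name=name)
    return insert_loss_leaves(tree)


def insert_loss_leaves(tree: ReconciledGeneTree) -> ReconciledGeneTree:
    """Complete a reconciled tree with explicit loss leaves.

    For every edge whose species assignment skips intermediate species, a
    speciation node is inserted at each skipped species with a loss leaf in
    the sibling lineage.  A lineage lost in an entire clade keeps a single
    loss leaf at the clade stem.  The operation is idempotent and returns a
    new tree.
    """
    tree = tree.copy()
    sp = tree.species_tree

    def complete(parent: GeneNode, child: GeneNode, start: SpeciesNode) -> None:
        """Rebuild the edge parent->child through the species chain
        start..S(child), inserting speciations with loss leaves."""
        path = sp.path_down(start, child.species)
        if len(path) == 1:
            return
        chain: list[GeneNode] = []
        for m, nxt in zip(path[:-1], path[1:]):
            sibling = m.children[1] if m.children[0] is nxt else m.children[0]
            spec = GeneNode(species=m, event=SPECIATION)
            loss = GeneNode(name=LOSS_NAME, species=sibling, event=LOSS_LEAF,
                            parent=spec)
            spec.children.append(loss)
            chain.append(spec)
        _replace_child(parent, child, chain[0])
        for a, b in zip(chain, chain[1:]):
            b.parent = a
            a.children.insert(0, b)  # continuing lineage first, loss second
        child.parent = chain[-1]
        chain[-1].children.insert(0, child)

    for node in list(_postorder(tree.root)):
        if node.is_leaf:
            continue
        for child in list(node.children):
            if node.event == DUPLICATION:
                start = node.species
            else:  # speciation: the edge heads into one species child
                if child.species is node.species:
                    raise ReconciliationError(
                        f"speciation {node.name!r} has child in its own "
                        f"species; expected a duplication"
                    )
                side = child.species
                while side.parent is not node.species:
                    side = side.parent
                start = side
            complete(node, child, start)

    return ReconciledGeneTree(tree.root, sp, name=tree.name, strict=True)


def _replace_child(parent: GeneNode, old: GeneNode, new: GeneNode) -> None:
    parent.children[parent.children.index(old)] = new
    new.parent = parent


def check_single_dup_constraint(
        tree: ReconciledGeneTree) -> tuple[bool, list[GeneNode]]:
    """Check that at most one duplication separates consecutive speciations.

    Two duplications on the same species branch appear as a duplication node
    whose parent is a duplication in the same species (no speciation can lie
    between two same-species nodes).  Returns ``(ok, offending_nodes)``.
    """
    offenders = [
        node for node in tree.postorder()
        if node.event == DUPLICATION and node.parent is not None
        and node.parent.event == DUPLICATION
        and node.parent.species is node.species
    ]
    return not offenders, offenders


# ---------------------------------------------------------------------------
# shared tree plumbing
# ---------------------------------------------------------------------------

def _postorder(root):
    stack, out = [root], []
    while stack:
        node = stack.pop()
        out.append(node)
        stack.extend(node.children)
    return reversed(out)


def _preorder(root):
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(node.children))


def _write_newick(out, node, label) -> None:
    if node.children:
        out.write("(")
        for i, child in enumerate(node.children):
            if i:
                out.write(",")
            _write_newick(out, child, label)
        out.write(")")
    out.write(label(node))


def _dendropy_to_nodes(text: str, node_cls, species_tree: SpeciesTree | None = None):
    """Parse Newick/NHX text into our node classes via dendropy."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True, suppress_leaf_node_taxa=True,
            extract_comment_metadata=True,
        )
    except Exception as exc:  # dendropy's reader errors are not a single type
        raise TreeStructureError(f"malformed tree: {exc}") from None

    def convert(dnode) -> object:
        raw = dnode.taxon.label if dnode.taxon is not None else dnode.label
        name = raw if raw else None
        node = node_cls(name=name, length=dnode.edge.length)
        if node_cls is GeneNode:
            _annotate_gene_node(node, dnode, species_tree)
        for dchild in dnode.child_nodes():
            child = convert(dchild)
            child.parent = node
            node.children.append(child)
        return node

    root = convert(dtree.seed_node)
    if not root.children and root.name is None:
        raise TreeStructureError("empty tree")
    return root


def _annotate_gene_node(node: GeneNode, dnode,
                        species_tree: SpeciesTree | None) -> None:
    tags = {a.name: a.value for a in dnode.annotations}
    is_leaf = not dnode.child_nodes()
    if species_tree is None:
        return
    sname = tags.get("S")
    if sname is None:
        raise ReconciliationError(
            f"node {node.name!r} lacks an S= species tag"
        )
    if sname not in species_tree:
        raise ReconciliationError(
            f"node {node.name!r} is tagged with unknown species {sname!r}"
        )
    node.species = species_tree[sname]
    if is_leaf:
        node.event = LOSS_LEAF if node.name == LOSS_NAME else EXTANT_LEAF
        if node.name == LOSS_NAME:
            node.name = LOSS_NAME
    else:
        dflag = tags.get("D")
        if dflag is None:
            node.event = None  # resolved after children are attached
        else:
            node.event = DUPLICATION if dflag.upper() in ("Y", "T", "1") \
                else SPECIATION
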