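"""Extant adjacencies and their homology classes.

An adjacency is an unordered pair of consecutive genes on one scaffold of one
extant species.  Two extant adjacencies are *homologous* when their
extremities can be paired so that each pair of extremities has a common
ancestor in the reconciled gene trees, with the two ancestors lying in the
same (ancestral) species — i.e. the two adjacencies may descend from a
single ancestral adjacency.  This is an equivalence relation; its classes
are the units of independent likelihood computation.  Each class is summed
up by its two *root* gene-tree nodes: the most ancient distinct common
ancestors of the side-1 and side-2 extremities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .trees import GeneNode, ReconciledGeneTree

__all__ = [
    "Adjacency",
    "AdjacencyClass",
    "load_gene_orders",
    "adjacencies_from_orders",
    "build_adjacency_classes",
    "write_classes",
]

ORDER_COLUMNS = ("species", "scaffold", "position", "gene_id")


@dataclass(frozen=True, order=True)
class Adjacency:
    """Unoriented pair of consecutive genes in an extant species."""

    species: str
    gene1: str
    gene2: str

    @classmethod
    def make(cls, species: str, a: str, b: str) -> "Adjacency":
        if a == b:
            raise ValueError(f"self-adjacency of gene {a!r} in {species!r}")
        if b < a:
            a, b = b, a
        return cls(species, a, b)

    @property
    def genes(self) -> tuple[str, str]:
        return (self.gene1, self.gene2)


def load_gene_orders(source) -> pd.DataFrame:
    """Read a gene-order table (TSV with species/scaffold/position/gene_id).

    Positions are integers, 0-based, gaps allowed; they totally order genes
    within each (species, scaffold).  Gene ids must be unique within a
    species.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", dtype={"position": "int64"})
    missing = set(ORDER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene-order table lacks columns {sorted(missing)}")
    df = df.loc[:, list(ORDER_COLUMNS)]
    dup_pos = df.duplicated(["species", "scaffold", "position"])
    if dup_pos.any():
        row = df[dup_pos].iloc[0]
        raise ValueError(
            f"duplicate position {row.position} on {row.species}/{row.scaffold}"
        )
    dup_gene = df.duplicated(["species", "gene_id"])
    if dup_gene.any():
        row = df[dup_gene].iloc[0]
        raise ValueError(f"duplicate gene id {row.gene_id!r} in {row.species}")
    return df.sort_values(["species", "scaffold", "position"],
                          kind="stable").reset_index(drop=True)


def adjacencies_from_orders(orders) -> set[Adjacency]:
    """Derive the adjacency set: one per consecutive gene pair per scaffold."""
    df = load_gene_orders(orders)
    out: set[Adjacency] = set()
    for (species, _), group in df.groupby(["species", "scaffold"], sort=False):
        genes = group["gene_id"].tolist()
        for a, b in zip(genes, genes[1:]):
            out.add(Adjacency.make(species, a, b))
    return out


@dataclass
class AdjacencyClass:
    """A homology class of extant adjacencies with its two root gene nodes."""

    id: int
    tree1: ReconciledGeneTree
    tree2: ReconciledGeneTree
    root1: GeneNode
    root2: GeneNode
    members: list[Adjacency] = field(default_factory=list)
    #: member -> (side-1 extremity node, side-2 extremity node)
    orientation: dict[Adjacency, tuple[GeneNode, GeneNode]] = field(
        default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _depths(tree: ReconciledGeneTree) -> dict[GeneNode, int]:
    d = {tree.root: 0}
    stack = [tree.root]
    while stack:
        n = stack.pop()
        for c in n.children:
            d[c] = d[n] + 1
            stack.append(c)
    return d


def _lca(a: GeneNode, b: GeneNode, depth: dict[GeneNode, int]) -> GeneNode:
    while a is not b:
        if depth[a] >= depth[b]:
            a = a.parent
        else:
            b = b.parent
    return a


def _ancestor_species(node: GeneNode) -> frozenset[str]:
    """Species of all ancestors-or-self of a gene node."""
    out = set()
    while node is not None:
        out.add(node.species.name)
        node = node.parent
    return frozenset(out)


def ancestors_share_species(a1: GeneNode, b1: GeneNode,
                            a2: GeneNode, b2: GeneNode,
                            depth1, depth2) -> bool:
    """True iff some common ancestor of (a1,b1) and some common ancestor of
    (a2,b2) lie in the same species."""
    l1 = _lca(a1, b1, depth1)
    l2 = _lca(a2, b2, depth2)
    return bool(_ancestor_species(l1) & _ancestor_species(l2))


def build_adjacency_classes(
        adjacencies: Iterable[Adjacency],
        trees: Sequence[ReconciledGeneTree]) -> list[AdjacencyClass]:
    """Partition extant adjacencies into homology classes.

    Every adjacency gene must be an extant leaf of exactly one tree.  Classes
    are maximal under the transitive closure of the pairwise homology
    condition (union-find); both extremity pairings are tried when the two
    genes belong to the same family, so tandem-array adjacencies cluster too.
    """
    leaf_of: dict[str, tuple[int, GeneNode]] = {}
    for ti, tree in enumerate(trees):
        for leaf in tree.extant_leaves:
            if leaf.name in leaf_of:
                raise ValueError(f"gene {leaf.name!r} occurs in several trees")
            leaf_of[leaf.name] = (ti, leaf)
    depths = [_depths(t) for t in trees]

    adjs = sorted(set(adjacencies))
    ends: list[tuple[tuple[int, GeneNode], tuple[int, GeneNode]]] = []
    groups: dict[tuple[int, int], list[int]] = {}
    for i, adj in enumerate(adjs):
        for g in adj.genes:
            if g not in leaf_of:
                raise ValueError(f"adjacency gene {g!r} absent from all trees")
        e1, e2 = leaf_of[adj.gene1], leaf_of[adj.gene2]
        if e2[0] < e1[0]:
            e1, e2 = e2, e1
        ends.append((e1, e2))
        groups.setdefault((e1[0], e2[0]), []).append(i)

    uf = _UnionFind(len(adjs))
    for (t1, t2), idx in groups.items():
        d1, d2 = depths[t1], depths[t2]
        for pos, i in enumerate(idx):
            (_, a1), (_, a2) = ends[i]
            for j in idx[:pos]:
                if uf.find(i) == uf.find(j):
                    continue
                (_, b1), (_, b2) = ends[j]
                if ancestors_share_species(a1, b1, a2, b2, d1, d2):
                    uf.union(i, j)
                elif t1 == t2 and ancestors_share_species(
                        a1, b2, a2, b1, d1, d2):
                    uf.union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(adjs)):
        clusters.setdefault(uf.find(i), []).append(i)

    classes: list[AdjacencyClass] = []
    for cid, idx in enumerate(sorted(clusters.values(), key=lambda g: g[0])):
        classes.append(_assemble_class(cid, idx, adjs, ends, trees, depths))
    return classes


def _assemble_class(cid, idx, adjs, ends, trees, depths) -> AdjacencyClass:
    """Fix a consistent side assignment for a class and find its roots."""
    t1, t2 = ends[idx[0]][0][0], ends[idx[0]][1][0]
    d1, d2 = depths[t1], depths[t2]
    orientation: dict[Adjacency, tuple[GeneNode, GeneNode]] = {}
    side1: list[GeneNode] = []
    side2: list[GeneNode] = []
    for i in idx:
        (ta, a), (tb, b) = ends[i]
        assert (ta, tb) == (t1, t2)
        if t1 == t2 and side1:
            # orient against the members already placed
            ok_direct = ancestors_share_species(side1[0], a, side2[0], b,
                                                d1, d2)
            if not ok_direct:
                a, b = b, a
        orientation[adjs[i]] = (a, b)
        side1.append(a)
        side2.append(b)

    u1 = side1[0]
    for n in side1[1:]:
        u1 = _lca(u1, n, d1)
    u2 = side2[0]
    for n in side2[1:]:
        u2 = _lca(u2, n, d2)

    if t1 != t2:
        root1, root2 = trees[t1].root, trees[t2].root
    else:
        top = _lca(u1, u2, d1)
        if top is u1 or top is u2:
            if u1 is u2:
                raise ValueError(
                    "degenerate adjacency class: extremity sides coincide"
                )
            root1, root2 = u1, u2
        else:
            root1 = u1
            while root1.parent is not top:
                root1 = root1.parent
            root2 = u2
            while root2.parent is not top:
                root2 = root2.parent

    members = [adjs[i] for i in idx]
    return AdjacencyClass(id=cid, tree1=trees[t1], tree2=trees[t2],
                          root1=root1, root2=root2, members=members,
                          orientation=orientation)


def write_classes(classes: Sequence[AdjacencyClass], path) -> None:
    """Write a class summary TSV: one row per member adjacency."""
    rows = []
    for cls in classes:
        for adj in cls.members:
            rows.append({
                "class_id": cls.id,
                "root1": cls.root1.name,
                "root2": cls.root2.name,
                "species_root1": cls.root1.species.name,
                "species_root2": cls.root2.species.name,
                "species": adj.species,
                "gene1": adj.gene1,
                "gene2": adj.gene2,
            })
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)
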