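"""Synthetic data generation under the exact generative model.

Simulates (i) reconciled gene families by a duplication/loss birth-death
process along a species tree, (ii) adjacency histories down the resulting
trees of possible adjacencies by stochastic (Gillespie) simulation of the
two-state gain/loss chain — with duplication dates uniform on their branch
and the adjacency transmitted to one uniformly chosen copy — and (iii) full
datasets: species tree, NHX gene trees, gene-order tables and a ground-truth
table, all of which re-parse through the package's own readers.

The simulator is deliberately independent of the closed-form kernels (it
only draws exponential waiting times from the generator rates), so it serves
as the Monte-Carlo oracle for the duplication-integrated kernels, and as
ground truth for parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .adjacencies import Adjacency, AdjacencyClass
from .adjtree import (DUP, LEAF, SPEC, AdjacencyForest, AdjNode,
                      assign_leaf_states, build_adjacency_forest)
from .likelihood import _dup_children_in_order
from .trees import (DUPLICATION, EXTANT_LEAF, LOSS_LEAF, LOSS_NAME,
                    SPECIATION, GeneNode, ReconciledGeneTree, SpeciesNode,
                    SpeciesTree)

__all__ = [
    "SimConfig",
    "SimClassTruth",
    "SimDataset",
    "random_species_tree",
    "simulate_reconciled_family",
    "simulate_adjacency_evolution",
    "generate_dataset",
    "evolve_state",
    "sample_dup1_outcomes",
    "sample_dup2_outcomes",
]


@dataclass
class SimConfig:
    """Study conditions of a synthetic dataset.

    Defaults emulate a dozen moderately diverged animal genomes: a 12-leaf
    species tree with branch lengths of 0.1-1.0 expected adjacency events per
    adjacency, per-gene duplication and loss rates of 0.05 and 0.1 events per
    unit branch length (losses about twice as common as duplications, giving
    mostly single-copy families with occasional duplications), a gain/loss
    ratio kappa = 1.5 and a stationary root prior.  ``drop_fraction`` removes
    observed extant adjacencies to emulate assembly fragmentation.
    """

    seed: int
    species_newick: str | None = None
    n_species: int = 12
    n_classes: int = 200
    dup_rate: float = 0.05
    loss_rate: float = 0.1
    kappa: float = 1.5
    root_presence_prob: float | None = None  # None -> stationary
    drop_fraction: float = 0.0
    branch_length_min: float = 0.1
    branch_length_max: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if not (0.0 <= self.drop_fraction < 1.0):
            raise ValueError("drop_fraction must be in [0, 1)")
        for r in (self.dup_rate, self.loss_rate):
            if r < 0:
                raise ValueError("rates must be non-negative")

    def resolved_root_prob(self) -> float:
        if self.root_presence_prob is None:
            return self.kappa / (self.kappa + 1.0)
        return float(self.root_presence_prob)


@dataclass
class SimClassTruth:
    """Ground truth for one simulated adjacency class."""

    class_id: int
    forest: AdjacencyForest
    tree1: ReconciledGeneTree
    tree2: ReconciledGeneTree
    #: id(AdjNode) -> true state (None for loss leaves)
    states: dict[int, int | None]
    #: extant PRESENT adjacencies surviving the observation drop
    observed: set[Adjacency]
    #: extant PRESENT adjacencies removed by the observation drop
    dropped: set[Adjacency]


@dataclass
class SimDataset:
    config: SimConfig
    species_tree: SpeciesTree
    gene_trees: list[ReconciledGeneTree]
    classes: list[SimClassTruth]
    orders: pd.DataFrame
    adjacencies: set[Adjacency]
    #: adjacencies discarded because they could not be threaded linearly
    conflicts: set[Adjacency]
    n_rejected_families: int
    paths: dict[str, Path] = field(default_factory=dict)

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for cls in self.classes:
            for node in cls.forest.postorder():
                st = cls.states[id(node)]
                rows.append({
                    "class_id": cls.class_id,
                    "node": node.label,
                    "kind": node.kind,
                    "species": node.species.name,
                    "true_state": "?" if st is None else st,
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# species trees
# ---------------------------------------------------------------------------

def random_species_tree(n_species: int, rng: np.random.Generator,
                        length_range: tuple[float, float] = (0.1, 1.0)
                        ) -> SpeciesTree:
    """Random rooted binary tree by sequential coalescence of leaf names
    SP01..SPnn, with branch lengths uniform in ``length_range``."""
    lo, hi = length_range
    nodes = [SpeciesNode(name=f"SP{i + 1:02d}",
                         length=float(rng.uniform(lo, hi)))
             for i in range(n_species)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = SpeciesNode(length=float(rng.uniform(lo, hi)),
                             children=[a, b])
        a.parent = b.parent = parent
        nodes.append(parent)
    nodes[0].length = None
    return SpeciesTree(nodes[0])


# ---------------------------------------------------------------------------
# gene family simulation
# ---------------------------------------------------------------------------

class _Reject(Exception):
    pass


def simulate_reconciled_family(species_tree: SpeciesTree, dup_rate: float,
                               loss_rate: float, rng: np.random.Generator,
                               name: str | None = None,
                               max_retries: int = 10000,
                               ) -> tuple[ReconciledGeneTree, int]:
    """Simulate a loss-annotated reconciled family originating at the root.

    Each gene lineage duplicates at rate ``dup_rate`` and dies at rate
    ``loss_rate`` per unit branch length.  Families that would put two
    duplications on one species branch of one lineage, or that go entirely
    extinct, are rejected and resampled; the number of rejections is
    returned alongside the tree.
    """
    counter = [0]

    def fresh_name(sp: SpeciesNode) -> str:
        counter[0] += 1
        return f"{name or 'F'}.{counter[0]}__{sp.name}"

    def at_species(sp: SpeciesNode) -> GeneNode:
        if sp.is_leaf:
            return GeneNode(name=fresh_name(sp), species=sp,
                            event=EXTANT_LEAF)
        node = GeneNode(species=sp, event=SPECIATION)
        for child_sp in sp.children:
            c = along_branch(child_sp, float(child_sp.length or 0.0),
                             had_dup=False)
            c.parent = node
            node.children.append(c)
        return node

    def along_branch(sp: SpeciesNode, remaining: float,
                     had_dup: bool) -> GeneNode:
        while True:
            w_dup = rng.exponential(1.0 / dup_rate) if dup_rate > 0 \
                else np.inf
            w_loss = rng.exponential(1.0 / loss_rate) if loss_rate > 0 \
                else np.inf
            w = min(w_dup, w_loss)
            if w >= remaining:
                return at_species(sp)
            remaining -= w
            if w_loss <= w_dup:
                return GeneNode(name=LOSS_NAME, species=sp, event=LOSS_LEAF)
            if had_dup:
                raise _Reject
            dup = GeneNode(species=sp, event=DUPLICATION)
            for _ in range(2):
                c = along_branch(sp, remaining, had_dup=True)
                c.parent = dup
                dup.children.append(c)
            return dup

    rejected = 0
    for _ in range(max_retries):
        counter[0] = 0
        try:
            root = at_species(species_tree.root)
        except _Reject:
            rejected += 1
            continue
        tree = ReconciledGeneTree(root, species_tree, name=name, strict=True)
        if tree.extant_leaves:
            return tree, rejected
        rejected += 1
    raise RuntimeError(f"family simulation failed after {max_retries} tries")


# ---------------------------------------------------------------------------
# adjacency history simulation
# ---------------------------------------------------------------------------

def _rates(kappa: float) -> tuple[float, float]:
    return (kappa + 1.0) / 2.0, (kappa + 1.0) / (2.0 * kappa)


def evolve_state(state: int, t: float, kappa: float,
                 rng: np.random.Generator) -> int:
    """Exact stochastic simulation of the two-state chain over duration t."""
    q01, q10 = _rates(kappa)
    remaining = t
    while True:
        rate = q01 if state == 0 else q10
        w = rng.exponential(1.0 / rate)
        if w >= remaining:
            return state
        state = 1 - state
        remaining -= w


def simulate_adjacency_evolution(tree1: ReconciledGeneTree,
                                 tree2: ReconciledGeneTree,
                                 kappa: float, root_prob: float,
                                 rng: np.random.Generator,
                                 class_id: int = 0) -> SimClassTruth:
    """Simulate one adjacency history on the forest spanned by two families.

    Root states are Bernoulli(root_prob); branches evolve by Gillespie
    simulation; at each duplication a uniform date is drawn, the current
    state passes to one uniformly chosen copy and the other copy starts
    absent.  Extant leaves receive their true state; loss leaves stay
    undetermined.
    """
    cls = AdjacencyClass(id=class_id, tree1=tree1, tree2=tree2,
                         root1=tree1.root, root2=tree2.root)
    forest = build_adjacency_forest(cls, tree1.species_tree)
    states: dict[int, int | None] = {}

    def down(node: AdjNode, state: int) -> None:
        states[id(node)] = state
        if node.kind == LEAF:
            if node.genes is None:
                states[id(node)] = None  # loss leaf: undetermined
            else:
                node.state = state
            return
        if node.kind == SPEC:
            for child in node.children:
                if child.kind == DUP:
                    down(child, state)
                elif child.kind == LEAF and child.genes is None:
                    states[id(child)] = None
                else:
                    down(child, evolve_state(state, child.t, kappa, rng))
            return
        # duplication node: node.state is the state at the top of the branch
        t = node.t
        end_states = _simulate_dup_branch(node, state, t, kappa, rng)
        for child, st in end_states:
            if child.kind == LEAF and child.genes is None:
                states[id(child)] = None
            else:
                down(child, st)

    for root in forest.roots:
        down(root, int(rng.random() < root_prob))

    observed: set[Adjacency] = set()
    for leaf in forest.leaves:
        if leaf.genes is not None and states[id(leaf)] == 1:
            g1, g2 = leaf.genes
            observed.add(Adjacency.make(leaf.species.name, g1.name, g2.name))
    return SimClassTruth(class_id=class_id, forest=forest, tree1=tree1,
                         tree2=tree2, states=states, observed=observed,
                         dropped=set())


def _simulate_dup_branch(node: AdjNode, state: int, t: float, kappa: float,
                         rng: np.random.Generator
                         ) -> list[tuple[AdjNode, int]]:
    """End states of a duplication node's children, by copy pair."""
    ordered = _dup_children_in_order(node)
    if node.n_dup == 1:
        tau = rng.uniform(0.0, t)
        mid = evolve_state(state, tau, kappa, rng)
        inh = int(rng.integers(2))
        ends = {inh: evolve_state(mid, t - tau, kappa, rng),
                1 - inh: evolve_state(0, t - tau, kappa, rng)}
        return [(ordered[i], ends[i]) for i in range(2)
                if ordered[i] is not None]

    tau1, tau2 = rng.uniform(0.0, t, size=2)
    first_gene = 0 if tau1 <= tau2 else 1
    tf, ts = min(tau1, tau2), max(tau1, tau2)
    s = evolve_state(state, tf, kappa, rng)
    i = int(rng.integers(2))          # copy of the first gene that inherits
    sA = evolve_state(s, ts - tf, kappa, rng)
    sB = evolve_state(0, ts - tf, kappa, rng)
    jA = int(rng.integers(2))         # transmissions at the second duplication
    jB = int(rng.integers(2))
    mid = {(i, jA): sA, (i, 1 - jA): 0, (1 - i, jB): sB, (1 - i, 1 - jB): 0}
    result = []
    for (cf, cs), st in mid.items():
        end = evolve_state(st, t - ts, kappa, rng)
        copy_index = (cf, cs) if first_gene == 0 else (cs, cf)
        child = ordered[_DUP2_POS[copy_index]]
        if child is not None:
            result.append((child, end))
    return result


_DUP2_POS = {(0, 0): 0, (0, 1): 1, (1, 0): 2, (1, 1): 3}


# ---------------------------------------------------------------------------
# vectorised Monte-Carlo oracles for the duplication kernels
# ---------------------------------------------------------------------------

def _evolve_segment_vec(states: np.ndarray, durations: np.ndarray,
                        kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Vectorised Gillespie: evolve each state over its duration."""
    q01, q10 = _rates(kappa)
    states = states.astype(np.int8).copy()
    remaining = durations.astype(float).copy()
    active = np.ones(states.shape, dtype=bool)
    while active.any():
        idx = np.flatnonzero(active)
        rate = np.where(states[idx] == 0, q01, q10)
        w = rng.exponential(1.0 / rate)
        flip = w < remaining[idx]
        fi = idx[flip]
        states[fi] = 1 - states[fi]
        remaining[fi] -= w[flip]
        active[idx[~flip]] = False
    return states


def sample_dup1_outcomes(kappa: float, t: float, x: int, n: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Empirical joint distribution (2,2) of the two copy-pair end states of
    a single-duplication branch, child-indexed by gene copy."""
    tau = rng.uniform(0.0, t, size=n)
    mid = _evolve_segment_vec(np.full(n, x), tau, kappa, rng)
    inh = rng.integers(2, size=n)
    end_inh = _evolve_segment_vec(mid, t - tau, kappa, rng)
    end_new = _evolve_segment_vec(np.zeros(n), t - tau, kappa, rng)
    y0 = np.where(inh == 0, end_inh, end_new)
    y1 = np.where(inh == 0, end_new, end_inh)
    counts = np.bincount(y0 * 2 + y1, minlength=4)
    return counts.reshape(2, 2) / n


def sample_dup2_outcomes(kappa: float, t: float, x: int, n: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Empirical joint distribution (2,2,2,2) of the four copy-pair end
    states of a double-duplication branch, indexed by (copy of gene 1,
    copy of gene 2)."""
    tau1 = rng.uniform(0.0, t, size=n)
    tau2 = rng.uniform(0.0, t, size=n)
    g1_first = tau1 <= tau2
    tf = np.minimum(tau1, tau2)
    ts = np.maximum(tau1, tau2)
    s = _evolve_segment_vec(np.full(n, x), tf, kappa, rng)
    i = rng.integers(2, size=n)
    sA = _evolve_segment_vec(s, ts - tf, kappa, rng)
    sB = _evolve_segment_vec(np.zeros(n), ts - tf, kappa, rng)
    jA = rng.integers(2, size=n)
    jB = rng.integers(2, size=n)
    # states at the second duplication, indexed by (first-gene copy,
    # second-gene copy)
    mid = np.zeros((n, 2, 2), dtype=np.int8)
    ar = np.arange(n)
    mid[ar, i, jA] = sA
    mid[ar, 1 - i, jB] = sB
    end = _evolve_segment_vec(mid.reshape(-1),
                              np.repeat(t - ts, 4), kappa, rng)
    end = end.reshape(n, 2, 2)
    # map (first, second) gene copies onto (gene-1 copy, gene-2 copy)
    swapped = np.swapaxes(end, 1, 2)
    y = np.where(g1_first[:, None, None], end, swapped)
    code = (y[:, 0, 0] * 8 + y[:, 0, 1] * 4 + y[:, 1, 0] * 2 + y[:, 1, 1])
    counts = np.bincount(code, minlength=16)
    return counts.reshape(2, 2, 2, 2) / n


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

def generate_dataset(config: SimConfig,
                     out_dir: str | Path | None = None) -> SimDataset:
    """Simulate a full dataset of gene-family pairs and adjacency histories.

    Each class uses a freshly simulated pair of families.  Observed PRESENT
    extant adjacencies (after the observation drop) are threaded into linear
    per-species scaffolds; the rare adjacency that cannot be placed without
    making a gene tri-adjacent is discarded and reported in ``conflicts``.
    When ``out_dir`` is given, writes ``species.nwk``, ``gene_trees.nhx``
    (one NHX string per line), ``orders.tsv`` and ``truth.tsv``.
    """
    rng = np.random.default_rng(config.seed)
    if config.species_newick is not None:
        species = SpeciesTree.from_newick(config.species_newick)
    else:
        species = random_species_tree(
            config.n_species, rng,
            (config.branch_length_min, config.branch_length_max))

    root_prob = config.resolved_root_prob()
    gene_trees: list[ReconciledGeneTree] = []
    classes: list[SimClassTruth] = []
    n_rejected = 0
    for c in range(config.n_classes):
        t1, r1 = simulate_reconciled_family(
            species, config.dup_rate, config.loss_rate, rng,
            name=f"F{2 * c + 1:05d}")
        t2, r2 = simulate_reconciled_family(
            species, config.dup_rate, config.loss_rate, rng,
            name=f"F{2 * c + 2:05d}")
        n_rejected += r1 + r2
        truth = simulate_adjacency_evolution(
            t1, t2, config.kappa, root_prob, rng, class_id=c)
        if config.drop_fraction > 0.0 and truth.observed:
            keep = rng.random(len(truth.observed)) >= config.drop_fraction
            obs_sorted = sorted(truth.observed)
            truth.dropped = {a for a, k in zip(obs_sorted, keep) if not k}
            truth.observed = {a for a, k in zip(obs_sorted, keep) if k}
        gene_trees.extend([t1, t2])
        classes.append(truth)

    adjacencies, conflicts = _thread_orders(classes)
    orders = _orders_frame(species, gene_trees, adjacencies)

    ds = SimDataset(config=config, species_tree=species,
                    gene_trees=gene_trees, classes=classes, orders=orders,
                    adjacencies=adjacencies, conflicts=conflicts,
                    n_rejected_families=n_rejected)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ds.paths["species"] = out / "species.nwk"
        ds.paths["species"].write_text(species.to_newick() + "\n")
        ds.paths["gene_trees"] = out / "gene_trees.nhx"
        ds.paths["gene_trees"].write_text(
            "".join(t.to_nhx() + "\n" for t in gene_trees))
        ds.paths["orders"] = out / "orders.tsv"
        orders.to_csv(ds.paths["orders"], sep="\t", index=False)
        ds.paths["truth"] = out / "truth.tsv"
        ds.truth_frame().to_csv(ds.paths["truth"], sep="\t", index=False)
    return ds


def _thread_orders(classes: Iterable[SimClassTruth]
                   ) -> tuple[set[Adjacency], set[Adjacency]]:
    """Keep a linearisable subset of the observed adjacencies."""
    accepted: set[Adjacency] = set()
    conflicts: set[Adjacency] = set()
    degree: dict[tuple[str, str], int] = {}
    comp: dict[tuple[str, str], tuple[str, str]] = {}

    def find(k):
        while comp[k] != k:
            comp[k] = comp[comp[k]]
            k = comp[k]
        return k

    for cls in classes:
        for adj in sorted(cls.observed):
            k1 = (adj.species, adj.gene1)
            k2 = (adj.species, adj.gene2)
            for k in (k1, k2):
                degree.setdefault(k, 0)
                comp.setdefault(k, k)
            if degree[k1] >= 2 or degree[k2] >= 2 or find(k1) == find(k2):
                conflicts.add(adj)
                cls.observed.discard(adj)
                continue
            accepted.add(adj)
            degree[k1] += 1
            degree[k2] += 1
            comp[find(k1)] = find(k2)
    return accepted, conflicts


def _orders_frame(species: SpeciesTree,
                  gene_trees: Iterable[ReconciledGeneTree],
                  adjacencies: set[Adjacency]) -> pd.DataFrame:
    """Lay out genes on scaffolds realising exactly the given adjacencies."""
    genes_by_species: dict[str, list[str]] = {s.name: [] for s in
                                              species.leaves}
    for tree in gene_trees:
        for leaf in tree.extant_leaves:
            genes_by_species[leaf.species.name].append(leaf.name)

    neighbours: dict[tuple[str, str], list[str]] = {}
    for adj in adjacencies:
        neighbours.setdefault((adj.species, adj.gene1), []).append(adj.gene2)
        neighbours.setdefault((adj.species, adj.gene2), []).append(adj.gene1)

    rows = []
    for sp_name in sorted(genes_by_species):
        genes = sorted(genes_by_species[sp_name])
        placed: set[str] = set()
        n_sc = 0
        for g in genes:
            if g in placed or len(neighbours.get((sp_name, g), [])) == 2:
                continue  # interior genes are placed from a path end
            path = [g]
            placed.add(g)
            while True:
                nxt = [h for h in neighbours.get((sp_name, path[-1]), [])
                       if h not in placed]
                if not nxt:
                    break
                path.append(nxt[0])
                placed.add(nxt[0])
            n_sc += 1
            for pos, gene in enumerate(path):
                rows.append({"species": sp_name,
                             "scaffold": f"{sp_name}_sc{n_sc:05d}",
                             "position": pos, "gene_id": gene})
        for g in genes:  # cycles cannot occur (union-find above)
            assert g in placed
    return pd.DataFrame(rows,
                        columns=["species", "scaffold", "position", "gene_id"])
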