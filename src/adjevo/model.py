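"""Model and results objects for adjacency-evolution inference.

:class:`AdjacencyEvolutionModel` bundles a species tree with the adjacency
forests of a dataset and exposes the log-likelihood as a function of the
gain/loss ratio ``kappa``, the root presence prior and the species-tree
branch lengths.  ``fit`` maximises it by bounded quasi-Newton on transformed
parameters and returns an :class:`AdjacencyFitResults` carrying the
estimates, posterior probabilities of ancestral adjacency presence, and
per-species summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .adjacencies import (Adjacency, adjacencies_from_orders,
                          build_adjacency_classes)
from .adjtree import (DUP, SPEC, AdjacencyForest, UnsupportedInstanceError,
                      assign_leaf_states, build_adjacency_forest)
from .likelihood import (BatchedPruner, KernelCache, ModelParams,
                         posterior_presence, tree_loglik)
from .trees import (SPECIATION, ReconciledGeneTree, SpeciesTree,
                    parse_reconciled_gene_tree, parse_species_tree)

__all__ = ["AdjacencyEvolutionModel", "AdjacencyFitResults", "load_gene_trees"]

_BOUNDS = {
    "kappa": (1e-3, 1e3),
    "root_prob": (1e-6, 1.0 - 1e-6),
    "length": (1e-6, 100.0),
}
FREE_ALL = ("kappa", "root_prob", "branch_lengths")


def load_gene_trees(path, species_tree: SpeciesTree
                    ) -> list[ReconciledGeneTree]:
    """Load NHX gene trees from a file (one per line) or a directory of
    ``*.nhx`` files."""
    from pathlib import Path
    p = Path(path)
    trees = []
    if p.is_dir():
        for f in sorted(p.glob("*.nhx")):
            trees.append(parse_reconciled_gene_tree(
                f.read_text().strip(), species_tree, name=f.stem))
    else:
        for i, line in enumerate(p.read_text().splitlines()):
            line = line.strip()
            if line:
                trees.append(parse_reconciled_gene_tree(
                    line, species_tree, name=f"T{i + 1}"))
    return trees


class AdjacencyEvolutionModel:
    """Likelihood model of adjacency evolution over a set of forests.

    Parameters
    ----------
    species_tree:
        Rooted binary species tree; its branch lengths are the starting
        values for optimisation (all must be present).
    forests:
        Trees of possible adjacencies with assigned leaf states.
    gene_trees:
        The reconciled gene trees behind the forests (used for per-species
        ancestral gene counts in summaries; optional).
    convention:
        Scenario-enumeration convention at 4-child duplication nodes;
        ``"generative"`` (default) matches the stochastic transmission
        process exactly.
    """

    def __init__(self, species_tree: SpeciesTree,
                 forests: Sequence[AdjacencyForest],
                 gene_trees: Sequence[ReconciledGeneTree] | None = None,
                 convention: str = "generative",
                 n_skipped: int = 0):
        if not forests:
            raise ValueError("no adjacency forests")
        self.species_tree = species_tree
        self.forests = list(forests)
        self.gene_trees = list(gene_trees) if gene_trees is not None else None
        self.convention = convention
        self.n_skipped = n_skipped

        self._lengths0 = np.zeros(len(list(species_tree.postorder())))
        for node in species_tree.postorder():
            if node.parent is not None:
                if node.length is None:
                    raise ValueError(
                        f"species branch to {node.name!r} has no length"
                    )
                self._lengths0[node.index] = node.length
        self._branch_idx = np.array(
            [n.index for n in species_tree.branches()], dtype=int)

        self._plain_roots = []
        self._dup_roots = []
        for forest in self.forests:
            for root in forest.roots:
                has_dup = any(n.kind == DUP for n in _subtree(root))
                (self._dup_roots if has_dup else self._plain_roots).append(root)
        self._pruner = BatchedPruner(self._plain_roots,
                                     len(self._lengths0)) \
            if self._plain_roots else None

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_data(cls, species_tree: SpeciesTree,
                  gene_trees: Sequence[ReconciledGeneTree],
                  adjacencies: Iterable[Adjacency],
                  convention: str = "generative"
                  ) -> "AdjacencyEvolutionModel":
        """Build forests from gene trees and extant adjacencies.

        Adjacency classes violating the single-duplication restriction are
        skipped (counted in ``n_skipped``), mirroring the filtering of
        unsupported families.
        """
        adjacencies = set(adjacencies)
        classes = build_adjacency_classes(adjacencies, list(gene_trees))
        forests = []
        n_skipped = 0
        for c in classes:
            try:
                forest = build_adjacency_forest(c, species_tree)
            except UnsupportedInstanceError:
                n_skipped += 1
                continue
            forests.append(assign_leaf_states(forest, adjacencies))
        return cls(species_tree, forests, gene_trees=gene_trees,
                   convention=convention, n_skipped=n_skipped)

    @classmethod
    def from_files(cls, species_path, gene_trees_path, orders_path,
                   convention: str = "generative") -> "AdjacencyEvolutionModel":
        from pathlib import Path
        species = parse_species_tree(Path(species_path).read_text())
        gene_trees = load_gene_trees(gene_trees_path, species)
        adjacencies = adjacencies_from_orders(orders_path)
        return cls.from_data(species, gene_trees, adjacencies,
                             convention=convention)

    @classmethod
    def from_simulation(cls, dataset,
                        convention: str = "generative"
                        ) -> "AdjacencyEvolutionModel":
        """Model over the simulated forests of a :class:`~adjevo.simulate.
        SimDataset`, with leaf states reset to the *observed* adjacencies
        (dropped observations appear absent, as they would in real data)."""
        forests = []
        for t in dataset.classes:
            forests.append(assign_leaf_states(t.forest, dataset.adjacencies))
        return cls(dataset.species_tree, forests,
                   gene_trees=dataset.gene_trees, convention=convention)

    # -- likelihood --------------------------------------------------------

    @property
    def start_lengths(self) -> np.ndarray:
        return self._lengths0.copy()

    def loglike(self, kappa: float, root_prob: float | None = None,
                lengths: np.ndarray | None = None,
                dup_free_only: bool = False) -> float:
        """Forest log-likelihood at the given parameters."""
        params = ModelParams(kappa, root_prob)
        lengths = self._lengths0 if lengths is None else np.asarray(lengths)
        total = 0.0
        if self._pruner is not None:
            total += self._pruner.loglik(params, lengths)
        if not dup_free_only and self._dup_roots:
            cache = KernelCache(kappa, self.convention)
            for root in self._dup_roots:
                total += tree_loglik(root, params, cache, lengths)
        return total

    # -- fitting -----------------------------------------------------------

    def fit(self, free: Sequence[str] = FREE_ALL,
            start_kappa: float = 1.0,
            start_root_prob: float | None = None,
            start_lengths: np.ndarray | None = None,
            dup_free_only: bool = False,
            maxiter: int = 1000, gtol: float = 1e-6
            ) -> "AdjacencyFitResults":
        """Maximise the log-likelihood over the selected free parameters.

        ``free`` is a subset of ``{"kappa", "root_prob", "branch_lengths"}``;
        fixed parameters keep their starting values.  ``dup_free_only``
        restricts the objective to duplication-free trees (useful for cheap
        branch-length optimisation, after which the full likelihood can be
        evaluated).  Deterministic given the starting point.
        """
        free = tuple(free)
        unknown = set(free) - set(FREE_ALL)
        if unknown:
            raise ValueError(f"unknown free parameters {sorted(unknown)}")
        lengths = (self._lengths0 if start_lengths is None
                   else np.asarray(start_lengths, dtype=float)).copy()
        if start_root_prob is None:
            start_root_prob = start_kappa / (start_kappa + 1.0)

        theta0, unpack, bounds = self._pack(free, start_kappa,
                                            start_root_prob, lengths)
        nfev = [0]

        def objective(theta: np.ndarray) -> float:
            kappa, p, lens = unpack(theta)
            nfev[0] += 1
            try:
                return -self.loglike(kappa, p, lens, dup_free_only)
            except (ValueError, FloatingPointError):
                return 1e12

        start_ll = -objective(theta0)
        if theta0.size:
            # 3-point gradients with a generous step: |loglik| can be ~1e4,
            # where forward differences at sqrt(eps) are roundoff-dominated
            res = minimize(objective, theta0, method="L-BFGS-B",
                           bounds=bounds, jac="3-point",
                           options={"maxiter": maxiter, "gtol": gtol,
                                    "finite_diff_rel_step": 1e-5})
            kappa, p, lens = unpack(res.x)
            llf = -float(res.fun)
            converged = bool(res.success)
            nit = int(res.nit)
            message = str(res.message)
            if llf < start_ll:  # optimizer wandered: keep the better point
                kappa, p, lens = start_kappa, start_root_prob, lengths
                llf = start_ll
        else:
            kappa, p, lens = start_kappa, start_root_prob, lengths
            llf, converged, nit, message = start_ll, True, 0, "nothing free"
        return AdjacencyFitResults(
            model=self, params=ModelParams(kappa, p), lengths=np.asarray(lens),
            llf=llf, llf_start=start_ll, converged=converged, niter=nit,
            nfev=nfev[0], message=message, free=free,
            dup_free_only=dup_free_only)

    def _pack(self, free, kappa, p, lengths):
        parts, bounds = [], []
        if "kappa" in free:
            parts.append([math.log(kappa)])
            bounds.append(tuple(np.log(_BOUNDS["kappa"])))
        if "root_prob" in free:
            parts.append([math.log(p / (1.0 - p))])
            b = _BOUNDS["root_prob"]
            bounds.append((math.log(b[0] / (1 - b[0])),
                           math.log(b[1] / (1 - b[1]))))
        if "branch_lengths" in free:
            vals = np.clip(lengths[self._branch_idx], *_BOUNDS["length"])
            parts.append(np.log(vals))
            bounds.extend([tuple(np.log(_BOUNDS["length"]))]
                          * len(self._branch_idx))
        theta0 = np.concatenate(parts) if parts else np.array([])

        def unpack(theta):
            k, pp, lens = kappa, p, lengths
            i = 0
            if "kappa" in free:
                k = math.exp(theta[i]); i += 1
            if "root_prob" in free:
                pp = 1.0 / (1.0 + math.exp(-theta[i])); i += 1
            if "branch_lengths" in free:
                lens = lengths.copy()
                lens[self._branch_idx] = np.exp(theta[i:])
            return k, pp, lens

        return theta0, unpack, bounds


@dataclass
class AdjacencyFitResults:
    """Parameter estimates and reconstructions from a fitted model."""

    model: AdjacencyEvolutionModel
    params: ModelParams
    lengths: np.ndarray
    llf: float
    llf_start: float
    converged: bool
    niter: int
    nfev: int
    message: str
    free: tuple
    dup_free_only: bool

    @property
    def kappa(self) -> float:
        return self.params.kappa

    @property
    def root_prob(self) -> float:
        return self.params.resolved_root_prob()

    @property
    def branch_lengths(self) -> pd.Series:
        tree = self.model.species_tree
        return pd.Series({n.name: self.lengths[n.index]
                          for n in tree.branches()}, name="branch_length")

    # -- reconstruction ----------------------------------------------------

    def posteriors(self) -> pd.DataFrame:
        """Posterior presence probability of every possible ancestral
        adjacency (one row per speciation-pair node of every forest)."""
        cache = KernelCache(self.params.kappa, self.model.convention)
        rows = []
        for fi, forest in enumerate(self.model.forests):
            cid = forest.cls.id if forest.cls is not None else fi
            for root in forest.roots:
                post = posterior_presence(root, self.params, cache,
                                          self.lengths)
                for node in _subtree(root):
                    if node.kind != SPEC:
                        continue
                    g1, g2 = node.genes
                    rows.append({
                        "class_id": cid, "species": node.species.name,
                        "gene1": g1.name, "gene2": g2.name,
                        "posterior": post[id(node)],
                    })
        return pd.DataFrame(
            rows, columns=["class_id", "species", "gene1", "gene2",
                           "posterior"])

    def ancestral_summary(self, threshold: float = 0.9) -> pd.DataFrame:
        """Per ancestral species: gene count, adjacencies above the
        posterior threshold, and genes in conflict (more than 2 such
        adjacencies)."""
        post = self.posteriors()
        genes_per_species: dict[str, int] = {
            s.name: 0 for s in self.model.species_tree.internal_nodes}
        if self.model.gene_trees is not None:
            seen = set()
            for tree in self.model.gene_trees:
                if id(tree) in seen:
                    continue
                seen.add(id(tree))
                for n in tree.postorder():
                    if n.event == SPECIATION:
                        genes_per_species[n.species.name] = \
                            genes_per_species.get(n.species.name, 0) + 1
        rows = []
        high = post[post["posterior"] > threshold]
        for sp in self.model.species_tree.internal_nodes:
            sub = high[high["species"] == sp.name]
            deg: dict[str, int] = {}
            for _, r in sub.iterrows():
                deg[r.gene1] = deg.get(r.gene1, 0) + 1
                deg[r.gene2] = deg.get(r.gene2, 0) + 1
            rows.append({
                "species": sp.name,
                "genes": genes_per_species.get(sp.name, 0),
                f"adjacencies_gt_{threshold}": len(sub),
                "genes_conflicting": sum(1 for d in deg.values() if d > 2),
            })
        return pd.DataFrame(rows)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Adjacency evolution model fit",
            "=" * 45,
            f"forests: {len(self.model.forests)}"
            + (f"  (skipped: {self.model.n_skipped})"
               if self.model.n_skipped else ""),
            f"free parameters: {', '.join(self.free) or 'none'}"
            + ("  [duplication-free trees only]" if self.dup_free_only
               else ""),
            f"log-likelihood: {self.llf:.4f}  (start: {self.llf_start:.4f})",
            f"converged: {self.converged}  iterations: {self.niter}"
            f"  evaluations: {self.nfev}",
            "-" * 45,
            f"kappa (gain/loss ratio): {self.kappa:.6g}",
            f"root presence prob:      {self.root_prob:.6g}",
            "branch lengths (events/adjacency):",
        ]
        for name, v in self.branch_lengths.items():
            lines.append(f"  {name:<12s} {v:.6g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kappa": float(self.kappa),
            "root_prob": float(self.root_prob),
            "branch_lengths": {k: float(v)
                               for k, v in self.branch_lengths.items()},
            "loglik": float(self.llf),
            "loglik_start": float(self.llf_start),
            "converged": bool(self.converged),
            "niter": int(self.niter),
            "free": list(self.free),
            "n_forests": len(self.model.forests),
            "n_skipped": int(self.model.n_skipped),
        }


def _subtree(root):
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(node.children)
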