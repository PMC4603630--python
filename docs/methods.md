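# Methods

## Model

An adjacency — an unordered pair of consecutive genes — is a binary
character evolving along the species phylogeny.  The generator of the
gain/loss chain is parameterised by a single shape parameter κ (gain rate
over breakage rate) with rates q₀₁ = (κ+1)/2 and q₁₀ = (κ+1)/(2κ).  This
normalisation fixes the time unit: at stationarity, π = (1, κ)/(κ+1), the
expected number of events per adjacency per unit branch length is exactly
one, so species-tree branch lengths read as expected adjacency events.  The
total rate is λ = (κ+1)²/(2κ), and P(t) = exp(Qt) has the spectral form
P(t) = S + E·e^{−λt} with S the stationary projector and E = I − S; all
closed forms below follow from this split and are cross-checked in the
tests against `scipy.linalg.expm` and numerical quadrature.

Gene content changes are not part of the chain: they come from reconciled
gene trees, in which every node carries a species and an event (speciation,
duplication, extant leaf, loss leaf).  For one homology class of extant
adjacencies, the *tree of possible adjacencies* has a node for every
same-species pair of speciation/leaf nodes taken from the two gene trees,
duplication nodes where a gene duplicates on a species branch, and loss
leaves where a gene lineage dies.  The model runs on this tree:

* plain branches use P(t) with t the species branch length;
* a branch on which one gene duplicates leads to a 2-child duplication
  node: the inheriting copy-pair evolves by P(t), the duplication-born pair
  starts absent at a uniformly distributed date and so evolves by the
  averaged kernel N¹(t) = (1/t)∫₀ᵗP(τ)dτ (only its 0→z row is needed);
* a branch on which both genes duplicate leads to a 4-child node governed
  by the (x,0,0,0) slice of P(t) ⊗ N¹¹(t), where
  N¹¹(t) = (2/t²)∫₀ᵗ P(u) ⊗ ∫₀ᵘ P(v)⊗P(v) dv du integrates the two
  uniform duplication dates through their order statistics (u the residual
  time of the earlier duplication, v of the later);
* loss leaves have undetermined state "?" and contribute a factor of one
  (equivalently, their subtree is marginalised out).

At most one duplication per gene lineage is allowed between consecutive
speciations; classes that violate this are reported and skipped, both in
inference and in the simulator (which enforces it by rejection).

### Scenario averaging at duplication nodes

The kernels are defined over *slots* (inheriting lineage, first-born
lineage, the two second-born lineages), while the tree's children are
labelled by gene-copy pairs.  The likelihood averages uniformly over the
admissible child-to-slot assignments.  For a 2-child node there are two
(either child inherits), reproducing the familiar symmetrised P/N¹ sum.
For a 4-child node the generative transmission process implies sixteen:
4 choices of the doubly-inheriting child × 2 orders of the duplications ×
2 choices of which copy of the second-duplicated gene continues the
first-born lineage.  A stochastic simulation of the transmission process
(uniform dates, state passed to one uniformly chosen copy, other copy
starting absent) matches the 16-scenario table to within Monte-Carlo error
(|z| < 3 at 2·10⁵ replicates per outcome), whereas the plausible-looking
8-scenario variant that pins the last choice deviates by up to ~0.02 in
outcome probability (|z| ≈ 20–30).  The 16-scenario table is therefore the
default (`convention="generative"`); the 8-scenario variant remains
available as `convention="ordered"` for comparison.

### Likelihood, posteriors, parsimony

Inside (bottom-up) conditional likelihoods follow Felsenstein pruning with
the duplication kernels as multi-child factors; per-node rescaling guards
against underflow (defensively — the trees are small).  An outside
(top-down) pass mirrors the same scenario averaging; posteriors of presence
are the normalised inside×outside products, and the suite verifies both
passes against brute-force enumeration over all ancestral state
assignments (relative error ≤ 1e−9 on trees of up to 10 internal nodes,
covering speciation-only, 2-child, 3-child-equivalent and 4-child cases and
"?" leaves).  An equivalent pattern/weight factorisation over the
exchangeable second-duplication slots is implemented and shown equal to the
plain enumeration.

The parsimony baseline is Sankoff dynamic programming with unit cost per
gain or breakage on every edge, including the bookkeeping edge into a
duplication node (so a single change dated before the duplication covers
all copy-pairs at once).  Undetermined leaves cost nothing in either state.
Ties are broken toward absence at the root and then toward the parent's
state; this tie-break is a convention.  The parsimony-versus-posterior
comparison restricts the parsimony set to the part of each tree below the
last common ancestor of the observed adjacencies, because a
parsimony method reconstructs nothing above that point while the
probabilistic model scores possible adjacencies all the way to the most
ancient ancestor pair of the class.

### Root prior and parameterisation

The root state prior is a free parameter p (default: the stationary π₁),
allowing non-stationary fits.  Optimisation maximises the forest
log-likelihood over log κ, logit p and log branch lengths with L-BFGS-B
under bounds κ ∈ [10⁻³, 10³], p ∈ [10⁻⁶, 1−10⁻⁶], t ∈ [10⁻⁶, 100].
Gradients are 3-point finite differences with relative step 10⁻⁵: with
|log L| of order 10⁴, forward differences at the default machine-epsilon
step are roundoff-dominated near the optimum and stall the line search.
Duplication-free trees are evaluated by a vectorised level-by-level pruning
over all trees simultaneously (identical to the recursive pruning to
1e−12); trees with duplications take the recursive path.  A flag restricts
the objective to duplication-free trees for cheap branch-length
optimisation.

## Synthetic data

The generator emulates the joint process the model assumes, plus the gene
content dynamics around it:

* gene families originate at the species root and evolve by per-lineage
  duplication (rate d) and loss (rate l) per unit branch length; families
  violating the one-duplication restriction or going extinct are rejected
  and resampled (rejection counts are reported — note rejection slightly
  thins the realised duplication rate, quantified in the tests);
* adjacency histories run down the class's tree of possible adjacencies by
  exact stochastic (Gillespie) simulation of the two-state chain — drawing
  exponential waiting times from the generator rates, never using the
  closed-form kernels, so the simulator doubles as an independent oracle
  for them;
* observed extant PRESENT adjacencies (optionally thinned by a
  `drop_fraction` emulating assembly fragmentation) are threaded into
  linear per-species scaffolds; the rare adjacency that would make a gene
  tri-adjacent is discarded and reported.  Emitted files (Newick species
  tree, NHX gene trees, gene-order TSV, truth TSV) re-parse through the
  package's own readers byte-identically.

Defaults (12 species, 200 classes, d = 0.05, l = 0.1, κ = 1.5, branch
lengths uniform in [0.1, 1.0]) depict a dozen moderately diverged animal
genomes with mostly single-copy families.  What the generator does *not*
simulate: genome-scale rearrangements that move many adjacencies jointly
(classes are independent by construction, exactly as the likelihood
assumes), joint duplications of neighbouring genes, horizontal transfer,
tandem-array (same-family) adjacency classes, and gene-tree estimation
error.  Passing tests therefore demonstrate correctness of inference under
the model's own assumptions, not robustness to their violation in real
genomes.

## Simulation studies

**Parameter recovery** uses a fixed balanced 12-leaf species tree (three
quartets of cherries) with log-uniform branch lengths in [0.04, 0.6]
events per adjacency — the conserved-synteny regime in which adjacency
data are informative; beyond roughly one event per branch the binary
channel saturates (e^{−λt} ≲ 0.1) and branch lengths become statistically
unidentifiable at any realistic class count.  2000 duplication-free
classes are simulated at κ = 1.5 (loss rate 0.05) and all parameters are
re-fitted from a neutral start (all branches 0.2).  Branch lengths are
compared on the identifiable parametrisation: the chain is reversible, so
with a near-stationary root only the *sum* of the two root-child branch
lengths is determined (the pulley principle) and that pair enters the
comparison as one summed value.  At seed 1 this recovers κ within 4% and
branch lengths at Pearson r ≈ 0.98.  Two caveats: the estimate routinely
attains a slightly higher likelihood than the truth (finite-sample ML),
and occasionally (roughly one seed in five) one deep branch's MLE runs
away into the saturated flat region — the branch-length analogue of a
divergent logistic-regression coefficient — deflating the correlation for
that replicate.

**Parsimony comparison** simulates 300 classes on a balanced 8-leaf tree
with all branches at a common length (0.05 for the conserved regime, 1.5
for the rearranged regime; d = 0.05, l = 0.1, κ = 1.5), computes posteriors
at the generating parameters, and measures the posterior of every
parsimony-reconstructed ancestral adjacency.  In the conserved regime
~97% of them exceed posterior 0.9; in the rearranged regime none reach 0.9
and a clear fraction (several percent) fall below 0.5 — parsimony commits
to ancestral adjacencies that the model, integrating over all scenarios,
does not support.

## Numerical choices

* Branch durations below 10⁻⁹ switch to exact limits (identity / point
  mass) to avoid 0/0 in the closed forms; N¹¹ additionally falls back to
  nested 32-point Gauss–Legendre quadrature of its (positive) integrand
  for λt < 10⁻³, where the closed form divides O((λt)²) cancellations
  by t².
* The quadrature evaluators are retained as independent references; closed
  forms must match them to 1e−8 (they agree to ~1e−14 in practice).
* Tree writers emit exact (`repr`) float round-trips, making every output
  byte-stable for a fixed seed.
* Sankoff ties and the inserted-speciation child order (continuing lineage
  first, loss leaf second) are fixed conventions for reproducibility.

## Known limitations

* Branch lengths in saturated regimes (≳1 event per adjacency per branch)
  are unidentifiable in principle; fits there should free κ only.
* Only the sum of the two root-incident branch lengths is well determined
  unless the root prior is strongly non-stationary.
* At most one duplication per gene per branch; families beyond that are
  skipped, which biases datasets toward simpler histories.
* Posterior adjacency sets are not assembled into linear ancestral
  chromosomes; the per-gene conflict count in the summary table is the
  only linearity diagnostic provided.
* The class-clustering step evaluates the homology relation pairwise
  within candidate groups; on datasets with very large tandem families
  this is quadratic in class size.
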