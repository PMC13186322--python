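# Methods

This note documents the models and numerical choices behind `orthocell`:
what each stage computes, why the defaults are what they are, what the
synthetic-data generator does and does not emulate, and the known
limitations.

## Ortho-gene aggregation

Cross-species expression comparison requires a shared feature space.  We use
orthogroups (OGs) — sets of genes descended from one ancestral gene — as
supplied by an OrthoFinder-style `Orthogroups.tsv` table, restricted to the
*universal* OGs with at least one member gene in every species of the panel
(`filter_universal_orthogroups`; presence-based, not single-copy — copy
number is deliberately not restricted, since within-species paralogs are
summed anyway).  Each species' gene × cell counts are collapsed to an
OG × cell "ortho-gene" matrix by summing raw counts of all member paralogs
per cell.  Summation (rather than averaging) preserves total count mass and
treats a duplicated gene's expression as the expression of its ancestral
locus.  Genes listed in the table but missing from the matrix are dropped
with a logged tally (annotation-version mismatches are routine and must not
abort a run); OGs with no present gene are kept as flagged zero rows so that
matrices from different species stay aligned on one OG universe.

## Cell-type profiles and fold change

Per species, the expression profile of cell type *t* is the depth-normalized
geometric mean: each cell's counts are scaled by (median total counts over
cells) / (cell's total counts), then

  g(o, t) = exp( mean over cells of type t of log(scaled(o, c) + ε) ) − ε,

floored at 0, with ε = 0.05 by default.  The geometric mean damps the
heavy right tail of single-cell counts; the ε offset keeps the ubiquitous
zeros finite, and at the cell level it makes the statistic sensitive to
detection rates (the fraction of zero cells), which carries most of the
discriminative signal in sparse data.  Depth normalization is applied to
cells *before* averaging — "cell size" refers to per-cell library size; a
post-hoc scaling of the type means is available for sensitivity analysis.

The regularized fold change against the species' own cell-type median,

  FC(o, t) = (g(o, t) + p) / (median over t′ of g(o, t′) + p),  p = 0.05,

removes species-level baseline differences (every species is compared to
itself) and is strictly positive by construction.  The median uses the
midpoint convention for even type counts.  Binary *activity* calls use a
strict threshold: state 1 iff FC > 1.1 in any focal (phagocyte-like) cell
type; an FC of exactly 1.1 is inactive.

*Metacells.*  `make_metacells` sums seeded-random groups of exactly
`group_size` (default 10) same-type cells, dropping leftovers so every
metacell has identical support.  Metacell aggregation is an optional
pre-averaging step for noise reduction in procedures that need dense
per-observation profiles; the KLD similarity analysis operates on cells
directly, because summing cells discards the detection-rate information the
cell-level geometric mean exploits (empirically, metacell pre-aggregation
measurably reduces homolog-recovery power on sparse synthetic panels).

## KLD similarity and link thresholding

For each species pair, FC matrices are joined on their common OGs.  Each
cell type's FC vector is normalized to a probability distribution (division
by its sum — well-defined because pseudocount regularization keeps every
entry positive), and each cross-species type pair receives the symmetrized
Kullback–Leibler divergence D = ½[KL(P‖Q) + KL(Q‖P)] in nats.  The
symmetrized form is the default because cell-type homology is an undirected
statement; directed mode is available.

Within each species pair, divergences are inverted to similarities by
min–max scaling (identical profiles → 1, the most divergent pair → 0; if all
divergences are equal, similarity ≡ 1).  Links at or above the 88th
empirical percentile of similarity (linear-interpolation percentile, ties
kept) are retained — the top 12% of connections.  Two properties make these
choices presentational rather than substantive: any strictly decreasing
inversion of KLD yields exactly the same retained link set, and the
percentile is computed within each species pair (a pooled, global percentile
is available as an option).

## Conserved markers and intersections

For a retained link (type *a* in species A, type *b* in species B), an OG is
a *shared marker* when (i) FC > 1.1 in the linked type in both species, and
(ii) a two-sided Wilcoxon rank-sum test of its per-cell expression
(linked-type cells vs. all other cells) is significant at
Benjamini–Hochberg FDR < 0.05 in both species, adjusted within species
across all tested OGs.  The rank-sum test uses the exact null distribution
when the product of group sizes is ≤ 400 and the pooled sample has no ties
(the exact enumeration assumes distinct ranks), otherwise the normal
approximation with tie correction; fully tied samples carry no rank
information and return p = 1.  The ingroup/outgroup cells have no natural
pairing, so an unpaired rank-sum test is the defined statistic.  BH
correction is applied because thousands of OGs are tested per species.

Per-species marker sets (OGs passing both criteria in that species' focal
cell type) are intersected with UpSet semantics: each OG is counted in
exactly the combination of species sets containing it, so combination sizes
partition the union; the all-species core set is the plain intersection.
`conserved_deg_orthogroups` applies the same species-counting logic to
externally supplied per-species DEG lists (OGs with ≥1 DEG in ≥ *k*
species).

## Maximum-parsimony trait evolution

Binary OG activity at the tips evolves on a rooted species tree with branch
lengths in Myr.  Ancestral states minimize the number of state transitions:

* *Bottom-up*: unit-cost Sankoff (the Fitch algorithm generalized to
  multifurcations) computes, per node, the minimal subtree cost of each
  state; the per-node candidate set is the argmin, and the root's minimum is
  the parsimony score.  Gains (0→1) and losses (1→0) are weighted equally;
  asymmetric costs would require a rationale the data do not provide.
* *Top-down (ACCTRAN-style)*: each node inherits its parent's state when it
  is among the node's candidates, else takes its unique candidate; a root
  tie is broken toward state 1 (active) and logged.  The resolution
  provably attains the parsimony score, and biases toward ancestral presence
  only at exact ties — an audited, deterministic convention.  The
  alternative of carrying fractional (marginal) state probabilities instead
  of a discrete resolution was rejected to keep per-branch transition counts
  integer-valued and auditable.

Per branch, gains and losses are tallied over all OGs and the change rate is
(gains + losses) / branch length, in transitions per Myr; branches with
missing or zero length get a missing rate with a warning.  Internal nodes
are addressed by Newick label when present and always by their tip-set
signature (`MRCA(...)`).

A sharp caveat for recovery claims: when a trait's only change lies on a
branch adjacent to a bifurcating root, the two root states tie exactly under
parsimony (both cost 1), so even single-change traits cannot always be
root-recovered; the tie-break toward activity decides those cases.  All
other single-change traits reconstruct the root uniquely and correctly.

## Synthetic panels

`simulate_panel` generates the study conditions used throughout testing:
3 species × 4 cell types × 200 cells per type over 300 OGs (defaults),
negative-binomial counts with mean μ and variance μ + μ²/θ (baseline per-OG
means log-normal around 2 counts/cell with σ = 0.5; θ = 2, typical
overdispersion for UMI counts), per-cell library sizes log-normal with
σ = 0.25, and species-specific paralog expansion: each OG has 1 + Poisson(0.5)
genes whose expected expression splits the OG total by a symmetric
Dirichlet(1), so ortho-gene aggregation recovers the OG-level signal in
expectation regardless of copy number.

Planted structure, all recorded as ground truth:

* a conserved 20-OG module multiplied by fold 4 in one designated
  phagocyte-like cell type per species (the cross-species signal);
* a disjoint 20-OG lineage-specific module at the same fold in one
  non-phagocyte cell type of one species only (a decoy that must *not*
  enter conserved-marker intersections);
* species-specific marker modules of 10 OGs at fold 3 for every
  *non-phagocyte* cell type, drawn independently per species from the
  background.  Without these, non-phagocyte cell types would be
  statistically identical — unlike any real annotated cluster — and
  cross-species links among them would be arbitrary; 10 of 300 OGs (≈3%)
  is a conservative marker fraction.  The phagocyte-like type carries no
  extra species-specific markers: its identity is the conserved module;
* a binary trait history on the species tree: root states Bernoulli(0.5),
  each trait flipping with probability 0.05 per branch.

What the generator does **not** emulate: batch effects, ambient RNA,
doublets, cell-type abundance imbalance, continuous differentiation
gradients, non-orthologous gene displacement, and gene-level (rather than
OG-level) evolutionary divergence of expression.  Passing tests therefore
demonstrate correctness and statistical power of the pipeline under its own
modelling assumptions, not robustness to every artifact of real single-cell
data.

## Problem sizes and determinism

Test and acceptance runs use the default panel (3 species, 800 cells each,
300 OGs) with 20 independent replicates for recovery statistics, 500–1,000
random trees of ≤7 tips for exhaustive parsimony verification, and a 9-tip
dated tree with 300 traits for ancestral-state recovery — sizes chosen so
the complete validation runs in seconds while keeping Monte-Carlo standard
errors well below the margins being asserted.  Every stochastic component
(simulation, metacell grouping, trait histories) draws from a single
`numpy.random.Generator` seeded explicitly; identical seeds give
byte-identical outputs, including the pipeline's on-disk results.

## Limitations

* Similarity is computed on the universal-OG subspace; lineage-restricted
  genes (often the most interesting innovations) are invisible by design.
* The 88th-percentile link rule retains the top 12% of connections *per
  species pair* even when no pair is biologically homologous; links are
  relative, not absolute, statements.
* Parsimony reconstruction ignores branch lengths when inferring states
  (only the rate normalization uses time); a likelihood (Mk-model) treatment
  is out of scope.
* The Wilcoxon marker test treats cells as independent replicates; it does
  not model donor- or batch-level pseudoreplication.
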