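# Methods

`discordate` quantifies how topological discordance between gene trees and
their species tree biases likelihood-based estimates of branch substitutions
(*n*), branch durations (*t*) and substitution rates (*r*), and evaluates two
mitigation strategies.  This note records the models, the numerical choices,
and what the synthetic data do and do not emulate.

## The quantities and why they are entangled

For a branch of a time-calibrated species tree, *n* = *r·t*: expected
substitutions per site are the product of the branch's duration and its
substitution rate.  Sequence data inform *n* only; separating *t* from *r*
requires clock assumptions and at least one absolute-time calibration (here,
a fixed root age).  Consequently an error in *n* propagates into *t* and *r*
in ways shaped by those assumptions — the central mechanism the experiments
expose is that a fixed root age converts *under*-estimation of internal-branch
*n* into *over*-estimation of terminal-branch *t*.

## Simulation designs (the `simulate` module)

All defaults are the study conditions and are not tuning knobs.

* **Fixed-topology mixtures.** 400 gene trees per dataset; a configured
  fraction (0–50%) are verbatim copies of one alternative topology carrying
  the species tree's exact node ages, the rest copies of the species tree.
  Gene trees differ from the species tree *only* topologically.
  Canonical trees: the four-taxon tree ((A,B),(C,D)) with internal nodes at
  0.5 and root at 1.0 (alternative ((A,C),(B,D)), same ages); a balanced
  16-taxon tree with every branch lasting 0.2 (root 0.8) whose alternatives
  reciprocally swap 2/4/6/8 terminals across the two halves (A↔I, B↔J, …);
  and a 16-taxon caterpillar with 0.2 internal branches (root 3.0).
* **Multispecies coalescent (MSC).** One haploid lineage per species; within
  each species branch, *k* lineages coalesce with exponential waiting times
  at rate *k(k−1)/(2Ne)* in species-tree time units, survivors passed to the
  parent population, everything coalescing above the root.  With *Ne* = 0.12
  and internal branches of 0.2 this leaves each internal branch congruent in
  1 − (2/3)e^(−0.2/0.12) ≈ 87.4% of gene trees, and makes every gene
  divergence predate its species divergence.  The simulator is cross-checked
  in tests against that closed form and against msprime (ploidy 1) on a
  three-taxon tree.
* **Sequences.** 800 bp per locus under Jukes–Cantor at rate 0.05
  substitutions/site/time along the gene tree (root state uniform; per-site
  stay probability 1/4 + (3/4)e^(−(4/3)rt); mutations uniform over the other
  three bases).  No rate heterogeneity, indels, or non-JC processes —
  matching the simulation design this package reproduces.

The 16-taxon design descriptions carry an internal inconsistency: root ages
of 1.0 and 3.2 alongside uniformly 0.2-long branches.  The depth-consistent
root ages (0.8 and 3.0) are used.  Percentage errors are invariant to this
overall scale under the free-rate clock, and the depth-consistent balanced
tree reproduces the concatenation, filtering and node-age reference values;
a variant with root 1.0 and 0.4-long terminal branches was tried and does
not (see Limitations).

## Estimation (the `inference` module)

All estimators maximize the exact Jukes–Cantor pruning likelihood over
site-pattern counts (pattern compression is exact, not approximate); inner
kernels are numba-compiled because the optimizers evaluate the likelihood
thousands of times on small arrays.

* **estimate_n_unrooted** — ML branch lengths on the fixed topology.
  Reversible model, so the root is unidentifiable: the two root-adjacent
  branches are estimated and reported as their sum.  Coordinate-wise Brent
  on each branch in [0, 10], then an L-BFGS-B polish; convergence when a
  sweep gains < 1e−8 log-likelihood.
* **estimate_t_strict_clock** — ML node ages with tips at 0 and the root
  fixed to the calibration age.  Each internal node's age is optimized by
  bounded Brent inside (oldest child, parent age); in the free-rate mode the
  single clock rate is profiled once per sweep on a log scale inside the
  uniform box [1e−6, 1].  Ages are initialized from pairwise JC clock
  distances (node height = mean cross-clade distance / 2), which starts the
  search essentially at the optimum; the `n_restarts` parameter adds random
  feasible restarts, and a test verifies restarts reach the same optimum —
  the constrained likelihood is well-behaved here, so the default is a
  single deterministic start.  Brent's age tolerance is 1e−6 of the root age
  for concatenated fits and 1e−4 for the per-locus datings of the
  congruent-branch method (measured effect on class means < 0.01 points).
* **estimate_r_fixed_times** — per-branch MAP rates with all node ages held
  at their true values, under independent lognormal priors parameterized by
  their *real-scale* mean *m* and variance *v* (σ² = ln(1 + v/m²),
  μ = ln m − σ²/2); *v* = 0 degenerates to *r* = *m* exactly.  The low- and
  high-variance settings are (0.05, 0.001) and (0.05, 0.1).  Note that on
  real scale *v* = 0.001 is a rate sd of 63% of the mean — diffuse relative
  to the per-branch likelihood information in tens of kilobases, so both
  standard settings track the data there; the near-clock regime (rates held
  marginally below the truth on biased data) only appears for *v* around
  1e−7 at those alignment sizes, which the tests exercise explicitly.

Point estimates (ML/MAP) stand in for the Bayesian posterior means of the
original analyses.  On concatenated alignments (≥ tens of kilobases) the two
are indistinguishable; on single 800-bp loci the tree prior can shift
posterior means by a few percent, which ML deliberately omits (see
Limitations).

## Congruence and equivalence (the `congruence` module)

Congruence is rooted and clade-based: a gene tree is congruent for a species
branch when it contains the branch's descendant clade; terminal branches are
trivially congruent.  *Equivalence* additionally requires the gene branch's
ancestral-node clade to match, so an equivalent branch spans the same two
divergences as the species branch and its duration is a direct estimate of
the species branch's duration.  Incomplete sampling uses intersection
semantics: species clades are restricted to the gene tree's taxa before
comparison, and a branch whose restricted descendant clade is empty or equal
to its restricted ancestral clade is untestable in that gene tree and leaves
its denominator.

## Estimation strategies (the `estimators` module)

* **Concatenation** — all loci joined (gap-padded over the taxon union),
  one fit on the species topology.
* **Congruent-locus filtering** — drop loci whose gene tree has more than a
  threshold number of incongruent branches (0 = fully congruent), then
  concatenate.  Fixed schemes are dated at the true rate; MSC data use the
  free-rate clock, because coalescent gene trees are older than the species
  root used as the calibration and a fixed true rate would add a bias
  unrelated to topology.
* **Congruent-branch averaging** — date each gene tree separately with its
  root fixed to the species root age, then estimate each species branch as
  the arithmetic mean duration over equivalent gene-tree branches.
  Per-locus dating defaults to *posterior-mean* ages from short
  Metropolis–Hastings chains (`mcmc_t_strict_clock`: sliding-window age
  proposals, multiplicative rate walk, conditioned-Yule tree prior with
  unit birth rate, uniform rate prior; started from a coarse ML fit).  At
  800 bp the tree prior shifts posterior means by a fraction of a percent
  to a few percent — matching the behavior of Bayesian per-locus dating,
  which pure ML (available via `dating="ml"`) does not show.  On
  concatenated data the two agree to < 0.5%, which a test verifies, and a
  single-free-node case is checked against direct quadrature of
  likelihood × prior.  No
  chronogram is assembled: branches borrow from different gene subsets, tip
  times need not align, sister estimates need not agree, and no interval
  estimates are produced.  For *n*, gene-root-adjacent equivalent branches
  are skipped (only their pairwise sum is identifiable).  A species branch
  with no equivalent branch anywhere yields a missing value, never a
  fallback.

## Error summaries (the `experiments` module)

Percentage error is 100·(estimate − truth)/truth, averaged unweighted over
branches within a class (internal vs terminal), then over replicates.  Node
ages are classed by whether the node subtends at least one internal branch;
with tips at 0, the terminal-subtending class's age error equals the
terminal-branch duration error.  The incongruence–error curve bins per-branch
errors by per-branch gene-tree incongruence in 5% bins.  Fixed schemes
follow the single-run design; MSC experiments are replicated with fresh gene
trees and sequences (50 in the full design; the bundled analyses and
acceptance runs use 10, which puts the Monte-Carlo error of class means well
under one percentage point).  Everything is deterministic under the master
seed via spawned child seeds.

## Numerical and degenerate-input choices

* Sweep convergence at |Δlog L| < 1e−8 everywhere; age feasibility margins
  at 1e−6 of the root age; ultrametricity tolerance 1e−9 absolute.
* JC distances cap mismatch fractions at 0.74999 so saturated pairs stay
  finite in initializations.
* Zero-duration branches are rejected by the rate estimator (the prior on a
  branch's substitutions is undefined); zero-truth branches make percentage
  error undefined and raise.
* Gene trees are the *true* simulated topologies throughout; gene-tree
  estimation error is out of scope by design.

## Known limitations

* **Posterior means vs point estimates on short loci.**  For the four-taxon
  mixtures, per-locus ML dating is unbiased, so the congruent-branch class
  means would center on 0; posterior-mean dating under the unit-birth-rate
  Yule prior moves them to about −0.6/+0.6, reproducing the direction but
  only part of the magnitude of the reference values −2.5/+2.3.  The remainder
  depends on prior settings not recoverable from the publication.
* **Calibration leakage in the congruent-branch method under the MSC.**
  Dating a coalescent gene tree with its root pinned to the *species* root
  age shrinks all its node ages by roughly (species root)/(gene root) — here
  ≈ 0.85 on average — so the method's class means come out near −9%
  (internal) and +23% (terminal) instead of the reference values +3.2/+5.9.  The
  unshrunken true equivalent-branch durations average +2.5% (internal) and
  +42% (terminal); no calibration variant reproduces the reference pair
  while leaving the (reproduced) concatenation results intact.
* **The four-taxon MSC concatenated value.**  With per-branch incongruence
  of ~12.6%, the fitted internal-branch error is ≈ −24% (free rate; −32%
  fixed-rate, verified against a brute-force likelihood grid), far from the
  reference −50.6%, which coincides with the 50%-incongruence mixture value.
  The filtered counterpart (−8.3%) does reproduce.
* The synthetic data exercise topological and coalescent-temporal
  discordance only: no gene-tree estimation error, no alignment error, no
  among-site or among-lineage rate variation, no missing data.  Passing
  tests demonstrate the estimators' behavior under those idealized
  conditions, not on real phylogenomic data.
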