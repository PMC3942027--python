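# Methods

This note records the models implemented in `mitorder`, the assumptions
behind them, the numerical choices, and the design decisions taken where
the underlying methodology left room. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Gene orders and the conservation index

A genome is a signed arrangement of uniquely named genes, circular by
default (fungal mtDNAs are circular; linear handling exists for
completeness). Mitochondrial protein-coding genes are single-copy in the
genomes this package targets, so duplicate symbols are rejected rather than
treated as a gene-matching problem.

For genomes g₁, g₂ sharing m orthologs, both orders are restricted to the
shared set by *delete-and-join* (removed genes' neighbours become
adjacent), and

GOC = |A₁ ∩ A₂| / m, GOL = 1 − GOC,

where Aᵢ is the set of adjacencies — **unordered, strand-blind** gene
pairs — of the restricted order. Strand-blindness is deliberate:
basidiomycete mt genes sit on both strands, and a contiguous pair remains
contiguous whichever strand either member is read from. A strand-aware
variant (`signed=True`, adjacencies on head/tail extremities) is available.
GOC requires m ≥ 3; with fewer shared genes the index is refused as
undefined rather than returned as a degenerate value.

tRNAs are excluded from GOC by default (the protein-coding order is the
object of study; tRNA placement gets its own test). The importer exposes
feature-class filtering so rRNA/tRNA inclusion is a caller's choice.

## Rearrangement distances

*Breakpoint distance* = m − |A₁ ∩ A₂| on the shared gene set; with the
default strand-blind adjacencies this equals m·GOL exactly. Note that only
the **signed** breakpoint count (extremity-based) is an upper bound on the
DCJ distance; the strand-blind count can be smaller than DCJ, because a
strand-blind adjacency need not be a signed adjacency. Both variants are
exposed.

*DCJ distance*: for two single circular chromosomes with identical gene
content, d = n − c with c the number of cycles of the adjacency graph on
gene extremities. Unequal gene content is refused (mirroring classical
rearrangement sorters) rather than patched by silent insertions/deletions.
The implementation is validated in the test suite against an independent
breadth-first search over adjacency-graph states under single DCJ
operations — exhaustively for n ≤ 5 and on sampled n = 6 instances — and
property-tested as a metric. Rearrangement *scenarios* (which operations
happened) are out of scope; only distances are computed.

## Decay models

Four single-parameter curves for GOC as a function of patristic distance t:

| model | curve | parameter |
|---|---|---|
| 0 | GOC = 2/(1+e^{αt}) | α ≥ 0 |
| 1 | GOC = 1 − √(αt), clamped to [0,1] | α ≥ 0 |
| 2 | GOC = 1/(αt+1) | α ≥ 0 |
| 3 | GOC = p^t | p ∈ (0,1] |

All satisfy GOC(0) = 1. Model 0's formula is sometimes typeset ambiguously
as "2/1 + e^{αt}"; it is parsed as 2/(1+e^{αt}), the only reading that
gives a decaying curve starting at 1. Model 1 leaves its natural domain at
αt > 1; predictions are clamped at 0 and residuals computed against the
clamp. Model 3 assumes the same per-unit-time retention probability for
every gene pair — unrealistic, but that is the model.

Goodness of fit is the residual sum of squares in GOC units (the natural
quantity for a curve "adjusted by regression"; no alternative definition is
implied by the methodology this reimplements, and published unitless fit
scores for these models are therefore not comparable to our RSS values).
Fitting is single-parameter bounded minimization: a deterministic 60-point
log-spaced grid scan over α ∈ [0, 100] (p ∈ (0, 1]) followed by bounded
Brent refinement in the best grid cell, convergence tolerance 1e−10. No
randomness, hence bit-reproducible fits.

## Branch-specific GOL

Pairwise GOL observations are decomposed onto the tree by minimizing
L = Σᵢ(Σⱼ b_ij xⱼ − GOLᵢ)² with b_ij the path indicator. Choices:

- **Nonnegativity** (xⱼ ≥ 0, solved with NNLS): a branch's contribution is
  a loss fraction; negative loss has no meaning. The unconstrained OLS
  solution is available for comparison (`nonnegative=False`); its residual
  is never larger, and the two coincide when the unconstrained optimum is
  feasible.
- **Root-independent branches.** Branches are identified by the leaf-set
  bipartition they induce; the two edges incident to a degree-2 root are
  merged into one branch (their lengths summed). Path indicators are then
  invariant to re-rooting, and so is the decomposition — a property the
  test suite asserts. A consequence: a 3-leaf rooted tree has 3 branches in
  this representation, not 4, and a 2-leaf tree has 1.
- **Underdetermined systems** (design rank < number of branches) are
  solved anyway but flagged with a warning; the returned solution is one
  minimizer among many.

Rate normalization (bsGOL per branch length, rearrangement events per
substitution rate) is an elementwise ratio with non-positive denominators
reported as NaN per taxon rather than aborting; an optional second step
divides by the mean ratio.

## Permutation tests

Both tests use Monte-Carlo p = (k+1)/(B+1) (never exactly zero) and a
single numpy `Generator` seeded by the caller. Defaults are B = 100,000
permutations; the test-suite and pipeline runs use smaller B chosen for
runtime, which only widens Monte-Carlo error.

*Gene-order shuffle test*: observed GOC against the distribution of GOC
after uniformly permuting one genome's shared-gene order (signs travel with
genes; shuffling one genome or both yields the same null for a
strand-blind statistic). One-sided in the conservation direction.
Bonferroni correction (min(1, p·m)) across the m = n(n−1)/2 pairwise
comparisons.

*tRNA clustering test*: "noncontiguous tRNA" is implemented as a tRNA with
no tRNA in either adjacent position of the circular gene+tRNA list — the
natural statistic for "grouped in a few clusters". The count of maximal
tRNA runs is available as an alternative statistic behind a flag.
One-sided (fewer noncontiguous tRNAs = clustering). Note that for very few
tRNAs the minimum statistic need not be significant: with 4 tRNAs among 12
positions, exhaustive enumeration gives P(statistic = 0) ≈ 0.109 under the
null, so even a perfect block cannot reach p < 0.05. Tests therefore
validate against exhaustive nulls and use larger tRNA complements (e.g. 20
tRNAs among 15 genes, the realistic organellar scale) for power checks.

## Association statistics

Pearson χ² and Wilks G² (with 0·ln 0 := 0) on per-cluster
(intergenic-repeat, rearrangement-event) count tables, expected counts from
the margins, no continuity correction; a randomization test of independence
simulating fixed-margin tables (Patefield sampling via
`scipy.stats.random_table`); Fisher's exact test for 2×2 and a Monte-Carlo
generalization for r×2 comparing conditional table probabilities. The
basal-fungi row is excluded from the headline six-cluster test (df = 5);
a seven-row variant is a flag away.

Two statistical caveats are documented rather than "corrected", because the
package reproduces the published analysis design:

1. Treating count *totals* as independent observations in a contingency
   test is generous — counts within a cluster are not independent trials.
2. The raw-totals χ² detects **departure from proportionality** of the two
   columns. It therefore fires for any disproportionality, including the
   flat-repeats-versus-heterogeneous-events kind; with clusters defined as
   clades, shared-branch exposure differences alone make the test
   anticonservative as a test of repeat–rearrangement coupling. The
   simulator's calibration checks are designed around this (below).

## The synthetic-data generator

The generator produces data with the statistical structure the analyses
assume, plus ground truth for recovery tests. What it emulates:

- **Trees**: Yule (pure birth) via dendropy, scaled to unit root-to-tip
  height. Real branch lengths are substitutions/site; the simulator's unit
  is arbitrary time, with events per unit branch length as the rate.
- **Rearrangement**: on each branch K ~ Poisson(rate × length) events;
  each event inverts a uniformly chosen circular segment (uniform start,
  uniform length 1..n−1, signs flipped), or is a transposition with the
  configured probability. Inversions are the default event type, the
  dominant process inferred for fungal mtDNA; no event-size model is
  imposed beyond uniformity.
- **Defaults as study conditions**: 14 genes (the fungal mt protein-coding
  core), ~25 tRNAs (the observed 7–30 range), 12-leaf trees (the scale of
  one fungal cluster analysis), rate 1 event per unit height.
- **tRNA placement**: one contiguous block ("clustered",
  sordariomycete-like) or uniform interleaving ("scattered",
  basidiomycete-like).
- **Repeats**: per-species intergenic-repeat counts are negative binomial
  with mean = baseline + slope × (that species' root-to-leaf event count)
  and dispersion 5 by default — NB overdispersion mirrors the
  order-of-magnitude spread of repeat counts between real clusters.
- **Cluster structure**: leaves are grouped into clades (largest-clade
  splitting, default 4 groups) or, optionally, random exchangeable groups.
  Per-cluster rearrangement events are counted once per event (branches
  inside the cluster), not per descendant leaf, avoiding double-counting
  overdispersion.
- **Rate heterogeneity** (`cluster_rate_heterogeneity`, default 0): with
  value η, branches inside a cluster evolve at the base rate times a
  lognormal(0, η) cluster multiplier. Real fungal clusters differ in
  rearrangement-event totals by ~30× and in repeat totals by ~160×, which
  corresponds to η around 2–3.

Calibration facts the test suite verifies: with rate 0 all leaves equal the
root and GOC ≡ 1; per-branch event counts are Poisson with the nominal
mean; mean pairwise GOC is non-increasing in the rate; DCJ distance from
the root never exceeds the true event count; estimated bsGOL correlates
positively (Spearman ρ > 0.5) with true per-branch event counts; the
fitted model-3 retention probability decreases with the inversion rate.

For the association test, the null check (slope 0) uses **random** cluster
assignment, because that is the exchangeability the χ² null actually
assumes — with clade clusters the test is anticonservative by construction
(caveat 2 above). The power check uses clade clusters with strong rate
heterogeneity (η = 3, base rate 32) and the slope-5/baseline-10 repeat
response. A subtlety worth recording: under a *linear* repeats-on-events
response with a single global rate, increasing the slope drives the
repeat and event columns *toward* proportionality, i.e. toward χ²
independence — coupling is only detectable through between-cluster rate
heterogeneity, which is precisely the regime the real data occupy.

What the generator does **not** emulate: nucleotide sequences, intron/
homing-endonuclease mobility mechanics (element counts are covariates
only), gene loss or duplication, non-ultrametric rate variation within
clusters, and linear chromosomes. Passing recovery tests on this generator
therefore validates the estimators under the stated model, not the
correctness of any biological claim about real genomes.

## Packaged fixtures

`mitorder/data/dikarya_species_stats.csv` and
`cluster_repeat_rearrangements.csv` transcribe the published per-species
and per-cluster summary tables for the 38-genome fungal data set, with
SHA-256 checksums verified before use (see `data/TRANSCRIPTION.md` for how
ambiguous digit groupings were resolved and cross-checked against the
cluster totals). The per-species bsGOL-rate columns (`gol_rate`,
`normalized_gol_rate`) are shipped as printed but are **not** used in any
computation: the printed values are not reproducible as bsGOL ÷ branch
length (e.g. 0.35/0.7 = 0.5 against a printed 1.05), and the transformation
actually used is unrecoverable, so these columns are treated as opaque.

Re-deriving the 38 genomes' bsGOL values from scratch is likewise out of
scope: it would require the GenBank gene orders and the exact published
tree. The decomposition is instead validated by synthetic parameter
recovery, and the fixture columns feed the downstream statistics.

## Degenerate inputs, tie-breaks, tolerances

- GOC/breakpoint/shuffle tests refuse < 3 shared genes; adjacency sets
  refuse < 2 genes; tRNA test refuses < 2 tRNAs or zero non-tRNAs.
- Contingency tests refuse zero margins; Fisher exact mode refuses
  non-2×2.
- Floating-point guards: permutation comparisons use a 1e−12 slack on
  "as extreme as observed"; Monte-Carlo χ² comparisons use 1e−9.
- Decay fits: objective tolerance 1e−10; the grid point is kept if local
  refinement fails to improve it.
- NNLS ties (flat optima in underdetermined systems) resolve to whatever
  scipy's active-set implementation returns; flagged via the
  `underdetermined` field.
- Problem sizes in the default test run (permutation counts of 199–20,000,
  100-dataset calibration batches, 12-leaf trees) are the package's chosen
  validation scale; library defaults remain at the full B = 100,000.
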