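# mitorder

Gene-order evolution in fungal mitochondrial genomes.

Fungal mtDNAs keep an almost constant core gene set (*atp6/8/9*,
*cox1–3*, *nad1–6*, *nad4L*, *cob*, *rnl*, tRNAs) while shuffling the
*order* of those genes remarkably freely, both between and within the major
phyla. `mitorder` is a library and CLI for quantifying that shuffling and
asking what drives it. It is aimed at comparative genomicists working with
organellar (or other small, mostly single-copy) genomes.

## What it computes

**Gene order conservation.** For two genomes sharing m orthologs, the gene
order conservation index is

    GOC = (# contiguous ortholog pairs in common) / m,      GOL = 1 − GOC

computed on the circular gene orders after restricting both genomes to the
shared gene set (deleted genes' neighbours are joined). Adjacencies are
unordered, strand-blind gene pairs by default.

**Rearrangement distances.** The breakpoint distance `m − |A₁ ∩ A₂|` and
the double-cut-and-join (DCJ) distance `n − c`, where `c` is the number of
cycles in the adjacency graph on signed gene extremities — the minimal
number of cut-two-adjacencies-and-rejoin operations between two equal
content circular genomes.

**Decay of conservation with time.** Four single-parameter curves fitted to
pairwise (patristic distance t, GOC) data by nonlinear least squares:
GOC = 2/(1+e^{αt}) (sigmoidal), 1 − √(αt) (square-root), 1/(αt+1)
(hyperbolic), and p^t (per-unit-time retention probability).

**Branch-specific gene-order loss (bsGOL).** Pairwise GOL values are
decomposed onto the tree by minimizing

    L = Σᵢ ( Σⱼ b_ij·xⱼ − GOLᵢ )²,   xⱼ ≥ 0,

where b_ij = 1 iff branch j lies on the path between pair i's leaves; the
nonnegative least-squares solution xⱼ is the bsGOL score of branch j.

**Randomization tests.** A gene-order shuffle test (is observed GOC higher
than for random orders?) with Bonferroni correction across pairs, and a
tRNA clustering test (statistic: number of tRNAs with no tRNA neighbour on
the circular gene+tRNA list; null: label permutation), both with
Monte-Carlo p = (k+1)/(B+1).

**Association statistics.** Pearson χ², Wilks G², Fisher-style exact /
Monte-Carlo tests and a fixed-margin randomization test of independence for
per-cluster (intergenic repeats × rearrangement events) count tables, plus
Pearson correlations and per-cluster bsGOL means.

**Synthetic data.** Signed circular gene orders evolving by Poisson
inversions (optionally transpositions) along simulated Yule trees, with
clustered or scattered tRNA placement, optional per-cluster rate
heterogeneity, and negative-binomial intergenic-repeat counts coupled to the
rearrangement process — so the whole pipeline runs and is validated without
any downloads. Ground truth (per-branch event counts) is returned for
parameter-recovery checks.

The package ships a per-species table for a published 38-genome fungal
data set (nine basidiomycetes, 27 ascomycetes, two early-diverging
outgroups; bsGOL, branch lengths, substitution rates, element counts) and
the matching per-cluster repeat/rearrangement table, as checksummed CSV
fixtures.

## Worked example

```python
from mitorder import GeneOrder, goc_gol, dcj_distance
from mitorder.pipeline import reproduce_reference_stats

a = GeneOrder("podospora-like", [("cox1",1),("nad1",1),("nad4",1),("atp8",1),
                                 ("atp6",1),("rnl",1),("cob",1)])
b = GeneOrder("fusarium-like",  [("cox1",1),("nad1",1),("atp8",-1),("nad4",-1),
                                 ("atp6",1),("rnl",1),("cob",1)])
goc, gol = goc_gol(a, b)
print("GOC =", goc, " GOL =", gol, " DCJ =", dcj_distance(a, b))
```

prints

```
GOC = 0.7142857142857143  GOL = 0.2857142857142857  DCJ = 1
```

the second genome differs by one inversion (of the `nad4 atp8` block): 2 of
the 7 circular adjacencies are broken, so GOC = 5/7 ≈ 0.71, and the DCJ
distance is exactly 1 operation.

Reproducing the headline statistics of the packaged 38-genome data set:

```python
print(reproduce_reference_stats(n_sim=5000, seed=1).to_string(index=False))
```

```
                    statistic         value
    mean_bsgol_basidiomycetes  2.094111e-01
   mean_bsgol_sordariomycetes  9.646250e-02
   mean_bsgol_dothideomycetes  1.642667e-01
    mean_bsgol_eurotiomycetes  1.363000e-01
  mean_bsgol_saccharomycetes1  1.836667e-01
  mean_bsgol_saccharomycetes2  1.971000e-01
pearson_r_bsgol_branch_length  6.872483e-01
pearson_p_bsgol_branch_length  1.881442e-06
  chi2_repeats_rearrangements  1.158370e+03
                      chi2_df  5.000000e+00
                       chi2_p 3.053978e-248
    g2_repeats_rearrangements  1.156383e+03
                         g2_p 8.226470e-248
   monte_carlo_independence_p  1.999600e-04
         fisher_monte_carlo_p  1.999600e-04
```

Basidiomycetes have lost the most gene order on average (mean bsGOL 0.21)
and sordariomycetes the least (0.10); bsGOL correlates moderately with
branch length (r ≈ 0.7); and across the six dikarya clusters the
intergenic-repeat and rearrangement-event counts are far from proportional
(χ² ≈ 1158 on 5 df), the pattern expected if intergenic repeats promote
recombination-driven rearrangement.

The same is available from the shell:

```sh
mitorder reproduce-reference --seed 1
mitorder simulate --seed 7 --out sim/       # synthetic data set
mitorder goc --orders sim/gene_orders.tsv --tree sim/tree.nwk
mitorder trna-test --orders sim/gene_orders.tsv --n-perm 100000 --seed 1
```

## Layout

- `mitorder.gene_order` — GOC/GOL, adjacencies, breakpoint and DCJ distances
- `mitorder.io_formats` — gene-order TSV, GenBank import, fixtures, trees
- `mitorder.phylo` — tree wrapper (dendropy), root-independent branches
- `mitorder.decay_models` — patristic distances, the four decay models
- `mitorder.branch_gol` — bsGOL decomposition, rate normalization
- `mitorder.permutation_tests` — shuffle and tRNA clustering tests
- `mitorder.association_stats` — χ²/G²/Fisher/randomization, correlations
- `mitorder.synthetic_data` — the simulator
- `mitorder.pipeline`, `mitorder.cli` — orchestration and the `mitorder` CLI

See `docs/methods.md` for the models, assumptions, and design choices.
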