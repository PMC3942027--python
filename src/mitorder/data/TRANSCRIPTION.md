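# Packaged fixtures

`dikarya_species_stats.csv` — per-species summary for a 38-genome fungal
mitochondrial data set (nine basidiomycetes, 27 ascomycetes, two early
diverging outgroups). One row per taxon: cluster membership, branch-specific
gene-order loss (bsGOL), ML branch length (substitutions/site), bsGOL rate
columns, NPRS substitution rate (subs/site/Myr), and counts of tRNAs,
intronic ORFs, introns, whole-genome repeats, intergenic tandem repeats, and
genome size (bp). The `accession` column gives the NCBI RefSeq record each
row summarises. Values were transcribed by hand from the published summary
tables for this data set; digit groupings that were ambiguous in the source
layout were resolved against the per-cluster column totals in
`cluster_repeat_rearrangements.csv`, which they reproduce exactly (both with
and without the listed outlier species).

`cluster_repeat_rearrangements.csv` — per-cluster totals of intergenic
repeats (all species; excluding outlier species) and inferred rearrangement
events, for the seven fungal clusters.

`CHECKSUMS.sha256` — SHA-256 digests of both CSVs, verified by
`mitorder.pipeline.load_verified_fixtures` before any reproduction run.
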