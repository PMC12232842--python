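# nichecord

Does the tissue microenvironment change a cell type's transcriptional
profile — and does predicted ligand–receptor communication agree with
where cell types actually colocalize?

`nichecord` is a pipeline for analysts who pair dissociated single-cell
RNA-seq with spot-level spatial transcriptomics (Visium-style slides,
1–9 cells per spot).  It assigns single cells to spots, stratifies a
focal cell type into spatial groups, and then compares the groups at
three resolutions:

1. **Global profiles** — pairwise cosine distances between normalized
   expression vectors (within group, between groups, and against the
   background of all other types), compared with two-sample
   Kolmogorov–Smirnov tests.
2. **Single genes** — differential expression by tie-corrected Wilcoxon
   rank-sum (flag: linear FC > 1.5 and BH-adjusted p < 0.05) and by a
   pseudobulk negative-binomial Wald test on 3 summed pseudo-replicates
   per group (flag: |log2FC| > 1.5 and adjusted p < 0.05).
3. **Communication vs space** — a permutation ligand–receptor test
   (score = mean of ligand value in sender and receptor value in
   receiver, complexes as minimum over subunits, labels permuted over
   all cells, p = (1 + #{null ≥ obs}) / (n_perm + 1)), set against
   Jaccard colocalization of binary spot-presence profiles
   (J(A,B) = |spots(A) ∩ spots(B)| / |spots(A) ∪ spots(B)|).

The headline statistic is the **concordance** ρ: for each focal spatial
group, the Spearman rank correlation between its per-partner counts of
significant LR interactions and its per-partner Jaccard values.  A
subsampling control (10 datasets equalized to the smallest group) guards
against cell-count artifacts in the communication stage.

Because real paired datasets are large and external, the package ships a
first-class synthetic-data module: negative-binomial counts from
cell-type signatures on a spot lattice with labeled regions, planted
niche-dependent fold changes, and planted LR activity that is either
restricted to colocalized type pairs ("coupled") or independent of space
("decoupled").  Every pipeline stage is validated against this planted
truth.

## Worked example

Run the full pipeline on the coupled breast-like scenario (two tissue
blocks hosting the focal "tumor" type with different partner
compositions), then on its decoupled counterpart:

```sh
$ nichecord run-all --preset breast_like --coupling-mode coupled --seed 1 --out out_coupled
tumor@region_A: rho=0.859041213929178 (n=8)
tumor@region_B: rho=0.859041213929178 (n=8)
outputs in out_coupled

$ nichecord run-all --preset breast_like --coupling-mode decoupled --seed 1 --out out_decoupled
tumor@region_A: rho=-0.05421686746987951 (n=8)
tumor@region_B: rho=-0.09036144578313252 (n=8)
outputs in out_decoupled
```

When communication is planted only between colocalized types, the
concordance ρ over the 8 partner types is high (≈ 0.86 for both tumor
groups).  When the same planted communication intensities are spread
without regard to space, ρ collapses to ≈ 0 even though the LR test
itself is unchanged — spatially agnostic interaction counts carry no
colocalization signal, and the two tumor groups' per-partner counts
become almost perfectly correlated with each other instead
(`between_group_count_rho` ≈ 1.0 in `summary.json`).

`out_coupled/summary.json` also records, for the same run: 75
Wilcoxon-flagged and 49 pseudobulk-flagged niche-dependent genes (50
were planted, plus the planted LR genes which are genuinely
niche-dependent), 43 significant LR triples, and median within-group
cosine distances of 0.61 vs 0.64 between groups.  Tables written per
run: assignment, groups, distance samples, DEG tables, the full CCC
table, presence/Jaccard matrices, per-partner concordance tables, and a
run log.  Reruns with the same seed are byte-identical.

The same stages are available as a library (`nichecord.run_pipeline`,
or the individual modules `io_core`, `synthetic_data`,
`spatial_mapping`, `spatial_groups`, `niche_expression`, `ccc`,
`coloc`) and as per-stage subcommands (`simulate`, `map`, `snap`,
`group`, `deg`, `ccc`, `coloc`, `concord`).  External mapper or
communication outputs can be ingested as plain TSV at any stage.

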