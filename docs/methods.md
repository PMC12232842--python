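# Methods

`nichecord` asks two related questions about a cell type in a tissue:
does its transcriptional profile depend on its spatial niche, and do
predicted ligand–receptor (LR) interactions agree with where cell types
actually colocalize?  The pipeline chains six stages; each is described
below together with its assumptions, parameters and numerical choices.

## 1. Inputs and preprocessing

Counts are gene × cell (or gene × spot) integer matrices.
Normalization is counts-per-`target_sum` (default 10,000) followed by
log1p, natural log by default with a log2 option (some mapping tools
expect log2 units).  Cells with zero totals are kept as zero columns
with a warning so downstream set sizes stay predictable; a caller can
drop them explicitly.

Spot QC keeps spots with `qc_min_counts < total < qc_max_counts`
(defaults 5000/35,000, the usual Visium window) and mitochondrial
fraction ≤ 20% (genes matched by the configurable `MT-` id prefix),
then drops genes detected in fewer than 10 remaining spots.  Because
gene removal changes spot totals, QC is only guaranteed idempotent when
thresholds are not razor-thin against the data; the property is tested
on generated data where margins exist.

Highly variable genes are ranked by normalized dispersion: per-gene
variance/mean of `expm1(norm)`, standardized within equal-count bins of
mean expression.  Two numerical choices matter at small gene counts:
bins are merged until each holds ≥ 20 genes (otherwise the within-bin
spread is not estimable), and standardization uses median/MAD rather
than mean/SD — the high-dispersion outliers being selected must not
inflate their own bin's scale.  Ties at the cutoff break
lexicographically by gene id, making selection fully deterministic.

Ortholog translation is a plain two-column table: unmapped genes are
dropped (logged), many-to-one targets are collapsed by summing counts,
and a source listed with several targets keeps the first target in
table order.

## 2. Synthetic data with planted truth

The generator emulates a Visium-style experiment paired with a
dissociated single-cell run:

- a square lattice of spots (spacing 100 slide units) partitioned into
  named rectangular regions;
- per-type placement weights per region; each cell of a type picks a
  region with probability ∝ weight × region size, then spots fill to a
  capacity drawn uniformly from `cells_per_spot_range` (default 1–9,
  the Visium occupancy range).  Filling is spot-by-spot, so every
  occupied spot is within the range except possibly one boundary spot
  per region when the regional cell total does not divide;
- counts are negative binomial with mean μ and dispersion θ
  (variance μ + μ²/θ, one global θ, default 2).  Sampling is the
  gamma–Poisson mixture, vectorized;
- each type owns an exclusive marker block (default 10 genes) whose
  mean is multiplied by 2^`signature_strength` (default 2 → 4×);
  baseline means are log-normal around `base_expr` = 0.3;
- niche effects multiply the means of dedicated genes by 2^log2FC for
  cells of one type inside one region — these are the planted DEGs;
- LR interactions get dedicated ligand/receptor genes at a low baseline
  mean (0.03, so unplanted interactions sit below the 10% expression
  gate); an active edge multiplies the ligand mean in sender cells and
  the receptor mean in receiver cells by 2^`lr_strength` (default 4 →
  16×).  In **coupled** mode an edge is only activated when its sender
  and receiver entities share ≥ 1 spot under the true assignment — the
  same predicate the pipeline later estimates.  In **decoupled** mode
  activation ignores space entirely;
- spot expression is the sum of the constituent cells' counts plus
  optional Poisson extra counts (`noise`, default 0, so totals are
  conserved and testable).

Three presets mirror common tissue geometries. `breast_like`: two
tissue blocks, a focal "tumor" type split 45/45 between them, and seven
partner types whose region splits (90/0, 70/20, 50/40, 36/54, 22/68,
9/81, 0/90 of 90 cells) produce a graded, well-separated colocalization
profile on both sides.  In coupled mode the planted edges are
region-qualified with multiplicities 8/6/4/2 following that gradient;
in decoupled mode the edges are type-level with multiplicities whose
rank pattern ([3,6,2,7,1,5,4] over the partners) has exactly zero rank
correlation with the designed colocalization ordering — the decoupled
negative control is therefore a fixed property of the design, not a
coin flip over random shuffles.  `layered_like`: a focal type spanning
three contiguous bands with band-specific neighbors and three planted
band programs (15 genes at log2FC 2.5).  `node_like`: a compact
annotated region dominated by one type inside a surrounding tissue.

What the generator does **not** emulate: gene–gene correlation beyond
the planted programs, batch effects, doublets, spatial diffusion of
ligands, hexagonal Visium geometry (the lattice is square; all
spot-level logic is geometry-agnostic).  Passing tests therefore show
that the statistics recover planted structure under clean NB noise, not
that they are robust to every artifact of real tissue data.

## 3. Cell-to-spot assignment

`map_cells_to_spots` is an explicit, simplified stand-in for external
mapping tools: cost(cell, spot) = 1 − Pearson correlation of
log-normalized profiles over a gene subset (default: top 500 HVGs of
the spot matrix; Spearman optional), solved exactly as a minimum-cost
assignment on the capacity-expanded bipartite problem (each spot
duplicated once per unit of capacity, Hungarian algorithm).  Spot
capacities are proportional to spot totals,
`max(1, round(n_cells · total_i / Σ totals))`, with any rounding
deficit added to the largest-total spots.  Cells and spots are
processed in lexicographic id order so ties resolve deterministically.
Capacity expansion is O((cells + slots)³) and fine at desk scale; a
greedy flag exists for large instances and logs that optimality is not
guaranteed.  Externally produced assignment tables (from any mapper)
can be ingested instead at any point.  `snap_to_nearest_spot` converts
coordinate-valued mappings by Euclidean distance with a lexicographic
tie-break.

## 4. Spatial grouping of the focal type

Region mode: each focal cell inherits the region label of its assigned
spot; cells in unlabeled spots are excluded with a warning.

Co-expression mode (for tissues without clean region labels): a
Gaussian kernel K_ij = exp(−d²/2σ²) over focal-cell coordinates is
row-normalized and used to smooth each gene's per-cell vector;
modules are average-linkage clusters (cut at k, default 3; minimum
module size 10) of the Pearson correlation matrix of the smoothed
vectors.  Smoothing-then-correlation was chosen over kernel-weighted
covariance because its σ→0 limit is plain correlation (testable) and
it avoids degenerate normalization.  The σ default is the median
pairwise focal-cell distance; note that heavy smoothing induces
spurious correlations among noise genes (any smooth random field
correlates with another), so for banded tissue the bandwidth should sit
below the band width — the layered preset uses one lattice spacing.
Per-cell module activity is the mean normalized expression of the
module genes minus that of control genes drawn per module gene (100
controls, seeded) from the same average-expression bin (24 bins),
excluding the module's own genes; cells are labeled by argmax score
with ties to the lexicographically first module.  This is a deliberate
simplification of the full weighted co-expression toolkit: no
soft-thresholding power, topological overlap or dynamic tree cut.

## 5. Niche-dependent expression

Global profile comparisons use cosine distances (1 − cosine
similarity) between normalized profiles for within-group, between-group
and background (focal vs all other types) pair sets; zero vectors are
excluded with a warning; distributions are compared with the two-sample
Kolmogorov–Smirnov test (asymptotic p).

Gene-level tests:

- **Wilcoxon**: tie-corrected asymptotic rank-sum per gene on
  normalized values; log2FC = log2 of the ratio of mean `expm1(norm)`
  with a 1e-9 pseudo-count (making the statistic total);
  Benjamini–Hochberg over all genes.  Significance gate: linear fold
  change > 1.5 in either direction AND adjusted p < 0.05.
- **Pseudobulk NB Wald**: each group's cells are randomly partitioned
  (seeded) into 3 near-equal pseudo-replicates and raw counts summed.
  Size factors by median-of-ratios (total-count fallback when < 10% of
  genes are zero-free); per-gene dispersion by method of moments on
  normalized counts, pooled within groups, floored at 1e-8; Wald z from
  a two-group log-link NB GLM with offset log size factors; BH.  Gate:
  |log2FC| > 1.5 (log2 scale) AND adjusted p < 0.05.  This is a
  deliberately unshrunk test — no dispersion trend, no LFC shrinkage,
  no independent filtering — and parity with full reference
  implementations is a non-goal (a cross-check test confirms agreement
  of unshrunk fold changes in direction and rough size).

The two significance gates intentionally differ in scale (linear 1.5
vs log2 1.5): both conventions are in active use for the respective
tests and both are exposed as config keys (`fc_threshold`,
`lfc_threshold`).  Calibration note: under heavy sparsity (≥ ~60%
zeros) the asymptotic rank-sum p is slightly anticonservative in the
deep tail, which inflates the empirical FDR of the flag; the validation
simulations use moderately expressed genes (mean 1 count, θ = 5) where
the test is well calibrated.

## 6. Communication and concordance

The LR score of (sender, receiver, interaction) is the arithmetic mean
of the ligand value in the sender and the receptor value in the
receiver; a complex value is the minimum over subunits of the
group-mean normalized expression.  Gate: every subunit expressed in
> `expr_prop` (default 0.1) of the group's cells; groups below
`min_cells` (default 10) are excluded.  Significance: group labels are
permuted across all eligible cells `n_perm` (default 1000) times and
p = (1 + #{null ≥ observed}) / (n_perm + 1) — the add-one rule never
reports 0.  An exhaustive mode enumerates all two-group label
arrangements and uses the plain fraction (the observed arrangement is
included, so p > 0 without correction).  Autocrine pairs are scored by
the same rule.  Significant-interaction counts per (focal group,
partner) sum both directions by default (`direction_mode`), because a
single undirected count per pair is the common reporting convention;
sender-only and receiver-only modes exist.

Colocalization: a spot is scored 1 for a type if ≥ 1 cell is assigned
there; Jaccard similarity between type columns (focal spatial groups
appear as their own columns; empty-vs-empty pairs are defined as 0 and
flagged to avoid spurious perfect colocalization of absent types).  The
spot universe is the QC-filtered slide.  The concordance statistic is
the Spearman correlation (average ranks, t-approximation p with n−2 df
— partner lists are short) between a focal group's per-partner
significant-LR counts and its per-partner Jaccard values; the focal
group itself is never a partner, the sibling focal group is included by
default.  A subsampling control equalizes focal group sizes to the
minimum (10 seeded datasets, pairwise distinct by rejection sampling
capped at 1000 attempts) and re-runs the communication stage,
reporting min/median/max counts per partner.

`run_pipeline` chains all stages and writes every table, a JSON
summary and a run log; all randomness derives from one seed through
fixed-tag `SeedSequence` children, and reruns are byte-identical.

## Validation problem sizes

The validation suite and the acceptance script run entirely on
generated data at desk scale, chosen so each check completes in
seconds: 720-cell / 144-spot slides for the end-to-end controls,
2000 genes × 400 cells for DEG recovery and calibration, 500
interactions × 200 cells × 1000 permutations × 10 seeds for
permutation calibration, 50 exhaustive instances of ≤ 6 cells × 3 spots
for assignment optimality, and 60-cell two-cluster fields for module
recovery.

## Known limitations

- The assignment stand-in matches profiles by correlation only; it does
  not model per-spot mixing proportions and is not a substitute for a
  probabilistic deconvolution of real slides.
- Wald inference on 3 pseudo-replicates with moment dispersions is
  approximate; with very few replicates the normal reference slightly
  underestimates tail uncertainty for genes whose moment estimate hits
  the dispersion floor.
- The scoexp route assumes spatially coherent programs wider than the
  kernel bandwidth; σ is a real tuning decision, not a free parameter.
- Spearman p-values over ~8 partners are coarse; the qualitative
  positive/negative control separation, not the p-value, is the
  designed readout.
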