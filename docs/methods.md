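# Methods

This note records the models, parameter choices, numerical conventions
and known limitations behind `stromastage`. Nothing here states a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Single-cell processing

Counts are depth-normalized to a fixed scale `s = 10^4` and
log-transformed, `v(g,c) = log(1 + s·x(g,c)/depth(c))` — the common
single-cell convention; cells with zero depth map to zero columns with
a warning. PCA operates on genes standardized to zero mean and unit
variance (zero-variance genes dropped); components carry a
deterministic sign (largest-magnitude loading positive) so embeddings
are reproducible bit-for-bit. The defaults are 10 components for the
all-cell pass and 7 for the fibroblast re-clustering, where fewer
axes of variation remain.

Clustering is Louvain community detection (networkx, seeded) at
resolution 1 on a shared-nearest-neighbor graph: `k = 20` nearest
neighbors per cell (Euclidean in PC space), edges weighted by the
Jaccard overlap of neighborhoods. Community detection by modularity at
a fixed resolution has a well-known resolution limit: sufficiently
large *homogeneous* populations are split into shards, and because
the split is chosen from the data itself, the shards always exhibit
weak post-selection "markers" (|log2FC| around 0.5 in our
experiments), so a raw significance filter cannot tell them from real
subtypes. The pipeline therefore applies a selection-robust merge
step, `merge_indistinct_clusters`: cluster pairs are visited in order
of centroid distance and merged whenever no gene distinguishes them at
Benjamini–Hochberg-adjusted `p < 0.05` **and** `|log2FC| > 1`. The
effect-size condition is the load-bearing part: a cluster is kept only
if at least one gene differs ≥ 2-fold. Subtypes separated purely by
sub-twofold shifts are deliberately collapsed; the planted subclusters
(and the strongly marked CAF subtypes this emulates) differ ~5-fold
and are untouched.

Cell typing scores each cluster for each candidate type as the mean
gene-standardized expression of that type's markers over the cluster's
cells; the top type above `τ = 0.25` wins, a cluster exceeding `τ` for
both ductal marker sets receives the combined ductal label, and a
cluster above `τ` for nothing becomes `others`. `τ` and the combined-label rule are design
choices of this package; no quantitative standard exists for when a
cluster carries two ductal programs.

Marker calling is a two-sided Wilcoxon rank-sum per gene (cluster vs
rest, asymptotic with tie correction), `log2FC` from expm1-means with
pseudocount 1, the default marker filter `raw p < 0.05` and
`|log2FC| > 0.5` (the package's default cutoffs), with BH-adjusted
p-values reported alongside for modern practice.

## Ligand–receptor scoring

`S = E_L · E_R · f_L · f_R`, where expression is the mean
log-normalized value over *all* cells of the type (not only expressing
cells — the simplest defensible convention) and "expressing" means a strictly positive
normalized value. Reporting keeps fibroblast-side genes passing
expression ≥ 0.5 and fraction ≥ 5% (ligand side) or ≥ 10% (receptor
side), then the top 4 fibroblast genes by expression and top 3 cognate
genes per partner type; ties break lexicographically. The chord-plot
aggregation is emitted as a table: per (sender, receiver) pair of
types, categories covering at least 9% (ligand side) / 7% (receptor
side) of interactions, with summed `S`. No p-values are attached to
`S` by design.

## Preranked GSEA

The running sum increments by `|score|^p / Σ_set |score|^p` at set
members and decrements by `1/(N − |set|)` elsewhere; the enrichment
score is the extremum (on an exact `|max| = |min|` tie — a structural
possibility, e.g. a singleton set at the list midpoint — the negative
extremum is taken). Weight `p = 1` by default. The null is gene-label
permutation (random sets of the same size), matching preranked
practice since the ranked lists are precomputed. The p-value is
sign-conditional — a positive ES is compared only against non-negative
permutation ES values with +1 smoothing, and symmetrically — because a
one-sided p against the full mixed-sign null is *not* uniform under
the null (it stacks near 0.5); the sign-conditional construction is
what keeps the reported p-values calibrated, as the acceptance suite
verifies by KS test. NES divides ES by the mean |ES| of same-sign
permutations. The leading edge is the set members at or before the
running-sum maximum (at or after the minimum for negative ES).

## Within-set correlation test

For a gene set on a chosen cell population, every within-set pair
contributes `|Pearson r|` across cells; the background is every pair
of genes *outside* the set (mixed set–nonset pairs excluded: the
background is strictly outside pairs). Genes with variance below
1e-12 are dropped (guards float residue on constant genes). When the
background exceeds 10^6 pairs a uniform seeded subsample of pairs is
used. The contrast is a two-sided Welch t-test treating pairs as
independent observations; under a fully independent null, sample
correlations sharing a gene are asymptotically uncorrelated, and the
measured type-I error is nominal (the acceptance suite checks
[0.025, 0.075] at α = 0.05), but under strong dependence the test is
anti-conservative; treat its p-values as descriptive rather than
strictly calibrated in that regime. Both absolute and signed summaries are reported.

## Stage-pattern mining

Candidate model profiles over the `S` ordered stages are all integer
sequences starting at 0 with per-stage steps in `[-c, c]`, `c = 2`
(625 candidates for 5 stages), greedily collapsed to 50 maximally
distinct profiles under correlation distance, always retaining the
flat profile (constant genes need a home; a constant gene is assigned
there directly). Genes are assigned to the best-correlated profile
(ties to the lowest index). Significance per profile: each gene's
stage values are permuted over all `S! = 120` orderings (exact and
deterministic at 5 stages; random permutations only if `S! > 720`),
assignments accumulated into an expected fraction per profile, and the
observed count tested against a binomial upper tail, Bonferroni-
corrected across profiles. Because Pearson correlation is translation-
and scale-invariant, gentle and strong versions of the same shape
assign identically; shapes lying near the bisector of two panel
profiles can split a cohort between them, which is why cohort-level
claims are made on the modal profile.

## PPI subnetwork extraction

Starting from the connected components of the seed-induced subgraph,
the extraction repeatedly joins the two closest components by a
shortest path in the full graph of at most `max_linker_path` edges
(default 2 — at most one linker per bridge, since the signatures
connect with few linkers in practice), adding interior
path nodes as linkers. Ties between equally short paths break on the
lexicographically smallest path (BFS with sorted adjacency and
smallest-predecessor backtracking, fully deterministic). Seeds that
cannot be connected within the cap remain as isolated components of
the result rather than being dropped. This greedy merge is the package's own
design (no canonical linker-selection rule exists for this task); on
small graphs it stays
within twice the exhaustive Steiner optimum (asserted in the tests).
Density is `2E/n(n−1)` and clustering the mean local coefficient with
degree-<2 nodes contributing 0 (networkx conventions).

## Invasion quantification

Areas are shoelace areas of the traced ROI polygons (shapely);
`δArea_t = Area_t − Area_t0` and `⟨δArea_t⟩ = δArea_t/L_interface`.
The front profile evaluates, at each integer interface position, the
maximal extent of the ROI beyond the interface line (image
convention: y down, invasion in +y); uncovered positions are 0.
Smoothing is a centered 20-px moving mean with truncated windows at
the edges (no padding — padding would invent signal). A pixel is a
fork candidate when the smoothed profile exceeds the mean over up to
40 px on each side by more than `min_prominence = 2` px; maximal runs
of candidates collapse to the run midpoint (floored), with depth read
from the smoothed profile there. The prominence margin is a deliberate
extension of the bare larger-than-either-side rule: on a flat front
with pixel-scale tracing noise the bare rule fires on roughly a
quarter of positions (smoothed noise is correlated over the smoothing
window, producing long spurious runs), whereas genuine forks exceed
their side averages by tens of pixels; 2 px is far below one cell
diameter (~10–20 px at the emulated magnification) and
`min_prominence=0` restores the literal rule. Depths between
conditions are compared by a two-sided Mann–Whitney U test — exact for
tie-free samples with both n ≤ 20, normal approximation with tie
correction otherwise, and p = 1 directly for degenerate all-identical
input.

## Synthetic data

The generator's defaults are the study conditions. 35 patients — 11
normal, 24 tumor split 5/6/9/4 over IB/IIA/IIB/III — at 143 cells each
(~5,000 cells), over 1,200 genes. Counts are negative binomial
(gamma–Poisson) with gene-level dispersion `θ = 4` (variance
`μ + μ²/θ`, a realistic regime for UMI data at these means) around a
mean that multiplies: the cell type's baseline profile, a log-normal
cell size factor (σ = 0.25, mean 1), the fibroblast subcluster's
marker fold change, the per-stage trajectory multiplier, and the ELI
latent factor. Eleven planted cell types (fibroblasts at 40%) carry
12-gene programs at 8-fold; eight fibroblast subclusters carry 20-gene
programs at `log2` effect 2.5 — transcriptional programs of dozens of
genes, not just the canonical markers used for labeling. Subcluster
stage proportions are homogeneous at Normal (cluster 2, 86%) and IIA
(cluster 5, 80%) and diverse at IB/IIB/III, mirroring the stage
dynamics the pipeline must resolve; real marker symbols are used for
the planted biology (e.g. SPINK1/SERPINA1/CTHRC1 for the
pre-metastatic cluster 5 analog, MMP14/COL10A1/COL11A1/COL12A1 for the
pro-invasive cluster 4 analog, which additionally carries a 0.75-log2
ELI^up boost so enrichment analysis can find it).

The ELI co-expression structure is a single standard-normal latent
factor per set acting multiplicatively on the log-mean,
`exp(s·z_c − s²/2)`. The loading `s` is solved in closed form from NB
moments so that the *count-scale* pairwise correlation of two set
genes equals the requested `r` (default 0.2), after removing the share
contributed by the shared size factor: with `A = e^{s²} − 1`,
`corr = μ²A / (μ + μ²(A+1)/θ + μ²A)`. The calibration is exact on
counts (measured 0.205 and 0.514 for targets 0.2 and 0.5 at 3,000
cells in the test suite); Pearson correlation measured after log1p
normalization is substantially attenuated (a property of the
transform, not an error), which is why the generator's contract and
its property test are stated on counts.

Three trajectories are planted on fibroblasts: a pro-resistive cohort
(40 ELI^dn genes) rising until IIA and collapsing on stromal trespass
(multipliers 1/1.5/2.2/1.0/0.65), a sustained-rise ELI^up cohort, and
a smaller ELI^up cohort peaking at IIB. Multiplier ranges are kept
below the 2-fold merge threshold between co-occurring stages so stage
structure does not masquerade as subcluster structure.

The PPI generator overlays an Erdős–Rényi background (`p = 0.01`, 500
nodes) with exactly `⌈target·C(k,2)⌉` edges among the ELI genes
(target density 0.3 by default) and sparse cross edges (p = 0.02) that
provide linker candidates. The bulk cohort stands in for a
lymph-node-stratified patient set at quarter scale (29 N0 / 78 N1
samples, a quarter of the full-scale cohort it emulates), with ELI^dn
planted at
`log2FC = −0.8` and the pro-invasive subcluster markers at `+0.8` in
N1, dispersion 10 (bulk is far less dispersed than single cells). The
invasion generator grows triangular forks (half-width 30 px, ≥ 100 px
spacing, jittered even placement) linearly in time on a rectangular
cancer compartment, with additive Gaussian pixel noise on the front;
the default study compares a control (depth 50 px) against a
perturbed condition (depth 25 px) on a 2,000-px interface with 6
forks and σ = 2 px noise.

What the generator does *not* emulate: doublets, ambient RNA, batch
and patient effects, mitochondrial/QC structure, realistic gene-gene
regulatory networks, or curved/overhanging invasion fronts (profiles
are single-valued in the interface coordinate). Passing tests
therefore demonstrate correctness of the statistics and recoverability
of planted structure under a clean NB model — not robustness to those
real-data pathologies.

## Determinism and seeds

Every stochastic operation takes a seed; the pipeline fans one root
seed out to per-stage child seeds by fixed offsets, so a repeated run
is byte-identical (asserted at TSV level in the tests). Cluster ids
are relabeled densely by decreasing size with smallest-member
tie-break; all tie-breaks elsewhere (gene sort, path choice, profile
assignment) are lexicographic or lowest-index and documented at the
function level.

## Problem sizes

The default study uses ~5,000 cells × 1,200 genes, 500 + 100 PPI
nodes, a 2,000-px invasion interface, and 1,000 GSEA permutations;
calibration experiments use 400 null and 100 power simulations for
the correlation test, 200 label-permutation simulations for the
marker test, and 500 random sets / 500 permutations for GSEA null
uniformity. These sizes give stable estimates (binomial 3 s.e. bands
of roughly ±0.03 on a rate of 0.05) while keeping a full run in tens
of seconds on one CPU.
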