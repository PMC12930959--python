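# Methods

This note documents the models, conventions and numerical choices behind
`scdimorph`, in the order the pipeline runs them.

## Synthetic cohorts

The generator emulates a 2×2 design: sex-chromosome complement (XX, XY) ×
treatment (E2, vehicle), with cells assigned round-robin to three replicate
samples per arm and several labelled cell types. Counts for gene *g* in a
cell of type *t* are negative binomial with mean
`base_mean[g] · profile[t, g] · size_factor[cell]` and a dispersion θ shared
across genes (default 10) — the simplest overdispersed model matching
droplet data. Baseline means are log-uniform over `nb_mean_range` (default
0.1–5 expected counts); cell-type profiles are per-(type, gene) log-normal
modulations (SD 0.4 on the log scale) so cell types are genuinely distinct;
size factors are log-normal with CV 0.3 (mean fixed at 1) so the
normalization stage is exercised nontrivially. A configurable fraction of
genes is flagged mitochondrial and a small fraction of "damaged" cells
(default 2%) has those genes' means multiplied by 30, giving the QC filter
something real to remove.

Planted effects multiply the NB mean in the targeted (cell type, sex, E2)
arm only:

* **Shifts** raise the log-mean of `n_shifted_genes` randomly chosen genes
  by δ·σ_g, where σ_g = √(1/μ + 1/θ) is the delta-method approximation to
  the SD of log expression for that gene. δ is therefore expressed in the
  per-gene SD units the downstream z-scored distance test operates in. The
  identity "mean log-expression gap ≈ δ·σ_g" is exact only in the
  large-mean limit; the calibration test uses means of 10–50 counts where
  the approximation error is a few percent. At droplet-typical low means the
  planted shift is still monotone in δ but its magnitude on the log scale is
  attenuated.
* **DEG effects** multiply the mean by 2^log2FC for named genes.

All applied effects are recorded in `uns['truth']`; the number of truth
records equals the number of applied effects by construction. Identical
(config, seed) gives bit-identical cohorts. The generator does **not**
emulate ambient RNA, doublets, batch effects beyond size factors, or real
marker-gene structure — passing tests demonstrate statistical correctness
and power against the stated generative model, not robustness to every
artefact of real droplet data.

Network and marker-table generators follow the same pattern: a
Barabási–Albert scale-free-ish graph with one hub forced to a chosen degree
and Bernoulli DEG labels at separate rates inside and outside its
neighbourhood; marker association p-values Uniform(0,1) in the background
and Beta(1/(1+shift), 1) for a chosen enriched gene set (so shift 0 is
exactly the null), with markers chunked into LD blocks whose within-block
r² is drawn Uniform(0.75, 0.99).

## QC, normalization, HVGs, z-scoring

Cells are kept when detected genes lie in the inclusive range [200, 7000],
total UMI < 20,000 (strict) and mitochondrial fraction < 10% (strict); the
mixed inclusivity mirrors the interval notations the thresholds came with,
and all bounds are configurable. The filter is idempotent and reports the
failing criteria per removed cell.

Normalization is `ln(1 + count/total × 10,000)`; the log base and scale
factor are recorded in the result so downstream numbers are unambiguous.
The map is monotone within a cell and exactly invertible given cell totals.

HVG ranking follows the variance-stabilizing-transformation recipe: fit a
smooth trend of log10(variance) on log10(mean) over raw counts, standardize
each gene by its observed mean and trend-predicted SD, clip standardized
values at √n_cells, and rank by the variance of the clipped values. The
trend is a lowess (locally linear, span 0.3) fit when ≥ 200 informative
genes are available and a global degree-2 polynomial otherwise. Constant
genes are excluded outright; a relative-tolerance guard (var ≤ (mean²+1)·1e−10
⇒ 0) prevents floating-point cancellation from promoting constant genes.
Ties in standardized variance break by gene id, so selection is fully
deterministic.

Gene z-scoring uses the **population** SD (divide by n); zero-SD genes map
to all-zero columns.

## Euclidean shift test

For a cell type and a within-sex treatment contrast, cells of both groups
are pooled, z-scored per HVG across the pool (pooling is what makes the
permutation null exchangeable), and the observed statistic is the Euclidean
distance between the two group mean vectors. The null relabels cells at
random preserving group sizes; B = 5,000 by default. The empirical p is the
plain proportion of permuted distances ≥ observed (ties count toward the
numerator); an add-one variant exists but is off by default, so p = 0 is
possible. logFC = log10(observed) − log10(median null); a zero null median
(impossible with ≥ 2 distinct cells) yields an ±∞ sentinel plus a status
flag.

Implementation notes: permutation subsets are drawn over a canonical cell
order derived from a content hash of each z-score row, and always at the
smaller group's size (the complement gives the other group), which makes the
seeded p-value exactly invariant to cell order and to swapping the group
labels. Exact mode enumerates all C(n, k) assignments and is allowed up to a
configurable cap (default 100,000). Groups under 10 cells are reported as
skipped, not errors. Scan rows get child seeds from
SeedSequence(root, crc32(cell_type|contrast)), so a row's p-value does not
depend on which other rows are scanned. BH FDR runs across all tested rows;
significance is FDR < 0.05.

## Differential expression and concordance

Wilcoxon rank-sum (two-sided) on log-normalized values, restricted to genes
with raw count > 0 in ≥ 10% of cells of either group; Bonferroni over the
genes actually tested (filter-then-test order); significance at adjusted
p < 0.05; Gm42418 and AY036118 excluded by default as known technical
artefacts. When both groups have ≤ 8 cells the p-value comes from exhaustive
enumeration of all C(n, n_A) rank assignments with midranks (exact under
ties); otherwise from the tie-corrected continuity-corrected normal
approximation, vectorized over genes. avg_log2FC =
log2[(mean(expm1 x_A)+ε)/(mean(expm1 x_B)+ε)], ε = 1e−9, with A the
treatment side, so positive means up under E2. The priority score is
|avg_log2FC| × (−log10(p_adj + 1e−300)); the floor keeps the score finite
(450 per unit log2FC) when p_adj underflows.

The concordance partition places every gene from either sex's DEG list into
exactly one of eight sets (concordant up/down, XX-only up/down, XY-only
up/down, two discordant patterns); within each set genes are ordered by
their maximum priority across sexes and the top 10 reported.

Cell-fraction ANOVA uses type-II sums of squares (a superset of the balanced
design), partial η² = SS_effect/(SS_effect+SS_error), TukeyHSD over the four
sex×treatment arms, and BH across cell types within each effect. A cell type
with identical fractions everywhere is reported as F = 0, p = 1 rather than
NaN; zero residual variance with a real effect reports F = ∞, p = 0.

## Stratified RRHO

Both rankings are restricted to shared genes and ordered by the signed score
−log10(p)·sign(effect) (p floored at 1e−300; ties broken by gene id). The
grid step defaults to max(1, ⌊N/100⌋), capping the map at roughly 100×100.
Each grid cell compares two threshold sets: in concordant quadrants both
sets grow from the matching list ends (top/top or bottom/bottom); in
discordant quadrants one from each end — equivalently, every quadrant's scan
is anchored at the lists' sign changes, which is what "stratified" means
here. The cell value is −log10 of the smaller hypergeometric tail (over- vs
under-enrichment), positive for overlap excess, negative for depletion.
Overlap counts come from a cumulative 2-D rank histogram, so the full map is
O(N + grid²). Swapping the lists transposes the map; order- and
sign-preserving rescaling of scores leaves it unchanged.

## Gene-set and marker-set enrichment

Hypergeometric upper-tail tests with Bonferroni over the sets tested; the
enrichment score is (k/n)/(K/N) with N the number of genes detected in the
cohort after QC. Pathway calls need p.adj < 0.01 **and** overlap ≥ 20; the
TF mode needs p.adj < 0.05 only. The same engine serves both — they differ
only in the library file and pass rule. Enriched TFs are partitioned into
direct vs indirect estrogen-receptor regulation by intersection with an
ER-target list.

Marker dependency filtering processes markers in descending association
score (ties by marker id) and keeps a marker iff its r² with every kept
marker is ≤ 0.70; only within-block pairs can be linked, and a missing
within-block r² is an error, never silently treated as independent.

MSEA uses ten tail quantiles of the global score distribution
{0.50, 0.60, 0.70, 0.80, 0.85, 0.90, 0.95, 0.98, 0.99, 0.999} and
X = Σ_j (O_j − E_j)/√(E_j + κ) with κ = 1; both grid and κ are parameters.
The null permutes gene-to-set membership (uniform gene draws of the same set
size, preserving each gene's marker count), which guards against LD and
marker-multiplicity confounding — the same concern MDF addresses. The
permutation p uses the add-one convention, (1 + #{X_perm ≥ X})/(1 + n_perm),
because MSEA p-values are compared across many sets under BH and a literal 0
would be unstable; this deliberately differs from the shift test's plain
convention. With the query equal to all mapped genes, O_j equals the global
count and X = 0 identically.

## Key-driver analysis

Neighbourhoods are all nodes within `depth` edges (default 1), direction
ignored, self excluded. For each node with ≥ 5 neighbours (smaller
neighbourhoods give unstable statistics; such nodes are reported, not
dropped silently): O = DEG neighbours, E = m·D/V, X = (O − E)/√(E + κ),
κ = 1, one-sided — the simplest stabilized standardized-excess statistic in
the χ²-like family; exponent and κ are configurable and logged. The null
re-draws the D DEG labels uniformly over the V nodes (not degree-preserving
rewiring: the question is about DEG assignment, and a rewiring mode would
test a different null). p uses the add-one convention; BH runs across scored
nodes; key drivers are FDR < 0.05. Note the interaction between the add-one
floor 1/(n_perm+1) and the BH rank-1 cutoff 0.05/n_scored: detecting a
single driver among ~150 scored nodes needs n_perm ≳ 3,000 — the validation
suite uses 6,000. Edge weights are ignored by default; a weighted mode
(weight-scaled O and m) exists but is off because no canonical weighting
formula is adopted here.

## Orchestration and problem sizes

The `run` command executes qc → normalize → hvg → sensitivity → deg →
concordance → rrho → fractions → enrich → kda → msea, each toggleable, all
seeds derived from one root seed, every output TSV accompanied by a
provenance sidecar (config hash + seed) and a run log with per-stage row
counts. Unknown config keys are rejected. Reruns with the same config are
bit-identical.

The validation suite runs at desk scale as a deliberate choice of problem
size: null calibration uses 200 cohorts of 5 cell types × 100 cells/arm with
200 genes and B = 400; shift recovery uses 50 cohorts of 3 cell types ×
500 cells/arm with 200 shifted genes among 2,000 HVGs; DEG recovery uses 100
planted effects at |log2FC| = 1 with 200 cells/group; KDA uses 500-node
graphs with a 50-neighbour hub at 80% vs 10% DEG rates over 50 seeds; MSEA
uses 300-gene marker tables with a 50-gene Beta(0.2, 1)-enriched set over 50
seeds. These sizes give the binomial margins the assertions need while
keeping each check to minutes.

## Known limitations

* The lowess trend in HVG selection is locally linear, not the degree-2
  loess some ecosystems use; rankings can differ slightly near the
  mean–variance curve's extremes.
* The χ²-like statistic's exact constants (κ, exponent, quantile grid) are
  declared package defaults within the named statistic family, not values
  transcribed from any external tool; users comparing against other KDA/MSEA
  implementations should align these knobs first.
* The plain b/B p-value of the shift test can be exactly 0; downstream BH
  treats it as the smallest value. Use the add-one mode when zeros are
  unacceptable.
* Between-LD-block marker correlation is assumed zero; real panels with
  long-range LD should pre-compute blocks accordingly.
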