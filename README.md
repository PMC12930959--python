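# scdimorph

Quantifying **sex- and cell-type-specific transcriptomic responses to a
treatment** in single-cell RNA-seq data.

Hormone treatments (here: 17β-estradiol, E2, versus vehicle, V) can remodel a
tissue's transcriptome differently in XX and XY animals, and differently in
each cell type. `scdimorph` is a tested, reusable implementation of the
analysis chain needed to dissect such a 2×2 (sex-chromosome complement ×
treatment) single-cell design:

1. **QC and normalization** — cells kept with 200–7,000 detected genes,
   < 20,000 UMIs and < 10% mitochondrial reads; counts are depth-normalized
   to 10,000 and natural-log transformed.
2. **Transcriptomic sensitivity** — for each cell type and sex, the Euclidean
   distance between E2 and V mean profiles over the top 2,000 z-scored
   highly variable genes (VST ranking), tested against a null of B = 5,000
   random relabellings: `p = #{d_perm ≥ d_obs}/B`,
   `logFC = log10(d_obs) − log10(median d_perm)`, BH FDR across rows.
3. **Differential expression** — per cell type, two-sided Wilcoxon rank-sum
   E2 vs V within each sex (10% expression filter, Bonferroni < 0.05,
   Gm42418/AY036118 excluded), ranked by the priority score
   `|avg.log₂FC| × (−log₁₀(p.adj + 10⁻³⁰⁰))`, and an eight-way cross-sex
   concordance partition (concordant / sex-specific / discordant, by
   direction).
4. **Stratified RRHO** — rank–rank hypergeometric overlap of the two sexes'
   signed rankings `−log₁₀(p) × sign(effect)`, scan anchored at each list's
   sign change.
5. **Enrichment** — hypergeometric gene-set tests with enrichment score
   GeneRatio/BackgroundRatio (pathways: p.adj < 0.01 and overlap ≥ 20;
   TF-target sets: p.adj < 0.05) plus an estrogen-receptor-target partition
   of enriched TFs.
6. **Key-driver analysis** — every network node scored by the standardized
   excess of DEGs among its neighbours, `X = (O − E)/√(E + κ)`, with a
   label-permutation null and BH FDR.
7. **Marker-set enrichment (MSEA)** — GWAS-style markers LD-pruned at
   r² ≤ 0.70, then a χ²-like tail-quantile statistic with a gene-permutation
   null tests whether markers of a DEG set carry stronger trait association
   than random gene sets.
8. **Cell fractions** — two-way ANOVA (sex × treatment, type-II SS) with
   partial η², TukeyHSD over the four arms, BH across cell types.

A first-class **synthetic cohort generator** (negative-binomial counts,
log-normal size factors, planted shifts / DEGs / network hubs /
trait-enriched gene sets with recorded ground truth) drives validation:
every statistical claim in the test suite is checked against planted truth
or an independent enumeration oracle.

## Worked example

```python
from scdimorph import (SimConfig, ShiftSpec, generate_cohort, lognormalize,
                       select_hvg_vst, sensitivity_scan)

cfg = SimConfig(seed=2, cell_types=("ASPC", "Mac"), cells_per_group=200,
                n_genes=400, nb_mean_range=(10, 50), mito_gene_fraction=0.0,
                damaged_cell_fraction=0.0,
                shift=ShiftSpec(cell_types=("ASPC",), sex="XX",
                                n_genes=100, delta=1.0))
cohort = generate_cohort(cfg)           # shift planted in XX ASPC cells only
norm = lognormalize(cohort)
hvg = select_hvg_vst(cohort, n_hvg=300)
table = sensitivity_scan(norm, hvg, B=300, seed=5)
print(table[["cell_type", "contrast", "empirical_p", "logfc", "fdr", "significant"]])
```

prints

```
  cell_type   contrast  empirical_p     logfc   fdr  significant
0      ASPC  XXE.v.XXV     0.000000  0.631672  0.00         True
1      ASPC  XYE.v.XYV     0.223333  0.014347  0.44        False
2       Mac  XXE.v.XXV     0.330000  0.008551  0.44        False
3       Mac  XYE.v.XYV     0.680000 -0.009206  0.68        False
```

Only the arm carrying the planted shift (XX ASPC) shows an observed distance
far above its permutation null (empirical p = 0, logFC ≈ 0.63, i.e. the
observed distance is ~4.3× the null median); the three unshifted rows are
indistinguishable from their nulls.

The same chain is available from the shell:

```bash
scdimorph simulate --out cohort/ --seed 1
scdimorph sensitivity --counts cohort/ --out sensitivity.tsv --seed 1
scdimorph run --outdir results/        # full pipeline on the default cohort
```

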