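# cotransmit

Analysis toolkit for detecting **combinatorial (multi-neurotransmitter)
neuron populations** in single-nucleus RNA-seq, and for screening
genotype × treatment effects on their transcriptomes. It is aimed at
groups studying midbrain (e.g. ventral tegmental area) neuron diversity
in 2×2 designs — knockout vs wild-type crossed with a drug challenge —
with a few biological replicates per arm.

The package bundles a ground-truth snRNA-seq simulator, so every stage of
the pipeline can be exercised and validated end-to-end without any external
data.

## What it computes

**Coexpression proportion.** For a gene pair (a, b) and a cluster *c* of
cells with log-normalized expression *x*,

    P_c(a, b) = |{ i ∈ c : x_ai > 0 ∧ x_bi > 0 }| / |c|

A cluster is called **combinatorial** when some pair of markers drawn from
*two different* neurotransmitter systems has P_c > 0.20 (strict). The
default panel covers three systems: GABA (*Slc6a1, Slc32a1, Gad1, Gad2*),
dopamine (*Ddc, Th, Slc18a2, Slc6a3*) and glutamate (*Slc17a6, Slc17a7,
Grm2*). Cluster identities are named by dominance order of per-system
expressing fractions (e.g. `GLU>DA`), and genotype differences in
coexpression are tested by permuting cell labels within the cluster.

**Resolution selection.** Leiden partitions are computed for resolutions
0.1–1.0 (step 0.1) on a shared-nearest-neighbor graph. The chosen
resolution is `min(plateau, max_valid)` where the *plateau* is the smallest
resolution whose modularity-Q increase falls below 10% of the largest
per-step increase, and *max_valid* is the largest resolution at which every
cluster still has a marker gene with cluster-vs-rest AUROC > 0.6 (markers
pre-filtered at min.pct 0.25 and |log FC| 0.25, Wilcoxon rank-sum,
Bonferroni per cluster).

**Pseudo-bulk two-way ANOVA.** Counts of a cell subset are summed per
sample and normalized to log2(1+CPM); each gene is decomposed into
genotype, treatment and interaction effects. Effect sizes use partial eta
squared, η²ₚ = SS_effect / (SS_effect + SS_residual); the screen keeps
genes with *P* < 0.05 **and** η²ₚ ≥ 0.06 (medium), tagging η²ₚ ≥ 0.14 as
large.

**Composition comparison.** Per-sample cluster fractions are compared
between groups with an exact (or Monte-Carlo) permutation test of the
sample-to-group assignment, Benjamini–Hochberg adjusted across cell types.

## Worked example

The bundled demo config simulates 4,800 cells (12 samples: WT/KO ×
saline/nicotine × 3 replicates) over four planted neuron subtypes. The
`GLU-DA` subtype carries planted GLU–DA coexpression of 0.30 in WT,
reduced to 0.10 by the knockout.

```sh
cotransmit all --config configs/demo.toml --out results/demo
# or stage by stage:
python analysis/01_simulate.py
python analysis/03_cluster_resolution.py
python analysis/06_pseudobulk_anova.py
```

Output of the final stage:

```
# Pipeline summary

- cells after QC: 4492
- chosen clustering resolution: 0.2 (5 clusters)
- combinatorial clusters (> 20% cross-system coexpression): 4 (DA>GLU)
- coexpression WT_S - KO_S in cluster 4: difference +0.422, p = 0.000999000999
- composition differences at FDR: none
- pseudo-bulk ANOVA effect genes: genotype 39, treatment 51, interaction 34
```

Reading this: QC removed 308 of 4,800 cells (doublets, mito-fraction and
depth violations); the modularity plateau picked resolution 0.2; the cells
coexpressing glutamatergic and dopaminergic markers resolve into their own
cluster (labelled `DA>GLU`), the only cluster passing the 20% combinatorial
rule on the WT_S reference group; within it, knockout cells show a 0.42
lower coexpression proportion (cell-permutation p ≈ 0.001, the smallest
value attainable with 1,000 permutations); and the gene-wise 2×2 ANOVA
gate passes a few dozen genes per effect, consistent with the planted
treatment/genotype/interaction genes plus the expected false-positive mass
at n = 3 per design cell.

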