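# Methods

## Scope and model

The package analyses sparse gene × cell count matrices from a 2×2
genotype (WT/KO) × treatment (saline/nicotine) snRNA-seq design with
biological replicates, and asks three questions: which neuron clusters
coexpress markers of more than one neurotransmitter system; whether the
knockout changes that coexpression; and which genes respond to genotype,
treatment, or their interaction at the replicate level. All statistics
operate on log-normalized expression, `ln(1 + s·count/total)` per cell with
scale factor `s = 10⁴`; "expressed" always means a strictly positive
log-normalized value, with no minimum-count option in the default path.

## Synthetic data generator

The simulator is first-class: it defines the conditions under which every
downstream claim is tested.

* **Count law.** Gene-wise negative binomial (Gamma–Poisson) with a shared
  dispersion θ (default 2), the standard overdispersed model for UMI-based
  snRNA-seq. Per-cell library-size factors are lognormal (log-mean 0,
  log-SD 0.25), multiplying all gene means of a cell.
* **Cluster structure.** Each planted cluster has a background mean
  profile: shared Gamma(1.5, 1)-distributed gene means plus a
  cluster-specific program of 40 genes upweighted 4-fold, so clusters are
  separable in PCA independently of their neurotransmitter markers.
* **Coexpression planting.** Within a cluster, each cell latently belongs
  to a subset of neurotransmitter systems. The joint distribution over
  membership patterns is fitted by iterative proportional fitting to the
  configured per-system expressing fractions and pairwise coexpression
  targets (validated against the Fréchet bounds; infeasible targets raise
  a configuration error naming the cluster and pair). Markers of a system
  have mean 25 in member cells and exactly zero elsewhere, which makes the
  planted coexpression a countable ground truth. At mean 25 and θ = 2 the
  per-gene dropout is ≈0.6%, so a planted pair target of 0.30 realizes
  ≈0.296 — the detection loss is kept well inside the ±3·binomial-SE
  recovery band rather than compensated for.
* **Effects.** Genotype modifiers multiply system fractions and pair
  targets in KO samples (the bundled demo lowers GLU–DA coexpression
  0.30 → 0.10 together with the GLU fraction 0.75 → 0.60, keeping the
  joint feasible). Group-dependent effect genes multiply a gene's mean in
  chosen design cells, encoding treatment main effects (equal multiplier
  in both nicotine arms) and genotype:treatment interactions (multiplier in
  one arm only).
* **Doublets** are sums of two distinct parent cells' count vectors,
  appended and flagged; they are consumed by QC as flags, mirroring a
  workflow where doublet prediction happens upstream.
* **Seeding.** One root seed spawns one child per sample plus one for the
  shared gene structure, so adding samples never changes earlier ones; the
  same config and seed give byte-identical output.

What the generator does **not** emulate: ambient RNA, batch effects,
spatial structure, realistic full-transcriptome marker atlases, or
continuous (graded) marker expression — membership is binary, so marker
structure is sharper than in tissue. Passing tests therefore demonstrate
correctness of the statistics and recoverability of planted effects at
these noise levels, not performance on any particular real dataset.

## QC, normalization, embedding

Removal criteria are strict inequalities (<300 or >6,000 detected genes,
<500 total counts, >1% mitochondrial counts, doublet flag), so cells
exactly at a boundary are retained. The mitochondrial fraction is a
fraction of *counts* (the standard reading), detected by the mouse `mt-`
gene-name prefix, case-insensitive; if no such genes exist the criterion is
skipped with a warning. Scaling z-scores each gene with the sample SD
(ddof 1), zeroes constant genes, and clips at ±10. PCA keeps 16 components
by default — exposed as a config field, not auto-selected; the elbow-based
choice is treated as an analyst decision. The exact full-SVD solver is
used up to 600 cells/genes, the seeded randomized solver above that.

## Clustering and resolution selection

The neighbor graph is a union-symmetrized kNN graph (k = 20 by default) in
PCA space with shared-neighbor Jaccard weights (neighbor sets include the
node itself, so every kNN edge has positive weight). Partitions come from
Leiden with the RB-configuration objective at each sweep resolution;
modularity is always *reported* at unit gamma (Newman–Girvan) so Q values
are comparable across the sweep.

The chosen resolution is `min(plateau, max_valid)`:

* plateau — the smallest resolution whose ΔQ to the next one is below
  `plateau_frac` (default 0.1) of the maximum ΔQ in the sweep; if no step
  qualifies, the last resolution; if Q never increases, the first. On
  noise-flat Q profiles (homogeneous data) the noise step that happens to
  be largest decides which early resolution is picked; any such pick is a
  single-cluster partition, but it is not guaranteed to be literally the
  first resolution.
* max_valid — the longest prefix of the sweep in which every cluster has a
  pre-filter-passing marker with AUC > 0.6. A single-cluster partition is
  vacuously valid; a cluster with fewer than 3 cells on either side of the
  split invalidates its resolution.

Marker statistics follow the common single-cell convention: genes tested if
expressed in ≥25% of either side and |log FC| ≥ 0.25 (log FC as difference
of `ln(1 + mean(expm1 x))`), two-sided Wilcoxon rank-sum with tie-corrected
normal approximation, AUC as the midrank Mann–Whitney U divided by
n_in·n_out, and a Bonferroni multiplier equal to the number of genes tested
*for that cluster* (recorded in the table metadata).

## Coexpression statistics

The pairwise coexpression matrix per cluster has single-gene expressing
fractions on the diagonal; the combinatorial call requires a strictly
greater than 0.20 proportion for a *cross-system* pair. In the pipeline,
classification and identity naming are evaluated on the reference
condition (default `WT_S`): a genotype that suppresses coexpression should
not mask a cluster's combinatorial character, and downstream genotype
comparisons would otherwise be conditioned on their own effect. Identity
labels order systems by the fraction of cells expressing ≥1 of the
system's markers, keeping systems at ≥0.2 (the combinatorial threshold
mirrored, since no sharper convention exists) and joining with `>`;
exact ties order alphabetically and are flagged.

Genotype differences use a cell-label permutation test on the mean
per-pair proportion difference (two-sided, add-one corrected; the pair set
defaults to all cross-system pairs and is restricted to the identity's two
leading systems in the pipeline). Add-one two-sided permutation p-values
on a proportion statistic are *conservative* at small group sizes — the
statistic lives on a 1/n grid, and ties at the observed value inflate p —
approaching uniformity as the grid becomes fine relative to the null SD
(group sizes in the thousands). The test suite checks both regimes:
uniformity (KS) at n = 1,500 per group and conservativeness at n = 80.

## Composition comparison

Per-type differences of mean per-sample fractions are tested by permuting
the sample-to-group assignment — exact enumeration when at most 200
assignments exist, otherwise Monte-Carlo with add-one correction — with BH
adjustment across cell types. The replicate, not the cell, is the unit.
With 3v3 samples the exact two-sided test enumerates C(6,3) = 20
assignments, so the smallest attainable p is 2/20 = 0.1; a planted
abundance drop is therefore "recovered" when its type attains that minimum
and shows the largest absolute difference, and no claim at FDR 0.05 is
possible at this replicate count. The procedure that produced each p is
recorded in the output row.

## Pseudo-bulk ANOVA

Counts are summed per sample over the chosen cell subset (the pipeline
selects clusters whose identity contains GLU, the glutamatergic
compartment) and normalized to log2(1+CPM) — summation first, normalization
second, so deep cells do not dominate. For the balanced 2×2 design the
sums of squares come from the closed-form cell-mean decomposition (Types
I/II/III coincide); unbalanced designs fall back to Type II via
full-vs-reduced least squares. η²ₚ = SS_effect/(SS_effect+SS_residual);
the identity η²ₚ = F·df_e/(F·df_e + df_err) holds to numerical precision
and is asserted in tests. The effect gate applies η²ₚ ≥ 0.06 inclusively
(source conventions differ between > and ≥ at the boundary; the inclusive
reading is recorded in the output metadata). No multiple-testing correction
is applied to the ANOVA p-values by default — the effect-size gate is the
guard — but a BH option is exposed. Note that with df = (1, 8), any gene
with p < 0.05 already has η²ₚ ≥ 0.40, so the gate's false-pass rate equals
the nominal test size at this design; the gate bites at larger replicate
counts.

For calibrated recovery experiments, a replicate-level generator plants
pure-interaction patterns (+d, −d, −d, +d over the four design cells) on
normal noise; with d = σ the population effect is Cohen's f² = 1, i.e.
true η²ₚ = 0.5 under the λ = f²·N noncentrality convention, giving the
interaction F-test ≈86% power at α = 0.05 with 3 replicates per cell.

## Pipeline and reproducibility

One TOML config drives all stages; a single root seed feeds the
simulator, PCA, Leiden and every permutation test. Rerunning a config
reproduces all tables byte-for-byte (the log carries wall-clock timings
and is excluded). The manifest records the package version, seed and
config SHA-256. Stage commands (`cotransmit qc|cluster|...`) recompute
their cheap upstream stages deterministically from the config rather than
caching intermediates on disk. Problem sizes in the bundled demo — 4,800
cells, 800 genes, 12 samples — were chosen so the full pipeline and the
recovery experiments each complete in well under a minute on one CPU while
keeping every per-cluster statistic comfortably inside its sampling
tolerance.

## Known limitations

* Binary latent system membership makes combinatorial subpopulations more
  transcriptionally distinct than in tissue; at realistic depths the
  clustering may resolve the coexpressing cells as their own cluster (as
  the demo does), which is a property of the data, not a failure of the
  selection rule.
* The permutation comparison treats cells within a cluster as exchangeable
  across genotypes; replicate-level variation in coexpression is not
  modelled (a replicate-aware variant would need more animals per arm).
* The composition test cannot reach FDR 0.05 with 3 samples per group (see
  above); it reports effect direction and the attainable minimum instead.
* No batch integration: samples are assumed technically homogeneous, as in
  the simulator.
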