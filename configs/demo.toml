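# Bundled demonstration run: 12-sample 2x2 design (WT/KO x saline/nicotine,
# 3 replicates), four planted neuron subtypes, one combinatorial GLU-DA
# cluster with a KO coexpression drop (0.30 -> 0.10), planted treatment,
# genotype and interaction effect genes.

[pipeline]
seed = 0

[simulation]
preset = "demo"
n_cells_per_sample = 400
n_genes = 800
doublet_rate = 0.05

[qc]
min_genes = 300
max_genes = 6000
min_counts = 500
max_mito_frac = 0.01
drop_doublets = true

[normalize]
scale_factor = 1e4
clip = 10.0

[cluster]
n_components = 16
k = 20
res_min = 0.1
res_max = 1.0
res_step = 0.1
auc_threshold = 0.6
plateau_frac = 0.1

[coexpression]
threshold = 0.20
reference_group = "WT_S"
identity_floor = 0.2
n_perm = 1000
compare = [["WT_S", "KO_S"]]

[composition]
n_perm = 10000
fdr = 0.05
compare = [["WT_S", "KO_S"]]

[anova]
identity_contains = "GLU"
p_max = 0.05
pes_min = 0.06
pes_large = 0.14
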