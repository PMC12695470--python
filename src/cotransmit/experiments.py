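"""Planted-truth recovery experiments at the bundled study conditions.

Each function simulates data with a known planted structure, runs the
corresponding analysis path of the package, and reports recovery metrics.
They define *fixed* study conditions (cell numbers, planted effect sizes,
replicate counts mirroring the 2x2 three-replicate design); only the seed
varies between runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cotransmit import cluster as cl
from cotransmit import coexpression as cx
from cotransmit import composition as cp
from cotransmit import io_qc
from cotransmit.pseudobulk import filter_effects, two_way_anova
from cotransmit.synthetic import (
    ClusterSpec,
    SimConfig,
    build_baseline_means,
    simulate_experiment,
    simulate_pseudobulk_table,
)

__all__ = [
    "combinatorial_detection_experiment",
    "genotype_effect_experiment",
    "interaction_screen_experiment",
    "resolution_selection_experiment",
    "composition_recovery_experiment",
]


def _specs(params, n_genes: int, seed: int, de_fold: float = 4.0, n_de: int = 40):
    baselines = build_baseline_means(
        n_genes=n_genes,
        n_clusters=len(params),
        mito_gene_count=0,
        n_marker_genes=len(cx.DEFAULT_PANEL.genes),
        seed=seed,
        de_fold=de_fold,
        n_de_genes=n_de,
    )
    return [
        ClusterSpec(
            name=name,
            fraction=frac,
            baseline_mean=baselines[i],
            system_expression=expr,
            coexpression_target=pairs,
            genotype_modifier=mod,
        )
        for i, (name, frac, expr, pairs, mod) in enumerate(params)
    ]


def _singlet_norm(config: SimConfig):
    counts, meta, truth = simulate_experiment(config)
    keep = ~meta["doublet"].to_numpy()
    counts = counts.subset_cells(keep)
    meta = meta.loc[keep].reset_index(drop=True)
    return io_qc.lognormalize(counts), meta, counts


# ---------------------------------------------------------------------------


def _combinatorial_config(seed: int, n_cells: int = 5000) -> SimConfig:
    """One 5,000-cell sample; the COMB cluster carries GLU-DA coexpression
    0.30, every other cluster's planted cross-system coexpression is <= 0.05."""
    params = [
        ("COMB", 0.30, {"GLU": 0.75, "DA": 0.40, "GABA": 0.02}, {"GLU|DA": 0.30}, {}),
        ("GLU", 0.30, {"GLU": 0.80, "DA": 0.04, "GABA": 0.02}, {"GLU|DA": 0.03}, {}),
        ("GABA", 0.20, {"GABA": 0.85, "GLU": 0.05, "DA": 0.02}, {"GABA|GLU": 0.04}, {}),
        ("DA", 0.20, {"DA": 0.80, "GLU": 0.05, "GABA": 0.03}, {"DA|GLU": 0.04}, {}),
    ]
    n_genes = 60
    return SimConfig(
        n_cells_per_sample=n_cells,
        n_genes=n_genes,
        samples=[("S1", "WT", "S")],
        cluster_spec=_specs(params, n_genes, seed),
        seed=seed,
    )


def combinatorial_detection_experiment(
    seed: int = 0, n_reps: int = 50, n_cells: int = 5000, threshold: float = 0.20
) -> dict:
    """Replicate-level recovery of the planted combinatorial cluster.

    A replicate succeeds when the COMB cluster — and no other — is
    classified combinatorial by the strict >20% cross-system rule applied
    to the planted (truth) cluster labels.
    """
    root = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    successes = 0
    planted_props = []
    for rep_seed in root:
        config = _combinatorial_config(int(rep_seed), n_cells)
        norm, meta, _ = _singlet_norm(config)
        labels = meta["truth_cluster"].to_numpy()
        profile = cx.coexpression_matrix(norm, labels)
        calls = cx.classify_combinatorial(profile, threshold=threshold)
        called = set(calls.loc[calls["combinatorial"], "cluster"])
        successes += called == {"COMB"}
        planted_props.append(
            float(
                calls.set_index("cluster").loc["COMB", "best_proportion"]
            )
        )
    return {
        "n_reps": n_reps,
        "n_success": successes,
        "success_rate": successes / n_reps,
        "mean_planted_proportion": float(np.mean(planted_props)),
    }


# ---------------------------------------------------------------------------


def _genotype_config(seed: int, effect: bool, n_cells_per_group: int = 500) -> SimConfig:
    mod = (
        {
            "system_expression": {"GLU": 0.8},
            "coexpression_target": {"GLU|DA": 1.0 / 3.0},
        }
        if effect
        else {}
    )
    params = [("C", 1.0, {"GLU": 0.75, "DA": 0.40}, {"GLU|DA": 0.30}, mod)]
    n_genes = 40
    return SimConfig(
        n_cells_per_sample=n_cells_per_group,
        n_genes=n_genes,
        samples=[("WT_S_1", "WT", "S"), ("KO_S_1", "KO", "S")],
        cluster_spec=_specs(params, n_genes, seed, de_fold=1.0, n_de=0),
        seed=seed,
    )


def genotype_effect_experiment(
    seed: int = 0,
    n_reps_effect: int = 50,
    n_reps_null: int = 200,
    n_cells_per_group: int = 500,
    n_perm: int = 199,
) -> dict:
    """Power and size of the coexpression permutation test.

    Effect replicates plant a WT 0.30 -> KO 0.10 GLU-DA coexpression drop
    (with the matching GLU expressing-fraction reduction); success is
    p < 0.01 with a positive (WT minus KO) difference. Null replicates
    plant no genotype effect and count rejections at alpha = 0.05.
    """
    ss = np.random.SeedSequence(seed)
    eff_seeds = ss.generate_state(n_reps_effect + n_reps_null) % (2**31)

    def one(rep_seed: int, effect: bool) -> dict:
        config = _genotype_config(rep_seed, effect, n_cells_per_group)
        norm, meta, _ = _singlet_norm(config)
        labels = meta["truth_cluster"].to_numpy()
        return cx.compare_coexpression(
            norm, labels, meta, "C",
            group_a="WT_S", group_b="KO_S",
            systems=("GLU", "DA"), n_perm=n_perm, seed=int(rep_seed),
        )

    detected = 0
    diffs = []
    for rep_seed in eff_seeds[:n_reps_effect]:
        res = one(int(rep_seed), True)
        diffs.append(res["difference"])
        detected += (res["p"] < 0.01) and (res["difference"] > 0)
    null_reject = 0
    for rep_seed in eff_seeds[n_reps_effect:]:
        res = one(int(rep_seed), False)
        null_reject += res["p"] <= 0.05
    return {
        "n_reps_effect": n_reps_effect,
        "n_detected": int(detected),
        "power": detected / n_reps_effect,
        "mean_difference": float(np.mean(diffs)),
        "n_reps_null": n_reps_null,
        "null_rejection_rate": null_reject / n_reps_null,
    }


# ---------------------------------------------------------------------------


def interaction_screen_experiment(
    seed: int = 0,
    n_planted: int = 200,
    n_null: int = 2000,
    effect_d: float = 1.0,
) -> dict:
    """Sensitivity / false-pass rate of the p < 0.05 AND pes >= 0.06 gate.

    Planted genes carry a pure genotype:treatment interaction with a true
    partial eta squared of 0.5 (Cohen's f^2 = 1) at n = 3 replicates per
    design cell; null genes are noise.
    """
    pb, planted = simulate_pseudobulk_table(
        n_null_genes=n_null, n_planted=n_planted, effect_d=effect_d, seed=seed
    )
    anova = two_way_anova(pb)
    hits = set(filter_effects(anova)["interaction"].index)
    planted_set = set(planted)
    sens = len(hits & planted_set) / n_planted
    null_pass = len(hits - planted_set) / n_null
    return {
        "n_planted": n_planted,
        "n_null": n_null,
        "sensitivity": sens,
        "null_pass_rate": null_pass,
        "true_partial_eta_sq": effect_d**2 / (effect_d**2 + 1.0),
    }


# ---------------------------------------------------------------------------


def _four_blob_config(seed: int, n_cells: int = 1600) -> SimConfig:
    params = [
        ("A", 0.25, {"GLU": 0.95, "DA": 0.02, "GABA": 0.02}, {}, {}),
        ("B", 0.25, {"GABA": 0.95, "GLU": 0.02, "DA": 0.02}, {}, {}),
        ("C", 0.25, {"DA": 0.95, "GLU": 0.02, "GABA": 0.02}, {}, {}),
        ("D", 0.25, {"GLU": 0.02, "DA": 0.02, "GABA": 0.02}, {}, {}),
    ]
    n_genes = 300
    return SimConfig(
        n_cells_per_sample=n_cells,
        n_genes=n_genes,
        samples=[("S1", "WT", "S")],
        cluster_spec=_specs(params, n_genes, seed, de_fold=6.0, n_de=40),
        seed=seed,
    )


def _homogeneous_config(seed: int, n_cells: int = 800) -> SimConfig:
    params = [("only", 1.0, {"GLU": 0.9, "DA": 0.02, "GABA": 0.02}, {}, {})]
    n_genes = 200
    return SimConfig(
        n_cells_per_sample=n_cells,
        n_genes=n_genes,
        samples=[("S1", "WT", "S")],
        cluster_spec=_specs(params, n_genes, seed, de_fold=1.0, n_de=0),
        seed=seed,
    )


def resolution_selection_experiment(seed: int = 0) -> dict:
    """Dual-criterion resolution choice on planted structure.

    Four well-separated clusters must be recovered exactly (every cluster
    keeping a marker with AUC > 0.6 at the chosen resolution); homogeneous
    data must select the lowest resolution of the sweep.
    """
    from sklearn.metrics import adjusted_rand_score

    def run(config: SimConfig):
        norm, meta, _ = _singlet_norm(config)
        scaled = io_qc.scale_genes(norm)
        emb = io_qc.pca(scaled, n_components=16, seed=config.seed)
        graph = cl.build_knn_graph(emb, k=20)
        sweep = cl.cluster_sweep(graph, seed=config.seed)
        choice = cl.select_resolution(sweep, norm)
        labels = sweep.labels[choice.chosen_resolution]
        return choice, labels, meta["truth_cluster"].to_numpy()

    choice4, labels4, truth4 = run(_four_blob_config(seed))
    n_clusters = int(labels4.max() + 1)
    ari = float(adjusted_rand_score(truth4, labels4))
    choice1, labels1, _ = run(_homogeneous_config(seed))
    return {
        "four_blob_n_clusters": n_clusters,
        "four_blob_ari": ari,
        "four_blob_resolution": float(choice4.chosen_resolution),
        "homogeneous_resolution": float(choice1.chosen_resolution),
        "lowest_resolution": 0.1,
    }


# ---------------------------------------------------------------------------


def composition_recovery_experiment(
    seed: int = 0,
    wt_neuron_fraction: float = 0.30,
    ko_neuron_fraction: float = 0.15,
    n_cells: int = 2000,
) -> dict:
    """Replicate-aware composition comparison on a planted abundance drop.

    Three WT and three KO samples; the neuron fraction drops from 0.30 to
    0.15 under KO with low multinomial noise. With 3v3 samples the exact
    two-sided permutation test enumerates C(6,3) = 20 assignments, so the
    smallest attainable p is 2/20 = 0.1; recovery is therefore measured as
    the neuron type attaining that minimum and ranking first.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g, frac in (("WT", wt_neuron_fraction), ("KO", ko_neuron_fraction)):
        other = np.array([0.5, 0.3, 0.2]) * (1 - frac)
        p = np.array([frac, *other])
        for r in range(3):
            counts = rng.multinomial(n_cells, p)
            for t, n in zip(("neuron", "astro", "oligo", "micro"), counts):
                rows.extend(
                    {
                        "cell_id": f"{g}_S_{r}_{t}_{i}",
                        "sample": f"{g}_S_{r + 1}",
                        "group": f"{g}_S",
                        "cluster": t,
                    }
                    for i in range(n)
                )
    meta = pd.DataFrame(rows)
    table = cp.composition_table(meta)
    res = cp.compare_composition(table, "WT_S", "KO_S", seed=seed)
    res = res.set_index("cell_type")
    return {
        "neuron_difference": float(res.loc["neuron", "difference"]),
        "neuron_p": float(res.loc["neuron", "p"]),
        "min_attainable_p": 2 / 20,
        "neuron_ranks_first": bool(
            res.loc["neuron", "p"] <= res["p"].min() + 1e-12
            and res["difference"].abs().idxmax() == "neuron"
        ),
        "n_assignments": 20,
    }
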