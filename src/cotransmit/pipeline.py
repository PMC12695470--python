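"""End-to-end orchestration: simulate -> QC -> cluster -> coexpression ->
composition -> ANOVA, from one TOML config, with a reproducibility manifest.

Every stage writes plain TSV/JSON under the output directory; rerunning
with the same config and seed reproduces the tables byte for byte (the log
carries wall-clock timings and is the one file excluded from that
guarantee). A stage failure leaves partial outputs in place next to a
``FAILED`` marker naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import cotransmit
from cotransmit import cluster as cl
from cotransmit import coexpression as cx
from cotransmit import composition as cp
from cotransmit import io_qc, synthetic
from cotransmit.pseudobulk import filter_effects, pseudobulk as make_pseudobulk, two_way_anova
from cotransmit.errors import ConfigurationError, PipelineError

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

__all__ = ["PipelineConfig", "run_pipeline", "report_summary"]

STAGES = ("simulate", "qc", "cluster", "coexpression", "composition", "anova")


@dataclass
class PipelineConfig:
    """Validated settings for every stage, plus the root seed."""

    seed: int = 0
    sim: synthetic.SimConfig | None = None
    input_dir: Path | None = None
    qc: io_qc.QCThresholds = field(default_factory=io_qc.QCThresholds)
    scale_factor: float = 1e4
    clip: float = 10.0
    n_components: int = 16
    knn_k: int = 20
    resolutions: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.1, 1.01, 0.1), 10)
    )
    auc_threshold: float = 0.6
    plateau_frac: float = 0.1
    min_pct: float = 0.25
    logfc_min: float = 0.25
    panel: cx.MarkerPanel = field(default_factory=lambda: cx.DEFAULT_PANEL)
    coexpr_threshold: float = 0.20
    coexpr_reference_group: str | None = "WT_S"
    identity_floor: float = 0.2
    coexpr_compare: list[tuple[str, str]] = field(default_factory=lambda: [("WT_S", "KO_S")])
    coexpr_n_perm: int = 1000
    comp_compare: list[tuple[str, str]] = field(default_factory=lambda: [("WT_S", "KO_S")])
    comp_n_perm: int = 10_000
    comp_fdr: float = 0.05
    anova_identity_contains: str = "GLU"
    anova_p_max: float = 0.05
    anova_pes_min: float = 0.06
    anova_pes_large: float = 0.14
    raw_config_text: str = ""

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        text = path.read_text()
        data = tomllib.loads(text)
        pipe = data.get("pipeline", {})
        seed = int(pipe.get("seed", 0))
        cfg = cls(seed=seed, raw_config_text=text)
        simd = data.get("simulation")
        if simd is not None:
            if simd.get("preset") == "demo":
                cfg.sim = synthetic.demo_config(
                    seed=int(simd.get("seed", seed)),
                    n_cells_per_sample=int(simd.get("n_cells_per_sample", 400)),
                    n_genes=int(simd.get("n_genes", 800)),
                    doublet_rate=float(simd.get("doublet_rate", 0.05)),
                )
            else:
                simd = dict(simd)
                simd.setdefault("seed", seed)
                cfg.sim = synthetic.SimConfig.from_dict(simd)
        if "input_dir" in pipe:
            cfg.input_dir = Path(pipe["input_dir"])
            for fname in ("matrix.mtx", "genes.tsv", "barcodes.tsv", "cell_meta.tsv"):
                if not (cfg.input_dir / fname).exists():
                    raise ConfigurationError(f"input_dir is missing {fname}")
        if cfg.sim is None and cfg.input_dir is None:
            raise ConfigurationError(
                "config must provide a [simulation] section or pipeline.input_dir"
            )
        qc = data.get("qc", {})
        cfg.qc = io_qc.QCThresholds(
            min_genes=int(qc.get("min_genes", 300)),
            max_genes=int(qc.get("max_genes", 6000)),
            min_counts=int(qc.get("min_counts", 500)),
            max_mito_frac=float(qc.get("max_mito_frac", 0.01)),
            drop_doublets=bool(qc.get("drop_doublets", True)),
        )
        norm = data.get("normalize", {})
        cfg.scale_factor = float(norm.get("scale_factor", 1e4))
        cfg.clip = float(norm.get("clip", 10.0))
        clu = data.get("cluster", {})
        cfg.n_components = int(clu.get("n_components", 16))
        cfg.knn_k = int(clu.get("k", 20))
        lo = float(clu.get("res_min", 0.1))
        hi = float(clu.get("res_max", 1.0))
        step = float(clu.get("res_step", 0.1))
        cfg.resolutions = np.round(np.arange(lo, hi + step / 2, step), 10)
        cfg.auc_threshold = float(clu.get("auc_threshold", 0.6))
        cfg.plateau_frac = float(clu.get("plateau_frac", 0.1))
        cfg.min_pct = float(clu.get("min_pct", 0.25))
        cfg.logfc_min = float(clu.get("logfc_min", 0.25))
        co = data.get("coexpression", {})
        if "panel" in co:
            cfg.panel = cx.MarkerPanel({s: tuple(g) for s, g in co["panel"].items()})
        cfg.coexpr_threshold = float(co.get("threshold", 0.20))
        ref = co.get("reference_group", "WT_S")
        cfg.coexpr_reference_group = ref if ref else None
        cfg.identity_floor = float(co.get("identity_floor", 0.2))
        cfg.coexpr_n_perm = int(co.get("n_perm", 1000))
        if "compare" in co:
            cfg.coexpr_compare = [tuple(p) for p in co["compare"]]
        comp = data.get("composition", {})
        cfg.comp_n_perm = int(comp.get("n_perm", 10_000))
        cfg.comp_fdr = float(comp.get("fdr", 0.05))
        if "compare" in comp:
            cfg.comp_compare = [tuple(p) for p in comp["compare"]]
        an = data.get("anova", {})
        cfg.anova_identity_contains = str(an.get("identity_contains", "GLU"))
        cfg.anova_p_max = float(an.get("p_max", 0.05))
        cfg.anova_pes_min = float(an.get("pes_min", 0.06))
        cfg.anova_pes_large = float(an.get("pes_large", 0.14))
        return cfg


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def stage(self, name: str, elapsed: float, **params) -> None:
        kv = " ".join(f"{k}={v}" for k, v in params.items())
        self.lines.append(f"stage={name} elapsed_s={elapsed:.2f} {kv}".strip())
        self.path.write_text("\n".join(self.lines) + "\n")


def run_pipeline(config: PipelineConfig, out_dir, upto: str = "anova") -> dict:
    """Run all stages up to and including ``upto``; return in-memory results.

    Raises :class:`PipelineError` (after writing a ``FAILED`` marker) if a
    stage fails; validation errors surface before any computation.
    """
    if upto not in STAGES:
        raise ConfigurationError(f"unknown stage {upto!r}; expected one of {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    log = _Log(out / "pipeline.log")
    results: dict = {"out_dir": out}
    last = STAGES.index(upto)

    manifest = {
        "package": "cotransmit",
        "version": cotransmit.__version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.raw_config_text.encode()).hexdigest(),
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    _json_dump(manifest, out / "manifest.json")

    def run_stage(name: str, fn) -> None:
        t0 = time.perf_counter()
        try:
            params = fn()
        except Exception as exc:
            failed_marker.write_text(f"stage={name}\nerror={exc}\n")
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        log.stage(name, time.perf_counter() - t0, **(params or {}))

    # -- simulate / load ----------------------------------------------------
    def stage_simulate():
        if config.sim is not None:
            counts, meta, truth = synthetic.simulate_experiment(config.sim)
            data_dir = out / "data"
            synthetic.write_experiment(counts, meta, truth, data_dir)
            _write_tsv(synthetic.truth_report(truth), data_dir / "truth_report.tsv")
            results["truth"] = truth
            params = {"n_cells": counts.n_cells, "n_genes": counts.n_genes, "seed": config.sim.seed}
        else:
            d = config.input_dir
            counts = io_qc.read_counts(d / "matrix.mtx", d / "genes.tsv", d / "barcodes.tsv")
            meta = pd.read_csv(d / "cell_meta.tsv", sep="\t")
            params = {"n_cells": counts.n_cells, "n_genes": counts.n_genes, "source": str(d)}
        results["counts"], results["meta"] = counts, meta
        return params

    run_stage("simulate", stage_simulate)
    if last == 0:
        return results

    # -- qc + normalize + pca ----------------------------------------------
    def stage_qc():
        counts, meta, report = io_qc.qc_filter(results["counts"], results["meta"], config.qc)
        _write_tsv(report.to_frame(), out / "qc_report.tsv")
        (out / "qc_report.json").write_text(report.to_json() + "\n")
        norm = io_qc.lognormalize(counts, config.scale_factor)
        scaled = io_qc.scale_genes(norm, config.clip)
        emb = io_qc.pca(scaled, config.n_components, seed=config.seed)
        results.update(counts_qc=counts, meta_qc=meta, norm=norm, embedding=emb, qc_report=report)
        return {"cells_in": report.cells_in, "cells_out": report.cells_out,
                "n_components": config.n_components}

    run_stage("qc", stage_qc)
    if last == 1:
        return results

    # -- clustering + resolution selection ----------------------------------
    def stage_cluster():
        graph = cl.build_knn_graph(results["embedding"], k=config.knn_k)
        sweep = cl.cluster_sweep(graph, config.resolutions, seed=config.seed)
        choice = cl.select_resolution(
            sweep,
            results["norm"],
            auc_threshold=config.auc_threshold,
            plateau_frac=config.plateau_frac,
            min_pct=config.min_pct,
            logfc_min=config.logfc_min,
        )
        labels = sweep.labels[choice.chosen_resolution]
        meta = results["meta_qc"].copy()
        meta["cluster"] = labels.astype(str)
        _write_tsv(sweep.to_frame(), out / "sweep.tsv")
        _json_dump(
            {
                "chosen_resolution": choice.chosen_resolution,
                "plateau_candidate": choice.plateau_candidate,
                "max_valid_resolution": choice.max_valid_resolution,
                "validity": {str(k): bool(v) for k, v in choice.validity.items()},
                "rationale": choice.rationale,
                "n_clusters": int(labels.max() + 1),
            },
            out / "resolution_choice.json",
        )
        markers = []
        for c in np.unique(labels):
            ms = cl.marker_stats(results["norm"], labels, c,
                                 min_pct=config.min_pct, logfc_min=config.logfc_min)
            ms.insert(0, "cluster", str(c))
            markers.append(ms)
        _write_tsv(pd.concat(markers, ignore_index=True), out / "markers.tsv")
        _write_tsv(meta, out / "cell_meta_clustered.tsv")
        sims = cl.cluster_similarity(results["norm"], labels, meta["group"].to_numpy())
        sim_rows = []
        for cond, mat in sims.items():
            tidy = mat.stack().rename("pearson_r").reset_index()
            tidy.columns = ["cluster_a", "cluster_b", "pearson_r"]
            tidy.insert(0, "condition", cond)
            sim_rows.append(tidy)
        _write_tsv(pd.concat(sim_rows, ignore_index=True), out / "cluster_similarity.tsv")
        results.update(graph=graph, sweep=sweep, choice=choice, labels=labels, meta_clustered=meta)
        return {"chosen_resolution": choice.chosen_resolution, "n_clusters": int(labels.max() + 1)}

    run_stage("cluster", stage_cluster)
    if last == 2:
        return results

    # -- coexpression --------------------------------------------------------
    def stage_coexpression():
        norm, labels = results["norm"], results["labels"]
        meta = results["meta_clustered"]
        # combinatorial classification and identity naming are evaluated on
        # the reference condition (default WT_S), so a genotype effect on
        # coexpression does not mask a cluster's combinatorial character
        ref = config.coexpr_reference_group
        if ref is not None and (meta["group"] == ref).any():
            ref_mask = (meta["group"] == ref).to_numpy()
        else:
            ref_mask = np.ones(len(meta), dtype=bool)
        norm_ref = io_qc.NormalizedMatrix(
            norm.values[:, ref_mask], norm.gene_ids, norm.cell_ids[ref_mask],
            scale_factor=norm.scale_factor,
        )
        labels_ref = labels[ref_mask]
        profile = cx.coexpression_matrix(norm_ref, labels_ref, config.panel)
        calls = cx.classify_combinatorial(profile, config.coexpr_threshold)
        identities = {}
        tie_flags = {}
        for c in profile.matrices:
            ident, scores, tie = cx.name_identity(
                norm_ref, labels_ref, c, config.panel, floor=config.identity_floor
            )
            identities[c] = ident
            tie_flags[c] = tie
        calls = calls.copy()
        calls["identity"] = [identities[c] for c in calls["cluster"]]
        calls["identity_tie"] = [tie_flags[c] for c in calls["cluster"]]
        calls["n_cells_reference"] = [profile.cluster_sizes[c] for c in calls["cluster"]]
        calls = calls.sort_values("cluster", kind="mergesort")
        _write_tsv(profile.to_frame(), out / "coexpression.tsv")
        _write_tsv(calls, out / "combinatorial.tsv")
        _write_tsv(profile.cross_system_summary(), out / "coexpression_systems.tsv")
        comp_rows = []
        for ga, gb in config.coexpr_compare:
            for c in calls.loc[calls["combinatorial"], "cluster"]:
                ident = identities[c]
                top2 = tuple(ident.split(">")[:2]) if ">" in ident else None
                try:
                    res = cx.compare_coexpression(
                        norm, labels, meta, c, config.panel,
                        group_a=ga, group_b=gb, systems=top2,
                        n_perm=config.coexpr_n_perm, seed=config.seed,
                    )
                except Exception as exc:
                    comp_rows.append({"cluster": str(c), "group_a": ga, "group_b": gb,
                                      "difference": np.nan, "p": np.nan, "note": str(exc)})
                    continue
                comp_rows.append({"cluster": str(c), "group_a": ga, "group_b": gb,
                                  "difference": res["difference"], "p": res["p"],
                                  "note": f"pairs={len(res['per_pair'])}"})
        _write_tsv(pd.DataFrame(comp_rows,
                                columns=["cluster", "group_a", "group_b", "difference", "p", "note"]),
                   out / "coexpression_comparison.tsv")
        results.update(profile=profile, combinatorial=calls, identities=identities)
        return {"n_combinatorial": int(calls["combinatorial"].sum())}

    run_stage("coexpression", stage_coexpression)
    if last == 3:
        return results

    # -- composition ---------------------------------------------------------
    def stage_composition():
        meta = results["meta_clustered"]
        table = cp.composition_table(meta, label_col="cluster")
        _write_tsv(table, out / "composition.tsv")
        _write_tsv(table.attrs["group_summary"], out / "composition_summary.tsv")
        comps = []
        for ga, gb in config.comp_compare:
            res = cp.compare_composition(
                table, ga, gb, n_perm=config.comp_n_perm, seed=config.seed, fdr=config.comp_fdr
            )
            res.insert(0, "group_a", ga)
            res.insert(1, "group_b", gb)
            comps.append(res)
        comp = pd.concat(comps, ignore_index=True)
        _write_tsv(comp, out / "composition_comparison.tsv")
        results.update(composition=table, composition_comparison=comp)
        return {"n_significant": int(comp["significant"].sum())}

    run_stage("composition", stage_composition)
    if last == 4:
        return results

    # -- pseudo-bulk ANOVA ----------------------------------------------------
    def stage_anova():
        meta = results["meta_clustered"]
        identities = results["identities"]
        target = config.anova_identity_contains
        chosen = {str(c) for c, ident in identities.items() if target in ident}
        subset = meta["cluster"].isin(chosen).to_numpy()
        if not subset.any():
            chosen = {str(c) for c in identities}
            subset = np.ones(len(meta), dtype=bool)
        pb = make_pseudobulk(
            results["counts_qc"], meta, subset,
            subset_label=f"clusters {sorted(chosen)} (identity contains {target!r})",
        )
        anova = two_way_anova(pb)
        effects = filter_effects(
            anova, p_max=config.anova_p_max, pes_min=config.anova_pes_min,
            pes_large=config.anova_pes_large,
        )
        _write_tsv(anova.reset_index(), out / "anova.tsv")
        counts = {}
        for eff, sel in effects.items():
            (out / f"effects_{eff}.txt").write_text(
                "".join(f"{g}\t{t}\n" for g, t in zip(sel.index, sel["tier"]))
            )
            counts[eff] = len(sel)
        results.update(pseudobulk=pb, anova=anova, effects=effects)
        return {"subset_cells": int(subset.sum()), **{f"n_{k}": v for k, v in counts.items()}}

    run_stage("anova", stage_anova)

    summary = _build_summary(results, config)
    _json_dump(summary, out / "summary.json")
    (out / "summary.md").write_text(report_summary(summary))
    results["summary"] = summary
    return results


def _build_summary(results: dict, config: PipelineConfig) -> dict:
    calls = results["combinatorial"]
    comp = results["composition_comparison"]
    effects = results["effects"]
    comparison = pd.read_csv(results["out_dir"] / "coexpression_comparison.tsv", sep="\t")
    return {
        "seed": config.seed,
        "cells_after_qc": int(results["qc_report"].cells_out),
        "chosen_resolution": float(results["choice"].chosen_resolution),
        "n_clusters": int(results["labels"].max() + 1),
        "combinatorial_clusters": {
            str(r["cluster"]): r["identity"]
            for _, r in calls.iterrows()
            if r["combinatorial"]
        },
        "coexpression_comparisons": [
            {k: (None if pd.isna(v) else v) for k, v in row.items()}
            for row in comparison.to_dict("records")
        ],
        "composition_significant_types": [
            str(t) for t in comp.loc[comp["significant"], "cell_type"]
        ],
        "effect_gene_counts": {eff: int(len(sel)) for eff, sel in effects.items()},
    }


def report_summary(summary: dict | Path) -> str:
    """One-page markdown summary; numbers are read from the stage outputs."""
    if isinstance(summary, (str, Path)):
        path = Path(summary)
        if path.is_dir():
            path = path / "summary.json"
        if not path.exists():
            missing = [
                s for s in STAGES
                if not any(Path(path.parent).glob(f"*{s}*"))
            ]
            return "# Pipeline summary\n\nIncomplete bundle; missing stages: " + ", ".join(missing or ["summary"])
        summary = json.loads(path.read_text())
    lines = [
        "# Pipeline summary",
        "",
        f"- cells after QC: {summary['cells_after_qc']}",
        f"- chosen clustering resolution: {summary['chosen_resolution']} "
        f"({summary['n_clusters']} clusters)",
        f"- combinatorial clusters (> {100 * 0.20:.0f}% cross-system coexpression): "
        + (
            ", ".join(f"{c} ({i})" for c, i in summary["combinatorial_clusters"].items())
            or "none"
        ),
    ]
    for row in summary["coexpression_comparisons"]:
        if row.get("difference") is None:
            continue
        lines.append(
            f"- coexpression {row['group_a']} - {row['group_b']} in cluster "
            f"{row['cluster']}: difference {row['difference']:+.3f}, p = {row['p']}"
        )
    lines.append(
        "- composition differences at FDR: "
        + (", ".join(summary["composition_significant_types"]) or "none")
    )
    eff = summary["effect_gene_counts"]
    lines.append(
        f"- pseudo-bulk ANOVA effect genes: genotype {eff.get('genotype', 0)}, "
        f"treatment {eff.get('treatment', 0)}, interaction {eff.get('interaction', 0)}"
    )
    lines.append("")
    return "\n".join(lines)
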