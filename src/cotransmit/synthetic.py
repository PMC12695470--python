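"""Seed-reproducible snRNA-seq simulator with planted ground truth.

The generator emulates a 12-sample 2x2 design (genotype WT/KO x treatment
S/N, 3 replicates each) of midbrain neurons. Counts follow a gene-wise
negative-binomial (Gamma-Poisson) law with a shared dispersion and per-cell
lognormal library-size factors. Each planted cluster carries:

* background expression from its ``baseline_mean`` profile (with
  cluster-specific upweighted identity genes so clusters are separable);
* neurotransmitter-system structure: each cell latently "belongs" to a set
  of systems drawn from a joint distribution fitted (iterative proportional
  fitting) to the configured per-system expressing fractions and planted
  pairwise coexpression targets; marker genes of a system have nonzero mean
  only in member cells, which makes the planted coexpression countable;
* genotype modifiers (multiplicative, applied to KO samples) on system
  fractions and coexpression targets;
* group-dependent effect genes (``interaction_genes``): any gene can carry
  a per-group mean multiplier, encoding treatment main effects and
  genotype:treatment interactions.

Doublets are sums of two random parent cells' count vectors, appended and
flagged. Mitochondrial genes are the first ``mito_gene_count`` genes, named
with the mouse ``mt-`` prefix so QC can find them.

One root seed fans out to per-sample child seeds (plus one for the shared
gene structure), so adding samples never changes earlier ones.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from cotransmit.coexpression import DEFAULT_PANEL, MarkerPanel
from cotransmit.errors import ConfigurationError
from cotransmit.io_qc import CountMatrix, write_counts
from cotransmit.pseudobulk import PseudobulkTable

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

__all__ = [
    "ClusterSpec",
    "SimConfig",
    "simulate_experiment",
    "truth_report",
    "write_experiment",
    "demo_config",
    "simulate_pseudobulk_table",
]

GROUPS = ("WT_S", "KO_S", "WT_N", "KO_N")


def _pair_key(a: str, b: str) -> str:
    return "|".join(sorted((a, b)))


@dataclass
class ClusterSpec:
    """One planted neuron subtype.

    ``system_expression`` gives, per neurotransmitter system, the fraction
    of the cluster's cells expressing that system's markers;
    ``coexpression_target`` plants the joint fraction for system pairs
    (key ``"A|B"``). ``genotype_modifier`` holds multiplicative KO changes:
    ``{"system_expression": {...}, "coexpression_target": {...}}``.
    """

    name: str
    fraction: float
    baseline_mean: np.ndarray
    system_expression: dict[str, float] = field(default_factory=dict)
    coexpression_target: dict[str, float] = field(default_factory=dict)
    genotype_modifier: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.baseline_mean = np.asarray(self.baseline_mean, dtype=float)
        if (self.baseline_mean < 0).any():
            raise ConfigurationError(f"cluster {self.name}: baseline_mean has negative entries")
        self.coexpression_target = {
            _pair_key(*k.split("|")) if isinstance(k, str) else _pair_key(*k): v
            for k, v in self.coexpression_target.items()
        }

    def effective(self, genotype: str) -> tuple[dict[str, float], dict[str, float]]:
        """System fractions and pair targets after the genotype modifier."""
        expr = dict(self.system_expression)
        pairs = dict(self.coexpression_target)
        if genotype == "KO":
            for s, m in self.genotype_modifier.get("system_expression", {}).items():
                expr[s] = expr.get(s, 0.0) * m
            for k, m in self.genotype_modifier.get("coexpression_target", {}).items():
                k = _pair_key(*k.split("|")) if isinstance(k, str) else _pair_key(*k)
                pairs[k] = pairs.get(k, 0.0) * m
        for s, v in expr.items():
            if not 0 <= v <= 1:
                raise ConfigurationError(
                    f"cluster {self.name}: system_expression[{s}]={v} outside [0,1]"
                )
        for k, t in pairs.items():
            a, b = k.split("|")
            pa, pb = expr.get(a, 0.0), expr.get(b, 0.0)
            if t > min(pa, pb) + 1e-9 or t < max(0.0, pa + pb - 1) - 1e-9:
                raise ConfigurationError(
                    f"cluster {self.name} ({genotype}): coexpression_target[{k}]={t:.3f} "
                    f"infeasible for marginals {pa:.3f}, {pb:.3f}"
                )
        return expr, pairs


@dataclass
class SimConfig:
    """Full experiment specification. Same seed => byte-identical output."""

    n_cells_per_sample: int
    n_genes: int
    samples: list[tuple[str, str, str]]  # (sample_id, genotype, treatment)
    cluster_spec: list[ClusterSpec]
    doublet_rate: float = 0.0
    mito_gene_count: int = 0
    nb_dispersion: float = 2.0
    library_size_lognormal: tuple[float, float] = (0.0, 0.25)
    interaction_genes: list[tuple[str, dict[str, float]]] = field(default_factory=list)
    seed: int = 0
    panel: MarkerPanel = field(default_factory=lambda: DEFAULT_PANEL)
    marker_mean: float = 25.0

    def __post_init__(self) -> None:
        if self.n_cells_per_sample <= 0 or self.n_genes <= 0:
            raise ConfigurationError("n_cells_per_sample and n_genes must be positive")
        if not 0 <= self.doublet_rate < 1:
            raise ConfigurationError(f"doublet_rate={self.doublet_rate} outside [0, 1)")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        frac = sum(c.fraction for c in self.cluster_spec)
        if abs(frac - 1.0) > 1e-8:
            raise ConfigurationError(
                f"cluster_spec fractions sum to {frac}, expected 1.0"
            )
        n_named = self.mito_gene_count + len(self.panel.genes)
        if self.n_genes < n_named:
            raise ConfigurationError(
                f"n_genes={self.n_genes} cannot hold {self.mito_gene_count} mito + "
                f"{len(self.panel.genes)} panel genes"
            )
        genes = set(self.gene_names())
        for g, mult in self.interaction_genes:
            if g not in genes:
                raise ConfigurationError(f"interaction_genes: unknown gene {g!r}")
            for grp in mult:
                if grp not in GROUPS:
                    raise ConfigurationError(
                        f"interaction_genes[{g}]: unknown group {grp!r}"
                    )
        for c in self.cluster_spec:
            if c.baseline_mean.shape != (self.n_genes,):
                raise ConfigurationError(
                    f"cluster {c.name}: baseline_mean length "
                    f"{c.baseline_mean.shape[0]} != n_genes {self.n_genes}"
                )
            for genotype in ("WT", "KO"):
                c.effective(genotype)  # validates feasibility
        ids = [s[0] for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate sample ids")
        for sid, g, t in self.samples:
            if g not in ("WT", "KO") or t not in ("S", "N"):
                raise ConfigurationError(f"sample {sid}: genotype/treatment invalid")

    def gene_names(self) -> list[str]:
        mito = [f"mt-Mito{i + 1:02d}" for i in range(self.mito_gene_count)]
        panel = list(self.panel.genes)
        n_fill = self.n_genes - len(mito) - len(panel)
        filler = [f"Gene{i + 1:04d}" for i in range(n_fill)]
        return mito + panel + filler

    @classmethod
    def from_toml(cls, path) -> "SimConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls.from_dict(data.get("simulation", data))

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        panel = (
            MarkerPanel({s: tuple(g) for s, g in d["panel"].items()})
            if "panel" in d
            else DEFAULT_PANEL
        )
        base_cfg = d.get("baseline", {})
        n_genes = int(d["n_genes"])
        mito = int(d.get("mito_gene_count", 0))
        cluster_dicts = d["clusters"]
        baselines = build_baseline_means(
            n_genes=n_genes,
            n_clusters=len(cluster_dicts),
            mito_gene_count=mito,
            n_marker_genes=len(panel.genes),
            seed=int(d["seed"]),
            mean_shape=float(base_cfg.get("mean_shape", 1.5)),
            mean_scale=float(base_cfg.get("mean_scale", 1.0)),
            n_de_genes=int(base_cfg.get("n_de_genes", 40)),
            de_fold=float(base_cfg.get("de_fold", 4.0)),
            mito_frac=float(base_cfg.get("mito_frac", 0.005)),
        )
        clusters = [
            ClusterSpec(
                name=c["name"],
                fraction=float(c["fraction"]),
                baseline_mean=baselines[i],
                system_expression={k: float(v) for k, v in c.get("system_expression", {}).items()},
                coexpression_target={k: float(v) for k, v in c.get("coexpression_target", {}).items()},
                genotype_modifier={
                    part: {k: float(v) for k, v in sub.items()}
                    for part, sub in c.get("genotype_modifier", {}).items()
                },
            )
            for i, c in enumerate(cluster_dicts)
        ]
        samples = [(s["id"], s["genotype"], s["treatment"]) for s in d["samples"]]
        interaction = [
            (g["gene"], {k: float(v) for k, v in g["multipliers"].items()})
            for g in d.get("interaction_genes", [])
        ]
        lib = d.get("library_size_lognormal", [0.0, 0.25])
        return cls(
            n_cells_per_sample=int(d["n_cells_per_sample"]),
            n_genes=n_genes,
            samples=samples,
            cluster_spec=clusters,
            doublet_rate=float(d.get("doublet_rate", 0.0)),
            mito_gene_count=mito,
            nb_dispersion=float(d.get("nb_dispersion", 2.0)),
            library_size_lognormal=(float(lib[0]), float(lib[1])),
            interaction_genes=interaction,
            seed=int(d["seed"]),
            panel=panel,
            marker_mean=float(d.get("marker_mean", 25.0)),
        )


# ---------------------------------------------------------------------------
# Baseline construction


def build_baseline_means(
    n_genes: int,
    n_clusters: int,
    mito_gene_count: int,
    n_marker_genes: int,
    seed: int,
    mean_shape: float = 1.5,
    mean_scale: float = 1.0,
    n_de_genes: int = 40,
    de_fold: float = 4.0,
    mito_frac: float = 0.005,
) -> list[np.ndarray]:
    """Shared gamma-distributed background means plus per-cluster DE programs.

    The same structure seed always yields the same profiles; each cluster
    upweights its own ``n_de_genes`` randomly chosen background genes by
    ``de_fold`` so clusters are separable in PCA beyond their markers.
    Mitochondrial genes are rescaled so they make up ``mito_frac`` of the
    expected library.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    base = rng.gamma(shape=mean_shape, scale=mean_scale, size=n_genes)
    marker_lo = mito_gene_count
    marker_hi = mito_gene_count + n_marker_genes
    base[marker_lo:marker_hi] = 0.0  # markers are governed by system membership
    candidates = np.arange(n_genes)
    candidates = candidates[(candidates < marker_lo) | (candidates >= marker_hi)]
    profiles = []
    for _ in range(n_clusters):
        prof = base.copy()
        de = rng.choice(candidates, size=min(n_de_genes, candidates.size), replace=False)
        prof[de] *= de_fold
        profiles.append(prof)
    if mito_gene_count:
        for prof in profiles:
            non_mito = prof[mito_gene_count:].sum()
            target_total = mito_frac / (1 - mito_frac) * non_mito
            prof[:mito_gene_count] = target_total / mito_gene_count
    return profiles


# ---------------------------------------------------------------------------
# Latent system membership


def membership_joint(
    marginals: dict[str, float],
    pair_targets: dict[str, float],
    max_iter: int = 2000,
    tol: float = 1e-12,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Joint distribution over system-membership patterns via IPF.

    Starts from independence and alternately rescales every planted pair's
    full 2x2 margin and every single marginal until all constraints hold.
    Returns ``(systems, states, probs)`` with ``states`` the 2^S x S 0/1
    pattern matrix.
    """
    systems = sorted(marginals)
    pv = np.array([marginals[s] for s in systems])
    states = np.array(list(product((0, 1), repeat=len(systems))), dtype=int)
    probs = np.prod(states * pv + (1 - states) * (1 - pv), axis=1)
    sys_idx = {s: i for i, s in enumerate(systems)}

    pair_list = []
    for key, t in pair_targets.items():
        a, b = key.split("|")
        if a not in sys_idx or b not in sys_idx:
            raise ConfigurationError(f"coexpression_target names unknown system in {key!r}")
        pa, pb = marginals[a], marginals[b]
        margin = np.array([1 - pa - pb + t, pb - t, pa - t, t])  # (00, 01, 10, 11)
        if (margin < -1e-9).any():
            raise ConfigurationError(
                f"pair target {key}={t} infeasible for marginals {pa}, {pb}"
            )
        pair_list.append((sys_idx[a], sys_idx[b], np.clip(margin, 0.0, 1.0)))

    def max_error() -> float:
        err = 0.0
        for ia, ib, margin in pair_list:
            for m, (xa, xb) in zip(margin, product((0, 1), (0, 1))):
                mask = (states[:, ia] == xa) & (states[:, ib] == xb)
                err = max(err, abs(probs[mask].sum() - m))
        for s, p in marginals.items():
            err = max(err, abs(probs[states[:, sys_idx[s]] == 1].sum() - p))
        return err

    for _ in range(max_iter):
        for ia, ib, margin in pair_list:
            for m, (xa, xb) in zip(margin, product((0, 1), (0, 1))):
                mask = (states[:, ia] == xa) & (states[:, ib] == xb)
                cur = probs[mask].sum()
                if cur > 0:
                    probs[mask] *= m / cur
                elif m > tol:
                    raise ConfigurationError(
                        "coexpression constraints jointly infeasible (zero-mass margin)"
                    )
        for s, p in marginals.items():
            col = states[:, sys_idx[s]] == 1
            cur = probs[col].sum()
            if 0 < cur < 1:
                probs[col] *= p / cur
                probs[~col] *= (1 - p) / (1 - cur)
        if max_error() < tol:
            break
    else:
        if max_error() > 1e-6:
            raise ConfigurationError(
                "membership IPF did not converge; planted coexpression targets "
                "are likely jointly infeasible"
            )
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    return systems, states, probs


# ---------------------------------------------------------------------------
# Simulation


def _largest_remainder(fractions: np.ndarray, n: int) -> np.ndarray:
    raw = fractions * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="mergesort")
    counts[order[:rem]] += 1
    return counts


def simulate_experiment(
    config: SimConfig,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate counts, cell metadata and the planted-truth table.

    Returns ``(counts, meta, truth)``; ``meta`` rows align positionally with
    the count-matrix columns and carry sample, genotype, treatment, group,
    doublet flag and the truth cluster label (``"A+B"`` for doublets).
    """
    genes = config.gene_names()
    gene_row = {g: i for i, g in enumerate(genes)}
    marker_rows = {g: gene_row[g] for g in config.panel.genes}
    theta = config.nb_dispersion
    mu_lib, sd_lib = config.library_size_lognormal
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(config.samples) + 1)  # child 0 reserved for structure

    fractions = np.array([c.fraction for c in config.cluster_spec])
    joint_cache: dict[tuple[str, str], tuple] = {}

    blocks = []
    meta_rows = []
    truth_rows = []

    for si, (sample_id, genotype, treatment) in enumerate(config.samples):
        rng = np.random.default_rng(children[si + 1])
        group = f"{genotype}_{treatment}"
        n_total = config.n_cells_per_sample
        n_doub = int(round(config.doublet_rate * n_total))
        n_sing = n_total - n_doub
        per_cluster = _largest_remainder(fractions, n_sing)

        sample_counts = np.zeros((config.n_genes, n_sing), dtype=np.int64)
        labels = np.empty(n_sing, dtype=object)
        col = 0
        for cspec, n_c in zip(config.cluster_spec, per_cluster):
            if n_c == 0:
                continue
            expr, pairs = cspec.effective(genotype)
            key = (cspec.name, genotype)
            if key not in joint_cache:
                joint_cache[key] = membership_joint(expr, pairs)
            systems, states, probs = joint_cache[key]
            draws = rng.choice(len(probs), size=n_c, p=probs)
            member = states[draws]  # n_c x n_systems

            mean = np.tile(cspec.baseline_mean[:, None], (1, n_c))
            for s_i, system in enumerate(systems):
                for g in config.panel.systems.get(system, ()):
                    mean[marker_rows[g]] = config.marker_mean * member[:, s_i]
            for gene, mult in config.interaction_genes:
                if group in mult:
                    mean[gene_row[gene]] *= mult[group]
            factors = np.exp(rng.normal(mu_lib, sd_lib, size=n_c))
            mean *= factors[None, :]
            lam = rng.gamma(shape=theta, scale=mean / theta)
            sample_counts[:, col : col + n_c] = rng.poisson(lam)
            labels[col : col + n_c] = cspec.name
            col += n_c

        cell_ids = [f"{sample_id}_C{i + 1:05d}" for i in range(n_sing)]
        doublet_flags = [False] * n_sing
        if n_doub:
            parents = np.array(
                [rng.choice(n_sing, size=2, replace=False) for _ in range(n_doub)]
            )
            doub_counts = sample_counts[:, parents[:, 0]] + sample_counts[:, parents[:, 1]]
            sample_counts = np.concatenate([sample_counts, doub_counts], axis=1)
            for j in range(n_doub):
                cid = f"{sample_id}_D{j + 1:04d}"
                cell_ids.append(cid)
                pair_label = "+".join(
                    sorted((labels[parents[j, 0]], labels[parents[j, 1]]))
                )
                labels = np.append(labels, pair_label)
                doublet_flags.append(True)
                truth_rows.append(
                    {
                        "kind": "doublet",
                        "cluster": "",
                        "genotype": genotype,
                        "group": group,
                        "key": cid,
                        "value": np.nan,
                        "detail": pair_label,
                    }
                )

        blocks.append(sparse.csr_matrix(sample_counts))
        for cid, lab, dbl in zip(cell_ids, labels, doublet_flags):
            meta_rows.append(
                {
                    "cell_id": cid,
                    "sample": sample_id,
                    "genotype": genotype,
                    "treatment": treatment,
                    "group": group,
                    "doublet": dbl,
                    "truth_cluster": lab,
                }
            )

    for cspec in config.cluster_spec:
        truth_rows.append(
            {
                "kind": "cluster_fraction",
                "cluster": cspec.name,
                "genotype": "",
                "group": "",
                "key": "",
                "value": cspec.fraction,
                "detail": "",
            }
        )
        for genotype in ("WT", "KO"):
            expr, pairs = cspec.effective(genotype)
            for s, v in sorted(expr.items()):
                truth_rows.append(
                    {
                        "kind": "system_expression",
                        "cluster": cspec.name,
                        "genotype": genotype,
                        "group": "",
                        "key": s,
                        "value": v,
                        "detail": "",
                    }
                )
            for k, v in sorted(pairs.items()):
                truth_rows.append(
                    {
                        "kind": "coexpression_target",
                        "cluster": cspec.name,
                        "genotype": genotype,
                        "group": "",
                        "key": k,
                        "value": v,
                        "detail": "",
                    }
                )
    for gene, mult in config.interaction_genes:
        for grp in GROUPS:
            truth_rows.append(
                {
                    "kind": "interaction_gene",
                    "cluster": "",
                    "genotype": "",
                    "group": grp,
                    "key": gene,
                    "value": mult.get(grp, 1.0),
                    "detail": "",
                }
            )

    counts = CountMatrix(
        sparse.hstack(blocks, format="csr"),
        np.array(genes, dtype=object),
        np.array([m["cell_id"] for m in meta_rows], dtype=object),
    )
    meta = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(
        truth_rows,
        columns=["kind", "cluster", "genotype", "group", "key", "value", "detail"],
    )
    return counts, meta, truth


def truth_report(truth: pd.DataFrame) -> pd.DataFrame:
    """One row per planted property (doublet bookkeeping rows excluded).

    Interaction genes are collapsed to one row per gene with the group
    multipliers spelled out in ``detail``. Round-trips through TSV.
    """
    rows = []
    t = truth[truth["kind"] != "doublet"]
    for _, r in t[t["kind"] == "cluster_fraction"].iterrows():
        rows.append(
            {"property": "cluster_fraction", "cluster": r["cluster"], "genotype": "",
             "key": "", "value": r["value"], "detail": ""}
        )
    for kind in ("system_expression", "coexpression_target"):
        for _, r in t[t["kind"] == kind].iterrows():
            rows.append(
                {"property": kind, "cluster": r["cluster"], "genotype": r["genotype"],
                 "key": r["key"], "value": r["value"], "detail": ""}
            )
    inter = t[t["kind"] == "interaction_gene"]
    for gene, sub in inter.groupby("key", sort=False):
        detail = ",".join(f"{r['group']}:{r['value']:g}" for _, r in sub.iterrows())
        rows.append(
            {"property": "interaction_gene", "cluster": "", "genotype": "",
             "key": gene, "value": np.nan, "detail": detail}
        )
    return pd.DataFrame(
        rows, columns=["property", "cluster", "genotype", "key", "value", "detail"]
    )


def write_experiment(counts, meta, truth, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = write_counts(counts, out)
    meta_path = out / "cell_meta.tsv"
    truth_path = out / "truth.tsv"
    meta.to_csv(meta_path, sep="\t", index=False)
    truth.to_csv(truth_path, sep="\t", index=False)
    paths.update({"meta": meta_path, "truth": truth_path})
    return paths


# ---------------------------------------------------------------------------
# Study-condition defaults


def demo_config(
    seed: int = 0,
    n_cells_per_sample: int = 400,
    n_genes: int = 800,
    doublet_rate: float = 0.05,
    n_replicates: int = 3,
) -> SimConfig:
    """The bundled study-condition configuration.

    Twelve samples (WT/KO x saline/nicotine x 3 replicates) over four
    planted neuron subtypes. The ``GLU-DA`` cluster is the planted
    combinatorial population: GLU-DA coexpression 0.30 in WT, reduced to
    0.10 by the KO genotype modifier (with a matching drop in GLU
    expressing fraction so the joint stays feasible). Treatment, genotype
    and interaction effect genes are planted on background genes.
    """
    samples = [
        (f"{g}_{t}_{r + 1}", g, t)
        for g in ("WT", "KO")
        for t in ("S", "N")
        for r in range(n_replicates)
    ]
    cluster_params = [
        # name, fraction, system_expression, coexpression_target, genotype_modifier
        (
            "GLU-DA",
            0.25,
            {"GLU": 0.75, "DA": 0.40, "GABA": 0.02},
            {"GLU|DA": 0.30},
            {
                "system_expression": {"GLU": 0.8},
                "coexpression_target": {"GLU|DA": 1.0 / 3.0},
            },
        ),
        ("GLU", 0.35, {"GLU": 0.80, "DA": 0.04, "GABA": 0.02}, {"GLU|DA": 0.03}, {}),
        ("GABA", 0.25, {"GABA": 0.85, "GLU": 0.05, "DA": 0.02}, {"GABA|GLU": 0.04}, {}),
        ("DA", 0.15, {"DA": 0.80, "GLU": 0.05, "GABA": 0.03}, {"DA|GLU": 0.04}, {}),
    ]
    baselines = build_baseline_means(
        n_genes=n_genes,
        n_clusters=len(cluster_params),
        mito_gene_count=10,
        n_marker_genes=len(DEFAULT_PANEL.genes),
        seed=seed,
    )
    clusters = [
        ClusterSpec(
            name=name,
            fraction=frac,
            baseline_mean=baselines[i],
            system_expression=expr,
            coexpression_target=pairs,
            genotype_modifier=mod,
        )
        for i, (name, frac, expr, pairs, mod) in enumerate(cluster_params)
    ]
    interaction = (
        # treatment main effect: up under nicotine in both genotypes
        [(f"Gene{i:04d}", {"WT_N": 1.6, "KO_N": 1.6}) for i in range(1, 6)]
        # genotype:treatment interaction: nicotine response present in WT only
        + [(f"Gene{i:04d}", {"WT_N": 1.8}) for i in range(6, 11)]
        # genotype main effect: down in KO regardless of treatment
        + [(f"Gene{i:04d}", {"KO_S": 0.6, "KO_N": 0.6}) for i in range(11, 16)]
    )
    return SimConfig(
        n_cells_per_sample=n_cells_per_sample,
        n_genes=n_genes,
        samples=samples,
        cluster_spec=clusters,
        doublet_rate=doublet_rate,
        mito_gene_count=10,
        nb_dispersion=2.0,
        library_size_lognormal=(0.0, 0.25),
        interaction_genes=interaction,
        seed=seed,
    )


def simulate_pseudobulk_table(
    n_null_genes: int = 1000,
    n_planted: int = 50,
    effect_d: float = 1.0,
    sigma: float = 1.0,
    n_replicates: int = 3,
    baseline: float = 8.0,
    seed: int = 0,
) -> tuple[PseudobulkTable, list[str]]:
    """Replicate-level table with planted interaction genes of known effect size.

    Planted genes follow the pure-interaction pattern (+d, -d, -d, +d over
    WT_S / WT_N / KO_S / KO_N cell means) on normal noise of SD ``sigma``;
    with ``effect_d = sigma`` the population effect is Cohen's f^2 = 1,
    i.e. a true partial eta squared of 0.5. Null genes are pure noise.
    Returns the table and the planted gene names.
    """
    rng = np.random.default_rng(seed)
    design_rows = []
    for g in ("WT", "KO"):
        for t in ("S", "N"):
            for r in range(n_replicates):
                design_rows.append({"sample": f"{g}_{t}_{r + 1}", "genotype": g, "treatment": t})
    design = pd.DataFrame(design_rows).set_index("sample")
    n_samples = len(design)
    n_genes = n_null_genes + n_planted
    Y = baseline + rng.normal(0.0, sigma, size=(n_samples, n_genes))
    sign = np.where(
        (design["genotype"] == "KO").to_numpy() ^ (design["treatment"] == "N").to_numpy(),
        -1.0,
        1.0,
    )
    planted = [f"planted{i + 1:03d}" for i in range(n_planted)]
    Y[:, :n_planted] += effect_d * sign[:, None]
    genes = planted + [f"null{i + 1:04d}" for i in range(n_null_genes)]
    values = pd.DataFrame(Y, index=design.index, columns=genes)
    return (
        PseudobulkTable(values=values, design=design, subset="replicate-level synthetic"),
        planted,
    )
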