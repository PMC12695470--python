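"""Coexpression-proportion statistics and combinatorial-neuron classification.

A cell "expresses" a gene when its log-normalized value is strictly
positive. The coexpression proportion of a gene pair within a cluster is
the fraction of the cluster's cells expressing both genes. A cluster is
called *combinatorial* when some pair of markers drawn from two different
neurotransmitter systems has coexpression proportion strictly above the
threshold (default 20%).

The default marker panel covers three systems of the mouse midbrain:
GABAergic (Slc6a1, Slc32a1, Gad1, Gad2), dopaminergic (Ddc, Th, Slc18a2,
Slc6a3) and glutamatergic (Slc17a6, Slc17a7, Grm2).
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from cotransmit.errors import ConfigurationError, CotransmitError
from cotransmit.io_qc import NormalizedMatrix

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

__all__ = [
    "MarkerPanel",
    "DEFAULT_PANEL",
    "CoexpressionProfile",
    "coexpression_proportion",
    "coexpression_matrix",
    "classify_combinatorial",
    "name_identity",
    "compare_coexpression",
    "expressing_fraction_by_sample",
]


@dataclass(frozen=True)
class MarkerPanel:
    """Mapping of neurotransmitter system -> marker gene symbols."""

    systems: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if len(self.systems) < 2:
            raise ConfigurationError("MarkerPanel requires at least 2 systems")
        object.__setattr__(
            self, "systems", {s: tuple(g) for s, g in self.systems.items()}
        )
        seen: dict[str, str] = {}
        for system, genes in self.systems.items():
            for g in genes:
                if g in seen:
                    raise ConfigurationError(
                        f"gene {g!r} appears in both {seen[g]!r} and {system!r}"
                    )
                seen[g] = system

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for genes in self.systems.values() for g in genes)

    def system_of(self, gene: str) -> str:
        for system, genes in self.systems.items():
            if gene in genes:
                return system
        raise KeyError(f"gene {gene!r} not in panel")

    def cross_system_pairs(self) -> list[tuple[str, str]]:
        """All gene pairs spanning two different systems."""
        return [
            (a, b)
            for a, b in combinations(self.genes, 2)
            if self.system_of(a) != self.system_of(b)
        ]

    def restrict(self, present: set[str]) -> "MarkerPanel":
        systems = {
            s: tuple(g for g in genes if g in present)
            for s, genes in self.systems.items()
        }
        return MarkerPanel({s: g for s, g in systems.items() if g})

    @classmethod
    def from_toml(cls, path) -> "MarkerPanel":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        systems = data.get("systems", data)
        return cls({s: tuple(genes) for s, genes in systems.items()})


DEFAULT_PANEL = MarkerPanel(
    {
        "GABA": ("Slc6a1", "Slc32a1", "Gad1", "Gad2"),
        "DA": ("Ddc", "Th", "Slc18a2", "Slc6a3"),
        "GLU": ("Slc17a6", "Slc17a7", "Grm2"),
    }
)


@dataclass
class CoexpressionProfile:
    """Per-cluster pairwise coexpression proportions over a marker panel.

    ``matrices[cluster]`` is a symmetric genes x genes DataFrame whose
    diagonal holds single-gene expressing fractions.
    """

    matrices: dict[object, pd.DataFrame]
    panel: MarkerPanel
    cluster_sizes: dict[object, int]

    def cross_system_summary(self) -> pd.DataFrame:
        """Max and mean coexpression per system pair per cluster."""
        rows = []
        systems = list(self.panel.systems)
        for cluster, mat in self.matrices.items():
            for sa, sb in combinations(systems, 2):
                ga = [g for g in self.panel.systems[sa] if g in mat.index]
                gb = [g for g in self.panel.systems[sb] if g in mat.index]
                if not ga or not gb:
                    continue
                block = mat.loc[ga, gb].to_numpy()
                rows.append(
                    {
                        "cluster": cluster,
                        "system_a": sa,
                        "system_b": sb,
                        "max_proportion": float(block.max()),
                        "mean_proportion": float(block.mean()),
                    }
                )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (cluster, gene_a, gene_b, proportion) table, upper triangle + diagonal."""
        rows = []
        for cluster, mat in self.matrices.items():
            genes = list(mat.index)
            for i, ga in enumerate(genes):
                for gb in genes[i:]:
                    rows.append(
                        {
                            "cluster": cluster,
                            "gene_a": ga,
                            "gene_b": gb,
                            "proportion": float(mat.loc[ga, gb]),
                        }
                    )
        return pd.DataFrame(rows)


def _positive_rows(norm: NormalizedMatrix, genes: list[str], cell_mask: np.ndarray) -> np.ndarray:
    """Boolean (len(genes) x n_selected_cells) expression-indicator matrix."""
    idx = [norm.gene_index(g) for g in genes]
    sub = norm.values[idx][:, cell_mask]
    return np.asarray((sub > 0).todense())


def coexpression_proportion(
    norm: NormalizedMatrix,
    labels: np.ndarray,
    cluster,
    gene_a: str,
    gene_b: str,
) -> float:
    """Fraction of the cluster's cells with strictly positive values for both genes."""
    labels = np.asarray(labels)
    mask = labels == cluster
    if not mask.any():
        raise CotransmitError(f"cluster {cluster!r} is empty")
    for g in (gene_a, gene_b):
        norm.gene_index(g)  # raises KeyError naming the gene
    B = _positive_rows(norm, [gene_a, gene_b], mask)
    return float((B[0] & B[1]).sum() / mask.sum())


def coexpression_matrix(
    norm: NormalizedMatrix,
    labels: np.ndarray,
    panel: MarkerPanel = DEFAULT_PANEL,
) -> CoexpressionProfile:
    """Pairwise coexpression proportions of all panel genes, per cluster."""
    labels = np.asarray(labels)
    present = set(map(str, norm.gene_ids))
    missing = [g for g in panel.genes if g not in present]
    if missing:
        if len(missing) == len(panel.genes):
            raise CotransmitError("none of the panel genes are present in the matrix")
        warnings.warn(f"panel genes absent from matrix, excluded: {missing}")
        panel = panel.restrict(present)
    genes = list(panel.genes)
    matrices: dict[object, pd.DataFrame] = {}
    sizes: dict[object, int] = {}
    for cluster in pd.unique(labels):
        mask = labels == cluster
        n = int(mask.sum())
        B = _positive_rows(norm, genes, mask).astype(np.float64)
        P = (B @ B.T) / n
        matrices[cluster] = pd.DataFrame(P, index=genes, columns=genes)
        sizes[cluster] = n
    return CoexpressionProfile(matrices=matrices, panel=panel, cluster_sizes=sizes)


def classify_combinatorial(
    profile: CoexpressionProfile, threshold: float = 0.20
) -> pd.DataFrame:
    """Apply the strict cross-system >threshold rule per cluster.

    Returns one row per cluster with the call and the best supporting pair;
    ``profile_supporting_pairs`` in ``attrs`` lists every qualifying pair
    sorted by proportion.
    """
    rows = []
    supporting: dict[object, list[dict]] = {}
    for cluster, mat in profile.matrices.items():
        pairs = []
        for ga, gb in profile.panel.cross_system_pairs():
            if ga in mat.index and gb in mat.index:
                pairs.append(
                    {
                        "gene_a": ga,
                        "gene_b": gb,
                        "system_a": profile.panel.system_of(ga),
                        "system_b": profile.panel.system_of(gb),
                        "proportion": float(mat.loc[ga, gb]),
                    }
                )
        pairs.sort(key=lambda d: -d["proportion"])
        hits = [p for p in pairs if p["proportion"] > threshold]
        supporting[cluster] = hits
        best = pairs[0] if pairs else None
        rows.append(
            {
                "cluster": cluster,
                "combinatorial": bool(hits),
                "n_supporting_pairs": len(hits),
                "best_pair": f"{best['gene_a']}|{best['gene_b']}" if best else "",
                "best_proportion": best["proportion"] if best else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["supporting_pairs"] = supporting
    out.attrs["threshold"] = threshold
    return out


def name_identity(
    norm: NormalizedMatrix,
    labels: np.ndarray,
    cluster,
    panel: MarkerPanel = DEFAULT_PANEL,
    floor: float = 0.2,
) -> tuple[str, dict[str, float], bool]:
    """Dominance-ordered identity label such as ``"GLU>DA"``.

    Per system the score is the fraction of the cluster's cells expressing at
    least one of the system's markers. Systems scoring >= ``floor`` are joined
    by ``>`` in descending score order (alphabetical on exact ties, flagged).
    Returns ``(identity, scores, tie_flag)``; identity is ``"undetermined"``
    when no system reaches the floor.
    """
    labels = np.asarray(labels)
    mask = labels == cluster
    if not mask.any():
        raise CotransmitError(f"cluster {cluster!r} is empty")
    present = set(map(str, norm.gene_ids))
    scores: dict[str, float] = {}
    for system, genes in panel.systems.items():
        genes = [g for g in genes if g in present]
        if not genes:
            continue
        B = _positive_rows(norm, genes, mask)
        scores[system] = float(B.any(axis=0).mean())
    qualifying = sorted(
        ((s, v) for s, v in scores.items() if v >= floor),
        key=lambda sv: (-sv[1], sv[0]),
    )
    if not qualifying:
        return "undetermined", scores, False
    vals = [v for _, v in qualifying]
    tie = len(vals) != len(set(vals))
    return ">".join(s for s, _ in qualifying), scores, tie


def _pair_indicators(
    norm: NormalizedMatrix, pairs: list[tuple[str, str]], mask: np.ndarray
) -> np.ndarray:
    genes = sorted({g for p in pairs for g in p})
    B = _positive_rows(norm, genes, mask)
    gidx = {g: i for i, g in enumerate(genes)}
    return np.stack([B[gidx[a]] & B[gidx[b]] for a, b in pairs])


def compare_coexpression(
    norm: NormalizedMatrix,
    labels: np.ndarray,
    meta: pd.DataFrame,
    cluster,
    panel: MarkerPanel = DEFAULT_PANEL,
    group_a: str = "WT_S",
    group_b: str = "KO_S",
    pairs: list[tuple[str, str]] | None = None,
    systems: tuple[str, str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation test of the mean pairwise coexpression difference a - b.

    The statistic is the mean over gene pairs of the per-pair
    coexpression-proportion difference between the two groups, within one
    cluster. The pair set is, in order of precedence: an explicit ``pairs``
    list, all cross pairs between the two named ``systems``, or every
    cross-system panel pair. The p-value permutes group labels over the
    cluster's cells (two-sided, add-one corrected). ``n_perm=0`` returns
    the difference only (``p`` is None).
    """
    labels = np.asarray(labels)
    groups = meta["group"].to_numpy()
    cmask = labels == cluster
    in_a = cmask & (groups == group_a)
    in_b = cmask & (groups == group_b)
    if not in_a.any() or not in_b.any():
        raise CotransmitError(
            f"cluster {cluster!r} has no cells in group "
            f"{group_a if not in_a.any() else group_b!r}"
        )
    present = set(map(str, norm.gene_ids))
    if pairs is None:
        pairs = [
            (a, b)
            for a, b in panel.cross_system_pairs()
            if a in present and b in present
        ]
        if systems is not None:
            sa, sb = systems
            pairs = [
                (a, b)
                for a, b in pairs
                if {panel.system_of(a), panel.system_of(b)} == {sa, sb}
            ]
    if not pairs:
        raise CotransmitError("no gene pairs available for comparison")

    both = in_a | in_b
    V = _pair_indicators(norm, pairs, both).astype(np.float64)  # pairs x cells
    is_a = in_a[both]
    n_a, n_b = int(is_a.sum()), int((~is_a).sum())

    def stat(assign_a: np.ndarray) -> np.ndarray:
        # assign_a: boolean (cells,) or matrix (n_draws, cells)
        pa = V @ assign_a.T / n_a
        pb = V @ (~assign_a).T / n_b
        return (pa - pb).mean(axis=0)

    per_pair = V[:, is_a].mean(axis=1) - V[:, ~is_a].mean(axis=1)
    observed = float(per_pair.mean())
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        draws = np.stack([rng.permutation(is_a) for _ in range(n_perm)])
        null = stat(draws)
        p = float((1 + np.sum(np.abs(null) >= abs(observed) - 1e-12)) / (n_perm + 1))
    return {
        "cluster": cluster,
        "group_a": group_a,
        "group_b": group_b,
        "difference": observed,
        "p": p,
        "n_perm": n_perm,
        "n_cells_a": n_a,
        "n_cells_b": n_b,
        "per_pair": pd.DataFrame(
            {"gene_a": [a for a, _ in pairs], "gene_b": [b for _, b in pairs], "difference": per_pair}
        ),
        "test": "cell-label permutation, two-sided, add-one corrected",
    }


def expressing_fraction_by_sample(
    norm: NormalizedMatrix,
    meta: pd.DataFrame,
    gene: str,
    group_a: str | None = None,
    group_b: str | None = None,
) -> dict:
    """Per-sample expressing fractions of one gene, group mean +- SD, t-test.

    The across-replicate test is a two-sided two-sample t-test on the
    per-sample fractions (the replicate, not the cell, is the unit). With a
    single sample in a group the SD is reported as NaN.
    """
    gi = norm.gene_index(gene)
    pos = np.asarray((norm.values[gi] > 0).todense()).ravel()
    df = pd.DataFrame({"sample": meta["sample"].to_numpy(), "group": meta["group"].to_numpy(), "pos": pos})
    per_sample = (
        df.groupby(["group", "sample"], sort=True)["pos"].mean().rename("fraction").reset_index()
    )
    summary = (
        per_sample.groupby("group", sort=True)["fraction"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    groups = list(summary["group"])
    if group_a is None and len(groups) == 2:
        group_a, group_b = groups
    p = t_stat = None
    if group_a is not None and group_b is not None:
        fa = per_sample.loc[per_sample["group"] == group_a, "fraction"]
        fb = per_sample.loc[per_sample["group"] == group_b, "fraction"]
        if len(fa) >= 2 and len(fb) >= 2:
            res = stats.ttest_ind(fa, fb)
            t_stat, p = float(res.statistic), float(res.pvalue)
    return {
        "gene": gene,
        "per_sample": per_sample,
        "summary": summary,
        "group_a": group_a,
        "group_b": group_b,
        "t": t_stat,
        "p": p,
        "test": "two-sample t-test across replicate fractions",
    }
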