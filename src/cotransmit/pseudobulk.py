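"""Pseudo-bulk aggregation and gene-wise two-way ANOVA with effect-size gating.

Counts of a chosen cell subset are summed per sample and normalized to
log2(1 + CPM). Each gene is then decomposed by a 2x2 genotype x treatment
ANOVA into genotype, treatment and interaction effects with partial eta
squared ``SS_effect / (SS_effect + SS_residual)``. Screening keeps genes
with ``p < p_max`` AND ``partial eta squared >= pes_min`` (0.06, a medium
effect; >= 0.14 tagged large). No multiple-testing correction is applied by
default — the effect-size gate is the guard — but a Benjamini-Hochberg
option is exposed.

For balanced designs the sums of squares are computed in closed form from
cell means (Type I = II = III there); unbalanced designs fall back to Type
II via full-versus-reduced least-squares fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cotransmit.errors import CotransmitError
from cotransmit.io_qc import CountMatrix

__all__ = ["PseudobulkTable", "pseudobulk", "two_way_anova", "filter_effects"]

GENOTYPES = ("WT", "KO")
TREATMENTS = ("S", "N")
EFFECTS = ("genotype", "treatment", "interaction")


@dataclass
class PseudobulkTable:
    """Samples x genes matrix (log2 CPM of summed counts) plus the 2x2 design."""

    values: pd.DataFrame  # index: sample, columns: genes
    design: pd.DataFrame  # index: sample, columns: genotype, treatment
    subset: str = "all cells"

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.design.index):
            raise CotransmitError("PseudobulkTable: values and design sample order differ")
        for sample, row in self.design.iterrows():
            if row["genotype"] not in GENOTYPES or row["treatment"] not in TREATMENTS:
                raise CotransmitError(
                    f"sample {sample!r} has genotype/treatment outside the 2x2 design"
                )

    def cell_counts(self) -> pd.Series:
        return self.design.groupby(["genotype", "treatment"]).size()


def pseudobulk(
    counts: CountMatrix,
    meta: pd.DataFrame,
    cell_subset: np.ndarray | None = None,
    subset_label: str = "all cells",
) -> PseudobulkTable:
    """Sum counts over the subset per sample and normalize to log2(1 + CPM)."""
    if cell_subset is None:
        cell_subset = np.ones(counts.n_cells, dtype=bool)
    cell_subset = np.asarray(cell_subset, dtype=bool)
    samples = meta["sample"].to_numpy()
    sample_order = list(pd.unique(samples))
    sums = np.zeros((len(sample_order), counts.n_genes))
    design_rows = []
    for i, s in enumerate(sample_order):
        mask = (samples == s) & cell_subset
        if not mask.any():
            raise CotransmitError(f"sample {s!r} contributes no cells to the subset")
        sums[i] = np.asarray(counts.values[:, mask].sum(axis=1)).ravel()
        srow = meta.loc[meta["sample"] == s].iloc[0]
        design_rows.append({"genotype": srow["genotype"], "treatment": srow["treatment"]})
    lib = sums.sum(axis=1, keepdims=True)
    logcpm = np.log2(1.0 + 1e6 * sums / lib)
    values = pd.DataFrame(logcpm, index=pd.Index(sample_order, name="sample"),
                          columns=list(counts.gene_ids))
    design = pd.DataFrame(design_rows, index=values.index)
    return PseudobulkTable(values=values, design=design, subset=subset_label)


def _closed_form_balanced(Y: np.ndarray, gi: np.ndarray, ti: np.ndarray) -> dict[str, np.ndarray]:
    """Balanced 2x2 SS decomposition from cell/row/column/grand means."""
    n_samples, _ = Y.shape
    grand = Y.mean(axis=0)
    ss = {}
    cell_mean = np.zeros_like(Y)
    row_means = {}
    col_means = {}
    for g in (0, 1):
        row_means[g] = Y[gi == g].mean(axis=0)
    for t in (0, 1):
        col_means[t] = Y[ti == t].mean(axis=0)
    cms = {}
    for g in (0, 1):
        for t in (0, 1):
            m = (gi == g) & (ti == t)
            cms[(g, t)] = Y[m].mean(axis=0)
            cell_mean[m] = cms[(g, t)]
    n_per_geno = (gi == 0).sum()
    n_per_treat = (ti == 0).sum()
    ss["genotype"] = n_per_geno * sum((row_means[g] - grand) ** 2 for g in (0, 1))
    ss["treatment"] = n_per_treat * sum((col_means[t] - grand) ** 2 for t in (0, 1))
    n_cell = n_samples // 4
    ss["interaction"] = n_cell * sum(
        (cms[(g, t)] - row_means[g] - col_means[t] + grand) ** 2
        for g in (0, 1)
        for t in (0, 1)
    )
    ss["residual"] = ((Y - cell_mean) ** 2).sum(axis=0)
    return ss


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return (resid**2).sum(axis=0)


def _type2_unbalanced(Y: np.ndarray, gi: np.ndarray, ti: np.ndarray) -> dict[str, np.ndarray]:
    one = np.ones_like(gi, dtype=float)
    g = gi.astype(float)
    t = ti.astype(float)
    X_full = np.column_stack([one, g, t, g * t])
    X_add = np.column_stack([one, g, t])
    X_g = np.column_stack([one, g])
    X_t = np.column_stack([one, t])
    rss_full = _rss(X_full, Y)
    rss_add = _rss(X_add, Y)
    return {
        "genotype": _rss(X_t, Y) - rss_add,
        "treatment": _rss(X_g, Y) - rss_add,
        "interaction": rss_add - rss_full,
        "residual": rss_full,
    }


def two_way_anova(pb: PseudobulkTable) -> pd.DataFrame:
    """Gene-wise 2x2 ANOVA: F, p and partial eta squared per effect.

    Returns one row per gene with ``F_<effect>``, ``p_<effect>`` and
    ``pes_<effect>`` columns plus a ``zero_residual`` flag (p undefined
    there). ``attrs`` records dfs and whether the design was balanced.
    """
    design = pb.design
    counts = pb.cell_counts()
    if len(counts) < 4 or (counts < 2).any():
        raise CotransmitError(
            f"two_way_anova requires a full 2x2 design with >=2 replicates per "
            f"cell; got {counts.to_dict()}"
        )
    Y = pb.values.to_numpy(dtype=np.float64)
    gi = (design["genotype"] == "KO").to_numpy().astype(int)
    ti = (design["treatment"] == "N").to_numpy().astype(int)
    balanced = counts.nunique() == 1
    ss = _closed_form_balanced(Y, gi, ti) if balanced else _type2_unbalanced(Y, gi, ti)
    n = Y.shape[0]
    df_effect = 1
    df_resid = n - 4
    zero_resid = ss["residual"] <= 0
    out = pd.DataFrame(index=pb.values.columns)
    out.index.name = "gene"
    ms_resid = np.where(zero_resid, np.nan, ss["residual"] / df_resid)
    for eff in EFFECTS:
        ss_e = np.maximum(ss[eff], 0.0)
        F = (ss_e / df_effect) / ms_resid
        p = stats.f.sf(F, df_effect, df_resid)
        denom = ss_e + ss["residual"]
        pes = np.where(denom > 0, ss_e / np.where(denom > 0, denom, 1.0), 0.0)
        out[f"F_{eff}"] = F
        out[f"p_{eff}"] = p
        out[f"pes_{eff}"] = pes
    out["zero_residual"] = zero_resid
    out.attrs["df_effect"] = df_effect
    out.attrs["df_residual"] = df_resid
    out.attrs["balanced"] = bool(balanced)
    out.attrs["subset"] = pb.subset
    out.attrs["ss_type"] = "balanced closed form (I=II=III)" if balanced else "Type II"
    return out


def filter_effects(
    anova: pd.DataFrame,
    p_max: float = 0.05,
    pes_min: float = 0.06,
    pes_large: float = 0.14,
    bh_fdr: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Gene sets per effect passing ``p < p_max`` and ``pes >= pes_min``.

    Each retained gene is tiered ``"medium"`` or ``"large"`` (pes >=
    ``pes_large``). When ``bh_fdr`` is set, Benjamini-Hochberg-adjusted
    p-values are used in place of raw ones (off by default).
    """
    out: dict[str, pd.DataFrame] = {}
    for eff in EFFECTS:
        p = anova[f"p_{eff}"].to_numpy()
        pes = anova[f"pes_{eff}"].to_numpy()
        ok = np.isfinite(p)
        p_used = p.copy()
        if bh_fdr is not None:
            adj = np.full_like(p, np.nan)
            if ok.any():
                adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
            p_used = adj
        keep = ok & (p_used < p_max) & (pes >= pes_min)
        sel = anova.loc[keep, [f"F_{eff}", f"p_{eff}", f"pes_{eff}"]].copy()
        sel["tier"] = np.where(sel[f"pes_{eff}"] >= pes_large, "large", "medium")
        sel = sel.sort_values(f"pes_{eff}", ascending=False, kind="mergesort")
        sel.attrs["effect"] = eff
        sel.attrs["p_max"] = p_max
        sel.attrs["pes_min"] = pes_min
        sel.attrs["pes_large"] = pes_large
        sel.attrs["threshold_note"] = (
            "pes gate applied as >= (inclusive); source conventions differ "
            "between > and >= at the boundary"
        )
        out[eff] = sel
    return out
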