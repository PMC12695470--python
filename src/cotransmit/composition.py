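"""Cell-type composition tables and replicate-aware comparison.

Per-sample cluster fractions are compared between groups with a
sample-level permutation test on the difference of mean fractions: the
sample-to-group assignment is permuted (exhaustively when there are at most
200 distinct assignments, Monte-Carlo with add-one correction otherwise)
and per-type p-values are Benjamini-Hochberg adjusted. The replicate — not
the cell — is the unit of inference, so the test respects biological
replication the way a compositional model would.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from cotransmit.errors import CotransmitError

__all__ = ["composition_table", "compare_composition"]

EXACT_ENUMERATION_LIMIT = 200


def composition_table(meta: pd.DataFrame, label_col: str = "cluster") -> pd.DataFrame:
    """Counts and fractions of each cell type per sample.

    Requires every cell to carry a sample and a non-null label; group
    summaries (mean fraction, SD over samples) live in ``attrs["group_summary"]``.
    """
    if label_col not in meta.columns:
        raise CotransmitError(f"meta has no {label_col!r} column")
    unlabeled = meta[label_col].isna().sum()
    if unlabeled:
        raise CotransmitError(f"{unlabeled} cells have no {label_col!r} label")
    counts = (
        meta.groupby(["sample", "group", label_col], sort=True, observed=True)
        .size()
        .rename("n_cells")
        .reset_index()
        .rename(columns={label_col: "cell_type"})
    )
    # complete missing (sample, type) combinations with zero counts
    samples = counts[["sample", "group"]].drop_duplicates()
    types = sorted(counts["cell_type"].unique())
    full = samples.merge(pd.DataFrame({"cell_type": types}), how="cross")
    counts = full.merge(counts, on=["sample", "group", "cell_type"], how="left").fillna(
        {"n_cells": 0}
    )
    counts["n_cells"] = counts["n_cells"].astype(int)
    totals = counts.groupby("sample")["n_cells"].transform("sum")
    counts["fraction"] = counts["n_cells"] / totals
    summary = (
        counts.groupby(["group", "cell_type"], sort=True)["fraction"]
        .agg(mean_fraction="mean", sd_fraction=lambda v: v.std(ddof=1), n_samples="count")
        .reset_index()
    )
    counts.attrs["group_summary"] = summary
    return counts


def compare_composition(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    n_perm: int = 10_000,
    seed: int = 0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-type difference of mean fractions with permutation p and BH-FDR.

    Two-sided p: fraction of sample-to-group assignments whose absolute
    difference is at least the observed one (exact over all assignments
    when feasible, otherwise Monte-Carlo with add-one correction).
    """
    sub = table[table["group"].isin([group_a, group_b])]
    wide = sub.pivot_table(index="sample", columns="cell_type", values="fraction", fill_value=0.0)
    sample_group = sub.drop_duplicates("sample").set_index("sample")["group"]
    sample_group = sample_group.loc[wide.index]
    n_a = int((sample_group == group_a).sum())
    n_b = int((sample_group == group_b).sum())
    if n_a < 2 or n_b < 2:
        raise CotransmitError(
            f"compare_composition needs >=2 samples per group (got {n_a} vs {n_b})"
        )
    F = wide.to_numpy()
    is_a = (sample_group == group_a).to_numpy()
    observed = F[is_a].mean(axis=0) - F[~is_a].mean(axis=0)

    n_total = n_a + n_b
    n_assign = comb(n_total, n_a)
    if n_assign <= EXACT_ENUMERATION_LIMIT:
        method = f"exact enumeration ({n_assign} assignments)"
        count = np.zeros(F.shape[1], dtype=int)
        for picked in combinations(range(n_total), n_a):
            mask = np.zeros(n_total, dtype=bool)
            mask[list(picked)] = True
            d = F[mask].mean(axis=0) - F[~mask].mean(axis=0)
            count += np.abs(d) >= np.abs(observed) - 1e-12
        p = count / n_assign
    else:
        method = f"Monte-Carlo ({n_perm} draws, add-one corrected)"
        rng = np.random.default_rng(seed)
        count = np.zeros(F.shape[1], dtype=int)
        for _ in range(n_perm):
            mask = np.zeros(n_total, dtype=bool)
            mask[rng.choice(n_total, size=n_a, replace=False)] = True
            d = F[mask].mean(axis=0) - F[~mask].mean(axis=0)
            count += np.abs(d) >= np.abs(observed) - 1e-12
        p = (1 + count) / (n_perm + 1)

    p_adj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "cell_type": wide.columns,
            "mean_fraction_a": F[is_a].mean(axis=0),
            "mean_fraction_b": F[~is_a].mean(axis=0),
            "difference": observed,
            "p": p,
            "p_adj": p_adj,
            "significant": p_adj < fdr,
            "method": method,
        }
    )
    out.attrs["group_a"] = group_a
    out.attrs["group_b"] = group_b
    out.attrs["fdr"] = fdr
    return out
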