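"""Coexpression proportions, combinatorial calls, identities, comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import make_norm
from cotransmit.coexpression import (
    DEFAULT_PANEL,
    MarkerPanel,
    classify_combinatorial,
    coexpression_matrix,
    coexpression_proportion,
    compare_coexpression,
    expressing_fraction_by_sample,
    name_identity,
)
from cotransmit.errors import ConfigurationError, CotransmitError

PANEL2 = MarkerPanel({"GLU": ("ga", "gb"), "DA": ("da", "db")})


def test_default_panel_is_the_eleven_gene_set():
    assert set(DEFAULT_PANEL.genes) == {
        "Slc6a1", "Slc32a1", "Gad1", "Gad2",
        "Ddc", "Th", "Slc18a2", "Slc6a3",
        "Slc17a6", "Slc17a7", "Grm2",
    }


def test_panel_rejects_shared_gene():
    with pytest.raises(ConfigurationError, match="appears in both"):
        MarkerPanel({"A": ("x",), "B": ("x", "y")})


def test_proportion_disjoint_and_full():
    vals = np.array([[1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0], [2.0, 2.0, 2.0, 2.0]])
    norm = make_norm(vals, genes=["a", "b", "c"])
    labels = np.zeros(4, dtype=int)
    assert coexpression_proportion(norm, labels, 0, "a", "b") == 0.0
    assert coexpression_proportion(norm, labels, 0, "c", "c") == 1.0


def test_proportion_matches_bruteforce_loop():
    vals = np.zeros((2, 10))
    vals[0, [0, 1, 2, 3, 4, 5, 8]] = 1.0
    vals[1, [0, 1, 2, 3, 4, 5, 9]] = 1.0
    norm = make_norm(vals, genes=["a", "b"])
    labels = np.zeros(10, dtype=int)
    brute = sum(1 for c in range(10) if vals[0, c] > 0 and vals[1, c] > 0) / 10
    assert brute == 0.6
    assert coexpression_proportion(norm, labels, 0, "a", "b") == brute


def test_proportion_errors():
    norm = make_norm(np.ones((1, 3)), genes=["a"])
    with pytest.raises(KeyError, match="zz"):
        coexpression_proportion(norm, np.zeros(3, dtype=int), 0, "a", "zz")
    with pytest.raises(CotransmitError, match="empty"):
        coexpression_proportion(norm, np.zeros(3, dtype=int), 7, "a", "a")


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_matrix_symmetry_and_frechet_bound(seed):
    rng = np.random.default_rng(seed)
    vals = rng.poisson(0.8, size=(4, 30)).astype(float)
    norm = make_norm(vals, genes=["ga", "gb", "da", "db"])
    labels = rng.integers(0, 2, 30)
    if (labels == 0).sum() == 0 or (labels == 1).sum() == 0:
        labels[0], labels[-1] = 0, 1
    prof = coexpression_matrix(norm, labels, PANEL2)
    for mat in prof.matrices.values():
        M = mat.to_numpy()
        np.testing.assert_allclose(M, M.T, atol=0)
        diag = np.diag(M)
        for i in range(4):
            for j in range(4):
                assert M[i, j] <= min(diag[i], diag[j]) + 1e-12


def test_matrix_invariant_to_cell_permutation(rng):
    vals = rng.poisson(0.8, size=(4, 40)).astype(float)
    labels = rng.integers(0, 2, 40)
    perm = rng.permutation(40)
    a = coexpression_matrix(make_norm(vals, genes=PANEL2.genes), labels, PANEL2)
    b = coexpression_matrix(make_norm(vals[:, perm], genes=PANEL2.genes), labels[perm], PANEL2)
    for c in a.matrices:
        pd.testing.assert_frame_equal(a.matrices[c], b.matrices[c])


def test_matrix_warns_on_missing_panel_genes(rng):
    vals = rng.poisson(0.8, size=(3, 20)).astype(float)
    norm = make_norm(vals, genes=["ga", "gb", "da"])
    with pytest.warns(UserWarning, match="db"):
        prof = coexpression_matrix(norm, np.zeros(20, dtype=int), PANEL2)
    assert "db" not in prof.matrices[0].index


def test_matrix_all_panel_genes_missing_errors(rng):
    norm = make_norm(np.ones((2, 5)), genes=["x", "y"])
    with pytest.raises(CotransmitError, match="none of the panel genes"):
        coexpression_matrix(norm, np.zeros(5, dtype=int), PANEL2)


def _profile_with(cross, within=0.0):
    """Single-cluster profile with a given max cross-system proportion."""
    n = 100
    k_cross = int(round(cross * n))
    k_within = int(round(within * n))
    vals = np.zeros((4, n))
    vals[0, :k_cross] = 1.0  # ga
    vals[2, :k_cross] = 1.0  # da
    vals[1, :k_within] = 1.0  # gb
    if within:
        vals[0, :k_within] = 1.0
    norm = make_norm(vals, genes=["ga", "gb", "da", "db"])
    return coexpression_matrix(norm, np.zeros(n, dtype=int), PANEL2)


def test_classify_strictly_above_threshold():
    assert classify_combinatorial(_profile_with(0.21)).loc[0, "combinatorial"]
    assert not classify_combinatorial(_profile_with(0.20)).loc[0, "combinatorial"]


def test_classify_ignores_within_system_pairs():
    calls = classify_combinatorial(_profile_with(cross=0.0, within=0.9))
    assert not calls.loc[0, "combinatorial"]


@settings(derandomize=True, max_examples=20, deadline=None)
@given(st.floats(0.0, 0.5), st.floats(0.0, 0.5))
def test_classify_monotone_in_threshold(t_low, t_high):
    t_low, t_high = min(t_low, t_high), max(t_low, t_high)
    prof = _profile_with(0.3)
    at_high = classify_combinatorial(prof, threshold=t_high).loc[0, "combinatorial"]
    at_low = classify_combinatorial(prof, threshold=t_low).loc[0, "combinatorial"]
    assert at_low or not at_high  # lowering threshold never loses a call


def _identity_norm(glu=0.9, da=0.4, gaba=0.05, n=200):
    rng = np.random.default_rng(0)
    vals = np.zeros((3, n))
    vals[0, : int(glu * n)] = 1.0
    vals[1, : int(da * n)] = 1.0
    vals[2, : int(gaba * n)] = 1.0
    return make_norm(vals, genes=["Slc17a6", "Th", "Gad1"])


def test_identity_dominance_order():
    ident, scores, tie = name_identity(_identity_norm(), np.zeros(200, dtype=int), 0)
    assert ident == "GLU>DA"
    assert not tie
    assert scores["GLU"] == pytest.approx(0.9)


def test_identity_single_system():
    ident, _, _ = name_identity(_identity_norm(glu=0.05, da=0.1, gaba=0.8),
                                np.zeros(200, dtype=int), 0)
    assert ident == "GABA"


def test_identity_tie_alphabetical_and_flagged():
    ident, _, tie = name_identity(_identity_norm(glu=0.4, da=0.4, gaba=0.0),
                                  np.zeros(200, dtype=int), 0)
    assert ident == "DA>GLU"
    assert tie


def test_identity_undetermined_below_floor():
    ident, _, _ = name_identity(_identity_norm(glu=0.05, da=0.05, gaba=0.05),
                                np.zeros(200, dtype=int), 0)
    assert ident == "undetermined"


# ---------------------------------------------------------------------------
# Group comparison


def _two_group_setup(rng, p_a=0.3, p_b=0.3, n=300):
    vals = np.zeros((4, 2 * n))
    both_a = rng.random(n) < p_a
    both_b = rng.random(n) < p_b
    for r in (0, 2):  # ga, da expressed jointly in the "both" cells
        vals[r, :n][both_a] = 1.0
        vals[r, n:][both_b] = 1.0
    norm = make_norm(vals, genes=["ga", "gb", "da", "db"])
    labels = np.zeros(2 * n, dtype=int)
    meta = pd.DataFrame({"group": ["A"] * n + ["B"] * n})
    return norm, labels, meta


def test_compare_null_case(rng):
    norm, labels, meta = _two_group_setup(rng)
    res = compare_coexpression(norm, labels, meta, 0, PANEL2,
                               group_a="A", group_b="B", n_perm=500, seed=0)
    assert abs(res["difference"]) < 0.1
    assert res["p"] > 0.01


def test_compare_detects_planted_difference(rng):
    norm, labels, meta = _two_group_setup(rng, p_a=0.35, p_b=0.10)
    res = compare_coexpression(norm, labels, meta, 0, PANEL2,
                               group_a="A", group_b="B",
                               pairs=[("ga", "da")], n_perm=199, seed=0)
    assert res["difference"] > 0.1
    assert res["p"] < 0.01


def test_compare_no_permutations_returns_difference_only(rng):
    norm, labels, meta = _two_group_setup(rng)
    res = compare_coexpression(norm, labels, meta, 0, PANEL2,
                               group_a="A", group_b="B", n_perm=0)
    assert res["p"] is None
    assert np.isfinite(res["difference"])


def test_compare_empty_group_errors(rng):
    norm, labels, meta = _two_group_setup(rng)
    with pytest.raises(CotransmitError, match="no cells"):
        compare_coexpression(norm, labels, meta, 0, PANEL2,
                             group_a="A", group_b="C")


def _null_pvalues(n, n_reps=200):
    pvals = []
    for i in range(n_reps):
        r = np.random.default_rng(10_000 + i)
        norm, labels, meta = _two_group_setup(r, n=n)
        res = compare_coexpression(norm, labels, meta, 0, PANEL2,
                                   group_a="A", group_b="B",
                                   pairs=[("ga", "da")], n_perm=199, seed=i)
        pvals.append(res["p"])
    return np.array(pvals)


def test_compare_null_pvalues_uniform_when_statistic_near_continuous():
    """KS over 200 null replicates does not reject uniformity at 1%.

    Group size 1,500 keeps the proportion-difference grid fine relative to
    its null SD; at small n the add-one two-sided p is visibly conservative
    (covered by the next test), which is the expected discrete behavior.
    """
    pvals = _null_pvalues(n=1500)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_compare_null_pvalues_conservative_at_small_n():
    """Discrete ties may only push the null p upward, never anti-conservative."""
    pvals = _null_pvalues(n=80)
    for alpha in (0.01, 0.05, 0.1, 0.25):
        se = np.sqrt(alpha * (1 - alpha) / len(pvals))
        assert (pvals <= alpha).mean() <= alpha + 3 * se


# ---------------------------------------------------------------------------
# Expressing fraction per sample


def _sample_norm(fracs_by_sample, n=50):
    vals = []
    meta_rows = []
    for sample, group, frac in fracs_by_sample:
        v = np.zeros(n)
        v[: int(round(frac * n))] = 1.0
        vals.append(v)
        meta_rows += [{"sample": sample, "group": group}] * n
    norm = make_norm(np.concatenate(vals)[None, :], genes=["Arvcf"])
    return norm, pd.DataFrame(meta_rows)


def test_expressing_fraction_silent_and_full():
    norm, meta = _sample_norm([("s1", "A", 0.0), ("s2", "A", 0.0)])
    res = expressing_fraction_by_sample(norm, meta, "Arvcf")
    assert (res["per_sample"]["fraction"] == 0).all()
    norm, meta = _sample_norm([("s1", "A", 1.0), ("s2", "A", 1.0)])
    res = expressing_fraction_by_sample(norm, meta, "Arvcf")
    assert (res["per_sample"]["fraction"] == 1).all()


def test_expressing_fraction_group_test():
    norm, meta = _sample_norm(
        [("a1", "A", 0.5), ("a2", "A", 0.5), ("a3", "A", 0.5),
         ("b1", "B", 0.1), ("b2", "B", 0.1), ("b3", "B", 0.1)]
    )
    res = expressing_fraction_by_sample(norm, meta, "Arvcf", "A", "B")
    summ = res["summary"].set_index("group")
    assert summ.loc["A", "mean"] == pytest.approx(0.5)
    assert summ.loc["B", "mean"] == pytest.approx(0.1)
    assert res["p"] < 0.05


def test_expressing_fraction_single_sample_sd_missing():
    norm, meta = _sample_norm([("s1", "A", 0.4)])
    res = expressing_fraction_by_sample(norm, meta, "Arvcf")
    assert np.isnan(res["summary"]["sd"].iloc[0])
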