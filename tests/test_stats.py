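"""Statistics battery: AUC/U identity, oracles, Bonferroni, report logic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tuggait.stats import (
    StatsConfig,
    build_shortlist,
    compare_groups,
    discriminate,
    kruskal_wallis,
    mann_whitney_auc,
    run_statistics,
    severity_correlation,
    spearman_manual,
)


# ----------------------------------------------------------------------
# AUC
# ----------------------------------------------------------------------
def test_auc_complete_separation():
    auc, u, p = mann_whitney_auc([4, 5, 6], [1, 2, 3])
    assert auc == 1.0 and u == 9.0


def test_auc_interleaved():
    auc, _, _ = mann_whitney_auc([2, 4], [1, 3])
    assert auc == pytest.approx(0.75)  # 3 of 4 concordant pairs


def test_auc_equals_u_over_n1n2_and_sklearn(rng):
    """Exact AUC-U identity (ties included) against the empirical ROC area."""
    from sklearn.metrics import roc_auc_score

    for _ in range(200):
        n1, n2 = rng.integers(3, 25, 2)
        x = rng.integers(0, 6, n1).astype(float)   # heavy ties
        y = rng.integers(0, 6, n2).astype(float)
        auc, u, _ = mann_whitney_auc(x, y)
        assert auc == pytest.approx(u / (n1 * n2), abs=1e-15)
        labels = np.r_[np.ones(n1), np.zeros(n2)]
        if len(np.unique(np.r_[x, y])) > 1:
            ref = roc_auc_score(labels, np.r_[x, y])
            assert auc == pytest.approx(ref, abs=1e-12)


def test_constant_feature_degenerates():
    auc, _, p = mann_whitney_auc([1.0, 1.0], [1.0, 1.0, 1.0])
    assert auc == 0.5 and p == 1.0


def test_discriminate_orientation():
    mat = pd.DataFrame({"group": ["HC"] * 3 + ["TD"] * 3,
                        "f": [1, 2, 3, 4, 5, 6]})
    row = discriminate(mat, "f", ("TD", "HC"))
    assert row["auc"] == 1.0 and row["higher_group"] == "TD"
    row = discriminate(mat, "f", ("HC", "TD"))
    assert row["auc"] == 1.0 and row["higher_group"] == "TD"
    assert 0.5 <= row["auc"] <= 1.0


# ----------------------------------------------------------------------
# Kruskal-Wallis
# ----------------------------------------------------------------------
def _manual_kw(groups):
    """Tie-corrected H from the rank-sum formula (independent of scipy)."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


def test_kw_matches_rank_formula(rng):
    for _ in range(50):
        groups = [rng.integers(0, 8, rng.integers(4, 10)).astype(float)
                  for _ in range(3)]
        if all(np.all(g == groups[0][0]) for g in groups):
            continue
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(_manual_kw(groups), abs=1e-10)


def test_kw_exhaustive_permutation_small():
    """On a tiny integer fixture the observed H equals the oracle H computed
    on the identical relabeling inside a full permutation enumeration, and
    the permutation p-value is consistent with rejection at the chi-square p."""
    import itertools

    a = np.array([1.0, 3.0, 5.0, 7.0])
    b = np.array([2.0, 4.0, 6.0, 8.0])
    c = np.array([9.0, 10.0, 11.0, 12.0])
    h_obs, p_chi2 = kruskal_wallis([a, b, c])
    pooled = np.concatenate([a, b, c])
    n = len(pooled)
    count_ge = 0
    total = 0
    idx = set(range(n))
    for ia in itertools.combinations(range(n), 4):
        rest = sorted(idx - set(ia))
        for ib in itertools.combinations(rest, 4):
            ic = sorted(set(rest) - set(ib))
            h = _manual_kw([pooled[list(ia)], pooled[list(ib)], pooled[ic]])
            total += 1
            if h >= h_obs - 1e-12:
                count_ge += 1
    assert total == 34650
    p_perm = count_ge / total
    # observed labeling is part of the enumeration; H matches itself exactly
    assert h_obs == pytest.approx(_manual_kw([a, b, c]), abs=1e-12)
    assert (p_perm < 0.05) == (p_chi2 < 0.05)
    assert p_perm < 0.05  # groups clearly separated


def test_bonferroni_triples_and_caps():
    mat = pd.DataFrame({
        "group": ["HC"] * 12 + ["TD"] * 12 + ["PIGD"] * 12,
        "f": np.r_[np.arange(12), np.arange(12) + 6.0, np.arange(12) + 12.0],
    })
    row = compare_groups(mat, "f")
    assert row["kw_p"] < 0.05
    _, _, raw = mann_whitney_auc(
        mat[mat.group == "HC"]["f"].to_numpy(),
        mat[mat.group == "TD"]["f"].to_numpy())
    assert row["p_HC_vs_TD"] == pytest.approx(min(1.0, 3 * raw))
    assert row["p_HC_vs_TD"] >= raw
    assert 0 < row["p_HC_vs_TD"] <= 1.0


def test_degenerate_all_identical():
    mat = pd.DataFrame({"group": ["HC"] * 5 + ["TD"] * 5 + ["PIGD"] * 5,
                        "f": 3.14})
    row = compare_groups(mat, "f")
    assert row["kw_p"] == 1.0 and row["degenerate"]


def test_summary_display_switch(rng):
    normal = rng.normal(10, 1, 45)
    skewed = rng.lognormal(1, 1.2, 45)
    for vals, token in ((normal, "±"), (skewed, "~")):
        mat = pd.DataFrame({"group": ["HC"] * 15 + ["TD"] * 15 + ["PIGD"] * 15,
                            "f": vals})
        row = compare_groups(mat, "f")
        assert token in row["summary_HC"]


# ----------------------------------------------------------------------
# Spearman
# ----------------------------------------------------------------------
def test_spearman_rank_invariance():
    mat = pd.DataFrame({"group": ["TD"] * 8,
                        "f": np.exp(np.arange(8.0)),
                        "updrs_part3_total": np.arange(8.0) ** 2})
    row = severity_correlation(mat, "f", "TD")
    assert row["r"] == pytest.approx(1.0)
    mat["f"] = -mat["f"]
    assert severity_correlation(mat, "f", "TD")["r"] == pytest.approx(-1.0)


def test_spearman_matches_rank_then_pearson(rng):
    for _ in range(50):
        x = rng.integers(0, 10, 20).astype(float)
        y = rng.integers(0, 10, 20).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            continue
        r_scipy = sps.spearmanr(x, y).statistic
        assert spearman_manual(x, y) == pytest.approx(r_scipy, abs=1e-12)


def test_spearman_guards():
    mat = pd.DataFrame({"group": ["TD"] * 3, "f": [1.0, 2.0, 3.0],
                        "updrs_part3_total": [1.0, 2.0, 3.0]})
    assert severity_correlation(mat, "f", "TD")["flag"] == "insufficient n"
    mat = pd.DataFrame({"group": ["TD"] * 6, "f": [2.0] * 6,
                        "updrs_part3_total": np.arange(6.0)})
    assert severity_correlation(mat, "f", "TD")["flag"] == "zero variance"


# ----------------------------------------------------------------------
# Report assembly
# ----------------------------------------------------------------------
def _constructed_matrix(rng, n=20, arm_effect=True):
    rows = []
    for g, base in (("HC", 0.0), ("TD", 0.0), ("PIGD", -60.0 if arm_effect else 0.0)):
        for i in range(n):
            rows.append({
                "group": g,
                "subject_id": f"{g}{i}",
                "updrs_part3_total": 0.0 if g == "HC" else rng.normal(25, 8),
                "MAS Arm Peak Velocity (°/s)": rng.normal(170 + base, 12),
                "LAS Arm Peak Velocity (°/s)": rng.normal(175 + base, 12),
                "MAS Swing (%)": rng.normal(39.5, 1.5),
            })
    return pd.DataFrame(rows)


def test_shortlist_differentiation_panel(rng):
    """A cohort where only arm velocities differ TD vs PIGD puts exactly
    those features in the differentiation panel."""
    mat = _constructed_matrix(rng)
    rep = run_statistics(mat, features=[
        "MAS Arm Peak Velocity (°/s)", "LAS Arm Peak Velocity (°/s)",
        "MAS Swing (%)"])
    assert set(rep.shortlist["subtype_differentiation"]) == {
        "MAS Arm Peak Velocity (°/s)", "LAS Arm Peak Velocity (°/s)"}
    assert "MAS Swing (%)" not in rep.shortlist["early_detection"]


def test_empty_significant_set_gives_empty_shortlist(rng):
    mat = _constructed_matrix(rng, arm_effect=False)
    rep = run_statistics(mat, features=["MAS Swing (%)"])
    assert rep.shortlist["early_detection"] == []
    assert rep.shortlist["subtype_differentiation"] == {}


def test_report_regeneration_is_byte_identical(rng, tmp_path):
    mat = _constructed_matrix(rng)
    feats = ["MAS Arm Peak Velocity (°/s)", "MAS Swing (%)"]
    d1, d2 = tmp_path / "a", tmp_path / "b"
    run_statistics(mat, features=feats).to_csv(d1)
    run_statistics(mat, features=feats).to_csv(d2)
    for name in ("group_comparison.csv", "discrimination_auc.csv",
                 "severity_correlation.csv", "biomarker_shortlist.json"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


def test_dunn_posthoc_variant(rng):
    mat = _constructed_matrix(rng)
    row = compare_groups(mat, "MAS Arm Peak Velocity (°/s)",
                         StatsConfig(posthoc="dunn"))
    assert np.isfinite(row["p_HC_vs_PIGD"])
    assert 0 < row["p_HC_vs_PIGD"] <= 1.0
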