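"""Group comparison, discrimination and severity-correlation statistics for a
cohort feature matrix.

The battery mirrors standard practice for non-normally distributed gait
variables: Kruskal-Wallis across the three groups per feature; if significant,
pairwise Mann-Whitney tests Bonferroni-corrected over the three group pairs
(adjusted p = min(1, 3p)); per-group summaries shown as mean ± SD when every
group passes Shapiro-Wilk normality at alpha = 0.05 and as median (Q1~Q3)
otherwise.  Discrimination is quantified by the ROC area under the curve,
computed through the Mann-Whitney identity AUC = U / (n1 * n2) with half
credit for ties, oriented so AUC >= 0.5, with the tie-corrected
normal-approximation p-value.  Disease-severity association uses the Spearman
rank correlation against the motor-exam total within each patient subtype,
restricted to features passing the selection rule (significant omnibus test
and significant relevant pairwise comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import registry

ALPHA = 0.05
CONTRASTS = (("TD", "HC"), ("PIGD", "HC"), ("TD", "PIGD"))
PAIR_NAMES = ("HC vs TD", "HC vs PIGD", "TD vs PIGD")


@dataclass
class StatsConfig:
    alpha: float = ALPHA
    auc_threshold: float = 0.7
    posthoc: str = "mannwhitney"     # or "dunn"
    min_group_n: int = 2
    min_subtype_n: int = 5


@dataclass
class StatsReport:
    """Bundle of the comparison, discrimination and correlation tables."""

    comparison: pd.DataFrame
    discrimination: pd.DataFrame
    correlation: pd.DataFrame
    shortlist: dict = field(default_factory=dict)
    config: StatsConfig = field(default_factory=StatsConfig)

    def to_csv(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.comparison.to_csv(os.path.join(outdir, "group_comparison.csv"), index=False)
        self.discrimination.to_csv(os.path.join(outdir, "discrimination_auc.csv"), index=False)
        self.correlation.to_csv(os.path.join(outdir, "severity_correlation.csv"), index=False)
        import json

        with open(os.path.join(outdir, "biomarker_shortlist.json"), "w") as fh:
            json.dump(self.shortlist, fh, indent=1, sort_keys=True)


# ----------------------------------------------------------------------
# Building blocks
# ----------------------------------------------------------------------
def mann_whitney_auc(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(auc, u_stat, p) for samples x (group 1) vs y (group 2), tie-aware.

    AUC is P(X > Y) + 0.5 P(X = Y) = U1 / (n1 n2); p from the two-sided
    normal approximation with tie-corrected variance.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        return np.nan, np.nan, np.nan
    both = np.concatenate([x, y])
    if np.all(both == both[0]):
        return 0.5, 0.5 * n1 * n2, 1.0
    ranks = sps.rankdata(both)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    auc = u1 / (n1 * n2)
    n = n1 + n2
    _, tie_counts = np.unique(both, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        return auc, u1, 1.0
    z = (u1 - n1 * n2 / 2.0) / np.sqrt(var_u)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(auc), float(u1), float(min(p, 1.0))


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p."""
    clean = [np.asarray(g, float) for g in groups]
    clean = [g[np.isfinite(g)] for g in clean]
    if any(len(g) < 2 for g in clean):
        return np.nan, np.nan
    pooled = np.concatenate(clean)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*clean)
    return float(h), float(p)


def _summary(vals: np.ndarray, normal: bool) -> str:
    if len(vals) == 0:
        return ""
    if normal:
        return f"{np.mean(vals):.2f} ± {np.std(vals, ddof=1):.2f}"
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return f"{med:.2f} ({q1:.2f}~{q3:.2f})"


# ----------------------------------------------------------------------
# Per-feature operations
# ----------------------------------------------------------------------
def compare_groups(matrix: pd.DataFrame, feature: str,
                   config: StatsConfig | None = None) -> dict:
    """Kruskal-Wallis + Bonferroni-corrected pairwise tests for one feature."""
    config = config or StatsConfig()
    data = {g: matrix.loc[matrix["group"] == g, feature].dropna().to_numpy()
            for g in ("HC", "TD", "PIGD")}
    present = [g for g, v in data.items() if len(v) >= config.min_group_n]
    row = {"feature": feature}
    h, p = kruskal_wallis([data[g] for g in present]) if len(present) >= 2 else (np.nan, np.nan)
    row["kw_h"], row["kw_p"] = h, p
    row["degenerate"] = bool(np.isfinite(h) and h == 0.0)

    normal = all(
        len(data[g]) < 3 or sps.shapiro(data[g]).pvalue >= config.alpha
        for g in present
    )
    for g in ("HC", "TD", "PIGD"):
        row[f"summary_{g}"] = _summary(data[g], normal)
    row["normal_display"] = normal

    for (a, b), name in zip((("HC", "TD"), ("HC", "PIGD"), ("TD", "PIGD")), PAIR_NAMES):
        col = f"p_{a}_vs_{b}"
        if not np.isfinite(p) or p >= config.alpha:
            row[col] = np.nan
            continue
        if config.posthoc == "dunn":
            row[col] = _dunn_pair(data, a, b)
        else:
            _, _, praw = mann_whitney_auc(data[a], data[b])
            row[col] = min(1.0, 3.0 * praw) if np.isfinite(praw) else np.nan
    return row


def _dunn_pair(data: dict, a: str, b: str) -> float:
    """Dunn's z-test for one pair on the pooled ranks, Bonferroni x3."""
    pooled = np.concatenate([data[g] for g in ("HC", "TD", "PIGD")])
    labels = np.concatenate([[g] * len(data[g]) for g in ("HC", "TD", "PIGD")])
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n - 1))
    means = {g: ranks[labels == g].mean() for g in ("HC", "TD", "PIGD")}
    ns = {g: (labels == g).sum() for g in ("HC", "TD", "PIGD")}
    se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / ns[a] + 1.0 / ns[b]))
    if se == 0:
        return 1.0
    z = (means[a] - means[b]) / se
    return min(1.0, 3.0 * 2.0 * sps.norm.sf(abs(z)))


def discriminate(matrix: pd.DataFrame, feature: str, contrast: tuple[str, str]) -> dict:
    """Oriented AUC row for one feature and one group contrast."""
    a, b = contrast
    x = matrix.loc[matrix["group"] == a, feature].dropna().to_numpy()
    y = matrix.loc[matrix["group"] == b, feature].dropna().to_numpy()
    auc, u, p = mann_whitney_auc(x, y)
    row = {"feature": feature, "contrast": f"{a} vs {b}",
           "n_1": len(x), "n_2": len(y), "p": p}
    if not np.isfinite(auc):
        row.update({"auc": np.nan, "higher_group": ""})
        return row
    if auc >= 0.5:
        row.update({"auc": auc, "higher_group": a})
    else:
        row.update({"auc": 1.0 - auc, "higher_group": b})
    row["flag_constant"] = bool(p == 1.0 and auc == 0.5)
    return row


def severity_correlation(matrix: pd.DataFrame, feature: str, subtype: str,
                         score_col: str = "updrs_part3_total",
                         min_n: int = 5) -> dict:
    """Spearman correlation of one feature with the motor score in a subtype."""
    sub = matrix[matrix["group"] == subtype][[feature, score_col]].dropna()
    row = {"feature": feature, "subtype": subtype, "n": len(sub)}
    if len(sub) < min_n:
        row.update({"r": np.nan, "p": np.nan, "flag": "insufficient n"})
        return row
    x = sub[feature].to_numpy()
    y = sub[score_col].to_numpy()
    if np.all(x == x[0]) or np.all(y == y[0]):
        row.update({"r": np.nan, "p": np.nan, "flag": "zero variance"})
        return row
    r, p = sps.spearmanr(x, y)
    row.update({"r": float(r), "p": float(p), "flag": ""})
    return row


def spearman_manual(x: np.ndarray, y: np.ndarray) -> float:
    """Rank-then-Pearson Spearman coefficient with average ranks (reference)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


# ----------------------------------------------------------------------
# Full battery and report
# ----------------------------------------------------------------------
def run_statistics(matrix: pd.DataFrame, config: StatsConfig | None = None,
                   features: list[str] | None = None) -> StatsReport:
    """Run the full battery on a cohort feature matrix.

    ``matrix`` needs ``group`` plus feature columns (and ``updrs_part3_total``
    for the severity block).
    """
    config = config or StatsConfig()
    features = features or [f for f in registry.FEATURE_NAMES if f in matrix.columns]

    comp = pd.DataFrame([compare_groups(matrix, f, config) for f in features])

    disc_rows = []
    for f in features:
        for contrast in CONTRASTS:
            disc_rows.append(discriminate(matrix, f, contrast))
    disc = pd.DataFrame(disc_rows)

    corr_rows = []
    if "updrs_part3_total" in matrix.columns:
        for subtype in ("TD", "PIGD"):
            pair_col = "p_HC_vs_TD" if subtype == "TD" else "p_HC_vs_PIGD"
            for _, row in comp.iterrows():
                sig_kw = np.isfinite(row["kw_p"]) and row["kw_p"] < config.alpha
                sig_pair = (np.isfinite(row.get(pair_col, np.nan))
                            and row[pair_col] < config.alpha)
                sig_subdiff = (np.isfinite(row.get("p_TD_vs_PIGD", np.nan))
                               and row["p_TD_vs_PIGD"] < config.alpha)
                if sig_kw and (sig_pair or sig_subdiff):
                    corr_rows.append(severity_correlation(
                        matrix, row["feature"], subtype,
                        min_n=config.min_subtype_n))
    corr = pd.DataFrame(corr_rows, columns=["feature", "subtype", "n", "r", "p", "flag"])

    shortlist = build_shortlist(comp, disc, corr, config)
    return StatsReport(comparison=comp, discrimination=disc, correlation=corr,
                       shortlist=shortlist, config=config)


def build_shortlist(comp: pd.DataFrame, disc: pd.DataFrame, corr: pd.DataFrame,
                    config: StatsConfig | None = None) -> dict:
    """Biomarker shortlist by role.

    * early detection: significant vs HC with AUC >= threshold in either
      patient contrast;
    * subtype differentiation: significant TD vs PIGD pairwise comparison
      (AUC reported for context);
    * severity monitoring: significant severity correlation, per subtype.
    """
    config = config or StatsConfig()
    early, differ, monitor = [], {}, {}
    comp_ix = comp.set_index("feature")
    for feat in comp_ix.index:
        row = comp_ix.loc[feat]
        if not (np.isfinite(row["kw_p"]) and row["kw_p"] < config.alpha):
            continue
        for contrast, pcol in (("TD vs HC", "p_HC_vs_TD"), ("PIGD vs HC", "p_HC_vs_PIGD")):
            if np.isfinite(row.get(pcol, np.nan)) and row[pcol] < config.alpha:
                d = disc[(disc["feature"] == feat) & (disc["contrast"] == contrast)]
                auc = float(d["auc"].iloc[0]) if len(d) else np.nan
                if np.isfinite(auc) and auc >= config.auc_threshold and feat not in early:
                    early.append(feat)
        if np.isfinite(row.get("p_TD_vs_PIGD", np.nan)) and row["p_TD_vs_PIGD"] < config.alpha:
            d = disc[(disc["feature"] == feat) & (disc["contrast"] == "TD vs PIGD")]
            differ[feat] = float(d["auc"].iloc[0]) if len(d) else np.nan
    for _, row in corr.iterrows():
        if np.isfinite(row["p"]) and row["p"] < config.alpha:
            monitor.setdefault(row["subtype"], []).append(row["feature"])
    return {"early_detection": sorted(early),
            "subtype_differentiation": dict(sorted(differ.items())),
            "severity_monitoring": {k: sorted(v) for k, v in monitor.items()}}
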