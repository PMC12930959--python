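"""Differential expression, priority scoring, cross-sex concordance, cell fractions.

DEG calling follows the single-cell convention: per cell type, a two-sided
Wilcoxon rank-sum test of log-normalized expression between treatment and
vehicle cells, restricted to genes expressed (raw count > 0) in at least 10%
of the cells of either group, Bonferroni correction over the tested genes,
significance at adjusted p < 0.05. Two genes known to reflect technical
artefacts (Gm42418, AY036118) are excluded by default. DEGs are ranked by a
priority score |avg_log2FC| * (-log10(p_adj + 1e-300)).

The contrast direction is fixed as treatment minus vehicle: positive
avg_log2FC means up-regulated under estradiol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

DEFAULT_EXCLUDE = ("Gm42418", "AY036118")
PRIORITY_FLOOR = 1e-300
LOG2FC_EPS = 1e-9
EXACT_MAX_GROUP = 8

CONCORDANCE_SETS = (
    "concordant_up",
    "concordant_down",
    "xx_only_up",
    "xx_only_down",
    "xy_only_up",
    "xy_only_down",
    "discordant_up_xx_down_xy",
    "discordant_down_xx_up_xy",
)


def priority_score(avg_log2fc: float, p_adj: float) -> float:
    """|avg_log2FC| * (-log10(p_adj + 1e-300)); the small constant keeps the
    score finite when p_adj underflows to 0."""
    return abs(avg_log2fc) * (-np.log10(p_adj + PRIORITY_FLOOR))


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p by exhaustive enumeration of group assignments.

    Midranks handle ties; the p-value is the fraction of the C(n, n_a)
    assignments whose rank sum is at least as far from the null mean as the
    observed one. Exact for small groups regardless of ties.
    """
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, a.size
    ranks = st.rankdata(pooled)
    w_obs = ranks[:n_a].sum()
    mu = n_a * (n + 1) / 2.0
    dev = abs(w_obs - mu) - 1e-9
    count = 0
    for idx in combinations(range(n), n_a):
        if abs(ranks[list(idx)].sum() - mu) >= dev:
            count += 1
    return count / comb(n, n_a)


def _dense(x) -> np.ndarray:
    return np.asarray(x.toarray() if sp.issparse(x) else x, dtype=np.float64)


def wilcoxon_deg(
    cohort: ad.AnnData,
    group_a: np.ndarray,
    group_b: np.ndarray,
    min_pct: float = 0.10,
    exclude: tuple[str, ...] = DEFAULT_EXCLUDE,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum DEG table between two cell groups.

    ``cohort`` must be log-normalized (counts preserved in
    ``layers['counts']`` for the expression filter). ``group_a``/``group_b``
    are boolean masks over cells; group A is the treatment side. Returns one
    row per tested gene with ``avg_log2fc``, ``p``, ``p_adj`` (Bonferroni over
    tested genes), expression fractions, ``priority``, ``direction`` and
    ``significant``. Exact enumeration is used when both groups have at most
    8 cells, the tie-corrected normal approximation otherwise.
    """
    group_a = np.asarray(group_a, dtype=bool)
    group_b = np.asarray(group_b, dtype=bool)
    if not group_a.any() or not group_b.any():
        raise ValueError("both groups must be non-empty")
    counts = cohort.layers["counts"] if "counts" in cohort.layers else cohort.X
    ca = _dense(counts[np.flatnonzero(group_a)])
    cb = _dense(counts[np.flatnonzero(group_b)])
    pct_a = (ca > 0).mean(axis=0)
    pct_b = (cb > 0).mean(axis=0)

    genes = np.asarray(cohort.var_names)
    keep = ((pct_a >= min_pct) | (pct_b >= min_pct)) & ~np.isin(genes, list(exclude))
    tested = np.flatnonzero(keep)
    cols = ["gene", "avg_log2fc", "p", "p_adj", "pct_a", "pct_b",
            "priority", "direction", "significant"]
    if tested.size == 0:
        out = pd.DataFrame(columns=cols)
        out.attrs["status"] = "empty: no genes pass the expression filter"
        return out

    xa = _dense(cohort.X[np.flatnonzero(group_a)])[:, tested]
    xb = _dense(cohort.X[np.flatnonzero(group_b)])[:, tested]
    n_a, n_b = xa.shape[0], xb.shape[0]

    mean_a = np.expm1(xa).mean(axis=0)
    mean_b = np.expm1(xb).mean(axis=0)
    log2fc = np.log2((mean_a + LOG2FC_EPS) / (mean_b + LOG2FC_EPS))

    if max(n_a, n_b) <= EXACT_MAX_GROUP:
        p = np.array([_exact_ranksum_p(xa[:, j], xb[:, j]) for j in range(tested.size)])
    else:
        p = st.mannwhitneyu(xa, xb, axis=0, alternative="two-sided",
                            method="asymptotic").pvalue
    p_adj = np.minimum(p * tested.size, 1.0)
    prio = np.abs(log2fc) * (-np.log10(p_adj + PRIORITY_FLOOR))

    out = pd.DataFrame({
        "gene": genes[tested],
        "avg_log2fc": log2fc,
        "p": p,
        "p_adj": p_adj,
        "pct_a": pct_a[tested],
        "pct_b": pct_b[tested],
        "priority": prio,
        "direction": np.where(log2fc >= 0, "up", "down"),
        "significant": p_adj < alpha,
    })
    out.attrs["status"] = "ok"
    out.attrs["n_tested"] = int(tested.size)
    return out


@dataclass
class ConcordanceSets:
    """Eight-way partition of the union of XX and XY DEGs of one cell type.

    ``sets`` maps each partition label to its genes ordered by the maximum
    priority across the two sexes (descending); ``top`` holds the first
    ``top_k`` of each.
    """

    sets: dict[str, list[str]]
    top: dict[str, list[str]] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"set": name, "rank": i + 1, "gene": g}
            for name in CONCORDANCE_SETS
            for i, g in enumerate(self.sets[name])
        ]
        return pd.DataFrame(rows, columns=["set", "rank", "gene"])


def classify_concordance(
    degs_xx: pd.DataFrame, degs_xy: pd.DataFrame, top_k: int = 10
) -> ConcordanceSets:
    """Partition significant DEGs of the two sexes by direction agreement.

    Every gene in either sex's DEG list lands in exactly one of eight sets:
    concordant (same direction), sex-specific (one sex only, by direction),
    or discordant (opposite directions). Within each set genes are ordered by
    the maximum priority score across sexes; the top 10 are reported as the
    set's representative genes.
    """
    for name, df in (("XX", degs_xx), ("XY", degs_xy)):
        if df["gene"].duplicated().any():
            dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
            raise ValueError(f"duplicated gene {dup!r} in {name} DEG list")

    def _sig(df: pd.DataFrame) -> pd.DataFrame:
        if "significant" in df.columns:
            df = df[df["significant"]]
        return df.set_index("gene")

    xx, xy = _sig(degs_xx), _sig(degs_xy)
    best = {}
    for g in set(xx.index) | set(xy.index):
        px = xx.at[g, "priority"] if g in xx.index else -np.inf
        py = xy.at[g, "priority"] if g in xy.index else -np.inf
        best[g] = max(px, py)

    assign: dict[str, list[str]] = {name: [] for name in CONCORDANCE_SETS}
    for g in best:
        dx = xx.at[g, "direction"] if g in xx.index else None
        dy = xy.at[g, "direction"] if g in xy.index else None
        if dx and dy:
            if dx == dy:
                name = f"concordant_{dx}"
            else:
                name = "discordant_up_xx_down_xy" if dx == "up" else "discordant_down_xx_up_xy"
        elif dx:
            name = f"xx_only_{dx}"
        else:
            name = f"xy_only_{dy}"
        assign[name].append(g)

    for name in assign:
        assign[name].sort(key=lambda g: (-best[g], g))
    return ConcordanceSets(sets=assign, top={k: v[:top_k] for k, v in assign.items()})


def cell_type_fractions(cohort: ad.AnnData) -> pd.DataFrame:
    """Per-sample cell-type fractions with sex and treatment factors."""
    obs = cohort.obs
    counts = obs.groupby(["sample_id", "cell_type"], observed=True).size().unstack(fill_value=0)
    frac = counts.div(counts.sum(axis=1), axis=0)
    meta = obs[["sample_id", "sex", "treatment"]].drop_duplicates().set_index("sample_id")
    long = frac.reset_index().melt(id_vars="sample_id", var_name="cell_type",
                                   value_name="fraction")
    return long.join(meta, on="sample_id")


def cell_fraction_anova(fractions: pd.DataFrame, fdr_threshold: float = 0.05
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way ANOVA (sex x treatment, type-II SS) of cell-type fractions.

    One row per (cell type, effect in {sex, treatment, sex:treatment}) with F,
    degrees of freedom, p, partial eta squared = SS_effect/(SS_effect +
    SS_error), and BH FDR across cell types within each effect. The second
    return value holds Tukey HSD adjusted p-values over the four combined
    sex x treatment arms per cell type. A cell type whose fractions are
    identical across all samples yields F = 0, p = 1.
    """
    required = {"cell_type", "sex", "treatment", "fraction"}
    if not required <= set(fractions.columns):
        raise ValueError(f"fractions table must have columns {sorted(required)}")
    arms = fractions.groupby(["sex", "treatment"], observed=True).size()
    if len(arms) < 4 or (arms < 2).any():
        raise ValueError("need >= 2 samples in each of the four sex x treatment arms")

    anova_rows, tukey_rows = [], []
    for ct, sub in fractions.groupby("cell_type", observed=True):
        sub = sub.copy()
        if np.allclose(sub["fraction"].var(ddof=0), 0.0):
            for effect in ("sex", "treatment", "sex:treatment"):
                anova_rows.append({"cell_type": ct, "effect": effect, "F": 0.0,
                                   "df_effect": 1, "df_error": len(sub) - 4,
                                   "p": 1.0, "partial_eta_sq": 0.0})
            continue
        model = ols("fraction ~ C(sex) * C(treatment)", data=sub).fit()
        table = anova_lm(model, typ=2)
        ss_err = table.loc["Residual", "sum_sq"]
        df_err = int(table.loc["Residual", "df"])
        label_map = {"C(sex)": "sex", "C(treatment)": "treatment",
                     "C(sex):C(treatment)": "sex:treatment"}
        for raw, effect in label_map.items():
            ss = table.loc[raw, "sum_sq"]
            f_val = table.loc[raw, "F"]
            p_val = table.loc[raw, "PR(>F)"]
            if not np.isfinite(f_val):  # zero residual variance
                f_val, p_val = np.inf, 0.0
            anova_rows.append({
                "cell_type": ct, "effect": effect, "F": float(f_val),
                "df_effect": int(table.loc[raw, "df"]), "df_error": df_err,
                "p": float(p_val),
                "partial_eta_sq": float(ss / (ss + ss_err)) if (ss + ss_err) > 0 else 0.0,
            })
        arm = (sub["sex"].astype(str) + sub["treatment"].astype(str)).to_numpy()
        arm_labels = sorted(set(arm))
        groups = [sub.loc[arm == a, "fraction"].to_numpy() for a in arm_labels]
        tk = st.tukey_hsd(*groups)
        for i in range(len(arm_labels)):
            for j in range(i + 1, len(arm_labels)):
                tukey_rows.append({"cell_type": ct, "group1": arm_labels[i],
                                   "group2": arm_labels[j],
                                   "p_adj": float(tk.pvalue[i, j])})

    anova = pd.DataFrame(anova_rows)
    anova["fdr"] = np.nan
    for effect in anova["effect"].unique():
        m = anova["effect"] == effect
        anova.loc[m, "fdr"] = multipletests(anova.loc[m, "p"], method="fdr_bh")[1]
    anova["significant"] = anova["fdr"] < fdr_threshold
    return anova, pd.DataFrame(tukey_rows, columns=["cell_type", "group1", "group2", "p_adj"])
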