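"""Stratified rank-rank hypergeometric overlap between two signed gene rankings.

Each gene carries a signed significance score s = -log10(p) * sign(effect),
so up-regulated genes rank at the top of the list and down-regulated genes at
the bottom. The two lists are restricted to their shared genes, and a grid of
rank thresholds is scanned; at each threshold pair the overlap between the
two threshold-defined gene sets is scored with a hypergeometric test
(smaller of the over-enrichment and depletion tails, sign-encoded: positive
for over-enrichment). The stratified variant anchors each quadrant's scan at
the sign change of each list rather than at the list ends, giving four
quadrants: up-up and down-down (concordant), up-down and down-up (discordant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

P_FLOOR = 1e-300


def signed_score(p: float | np.ndarray, effect: float | np.ndarray) -> float | np.ndarray:
    """-log10(p) * sign(effect), with p floored at 1e-300; sign(0) = 0."""
    p = np.maximum(np.asarray(p, dtype=np.float64), P_FLOOR)
    out = -np.log10(p) * np.sign(np.asarray(effect, dtype=np.float64))
    return float(out) if out.ndim == 0 else out


def ranking_from_dea(dea: pd.DataFrame) -> pd.Series:
    """Signed ranking scores from an unfiltered DE table (gene, p, avg_log2fc)."""
    if dea["gene"].duplicated().any():
        raise ValueError("duplicated genes in DE table")
    s = signed_score(dea["p"].to_numpy(), dea["avg_log2fc"].to_numpy())
    return pd.Series(s, index=dea["gene"].to_numpy())


@dataclass
class RRHOMap:
    """Threshold-grid map of signed -log10 hypergeometric overlap p-values.

    ``matrix[i, j]`` scores the overlap at thresholds ``thresholds[i]`` (list
    A) and ``thresholds[j]`` (list B); ``quadrant`` labels each cell up_up /
    down_down / up_down / down_up. ``boundary_a``/``boundary_b`` give the
    number of positive-score genes in each list (the sign-change anchor).
    """

    matrix: np.ndarray
    quadrant: np.ndarray
    thresholds: np.ndarray
    step: int
    n_genes: int
    boundary_a: int
    boundary_b: int

    def quadrant_summary(self) -> pd.DataFrame:
        rows = []
        for q in ("up_up", "down_down", "up_down", "down_up"):
            mask = self.quadrant == q
            if not mask.any():
                rows.append({"quadrant": q, "max_signed_log10p": 0.0, "n_cells": 0})
                continue
            vals = self.matrix[mask]
            rows.append({"quadrant": q,
                         "max_signed_log10p": float(vals.max()),
                         "n_cells": int(mask.sum())})
        return pd.DataFrame(rows)


def _ranks(scores: pd.Series) -> pd.Series:
    # descending score, ties broken by gene id: rank 1 = most up-regulated
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    return pd.Series(np.arange(1, len(order) + 1), index=order)


def stratified_rrho(
    scores_a: pd.Series, scores_b: pd.Series, step: int | None = None
) -> RRHOMap:
    """Stratified RRHO map between two signed rankings.

    Restricts to shared genes (N), ranks each list by score descending, and
    evaluates every grid cell (i*step, j*step). In concordant quadrants the
    threshold sets grow from the matching list ends (top for up-up, bottom for
    down-down); in discordant quadrants one set grows from each end. The cell
    value is -log10 of the smaller hypergeometric tail, positive when overlap
    exceeds expectation, negative when depleted. Invariant under any
    order-and-sign-preserving rescaling of the scores, and symmetric:
    swapping the lists transposes the map.
    """
    shared = sorted(set(scores_a.index) & set(scores_b.index))
    n = len(shared)
    if n < 2:
        raise ValueError(f"need >= 2 shared genes, got {n}")
    a = scores_a[shared]
    b = scores_b[shared]
    if step is None:
        step = max(1, n // 100)
    if step < 1:
        raise ValueError("step must be >= 1")

    rank_a = _ranks(a)
    rank_b = _ranks(b)
    boundary_a = int((a > 0).sum())
    boundary_b = int((b > 0).sum())

    m = int(np.ceil(n / step))
    thresholds = np.minimum(np.arange(1, m + 1) * step, n)

    # joint rank histogram -> cumulative top-top overlap counts k(i, j)
    bins_a = np.searchsorted(thresholds, rank_a[shared].to_numpy(), side="left")
    bins_b = np.searchsorted(thresholds, rank_b[shared].to_numpy(), side="left")
    hist = np.zeros((m, m))
    np.add.at(hist, (bins_a, bins_b), 1.0)
    k_tt = hist.cumsum(axis=0).cumsum(axis=1)  # genes with rank_a <= t_i and rank_b <= t_j

    ti = thresholds[:, None].astype(float)
    tj = thresholds[None, :].astype(float)
    a_up = ti <= boundary_a
    b_up = tj <= boundary_b

    # per-cell set sizes and overlap, by quadrant geometry
    size_a = np.where(a_up, ti, n - ti)
    size_b = np.where(b_up, tj, n - tj)
    k = np.where(
        a_up & b_up, k_tt,
        np.where(~a_up & ~b_up, n - ti - tj + k_tt,
                 np.where(a_up & ~b_up, ti - k_tt, tj - k_tt)),
    )

    p_over = hypergeom.sf(k - 1, n, size_a, size_b)
    p_under = hypergeom.cdf(k, n, size_a, size_b)
    val = -np.log10(np.maximum(np.minimum(p_over, p_under), P_FLOOR))
    matrix = np.where(p_over <= p_under, val, -val)

    quadrant = np.where(
        a_up & b_up, "up_up",
        np.where(~a_up & ~b_up, "down_down",
                 np.where(a_up, "up_down", "down_up")),
    )
    return RRHOMap(matrix=matrix, quadrant=quadrant, thresholds=thresholds,
                   step=step, n_genes=n, boundary_a=boundary_a, boundary_b=boundary_b)
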