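"""Permutation-null Euclidean-distance test for per-cell-type transcriptomic shift.

For each cell type and treatment contrast within one sex, the test measures
the Euclidean distance between the two treatment groups' mean expression
profiles over z-scored highly variable genes, and compares it with a null
distribution obtained by reassigning cell labels at random while preserving
group sizes (B = 5,000 by default). The empirical p-value is the proportion
of permuted distances >= the observed one; the effect size is
logFC = log10(observed distance) - log10(median permuted distance).
Benjamini-Hochberg FDR is applied across all (cell type x contrast) rows and
significance is called at FDR < 0.05.

Cells are z-scored per gene across the pooled cells of the tested cell type
(both treatment groups together) so that the permutation null is exchangeable.
"""

from __future__ import annotations

import hashlib
import itertools
import zlib
from dataclasses import dataclass
from math import comb

import anndata as ad
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .preprocess import zscore_genes

DEFAULT_B = 5000
DEFAULT_MIN_CELLS = 10
DEFAULT_EXACT_CAP = 100_000


@dataclass
class ShiftTestResult:
    observed_distance: float
    null_median: float
    n_permutations: int
    empirical_p: float
    logfc: float
    n_a: int
    n_b: int
    mode: str
    status: str = "ok"
    null_distances: np.ndarray | None = None


def group_mean_profile(zmatrix: np.ndarray, cell_idx: np.ndarray) -> np.ndarray:
    """Arithmetic per-gene mean over the given cells (rows of zmatrix)."""
    idx = np.asarray(cell_idx)
    if idx.size == 0:
        raise ValueError("empty cell subset")
    return np.asarray(zmatrix, dtype=np.float64)[idx].mean(axis=0)


def _canonical_order(z: np.ndarray) -> np.ndarray:
    # order cells by a content hash so results do not depend on row order
    keys = [hashlib.blake2b(z[i].tobytes(), digest_size=8).digest() for i in range(z.shape[0])]
    return np.array(sorted(range(z.shape[0]), key=keys.__getitem__), dtype=int)


def _subset_distances(z: np.ndarray, subsets: np.ndarray, k: int) -> np.ndarray:
    """Distance between mean of each k-subset (boolean rows of ``subsets``) and
    the mean of its complement."""
    n = z.shape[0]
    total = z.sum(axis=0)
    s_a = subsets.astype(np.float64) @ z  # (B, genes)
    m_a = s_a / k
    m_b = (total[None, :] - s_a) / (n - k)
    return np.linalg.norm(m_a - m_b, axis=1)


def euclidean_shift_test(
    zmatrix: np.ndarray,
    labels: np.ndarray,
    B: int = DEFAULT_B,
    seed: int = 0,
    mode: str = "sampled",
    exact_cap: int = DEFAULT_EXACT_CAP,
    p_convention: str = "plain",
    keep_null: bool = False,
) -> ShiftTestResult:
    """Permutation test of the Euclidean distance between group mean profiles.

    Parameters
    ----------
    zmatrix
        Cells x genes array of z-scored expression (z-scoring over the pooled
        cells of both groups).
    labels
        Boolean per cell: True for group A, False for group B.
    mode
        ``"sampled"`` draws B random relabellings; ``"exact"`` enumerates all
        C(n, n_A) label assignments (allowed only when that count is at most
        ``exact_cap``); ``"auto"`` picks exact when cheap.
    p_convention
        ``"plain"`` gives p = b/B (the proportion of permuted distances >= the
        observed, ties included); ``"add_one"`` gives (b+1)/(B+1).

    Both the observed distance and the seeded p-value are invariant to the
    order of the cells and to swapping the two group labels.
    """
    z = np.ascontiguousarray(np.asarray(zmatrix, dtype=np.float64))
    labels = np.asarray(labels, dtype=bool)
    if labels.shape[0] != z.shape[0]:
        raise ValueError("labels length must equal number of cells")
    n_a, n_b = int(labels.sum()), int((~labels).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    n = n_a + n_b

    observed = float(np.linalg.norm(z[labels].mean(axis=0) - z[~labels].mean(axis=0)))

    # canonicalize: subsets are drawn over a content-ordered view, at the
    # smaller group's size (complement symmetry makes the choice label-free)
    order = _canonical_order(z)
    zc = z[order]
    k = min(n_a, n_b)
    n_exact = comb(n, k)

    if mode == "auto":
        mode = "exact" if n_exact <= min(exact_cap, B) else "sampled"
    if mode == "exact":
        if n_exact > exact_cap:
            raise ValueError(f"exact mode needs C({n},{k}) = {n_exact} <= exact_cap ({exact_cap})")
        subsets = np.zeros((n_exact, n), dtype=bool)
        for i, cmb in enumerate(itertools.combinations(range(n), k)):
            subsets[i, list(cmb)] = True
        null = _subset_distances(zc, subsets, k)
        n_perm = n_exact
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        null = np.empty(B)
        chunk = max(1, min(B, 512))
        pos = 0
        while pos < B:
            b = min(chunk, B - pos)
            subsets = np.zeros((b, n), dtype=bool)
            for i in range(b):
                subsets[i, rng.choice(n, size=k, replace=False)] = True
            null[pos:pos + b] = _subset_distances(zc, subsets, k)
            pos += b
        n_perm = B
    else:
        raise ValueError(f"unknown mode {mode!r}")

    b_count = int(np.sum(null >= observed - 1e-12))
    if p_convention == "plain":
        p = b_count / n_perm
    elif p_convention == "add_one":
        p = (b_count + 1) / (n_perm + 1)
    else:
        raise ValueError(f"unknown p_convention {p_convention!r}")

    null_median = float(np.median(null))
    status = "ok"
    if observed == 0.0:
        logfc = 0.0 if null_median == 0.0 else -np.inf
        status = "degenerate: zero observed distance" if null_median == 0.0 else status
    elif null_median == 0.0:
        logfc = np.inf
        status = "degenerate: zero null median"
    else:
        logfc = float(np.log10(observed) - np.log10(null_median))

    return ShiftTestResult(
        observed_distance=observed, null_median=null_median, n_permutations=n_perm,
        empirical_p=float(p), logfc=logfc, n_a=n_a, n_b=n_b, mode=mode, status=status,
        null_distances=null if keep_null else None,
    )


def _child_seed(root: int, label: str) -> int:
    return int(np.random.SeedSequence([int(root), zlib.crc32(label.encode())])
               .generate_state(1)[0] % (2**31))


def sensitivity_scan(
    cohort: ad.AnnData,
    hvg: list[str],
    contrasts: list[tuple[str, tuple[str, str]]] | None = None,
    B: int = DEFAULT_B,
    seed: int = 0,
    min_cells: int = DEFAULT_MIN_CELLS,
    mode: str = "sampled",
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Run the Euclidean shift test for every (cell type x contrast).

    ``cohort`` must be log-normalized with ``sex``, ``treatment`` and
    ``cell_type`` obs columns. Default contrasts are E2 vs V within each sex.
    Rows where either group has fewer than ``min_cells`` cells are reported
    with status ``"skipped: min cells"`` and excluded from FDR. Per-row child
    seeds derive from the root seed and the (cell type, contrast) label, so a
    row's p-value does not depend on scan order.
    """
    if contrasts is None:
        contrasts = [("XX", ("E2", "V")), ("XY", ("E2", "V"))]
    if "cell_type" not in cohort.obs.columns:
        raise ValueError("cohort must carry a 'cell_type' obs column")
    hvg_idx = cohort.var_names.get_indexer(hvg)
    if (hvg_idx < 0).any():
        missing = [g for g, i in zip(hvg, hvg_idx) if i < 0]
        raise ValueError(f"HVGs absent from cohort: {missing[:5]}")

    rows = []
    cell_types = sorted(cohort.obs["cell_type"].unique())
    for ct in cell_types:
        for sex, (trt_a, trt_b) in contrasts:
            label = f"{sex}{trt_a[0]}.v.{sex}{trt_b[0]}"
            sel = (cohort.obs["cell_type"] == ct) & (cohort.obs["sex"] == sex)
            in_a = sel & (cohort.obs["treatment"] == trt_a)
            in_b = sel & (cohort.obs["treatment"] == trt_b)
            n_a, n_b = int(in_a.sum()), int(in_b.sum())
            base = {"cell_type": ct, "contrast": label, "n_a": n_a, "n_b": n_b}
            if min(n_a, n_b) < min_cells:
                rows.append({**base, "observed_distance": np.nan, "null_median": np.nan,
                             "n_permutations": 0, "empirical_p": np.nan, "logfc": np.nan,
                             "status": "skipped: min cells"})
                continue
            pooled = (in_a | in_b).to_numpy()
            z = zscore_genes(cohort.X[np.flatnonzero(pooled)][:, hvg_idx])
            labels = in_a.to_numpy()[pooled]
            res = euclidean_shift_test(
                z, labels, B=B, seed=_child_seed(seed, f"{ct}|{label}"), mode=mode)
            rows.append({**base, "observed_distance": res.observed_distance,
                         "null_median": res.null_median, "n_permutations": res.n_permutations,
                         "empirical_p": res.empirical_p, "logfc": res.logfc,
                         "status": res.status})

    table = pd.DataFrame(rows)
    if table.empty or table["status"].str.startswith("skipped").all():
        raise ValueError("no eligible (cell type x contrast) rows; check min_cells")
    tested = ~table["status"].str.startswith("skipped")
    fdr = np.full(len(table), np.nan)
    fdr[tested.to_numpy()] = multipletests(
        table.loc[tested, "empirical_p"].to_numpy(), method="fdr_bh")[1]
    table["fdr"] = fdr
    table["significant"] = (table["fdr"] < fdr_threshold) & tested
    return table
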