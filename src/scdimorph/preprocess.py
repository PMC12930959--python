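"""Cell QC, log-normalization, VST highly-variable-gene selection, z-scoring.

Conventions, stated once so downstream numbers are unambiguous:

* QC gene-count bounds are inclusive ([min_genes, max_genes]); the UMI and
  mitochondrial-fraction bounds are strict (<). Both are configurable.
* Log-normalization uses the natural log: log(1 + count/total * scale_factor)
  with scale_factor 10,000 by default.
* z-scoring uses the population SD (divide by n).
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.nonparametric.smoothers_lowess import lowess


@dataclass(frozen=True)
class QCThresholds:
    min_genes: int = 200
    max_genes: int = 7000
    max_umi: int = 20000
    max_mito_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes must be <= max_genes")
        if min(self.min_genes, self.max_genes, self.max_umi) <= 0 or self.max_mito_fraction <= 0:
            raise ValueError("all QC thresholds must be > 0")


def _counts_matrix(cohort: ad.AnnData) -> sp.csr_matrix:
    x = cohort.X
    return x.tocsr() if sp.issparse(x) else sp.csr_matrix(np.asarray(x))


def qc_filter(
    cohort: ad.AnnData, thresholds: QCThresholds = QCThresholds()
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Remove low-quality cells; return the filtered cohort and a per-cell report.

    A cell is retained when min_genes <= detected genes <= max_genes, total
    UMI < max_umi and mitochondrial-read fraction < max_mito_fraction. The
    report lists every input cell with its metrics, pass flag, and the failed
    criteria (semicolon-joined) for removed cells. Applying the filter twice
    is a no-op.
    """
    if cohort.n_obs == 0:
        raise ValueError("cohort has zero cells")
    if "is_mito" not in cohort.var.columns:
        raise ValueError("gene metadata must carry an 'is_mito' column")
    x = _counts_matrix(cohort)
    n_genes = np.asarray((x > 0).sum(axis=1)).ravel()
    total = np.asarray(x.sum(axis=1)).ravel()
    mito_counts = np.asarray(x[:, cohort.var["is_mito"].to_numpy()].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_counts / np.maximum(total, 1), 1.0)

    t = thresholds
    fails = {
        "low_genes": n_genes < t.min_genes,
        "high_genes": n_genes > t.max_genes,
        "high_umi": total >= t.max_umi,
        "high_mito": mito_frac >= t.max_mito_fraction,
    }
    fail_any = np.zeros(cohort.n_obs, dtype=bool)
    reasons = np.empty(cohort.n_obs, dtype=object)
    reasons[:] = ""
    for name, mask in fails.items():
        fail_any |= mask
        for i in np.flatnonzero(mask):
            reasons[i] = f"{reasons[i]};{name}" if reasons[i] else name

    report = pd.DataFrame(
        {
            "n_genes": n_genes,
            "total_umi": total.astype(int),
            "mito_fraction": mito_frac,
            "passed": ~fail_any,
            "failed_criteria": reasons,
        },
        index=cohort.obs_names,
    )
    if fail_any.all():
        counts = {k: int(v.sum()) for k, v in fails.items()}
        raise ValueError(f"QC removed every cell; failures per criterion: {counts}")
    return cohort[~fail_any].copy(), report


def lognormalize(cohort: ad.AnnData, scale_factor: float = 10000.0) -> ad.AnnData:
    """Depth-normalize and log-transform counts.

    value(g, c) = ln(1 + count(g, c) / total(c) * scale_factor). Returns a new
    AnnData whose ``X`` holds the normalized values; the raw counts stay in
    ``layers['counts']``. ``uns['lognorm']`` records the scale factor and log
    base. Zero counts map exactly to zero; the map is invertible given cell
    totals.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be > 0")
    x = _counts_matrix(cohort)
    total = np.asarray(x.sum(axis=1)).ravel()
    zero = np.flatnonzero(total == 0)
    if zero.size:
        names = list(cohort.obs_names[zero[:5]])
        raise ValueError(f"cells with zero total counts cannot be normalized: {names}")
    out = cohort.copy()
    norm = x.astype(np.float64).multiply(scale_factor / total[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    out.layers["counts"] = x
    out.X = norm
    out.uns["lognorm"] = {"scale_factor": float(scale_factor), "log_base": "e"}
    return out


def _vst_trend(log_mean: np.ndarray, log_var: np.ndarray, span: float = 0.3) -> np.ndarray:
    """Predicted log10 variance at each gene's log10 mean.

    Local linear regression (lowess, span 0.3) when enough informative genes
    are available; a global degree-2 polynomial otherwise.
    """
    if log_mean.size >= 200:
        order = np.argsort(log_mean, kind="stable")
        fitted = lowess(log_var[order], log_mean[order], frac=span,
                        it=2, return_sorted=False)
        out = np.empty_like(fitted)
        out[order] = fitted
        return out
    coef = np.polyfit(log_mean, log_var, deg=2)
    return np.polyval(coef, log_mean)


def select_hvg_vst(cohort: ad.AnnData, n_hvg: int = 2000, span: float = 0.3) -> list[str]:
    """Rank genes by variance-stabilized standardized variance; return the top n_hvg.

    Per gene over raw counts: fit a smooth trend of log10(variance) on
    log10(mean), standardize each gene's counts by its observed mean and the
    trend-predicted SD, clip standardized values at sqrt(n_cells), and rank by
    the variance of the clipped values (descending; ties broken by gene id).
    Deterministic — no RNG involved.
    """
    x = _counts_matrix(cohort).astype(np.float64)
    n = cohort.n_obs
    mean = np.asarray(x.mean(axis=0)).ravel()
    sq = np.asarray(x.multiply(x).mean(axis=0)).ravel()
    var = (sq - mean**2) * n / max(n - 1, 1)
    # guard against cancellation noise making constant genes look variable
    var[var <= (mean**2 + 1.0) * 1e-10] = 0.0

    informative = (var > 0) & (mean > 0)
    n_inf = int(informative.sum())
    if n_inf < n_hvg:
        raise ValueError(
            f"only {n_inf} genes with nonzero variance; cannot select {n_hvg} HVGs"
        )
    idx = np.flatnonzero(informative)
    log_mean = np.log10(mean[idx])
    log_var = np.log10(var[idx])
    exp_sd = np.sqrt(10.0 ** _vst_trend(log_mean, log_var, span=span))

    clip = np.sqrt(n)
    std_var = np.zeros(cohort.n_vars)
    xc = x.tocsc()
    for pos, g in enumerate(idx):
        col = xc.data[xc.indptr[g]:xc.indptr[g + 1]]
        m, sd = mean[g], exp_sd[pos]
        z_nz = np.minimum((col - m) / sd, clip)
        z_zero = min(-m / sd, clip)
        n_zero = n - col.size
        total = float(np.sum(z_nz**2) + n_zero * z_zero**2)
        # variance of clipped standardized values about the (standardized) gene mean
        std_var[g] = total / max(n - 1, 1)

    gene_ids = np.asarray(cohort.var_names)
    order = sorted(idx, key=lambda g: (-std_var[g], gene_ids[g]))
    return [gene_ids[g] for g in order[:n_hvg]]


def zscore_genes(matrix: np.ndarray | sp.spmatrix, cell_idx: np.ndarray | None = None) -> np.ndarray:
    """Z-score each gene (column) over the given cells using the population SD.

    ``matrix`` is cells x genes. Genes with zero SD map to all-zero columns.
    Returns a dense float array restricted to ``cell_idx`` when given.
    """
    if sp.issparse(matrix):
        matrix = matrix.toarray()
    m = np.asarray(matrix, dtype=np.float64)
    if cell_idx is not None:
        m = m[np.asarray(cell_idx)]
    if m.shape[0] == 0:
        raise ValueError("empty cell subset")
    if m.shape[0] < 2:
        raise ValueError("z-scoring needs at least 2 cells")
    mu = m.mean(axis=0)
    sd = m.std(axis=0)  # population SD
    out = m - mu
    nz = sd > 0
    out[:, nz] /= sd[nz]
    out[:, ~nz] = 0.0
    return out
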