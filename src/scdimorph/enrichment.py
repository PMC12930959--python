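"""Gene-set enrichment machinery: hypergeometric tests, estrogen-receptor
target partitioning, LD-based marker pruning, and marker-set enrichment (MSEA).

One hypergeometric engine serves both pathway and transcription-factor
libraries; they differ only in their pass thresholds (pathways: Bonferroni
p_adj < 0.01 and overlap >= 20; TFs: p_adj < 0.05). The enrichment score is
GeneRatio / BackgroundRatio = (k/n) / (K/N) with N the total genes detected
in the cohort.

MSEA asks whether markers (SNPs) mapped to a gene set carry stronger trait
association than markers of random gene sets, using a chi-square-like
standardized-excess statistic summed over tail quantile cutoffs of the global
association-score distribution, with a gene-permutation null. Markers are
first de-correlated by greedy LD pruning at r2 <= 0.70 (marker dependency
filtering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .simulate import MarkerTable

DEFAULT_QUANTILES = (0.50, 0.60, 0.70, 0.80, 0.85, 0.90, 0.95, 0.98, 0.99, 0.999)
DEFAULT_KAPPA = 1.0


@dataclass
class GeneSetLibrary:
    """Named gene sets plus the size of the background universe.

    ``background`` is the total number of genes detected in the study (after
    QC); ``universe`` optionally lists them, enabling the query-containment
    check.
    """

    sets: dict[str, list[str]]
    background: int
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        clean = {}
        for name, genes in self.sets.items():
            uniq = list(dict.fromkeys(genes))
            if not uniq:
                continue
            clean[name] = uniq
        self.sets = clean
        if self.background < max((len(g) for g in self.sets.values()), default=0):
            raise ValueError("background smaller than the largest gene set")


def hypergeom_enrich(
    query: list[str] | set[str],
    library: GeneSetLibrary,
    p_adj_threshold: float | None = None,
    min_overlap: int = 20,
    mode: str = "pathway",
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query gene set in a library.

    For each library set of size K, with query size n and background N, the
    p-value is P(X >= k) for the observed overlap k under sampling without
    replacement; Bonferroni correction runs over the sets tested. ``mode``
    picks the pass rule: ``"pathway"`` requires p_adj < 0.01 and k >= 20,
    ``"tf"`` requires p_adj < 0.05 (min_overlap ignored). Query genes outside
    the declared universe are dropped (counted in ``attrs['n_dropped']``).
    """
    query = list(dict.fromkeys(query))
    if not query:
        raise ValueError("empty query gene set")
    n_dropped = 0
    if library.universe is not None:
        kept = [g for g in query if g in library.universe]
        n_dropped = len(query) - len(kept)
        if n_dropped:
            warnings.warn(f"dropped {n_dropped} query genes outside the background universe")
        query = kept
        if not query:
            raise ValueError("no query genes remain within the background universe")
    qset = set(query)
    n, big_n = len(query), library.background

    if mode == "tf":
        p_cut = 0.05 if p_adj_threshold is None else p_adj_threshold
        k_cut = 1
    elif mode == "pathway":
        p_cut = 0.01 if p_adj_threshold is None else p_adj_threshold
        k_cut = min_overlap
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rows = []
    for name, genes in sorted(library.sets.items()):
        big_k = len(genes)
        k = len(qset & set(genes))
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        gene_ratio = k / n
        bg_ratio = big_k / big_n
        rows.append({"set": name, "overlap": k, "query_size": n, "set_size": big_k,
                     "background": big_n, "gene_ratio": gene_ratio,
                     "background_ratio": bg_ratio,
                     "enrichment_score": gene_ratio / bg_ratio if bg_ratio > 0 else np.nan,
                     "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.minimum(out["p"] * len(out), 1.0)
    out["pass"] = (out["p_adj"] < p_cut) & (out["overlap"] >= k_cut)
    out.attrs["n_dropped"] = n_dropped
    return out


def er_target_partition(
    enriched_tfs: list[str], er_targets: list[str]
) -> dict[str, object]:
    """Split enriched TFs into direct estrogen-receptor targets vs the rest."""
    enriched = list(dict.fromkeys(enriched_tfs))
    targets = set(er_targets)
    direct = [t for t in enriched if t in targets]
    indirect = [t for t in enriched if t not in targets]
    frac = len(direct) / len(enriched) if enriched else 0.0
    return {"direct": direct, "indirect": indirect, "fraction_direct": frac}


def mdf_prune(markers: MarkerTable, r2_threshold: float = 0.70) -> MarkerTable:
    """Greedy LD pruning of the marker table (marker dependency filtering).

    Markers are processed in descending association score (ties broken by
    marker id); a marker is kept iff its r2 with every already-kept marker is
    <= ``r2_threshold``. Only within-block pairs can be linked; a missing r2
    for a within-block pair is an error. With distinct scores the result does
    not depend on the input row order.
    """
    table = markers.table
    order = table.sort_values(["score", "marker_id"],
                              ascending=[False, True], kind="stable")
    kept_by_block: dict[object, list[str]] = {}
    kept_ids = []
    for _, row in order.iterrows():
        mid, block = row["marker_id"], row["block_id"]
        ok = True
        for other in kept_by_block.get(block, []):
            r2 = markers.pair_r2(mid, other)
            if r2 is None:
                raise ValueError(f"missing r2 for within-block pair ({mid}, {other})")
            if r2 > r2_threshold:
                ok = False
                break
        if ok:
            kept_ids.append(mid)
            kept_by_block.setdefault(block, []).append(mid)
    kept_set = set(kept_ids)
    pruned = table[table["marker_id"].isin(kept_set)].reset_index(drop=True)
    r2 = {pair: v for pair, v in markers.r2.items() if pair <= kept_set}
    return MarkerTable(table=pruned, r2=r2)


@dataclass
class MSEAResult:
    gene_set: str
    statistic: float
    p: float
    n_genes_mapped: int
    n_markers: int
    diagnostics: pd.DataFrame = field(repr=False, default=None)
    fdr: float = np.nan


def _quantile_counts(scores: np.ndarray, cutoffs: np.ndarray) -> np.ndarray:
    """# of scores >= each cutoff."""
    s = np.sort(scores)
    return scores.size - np.searchsorted(s, cutoffs, side="left")


def msea(
    deg_set: list[str] | set[str],
    markers: MarkerTable,
    quantiles: tuple[float, ...] = DEFAULT_QUANTILES,
    n_perm: int = 1000,
    kappa: float = DEFAULT_KAPPA,
    seed: int = 0,
) -> MSEAResult:
    """Marker-set enrichment of one gene set against the global marker background.

    For each tail quantile q_j of the global association-score distribution
    (cutoff c_j), let O_j be the number of set markers with score >= c_j and
    E_j = (set marker count) x (global fraction >= c_j). The statistic is
    X = sum_j (O_j - E_j) / sqrt(E_j + kappa). The null permutes gene-to-set
    membership (drawing random gene sets of the same gene count, preserving
    each gene's marker multiplicity); p = (1 + #{X_perm >= X}) / (1 + n_perm),
    so p >= 1/(n_perm + 1) always. With deg_set equal to all mapped genes,
    X = 0 exactly.
    """
    table = markers.table
    genes = table["gene"].to_numpy()
    scores = table["score"].to_numpy(dtype=np.float64)
    all_genes = sorted(set(genes))
    requested = set(deg_set)
    mapped = sorted(requested & set(all_genes))
    n_absent = len(requested) - len(mapped)
    if not mapped:
        raise ValueError("no deg_set genes present in the marker mapping")

    cutoffs = np.quantile(scores, quantiles)
    global_counts = _quantile_counts(scores, cutoffs).astype(float)
    global_frac = global_counts / scores.size

    # per-gene counts of markers >= each cutoff, and per-gene marker totals
    gene_ids = pd.Index(all_genes)
    gidx = gene_ids.get_indexer(genes)
    above = scores[:, None] >= cutoffs[None, :]
    per_gene = np.zeros((len(all_genes), len(cutoffs)))
    np.add.at(per_gene, gidx, above.astype(float))
    per_gene_total = np.bincount(gidx, minlength=len(all_genes)).astype(float)

    def _stat(member_idx: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, float]:
        o = per_gene[member_idx].sum(axis=0)
        n_markers = per_gene_total[member_idx].sum()
        e = n_markers * global_frac
        return float(np.sum((o - e) / np.sqrt(e + kappa))), o, e, n_markers

    member = gene_ids.get_indexer(mapped)
    x_obs, o_j, e_j, n_markers = _stat(member)

    rng = np.random.default_rng(seed)
    x_perm = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(len(all_genes), size=len(mapped), replace=False)
        x_perm[i] = _stat(pick)[0]
    p = (1 + int(np.sum(x_perm >= x_obs))) / (1 + n_perm)

    diag = pd.DataFrame({"quantile": quantiles, "cutoff": cutoffs,
                         "observed": o_j, "expected": e_j})
    res = MSEAResult(gene_set="deg_set", statistic=x_obs, p=p,
                     n_genes_mapped=len(mapped), n_markers=int(n_markers),
                     diagnostics=diag)
    res.n_genes_absent = n_absent
    return res


def msea_scan(
    sets: dict[str, list[str]],
    markers: MarkerTable,
    fdr_threshold: float = 0.05,
    **kwargs,
) -> pd.DataFrame:
    """MSEA over many gene sets with BH FDR across sets (significant < 0.05)."""
    seed = int(kwargs.pop("seed", 0))
    rows = []
    for i, (name, genes) in enumerate(sorted(sets.items())):
        res = msea(genes, markers, seed=seed + i, **kwargs)
        rows.append({"gene_set": name, "statistic": res.statistic, "p": res.p,
                     "n_genes_mapped": res.n_genes_mapped, "n_markers": res.n_markers})
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_threshold
    return out
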