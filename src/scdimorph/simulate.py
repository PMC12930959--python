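"""Synthetic cohort, network, and marker-table generators with planted ground truth.

Every downstream stage of the pipeline (QC, the Euclidean shift test, DEG
calling, key-driver analysis, marker-set enrichment) is validated against
data produced here, where the true effects are known by construction:

* ``generate_cohort`` draws negative-binomial gene counts for a 2x2
  (sex-chromosome complement x treatment) design over several labelled cell
  types, optionally planting a multivariate transcriptomic shift in chosen
  cell types of one sex and per-gene differential-expression effects with
  known signs.
* ``generate_grn`` builds a scale-free-ish gene regulatory network with one
  hub whose neighbourhood is enriched for DEG labels.
* ``generate_marker_table`` emits a GWAS-style marker-to-gene association
  table with block LD structure and one trait-enriched gene set.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

SEXES = ("XX", "XY")
TREATMENTS = ("E2", "V")
N_REPLICATES = 3


@dataclass(frozen=True)
class ShiftSpec:
    """A planted treatment shift: raise the log-mean of ``n_genes`` randomly
    chosen genes by ``delta`` per-gene SDs in (cell_types x sex x E2) cells.

    ``delta`` is expressed in units of the per-gene SD of log expression, the
    same scale on which the sensitivity test operates after z-scoring. For a
    negative binomial with mean mu and dispersion theta that SD is
    approximated (delta method) as sqrt(1/mu + 1/theta).
    """

    cell_types: tuple[str, ...]
    sex: str
    n_genes: int
    delta: float
    genes: tuple[str, ...] | None = None  # explicit override of the random choice

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError(f"shift delta must be >= 0, got {self.delta}")
        if self.sex not in SEXES:
            raise ValueError(f"shift sex must be one of {SEXES}, got {self.sex!r}")


@dataclass(frozen=True)
class DegEffect:
    """A planted per-gene effect: multiply the NB mean by 2**log2fc in
    (cell_type x sex x E2) cells."""

    gene: str
    cell_type: str
    sex: str
    log2fc: float

    @property
    def direction(self) -> str:
        return "up" if self.log2fc >= 0 else "down"


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the study design this pipeline targets: a 2x2 design
    (XX/XY x estradiol/vehicle) with three replicate samples per arm and
    several cell types, droplet-style overdispersed counts, and log-normal
    per-cell size factors.
    """

    seed: int = 0
    cell_types: tuple[str, ...] = ("ASPC", "Mac", "B", "T", "Endo")
    cells_per_group: int | Mapping[str, int] = 100
    n_genes: int = 2000
    nb_mean_range: tuple[float, float] = (0.1, 5.0)
    nb_dispersion: float = 10.0
    mito_gene_fraction: float = 0.02
    damaged_cell_fraction: float = 0.02
    mito_boost: float = 30.0
    library_size_cv: float = 0.3
    celltype_profile_sd: float = 0.4
    shift: ShiftSpec | None = None
    deg_effects: tuple[DegEffect, ...] = ()

    def __post_init__(self) -> None:
        for frac in (self.mito_gene_fraction, self.damaged_cell_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fractions must lie in [0, 1], got {frac}")
        lo, hi = self.nb_mean_range
        if not (0 < lo <= hi):
            raise ValueError(f"nb_mean_range must be positive and ordered, got {self.nb_mean_range}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for ct, n in self._cells_per_group_map().items():
            if n < 1:
                raise ValueError(f"cells_per_group must be >= 1 everywhere; cell type {ct!r} has {n}")
        seen: dict[tuple[str, str, str], DegEffect] = {}
        for eff in self.deg_effects:
            key = (eff.gene, eff.cell_type, eff.sex)
            if key in seen:
                raise ValueError(
                    f"conflicting deg effects for gene={eff.gene!r}, "
                    f"cell_type={eff.cell_type!r}, sex={eff.sex!r}"
                )
            seen[key] = eff

    def _cells_per_group_map(self) -> dict[str, int]:
        if isinstance(self.cells_per_group, Mapping):
            return dict(self.cells_per_group)
        return {ct: int(self.cells_per_group) for ct in self.cell_types}


def _gene_ids(n_genes: int, mito_fraction: float) -> tuple[list[str], np.ndarray]:
    n_mito = int(round(mito_fraction * n_genes))
    ids = [f"mt-g{i:05d}" for i in range(n_mito)]
    ids += [f"g{i:05d}" for i in range(n_mito, n_genes)]
    is_mito = np.zeros(n_genes, dtype=bool)
    is_mito[:n_mito] = True
    return ids, is_mito


def _size_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n)


def generate_cohort(config: SimConfig) -> ad.AnnData:
    """Draw a synthetic cell cohort with known planted structure.

    Returns an :class:`anndata.AnnData` with integer counts (cells x genes,
    CSR), per-cell metadata columns ``sample_id``, ``sex``, ``treatment``,
    ``replicate``, ``cell_type``; per-gene ``is_mito``; and the applied
    effects recorded in ``uns['truth']`` (keys ``'shift'`` and ``'deg'``,
    both data frames).

    Counts for gene g in a cell of type t are negative binomial with mean
    ``base_mean[g] * profile[t, g] * size_factor[cell]`` and shared
    dispersion; planted effects multiply the mean in the targeted
    (cell type, sex, E2) arm only. Identical config (including seed) gives
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids, is_mito = _gene_ids(config.n_genes, config.mito_gene_fraction)
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    for eff in config.deg_effects:
        if eff.gene not in gene_index:
            raise ValueError(f"deg effect references unknown gene {eff.gene!r}")
        if eff.cell_type not in config.cell_types:
            raise ValueError(f"deg effect references unknown cell type {eff.cell_type!r}")

    lo, hi = config.nb_mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))
    # cell-type expression profiles: per-(type, gene) log-normal modulation
    profiles = {
        ct: base_mean * rng.lognormal(mean=0.0, sigma=config.celltype_profile_sd, size=config.n_genes)
        for ct in config.cell_types
    }

    shift_genes: list[str] = []
    shift = config.shift
    if shift is not None:
        for ct in shift.cell_types:
            if ct not in config.cell_types:
                raise ValueError(f"shift references unknown cell type {ct!r}")
        if shift.genes is not None:
            shift_genes = list(shift.genes)
            for g in shift_genes:
                if g not in gene_index:
                    raise ValueError(f"shift references unknown gene {g!r}")
        else:
            non_mito = np.flatnonzero(~is_mito)
            if shift.n_genes > non_mito.size:
                raise ValueError("shift n_genes exceeds number of non-mito genes")
            picked = rng.choice(non_mito, size=shift.n_genes, replace=False)
            shift_genes = [gene_ids[i] for i in np.sort(picked)]

    cells_per = config._cells_per_group_map()
    theta = config.nb_dispersion

    blocks: list[np.ndarray] = []
    obs_rows: list[dict] = []
    truth_shift_rows: list[dict] = []
    truth_deg_rows: list[dict] = []

    deg_by_arm: dict[tuple[str, str], list[DegEffect]] = {}
    for eff in config.deg_effects:
        deg_by_arm.setdefault((eff.cell_type, eff.sex), []).append(eff)

    for ct in config.cell_types:
        n_arm = cells_per[ct]
        for sex in SEXES:
            for trt in TREATMENTS:
                mean = profiles[ct].copy()
                if trt == "E2":
                    if shift is not None and sex == shift.sex and ct in shift.cell_types:
                        idx = np.array([gene_index[g] for g in shift_genes], dtype=int)
                        sigma = np.sqrt(1.0 / mean[idx] + 1.0 / theta)
                        mean[idx] *= np.exp(shift.delta * sigma)
                        for g, s in zip(shift_genes, sigma):
                            truth_shift_rows.append(
                                {"gene": g, "cell_type": ct, "sex": sex,
                                 "delta": shift.delta, "log_sd": float(s)}
                            )
                    for eff in deg_by_arm.get((ct, sex), []):
                        mean[gene_index[eff.gene]] *= 2.0 ** eff.log2fc
                        truth_deg_rows.append(
                            {"gene": eff.gene, "cell_type": ct, "sex": sex,
                             "log2fc": eff.log2fc, "direction": eff.direction}
                        )
                sf = _size_factors(rng, n_arm, config.library_size_cv)
                mean_cells = np.outer(sf, mean)  # cells x genes
                if config.damaged_cell_fraction > 0 and is_mito.any():
                    n_damaged = int(round(config.damaged_cell_fraction * n_arm))
                    if n_damaged:
                        damaged = rng.choice(n_arm, size=n_damaged, replace=False)
                        mean_cells[np.ix_(damaged, np.flatnonzero(is_mito))] *= config.mito_boost
                lam = rng.gamma(shape=theta, scale=mean_cells / theta)
                counts = rng.poisson(lam)
                blocks.append(counts)
                arm = f"{sex}{'E' if trt == 'E2' else 'V'}"
                for i in range(n_arm):
                    rep = i % N_REPLICATES + 1
                    obs_rows.append(
                        {"sample_id": f"{arm}_{rep}", "sex": sex, "treatment": trt,
                         "replicate": rep, "cell_type": ct}
                    )

    counts = np.vstack(blocks)
    obs = pd.DataFrame(obs_rows)
    obs.index = [f"cell{i:06d}" for i in range(len(obs))]
    var = pd.DataFrame({"is_mito": is_mito}, index=pd.Index(gene_ids, name="gene_id"))

    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)
    adata.uns["truth"] = {
        "shift": pd.DataFrame(truth_shift_rows,
                              columns=["gene", "cell_type", "sex", "delta", "log_sd"]),
        "deg": pd.DataFrame(truth_deg_rows,
                            columns=["gene", "cell_type", "sex", "log2fc", "direction"]),
    }
    adata.uns["sim_config"] = {
        k: v for k, v in dataclasses.asdict(config).items()
        if k not in ("shift", "deg_effects")
    }
    return adata


def generate_grn(
    n_nodes: int,
    hub_spec: Mapping[str, object],
    seed: int = 0,
) -> tuple[nx.Graph, set[str], str]:
    """Scale-free-ish undirected network with one planted DEG-enriched hub.

    ``hub_spec`` keys: ``n_neighbors`` (hub degree), ``deg_fraction_in_neighborhood``
    (Bernoulli DEG rate among hub neighbours), ``background_deg_fraction``
    (rate elsewhere). Returns (graph, DEG label set, hub node id).
    """
    n_neighbors = int(hub_spec["n_neighbors"])
    p_hub = float(hub_spec["deg_fraction_in_neighborhood"])
    p_bg = float(hub_spec["background_deg_fraction"])
    if not (0.0 <= p_hub <= 1.0 and 0.0 <= p_bg <= 1.0):
        raise ValueError("DEG fractions must lie in [0, 1]")
    if n_neighbors >= n_nodes:
        raise ValueError(f"n_neighbors ({n_neighbors}) must be < n_nodes ({n_nodes})")

    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n_nodes, m=2, seed=int(rng.integers(2**31)))
    names = {i: f"g{i:05d}" for i in range(n_nodes)}
    g = nx.relabel_nodes(g, names)
    hub = str(hub_spec.get("hub", names[0]))
    # force the hub to the requested degree
    current = set(g.neighbors(hub))
    others = [n for n in g.nodes if n != hub]
    while len(current) > n_neighbors:
        drop = others[int(rng.integers(len(others)))]
        if drop in current and g.degree(drop) > 1:
            g.remove_edge(hub, drop)
            current.discard(drop)
    candidates = [n for n in others if n not in current]
    rng.shuffle(candidates)
    for n in candidates:
        if len(current) >= n_neighbors:
            break
        g.add_edge(hub, n)
        current.add(n)

    degs: set[str] = set()
    neighborhood = set(g.neighbors(hub))
    for node in sorted(g.nodes):
        if node == hub:
            continue
        p = p_hub if node in neighborhood else p_bg
        if rng.random() < p:
            degs.add(node)
    return g, degs, hub


@dataclass
class MarkerTable:
    """SNP-style marker associations: one row per marker with its mapped gene,
    association score (-log10 p), and LD block id; ``r2`` holds pairwise
    within-block linkage values keyed by frozenset of two marker ids."""

    table: pd.DataFrame
    r2: dict[frozenset, float] = field(default_factory=dict)

    def pair_r2(self, a: str, b: str) -> float | None:
        return self.r2.get(frozenset((a, b)))


def generate_marker_table(
    n_genes: int,
    markers_per_gene: int,
    ld_block_size: int,
    enriched_set: Sequence[str] = (),
    enrichment_shift: float = 0.0,
    seed: int = 0,
) -> MarkerTable:
    """GWAS-style marker table with block LD and an optional enriched gene set.

    Background gene markers carry association p drawn Uniform(0,1); markers of
    genes in ``enriched_set`` draw p ~ Beta(1/(1+enrichment_shift), 1), i.e.
    skewed toward 0 for positive shift and exactly uniform at shift 0. Scores
    are -log10(p). Markers of each gene are chunked into LD blocks of
    ``ld_block_size`` consecutive markers; within-block pairwise r2 is drawn
    Uniform(0.75, 0.99), between-block r2 is 0 (omitted).
    """
    if ld_block_size < 1:
        raise ValueError(f"ld_block_size must be >= 1, got {ld_block_size}")
    if enrichment_shift < 0:
        raise ValueError("enrichment_shift must be >= 0")
    genes = [f"g{i:05d}" for i in range(n_genes)]
    missing = set(enriched_set) - set(genes)
    if missing:
        raise ValueError(f"enriched_set genes not in universe: {sorted(missing)[:5]}")
    enriched = set(enriched_set)
    rng = np.random.default_rng(seed)
    a = 1.0 / (1.0 + enrichment_shift)

    rows = []
    r2: dict[frozenset, float] = {}
    block_counter = 0
    for gene in genes:
        p = rng.beta(a, 1.0, size=markers_per_gene) if gene in enriched \
            else rng.uniform(0.0, 1.0, size=markers_per_gene)
        scores = -np.log10(np.maximum(p, 1e-300))
        marker_ids = [f"rs_{gene}_{j}" for j in range(markers_per_gene)]
        for start in range(0, markers_per_gene, ld_block_size):
            block = marker_ids[start:start + ld_block_size]
            for j, mid in enumerate(block):
                rows.append({"marker_id": mid, "gene": gene,
                             "score": float(scores[start + j]),
                             "block_id": f"b{block_counter:06d}"})
            for i in range(len(block)):
                for j in range(i + 1, len(block)):
                    r2[frozenset((block[i], block[j]))] = float(rng.uniform(0.75, 0.99))
            block_counter += 1
    return MarkerTable(table=pd.DataFrame(rows), r2=r2)
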