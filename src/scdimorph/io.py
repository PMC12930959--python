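"""Readers and writers for the pipeline's on-disk formats.

Cohorts travel as 10x-style MTX triples (matrix.mtx with genes as rows,
features.tsv, barcodes.tsv) plus a cell-metadata TSV keyed by barcode.
Gene sets use the GMT dialect (set name, description, genes; tab-separated),
networks a 2-or-3-column edge TSV, and marker tables a TSV with header
(marker_id, gene, score, block_id) plus a long-form r2 TSV. All tabular
output is TSV: gene identifiers may legally contain commas.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .simulate import MarkerTable

REQUIRED_META = ("sex", "treatment", "cell_type")


def write_cohort_10x(cohort: ad.AnnData, outdir: str | Path) -> None:
    """Write counts as an MTX triple plus metadata TSVs under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = cohort.X
    counts = x.tocsr() if sp.issparse(x) else sp.csr_matrix(np.asarray(x))
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), counts.T.astype(int))  # genes x cells
    features = pd.DataFrame({
        "gene_id": cohort.var_names,
        "gene_name": cohort.var_names,
        "feature_type": "Gene Expression",
    })
    features.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(cohort.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                       header=False, index=False)
    cohort.obs.rename_axis("barcode").reset_index().to_csv(
        outdir / "cell_meta.tsv", sep="\t", index=False)
    truth = cohort.uns.get("truth")
    if truth:
        for key, df in truth.items():
            if isinstance(df, pd.DataFrame) and len(df):
                df.to_csv(outdir / f"truth_{key}.tsv", sep="\t", index=False)


def read_cohort_10x(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    meta_path: str | Path,
    mito_prefix: str = "mt-",
) -> ad.AnnData:
    """Load a cohort from an MTX triple and a cell-metadata TSV.

    The metadata is joined by barcode and must provide ``sex``, ``treatment``
    and ``cell_type``; mitochondrial genes are flagged by the id prefix
    (default ``"mt-"``).
    """
    counts = sp.csr_matrix(scipy.io.mmread(str(matrix_path))).T  # cells x genes
    features = pd.read_csv(features_path, sep="\t", header=None)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
    if counts.shape[1] != len(features):
        raise ValueError(
            f"matrix has {counts.shape[1]} genes but features.tsv lists {len(features)}")
    if counts.shape[0] != len(barcodes):
        raise ValueError(
            f"matrix has {counts.shape[0]} cells but barcodes.tsv lists {len(barcodes)}")
    meta = pd.read_csv(meta_path, sep="\t")
    if "barcode" not in meta.columns:
        raise ValueError("metadata must have a 'barcode' column")
    missing_cols = [c for c in REQUIRED_META if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata missing required columns: {missing_cols}")
    unknown = set(meta["barcode"].astype(str)) - set(barcodes)
    if unknown:
        raise ValueError(
            f"metadata barcodes absent from the matrix: {sorted(unknown)[:5]}")

    gene_ids = features[0].astype(str)
    var = pd.DataFrame({"is_mito": gene_ids.str.startswith(mito_prefix).to_numpy()},
                       index=pd.Index(gene_ids, name="gene_id"))
    obs = (pd.DataFrame({"barcode": barcodes}).merge(meta, on="barcode", how="left")
           .set_index("barcode").rename_axis(None))
    keep = obs[list(REQUIRED_META)].notna().all(axis=1).to_numpy()
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} cells without metadata")
    adata = ad.AnnData(X=counts[keep], obs=obs.loc[keep], var=var)
    return adata


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into {set name: unique gene list}.

    Duplicate genes within a set are deduplicated with a warning; empty sets
    are dropped with a warning; a duplicated set name or a line with fewer
    than 3 fields is an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {ln} has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: set {name!r} listed twice")
            genes = [g for g in fields[2:] if g]
            uniq = list(dict.fromkeys(genes))
            if len(uniq) < len(genes):
                warnings.warn(f"{path}: set {name!r} has duplicate genes; deduplicated")
            if not uniq:
                warnings.warn(f"{path}: set {name!r} is empty; dropped")
                continue
            sets[name] = uniq
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_network_tsv(path: str | Path) -> pd.DataFrame:
    """Edge list TSV with header: source, target[, weight]."""
    edges = pd.read_csv(path, sep="\t")
    if edges.shape[1] < 2:
        raise ValueError(f"{path}: edge list needs at least 2 columns")
    return edges


def write_network_tsv(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_marker_table(path: str | Path, r2_path: str | Path | None = None) -> MarkerTable:
    """Marker TSV (marker_id, gene, score, block_id) plus optional long-form
    r2 TSV (marker_a, marker_b, r2)."""
    table = pd.read_csv(path, sep="\t")
    required = {"marker_id", "gene", "score", "block_id"}
    if not required <= set(table.columns):
        raise ValueError(f"{path}: marker table must have columns {sorted(required)}")
    r2: dict[frozenset, float] = {}
    if r2_path is not None:
        ld = pd.read_csv(r2_path, sep="\t")
        for row in ld.itertuples(index=False):
            r2[frozenset((str(row[0]), str(row[1])))] = float(row[2])
    return MarkerTable(table=table, r2=r2)


def write_marker_table(markers: MarkerTable, path: str | Path,
                       r2_path: str | Path | None = None) -> None:
    markers.table.to_csv(path, sep="\t", index=False)
    if r2_path is not None:
        rows = [{"marker_a": a, "marker_b": b, "r2": v}
                for (a, b), v in sorted(((tuple(sorted(p)), v)
                                         for p, v in markers.r2.items()))]
        pd.DataFrame(rows, columns=["marker_a", "marker_b", "r2"]).to_csv(
            r2_path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path: str | Path, provenance: str | None = None) -> None:
    """Write a result table with a provenance sidecar (<path>.prov)."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    if provenance is not None:
        Path(str(path) + ".prov").write_text(provenance + "\n")
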