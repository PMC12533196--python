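"""Reading/writing count matrices and the cell-level quality filters.

On disk a cohort is a MatrixMarket file (genes x rows, cells x columns, the
orientation CellRanger-style exports use), a one-column gene TSV, and a cell
metadata TSV whose first column is the cell id.  In memory the cohort is an
AnnData (cells x genes) whose ``obs`` must carry mouse, sex, genotype and
timepoint for every cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["QCParams", "read_matrix", "write_matrix", "apply_qc", "validate_cell_matrix"]

REQUIRED_OBS = ("mouse", "sex", "genotype", "timepoint")


@dataclass
class QCParams:
    """Cell-level quality thresholds.

    Cells are retained when detected genes > ``min_genes_per_cell``, the
    fraction of mitochondrially-encoded reads < ``max_mito_fraction``, and
    detected genes < ``max_genes_factor`` x the per-sample (per-mouse) median
    of detected genes.  All three strict inequalities are applied jointly
    against pre-filter medians.  ``excluded_features`` (e.g. a feature whose
    reads align ambiguously between wild-type and knockout alleles) are
    dropped from the matrix before counting.
    """

    min_genes_per_cell: int = 200
    max_mito_fraction: float = 0.5
    max_genes_factor: float = 3.0
    excluded_features: tuple[str, ...] = ()
    mito_prefixes: tuple[str, ...] = ("mt-",)

    def __post_init__(self) -> None:
        if not 0 < self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must lie in (0, 1]")
        if self.max_genes_factor <= 1:
            raise ValueError("max_genes_factor must be > 1")


def validate_cell_matrix(adata: ad.AnnData) -> None:
    """Raise if the AnnData does not satisfy the cohort contract."""
    if adata.obs.index.duplicated().any():
        dupes = adata.obs.index[adata.obs.index.duplicated()][:5].tolist()
        raise ValueError(f"duplicate cell ids: {dupes}")
    for col in REQUIRED_OBS:
        if col not in adata.obs.columns:
            raise ValueError(f"cell metadata is missing required column {col!r}")
        if adata.obs[col].isna().any():
            raise ValueError(f"cell metadata column {col!r} has missing values")
    X = adata.X
    data = X.data if sp.issparse(X) else np.asarray(X)
    if data.size and (np.min(data) < 0 or np.any(data != np.floor(data))):
        raise ValueError("counts must be non-negative integers")


def read_matrix(mtx_path, genes_path, meta_path) -> ad.AnnData:
    """Read a genes x cells MatrixMarket file plus gene and cell-metadata TSVs."""
    mtx_path, genes_path, meta_path = Path(mtx_path), Path(genes_path), Path(meta_path)
    M = scipy.io.mmread(str(mtx_path))
    M = sp.csr_matrix(M.T)  # -> cells x genes
    genes = pd.read_csv(genes_path, sep="\t")
    gene_col = genes.columns[0]
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    if M.shape[1] != len(genes):
        raise ValueError(
            f"matrix has {M.shape[1]} genes but gene table has {len(genes)}"
        )
    if M.shape[0] != len(meta):
        raise ValueError(
            f"matrix has {M.shape[0]} cells but metadata table has {len(meta)}"
        )
    var = genes.set_index(gene_col)
    var.index = var.index.astype(str)
    var.index.name = "gene_id"
    adata = ad.AnnData(X=M, obs=meta, var=var)
    if "mito_flag" in adata.var.columns:
        adata.var["mito_flag"] = adata.var["mito_flag"].astype(bool)
    validate_cell_matrix(adata)
    return adata


def write_matrix(adata: ad.AnnData, outdir) -> dict[str, Path]:
    """Write matrix.mtx (genes x cells) + genes.tsv + metadata.tsv; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": outdir / "matrix.mtx",
        "genes": outdir / "genes.tsv",
        "meta": outdir / "metadata.tsv",
    }
    X = adata.X
    M = sp.coo_matrix(X.T if sp.issparse(X) else np.asarray(X).T)
    scipy.io.mmwrite(str(paths["mtx"]), M, field="integer")
    adata.var.reset_index().to_csv(paths["genes"], sep="\t", index=False)
    adata.obs.to_csv(paths["meta"], sep="\t", index_label="cell_id")
    return paths


def apply_qc(adata: ad.AnnData, params: QCParams | None = None) -> tuple[ad.AnnData, dict]:
    """Apply the cell filters; returns the filtered matrix and removal counts.

    The per-sample median of detected genes is computed per mouse on the
    pre-filter matrix; all thresholds are applied jointly in one pass.
    """
    params = params or QCParams()
    validate_cell_matrix(adata)
    if params.excluded_features:
        keep_genes = ~adata.var.index.isin(params.excluded_features)
        adata = adata[:, keep_genes].copy()

    if "mito_flag" in adata.var.columns:
        mito = adata.var["mito_flag"].to_numpy(dtype=bool)
    else:
        mito = np.zeros(adata.n_vars, dtype=bool)
        for pref in params.mito_prefixes:
            mito |= adata.var.index.str.lower().str.startswith(pref.lower())

    X = adata.X
    if sp.issparse(X):
        X = sp.csr_matrix(X)
        n_genes = X.getnnz(axis=1)
        total = np.asarray(X.sum(axis=1)).ravel()
        mito_counts = np.asarray(X[:, mito].sum(axis=1)).ravel()
    else:
        X = np.asarray(X)
        n_genes = (X > 0).sum(axis=1)
        total = X.sum(axis=1)
        mito_counts = X[:, mito].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)

    sample_median = (
        pd.Series(n_genes, index=adata.obs["mouse"].to_numpy()).groupby(level=0).median()
    )
    med_per_cell = sample_median.loc[adata.obs["mouse"].to_numpy()].to_numpy()

    pass_min = n_genes > params.min_genes_per_cell
    if params.max_mito_fraction >= 1.0:  # threshold at the ceiling disables the filter
        pass_mito = np.ones_like(pass_min, dtype=bool)
    else:
        pass_mito = mito_frac < params.max_mito_fraction
    pass_max = n_genes < params.max_genes_factor * med_per_cell
    keep = pass_min & pass_mito & pass_max

    removal = {
        "input_cells": int(adata.n_obs),
        "fail_min_genes": int((~pass_min).sum()),
        "fail_mito_fraction": int((~pass_mito).sum()),
        "fail_max_genes": int((~pass_max).sum()),
        "removed": int((~keep).sum()),
        "retained": int(keep.sum()),
    }
    if removal["retained"] == 0:
        warnings.warn("all cells removed by QC filters", stacklevel=2)
    out = adata[keep].copy()
    return out, removal
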