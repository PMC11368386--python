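"""Expression-matrix container, readers/writers and preprocessing.

The container is deliberately thin: a dense cells x genes array with gene
names, a cell-metadata table, and a ``layer_tag`` recording whether the
values are raw counts or log-normalized. Heavy lifting (h5ad, MatrixMarket,
filtering, normalization) is delegated to anndata / scanpy / pandas.

Preprocessing follows the standard single-cell recipe: drop cells with
fewer than 10 total counts and genes detected in fewer than 3 cells, scale
each cell to 10,000 total counts and apply log(1 + x).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse

RAW = "raw_counts"
LOGNORM = "lognorm"


class ValidationError(ValueError):
    """Raised when expression data violates the container invariants."""


@dataclass
class ExpressionMatrix:
    """Dense cells x genes expression values with labels.

    Attributes
    ----------
    values : (n_cells, n_genes) non-negative float array.
    gene_names : ordered, unique gene identifiers (one per column).
    cell_labels : per-cell categorical annotations (may have zero columns).
    layer_tag : ``"raw_counts"`` or ``"lognorm"``.
    """

    values: np.ndarray
    gene_names: list[str]
    cell_labels: pd.DataFrame = field(default_factory=pd.DataFrame)
    layer_tag: str = RAW

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D cells x genes array")
        n_bad = int(np.sum(~np.isfinite(self.values)))
        if n_bad:
            raise ValidationError(f"{n_bad} non-finite entries in values")
        n_neg = int(np.sum(self.values < 0))
        if n_neg:
            raise ValidationError(f"{n_neg} negative entries in values")
        self.gene_names = [str(g) for g in self.gene_names]
        if len(self.gene_names) != self.values.shape[1]:
            raise ValidationError(
                f"{len(self.gene_names)} gene names for {self.values.shape[1]} columns")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValidationError("gene names are not unique")
        if self.cell_labels is None or len(self.cell_labels.columns) == 0:
            self.cell_labels = pd.DataFrame(index=pd.RangeIndex(self.n_cells))
        if len(self.cell_labels) != self.n_cells:
            raise ValidationError("cell_labels rows do not match number of cells")
        if self.cell_labels.isna().any().any():
            raise ValidationError("cell_labels contains missing values")
        if self.layer_tag not in (RAW, LOGNORM):
            raise ValidationError(f"unknown layer_tag {self.layer_tag!r}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, idx: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[idx],
            list(self.gene_names),
            self.cell_labels.iloc[np.asarray(idx)].reset_index(drop=True),
            self.layer_tag,
        )

    def to_anndata(self) -> ad.AnnData:
        adata = ad.AnnData(
            X=self.values.copy(),
            obs=self.cell_labels.astype(str).set_index(
                pd.Index([f"cell{i}" for i in range(self.n_cells)])),
            var=pd.DataFrame(index=pd.Index(self.gene_names, name="gene")),
        )
        adata.uns["layer_tag"] = self.layer_tag
        return adata

    @classmethod
    def from_anndata(cls, adata: ad.AnnData, layer_tag: str | None = None) -> "ExpressionMatrix":
        X = adata.X
        if sparse.issparse(X):
            X = X.toarray()
        labels = adata.obs.reset_index(drop=True)
        labels = labels[[c for c in labels.columns]]
        tag = layer_tag or adata.uns.get("layer_tag", RAW)
        return cls(np.asarray(X, dtype=float), list(adata.var_names), labels, tag)


# ---------------------------------------------------------------------------
# Readers / writers: h5ad, MatrixMarket triplet (mtx + genes.tsv + barcodes.tsv),
# dense CSV (header = gene names, first column = cell IDs). Labels come from
# the h5ad obs table or a sidecar ``<stem>_labels.tsv`` for mtx/csv.
# ---------------------------------------------------------------------------

def _sidecar_labels(path: Path, n_cells: int) -> pd.DataFrame:
    sidecar = path.parent / (path.stem + "_labels.tsv")
    if sidecar.exists():
        df = pd.read_csv(sidecar, sep="\t", dtype=str)
        if len(df) != n_cells:
            raise ValidationError(
                f"label sidecar has {len(df)} rows for {n_cells} cells")
        return df
    return pd.DataFrame(index=pd.RangeIndex(n_cells))


def read_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from h5ad, MatrixMarket or dense CSV.

    Orientation is normalized to cells x genes regardless of on-disk layout;
    the result is tagged ``raw_counts`` (validation rejects negatives).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or {".h5ad": "h5ad", ".mtx": "mtx", ".csv": "csv"}.get(path.suffix)
    if fmt is None:
        raise ValueError(f"cannot infer format from {path.name}; pass format=")

    if fmt == "h5ad":
        adata = ad.read_h5ad(path)
        return ExpressionMatrix.from_anndata(adata, layer_tag=RAW)
    if fmt == "mtx":
        mat = sc.read_mtx(path).X  # stored rows x cols as written
        genes = pd.read_csv(path.parent / "genes.tsv", sep="\t", header=None)[0].tolist()
        barcodes = pd.read_csv(path.parent / "barcodes.tsv", sep="\t", header=None)[0].tolist()
        X = mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
        if X.shape == (len(genes), len(barcodes)):
            X = X.T  # CellRanger convention stores genes x cells
        elif X.shape != (len(barcodes), len(genes)):
            raise ValidationError(
                f"mtx shape {X.shape} matches neither orientation for "
                f"{len(barcodes)} barcodes x {len(genes)} genes")
        labels = _sidecar_labels(path, len(barcodes))
        return ExpressionMatrix(X, genes, labels, RAW)
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        labels = _sidecar_labels(path, df.shape[0])
        return ExpressionMatrix(df.to_numpy(dtype=float), list(df.columns), labels, RAW)
    raise ValueError(f"unknown format {fmt!r}")


def write_expression(X: ExpressionMatrix, path: str | Path, format: str | None = None) -> Path:
    """Write to h5ad, MatrixMarket triplet or dense CSV (with label sidecar)."""
    path = Path(path)
    fmt = format or {".h5ad": "h5ad", ".mtx": "mtx", ".csv": "csv"}.get(path.suffix)
    if fmt == "h5ad":
        X.to_anndata().write_h5ad(path)
        return path
    if fmt == "mtx":
        from scipy.io import mmwrite
        mmwrite(str(path), sparse.coo_matrix(X.values.T))  # genes x cells on disk
        pd.Series(X.gene_names).to_csv(path.parent / "genes.tsv", sep="\t",
                                       index=False, header=False)
        pd.Series([f"cell{i}" for i in range(X.n_cells)]).to_csv(
            path.parent / "barcodes.tsv", sep="\t", index=False, header=False)
    elif fmt == "csv":
        pd.DataFrame(X.values, columns=X.gene_names,
                     index=[f"cell{i}" for i in range(X.n_cells)]).to_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if len(X.cell_labels.columns):
        X.cell_labels.to_csv(path.parent / (path.stem + "_labels.tsv"),
                             sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def filter_cells_genes(X: ExpressionMatrix, min_cell_counts: int = 10,
                       min_cells_per_gene: int = 3) -> ExpressionMatrix:
    """Drop low-count cells, then genes detected in too few cells.

    Cells with total count below ``min_cell_counts`` are removed first, then
    genes with a positive count in fewer than ``min_cells_per_gene`` of the
    remaining cells. Single pass (no iteration to a joint fixed point).
    """
    if X.layer_tag != RAW:
        raise ValidationError("filtering expects raw counts")
    adata = X.to_anndata()
    sc.pp.filter_cells(adata, min_counts=min_cell_counts)
    sc.pp.filter_genes(adata, min_cells=min_cells_per_gene)
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValidationError(
            f"filtering with min_cell_counts={min_cell_counts}, "
            f"min_cells_per_gene={min_cells_per_gene} left an empty matrix "
            f"({adata.n_obs} cells x {adata.n_vars} genes)")
    adata.obs = adata.obs.drop(columns=["n_counts"], errors="ignore")
    adata.var = adata.var.drop(columns=["n_cells"], errors="ignore")
    return ExpressionMatrix.from_anndata(adata, layer_tag=RAW)


def normalize_log(X: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Scale each cell to ``target_sum`` total counts, then apply log1p.

    Refuses lognorm input (double transformation) and zero-total cells
    (those should have been filtered out).
    """
    if X.layer_tag != RAW:
        raise ValidationError("input is already log-normalized")
    totals = X.values.sum(axis=1)
    if np.any(totals <= 0):
        raise ValidationError(f"{int(np.sum(totals <= 0))} cells have zero total count")
    adata = X.to_anndata()
    sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)
    out = ExpressionMatrix.from_anndata(adata, layer_tag=LOGNORM)
    return out


def split_dataset(X: ExpressionMatrix, train_fraction: float = 0.8,
                  seed: int = 0) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Deterministic train/test split, stratified by the first label column.

    Falls back (with a warning) to an unstratified split when some class has
    fewer than 2 members.
    """
    from sklearn.model_selection import train_test_split

    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    idx = np.arange(X.n_cells)
    strat = None
    if len(X.cell_labels.columns):
        y = X.cell_labels.iloc[:, 0].to_numpy()
        counts = pd.Series(y).value_counts()
        if counts.min() >= 2:
            strat = y
        else:
            warnings.warn("a label class has < 2 members; splitting without stratification")
    tr, te = train_test_split(idx, train_size=train_fraction,
                              random_state=seed, stratify=strat)
    return X.subset_cells(np.sort(tr)), X.subset_cells(np.sort(te))
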