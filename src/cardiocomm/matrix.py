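"""Count-matrix container and on-disk formats.

The central object of the pipeline is a cells × genes matrix of
nonnegative integer UMI counts with aligned per-cell annotations:
condition (e.g. ``Normal`` vs ``HCM``), cell type, cluster, a 2D
embedding (UMAP-like coordinates used for spatial autocorrelation) and
an optional pseudotime.  Counts are stored sparsely (CSR); metadata is
a :class:`pandas.DataFrame` indexed by cell barcode.

Supported on-disk layouts are the CellRanger-style triplet
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``, with a separate
``cell_meta.tsv``) and a dense CSV (cells × genes with an index column).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["CountMatrix", "ValidationError", "read_mtx_dir", "read_csv"]

#: metadata columns every CountMatrix carries (pseudotime is optional)
META_COLUMNS = ("condition", "cell_type", "cluster", "embedding_x", "embedding_y")


class ValidationError(ValueError):
    """Raised when a count matrix violates its structural invariants."""


def _as_csr_counts(counts) -> sp.csr_matrix:
    if sp.issparse(counts):
        mat = counts.tocsr(copy=True)
    else:
        mat = sp.csr_matrix(np.asarray(counts))
    mat.eliminate_zeros()
    return mat


@dataclass
class CountMatrix:
    """Cells × genes integer counts with aligned per-cell metadata.

    Parameters
    ----------
    counts
        Nonnegative integer matrix, dense or sparse, shape
        ``(n_cells, n_genes)``.  Stored internally as CSR.
    gene_ids
        Unique gene symbols, one per column.
    cell_ids
        Unique cell barcodes, one per row.
    cell_meta
        One record per cell (aligned to ``cell_ids``) with at least the
        columns in :data:`META_COLUMNS`; ``pseudotime`` and ``batch``
        are recognised optional extras.
    """

    counts: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame
    validate_on_init: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.counts = _as_csr_counts(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.cell_meta = self.cell_meta.copy()
        if self.validate_on_init:
            self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if n_cells != len(self.cell_ids) or n_genes != len(self.gene_ids):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene symbols")
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("duplicate cell barcodes")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise ValidationError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integer counts")
        if len(self.cell_meta) != n_cells:
            raise ValidationError("cell_meta must have exactly one record per cell")
        if not list(self.cell_meta.index) == self.cell_ids:
            # accept any order but require the same set, then align
            if set(self.cell_meta.index) != set(self.cell_ids):
                raise ValidationError("cell_meta index does not match cell_ids")
            self.cell_meta = self.cell_meta.loc[self.cell_ids]
        missing = [c for c in META_COLUMNS if c not in self.cell_meta.columns]
        if missing:
            raise ValidationError(f"cell_meta missing columns: {missing}")

    # -- basic properties ----------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def genes_per_cell(self) -> np.ndarray:
        """Number of genes with count > 0 in each cell."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def cells_per_gene(self) -> np.ndarray:
        """Number of cells with count > 0 for each gene."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in matrix") from None

    # -- subsetting ----------------------------------------------------
    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            self.counts[:, keep],
            [self.gene_ids[i] for i in keep],
            self.cell_ids,
            self.cell_meta,
            validate_on_init=False,
        )

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        cell_ids = [self.cell_ids[i] for i in keep]
        return CountMatrix(
            self.counts[keep, :],
            self.gene_ids,
            cell_ids,
            self.cell_meta.iloc[keep],
            validate_on_init=False,
        )

    def stratum(self, condition: str | None = None, **meta_equals) -> "CountMatrix":
        """Cells matching ``condition`` and any ``column=value`` filters."""
        mask = np.ones(self.n_cells, dtype=bool)
        if condition is not None:
            mask &= (self.cell_meta["condition"] == condition).to_numpy()
        for col, val in meta_equals.items():
            mask &= (self.cell_meta[col] == val).to_numpy()
        return self.subset_cells(mask)

    # -- conversions ---------------------------------------------------
    def to_anndata(self):
        """Export as :class:`anndata.AnnData` (embedding in ``obsm['X_embed']``)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene")),
        )
        adata.obsm["X_embed"] = self.cell_meta[["embedding_x", "embedding_y"]].to_numpy()
        return adata

    @classmethod
    def from_anndata(cls, adata) -> "CountMatrix":
        meta = adata.obs.copy()
        if "embedding_x" not in meta.columns and "X_embed" in adata.obsm:
            emb = np.asarray(adata.obsm["X_embed"])
            meta["embedding_x"] = emb[:, 0]
            meta["embedding_y"] = emb[:, 1]
        return cls(adata.X, list(adata.var_names), list(adata.obs_names), meta)

    # -- IO ------------------------------------------------------------
    def write_mtx_dir(self, path: str) -> None:
        """Write CellRanger-style triplet plus ``cell_meta.tsv``."""
        os.makedirs(path, exist_ok=True)
        # MTX convention is genes x cells
        scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), self.counts.T.astype(int))
        pd.Series(self.gene_ids).to_csv(
            os.path.join(path, "features.tsv"), sep="\t", index=False, header=False
        )
        pd.Series(self.cell_ids).to_csv(
            os.path.join(path, "barcodes.tsv"), sep="\t", index=False, header=False
        )
        self.cell_meta.to_csv(os.path.join(path, "cell_meta.tsv"), sep="\t")

    def write_csv(self, path: str, meta_path: str | None = None) -> None:
        dense = pd.DataFrame(
            self.counts.toarray(), index=self.cell_ids, columns=self.gene_ids
        )
        dense.to_csv(path)
        if meta_path is not None:
            self.cell_meta.to_csv(meta_path, sep="\t")


def _read_meta(path: str, cell_ids: Sequence[str]) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    return meta.loc[list(cell_ids)]


def read_mtx_dir(path: str) -> CountMatrix:
    """Read the CellRanger-style triplet written by :meth:`CountMatrix.write_mtx_dir`."""
    counts = scipy.io.mmread(os.path.join(path, "matrix.mtx")).T.tocsr()
    genes = pd.read_csv(os.path.join(path, "features.tsv"), sep="\t", header=None)[0]
    cells = pd.read_csv(os.path.join(path, "barcodes.tsv"), sep="\t", header=None)[0]
    cell_ids = [str(c) for c in cells]
    meta = _read_meta(os.path.join(path, "cell_meta.tsv"), cell_ids)
    return CountMatrix(counts, [str(g) for g in genes], cell_ids, meta)


def read_csv(path: str, meta_path: str) -> CountMatrix:
    """Read a dense cells × genes CSV (index column = barcodes)."""
    dense = pd.read_csv(path, index_col=0)
    cell_ids = [str(c) for c in dense.index]
    meta = _read_meta(meta_path, cell_ids)
    return CountMatrix(
        sp.csr_matrix(dense.to_numpy()), [str(g) for g in dense.columns], cell_ids, meta
    )
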