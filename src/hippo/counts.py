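"""Containers and I/O for genes x cells UMI count matrices.

The central object is :class:`CountMatrix`: a sparse genes x cells matrix of
nonnegative integer molecule counts with gene and cell identifiers.  Readers
accept either 10x-style MatrixMarket triplets (matrix.mtx + features/genes +
barcodes) or dense delimited text; writers emit the same formats so that
simulated fixtures round-trip through the readers.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "CellLabels",
    "FormatError",
    "ValidationError",
    "read_mtx",
    "read_dense",
    "write_mtx",
    "read_labels",
    "write_labels",
    "filter_genes",
]


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


class ValidationError(ValueError):
    """File contents parse but violate count-matrix invariants."""


def _dedupe(ids: Sequence[str], what: str) -> list[str]:
    """Disambiguate duplicate identifiers by appending a numeric suffix."""
    seen: dict[str, int] = {}
    out = []
    n_dupes = 0
    for x in ids:
        x = str(x)
        if x in seen:
            seen[x] += 1
            out.append(f"{x}.{seen[x]}")
            n_dupes += 1
        else:
            seen[x] = 0
            out.append(x)
    if n_dupes:
        logger.warning("%d duplicate %s ids renamed with numeric suffixes", n_dupes, what)
    return out


@dataclass
class CountMatrix:
    """Genes x cells matrix of nonnegative integer UMI counts.

    Parameters
    ----------
    values
    	Sparse (CSR) or dense matrix, genes in rows, cells in columns.
    gene_ids, cell_ids
    	Unique identifiers for the row and column axes.
    """

    values: sp.csr_matrix
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values
        if not sp.issparse(v):
            v = sp.csr_matrix(np.asarray(v))
        v = v.tocsr()
        if not np.issubdtype(v.dtype, np.integer):
            data = v.data
            if data.size and np.max(np.abs(data - np.rint(data))) > 1e-9:
                raise ValidationError("counts must be integers")
            v = sp.csr_matrix((np.rint(data).astype(np.int64), v.indices, v.indptr), shape=v.shape)
        if v.data.size and v.data.min() < 0:
            raise ValidationError("counts must be nonnegative")
        v.eliminate_zeros()
        self.values = v
        if not self.gene_ids:
            self.gene_ids = [f"gene{i}" for i in range(v.shape[0])]
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(v.shape[1])]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.gene_ids) != v.shape[0]:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {v.shape[0]} matrix rows"
            )
        if len(self.cell_ids) != v.shape[1]:
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {v.shape[1]} matrix columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        """Counts as a dense int array (genes x cells)."""
        return np.asarray(self.values.todense())

    def subset(self, genes: np.ndarray | None = None, cells: np.ndarray | None = None) -> "CountMatrix":
        """Restrict to the given gene and/or cell index arrays (order kept)."""
        v = self.values
        gids, cids = self.gene_ids, self.cell_ids
        if genes is not None:
            genes = np.asarray(genes)
            v = v[genes]
            gids = [self.gene_ids[i] for i in genes]
        if cells is not None:
            cells = np.asarray(cells)
            v = v[:, cells]
            cids = [self.cell_ids[i] for i in cells]
        return CountMatrix(v.tocsr(), gids, cids)


@dataclass
class CellLabels:
    """Integer cluster assignments (0-based, contiguous) for an ordered set of cells."""

    cell_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.cell_ids) != self.labels.shape[0]:
            raise ValidationError("cell_ids and labels have different lengths")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def relabeled(self) -> "CellLabels":
        """Map labels onto the contiguous set {0,...,k-1}, ordered by first appearance."""
        _, inv = np.unique(self.labels, return_inverse=True)
        order = {}
        out = np.empty_like(self.labels)
        for i, lab in enumerate(self.labels):
            if lab not in order:
                order[lab] = len(order)
            out[i] = order[lab]
        return CellLabels(self.cell_ids, out)


def _read_ids(path: Path, what: str) -> list[str]:
    """First column of a headerless TSV (plain id list or 10x features.tsv)."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0])
    return _dedupe(ids, what)


def read_mtx(matrix_path: str | Path, genes_path: str | Path, barcodes_path: str | Path) -> CountMatrix:
    """Read a 10x-style MatrixMarket triplet + gene list + barcode list.

    Coordinates in the file are 1-based; the returned matrix is 0-indexed.
    Real-valued entries are accepted only when integral within 1e-9.
    """
    try:
        m = mmread(str(matrix_path))
    except Exception as exc:  # scipy raises plain ValueError on bad headers
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    m = sp.coo_matrix(m)
    genes = _read_ids(Path(genes_path), "gene")
    cells = _read_ids(Path(barcodes_path), "barcode")
    if m.shape[0] != len(genes) or m.shape[1] != len(cells):
        raise FormatError(
            f"matrix is {m.shape[0]}x{m.shape[1]} but annotations give "
            f"{len(genes)} genes x {len(cells)} barcodes"
        )
    return CountMatrix(m.tocsr(), genes, cells)


def write_mtx(m: CountMatrix, matrix_path: str | Path, genes_path: str | Path, barcodes_path: str | Path) -> None:
    """Write MatrixMarket + gene/barcode id files readable by :func:`read_mtx`."""
    mmwrite(str(matrix_path), m.values.tocoo(), field="integer")
    Path(genes_path).write_text("".join(g + "\n" for g in m.gene_ids))
    Path(barcodes_path).write_text("".join(c + "\n" for c in m.cell_ids))


def read_dense(path: str | Path, delimiter: str = "\t", genes_in_rows: bool = True) -> CountMatrix:
    """Read a dense delimited table with a header row and an id column.

    With ``genes_in_rows`` (default) rows are genes and columns are cells;
    otherwise the table is transposed after reading.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"cannot parse dense table {path}: {exc}") from exc
    if df.isna().any().any():
        raise FormatError(f"ragged or missing entries in {path}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValidationError(f"non-numeric entries in {path}")
    if np.max(np.abs(arr - np.rint(arr)), initial=0) > 1e-9:
        raise ValidationError(f"non-integer counts in {path}")
    if not genes_in_rows:
        df = df.T
    return CountMatrix(
        sp.csr_matrix(df.to_numpy()),
        _dedupe(df.index, "gene"),
        _dedupe(df.columns, "cell"),
    )


def read_labels(path: str | Path) -> CellLabels:
    """Read a two-column TSV (cell_id, integer label); a header row is optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError("label file must have two columns: cell_id, label")
    try:
        int(df.iloc[0, 1])
    except ValueError:
        df = df.iloc[1:]
    return CellLabels(list(df.iloc[:, 0]), df.iloc[:, 1].astype(int).to_numpy())


def write_labels(labels: CellLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_id\tlabel\n")
        for cid, lab in zip(labels.cell_ids, labels.labels):
            fh.write(f"{cid}\t{lab}\n")


def filter_genes(m: CountMatrix, min_cells_expressing: int) -> tuple[CountMatrix, np.ndarray]:
    """Keep genes detected (count > 0) in at least ``min_cells_expressing`` cells.

    Returns the filtered matrix and the indices of kept genes in the input
    order.  A threshold of 0 keeps everything; a threshold larger than the
    number of cells yields an empty result with a warning, not an error.
    """
    if min_cells_expressing < 0:
        raise ValidationError("min_cells_expressing must be >= 0")
    n_expressing = np.asarray((m.values > 0).sum(axis=1)).ravel()
    kept = np.flatnonzero(n_expressing >= min_cells_expressing)
    if kept.size == 0:
        warnings.warn("gene filter removed every gene", stacklevel=2)
    if kept.size == m.n_genes:
        return m, kept
    return m.subset(genes=kept), kept
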