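"""Sparse cell x gene UMI count matrix with MatrixMarket persistence.

Cells are keyed by the two-barcode combination rendered ``round1-round2``;
values are UMI-deduplicated molecule counts. Per-cell assigned-read totals
are kept alongside as metadata so QC can report reads per cell and the
reads-in-cells fraction.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import scipy.io
import scipy.sparse as sp

from .barcode import CellKey
from .errors import MatrixFormatError

MATRIX_FILE = "matrix.mtx"
BARCODES_FILE = "barcodes.tsv"
GENES_FILE = "genes.tsv"
CELL_READS_FILE = "cell_reads.tsv"


class CellGeneMatrix:
    """UMI-deduplicated counts, cells x genes.

    Parameters
    ----------
    X:
        Sparse (n_cells, n_genes) nonnegative integer matrix.
    cells:
        Cell ids, ``round1-round2`` strings, unique.
    genes:
        Gene ids, unique.
    cell_reads:
        Optional per-cell assigned-read totals (same order as ``cells``).
    """

    def __init__(
        self,
        X: sp.spmatrix,
        cells: Iterable[str],
        genes: Iterable[str],
        cell_reads: np.ndarray | None = None,
    ):
        self.cells = list(cells)
        self.genes = list(genes)
        X = sp.csr_matrix(X, dtype=np.int64, copy=True)
        X.eliminate_zeros()
        if X.shape != (len(self.cells), len(self.genes)):
            raise ValueError(
                f"matrix shape {X.shape} != ({len(self.cells)}, {len(self.genes)})"
            )
        if X.nnz and X.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell ids")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        self.X = X
        if cell_reads is not None:
            cell_reads = np.asarray(cell_reads, dtype=np.int64)
            if cell_reads.shape != (len(self.cells),):
                raise ValueError("cell_reads length must match number of cells")
        self.cell_reads = cell_reads

    # -- construction -------------------------------------------------------

    @classmethod
    def from_counts(
        cls,
        counts: Mapping,
        cell_reads: Mapping | None = None,
        genes: Iterable[str] | None = None,
    ) -> "CellGeneMatrix":
        """Build from a mapping (cell_id or CellKey, gene) -> count.

        Cell and gene axes are sorted lexicographically (genes follow the
        given order when ``genes`` is supplied) so construction is
        deterministic for any input ordering.
        """
        norm = {}
        for (cell, gene), v in counts.items():
            cid = str(cell)
            norm[(cid, gene)] = int(v)
        cell_ids = sorted({c for c, _ in norm})
        if genes is None:
            gene_ids = sorted({g for _, g in norm})
        else:
            gene_ids = list(genes)
        ci = {c: i for i, c in enumerate(cell_ids)}
        gi = {g: i for i, g in enumerate(gene_ids)}
        rows, cols, vals = [], [], []
        for (cell, gene), v in norm.items():
            if v == 0:
                continue
            rows.append(ci[cell])
            cols.append(gi[gene])
            vals.append(v)
        X = sp.coo_matrix(
            (vals, (rows, cols)), shape=(len(cell_ids), len(gene_ids)), dtype=np.int64
        )
        reads = None
        if cell_reads is not None:
            reads = np.array([int(cell_reads.get(c, 0)) for c in cell_ids], dtype=np.int64)
        return cls(X.tocsr(), cell_ids, gene_ids, reads)

    # -- summaries -----------------------------------------------------------

    @property
    def shape(self) -> tuple:
        return self.X.shape

    def umi_per_cell(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=1)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        return np.diff(self.X.indptr)

    def cell_index(self) -> dict:
        return {c: i for i, c in enumerate(self.cells)}

    def cell_keys(self) -> list:
        return [CellKey.from_string(c) for c in self.cells]

    def to_dict(self) -> dict:
        """Nonzero entries as {(cell_id, gene_id): count}; order-free equality."""
        coo = self.X.tocoo()
        return {
            (self.cells[i], self.genes[j]): int(v)
            for i, j, v in zip(coo.row, coo.col, coo.data)
        }

    def __eq__(self, other) -> bool:
        if not isinstance(other, CellGeneMatrix):
            return NotImplemented
        if self.cells != other.cells or self.genes != other.genes:
            return False
        if (self.X != other.X).nnz != 0:
            return False
        if (self.cell_reads is None) != (other.cell_reads is None):
            return False
        if self.cell_reads is not None and not np.array_equal(
            self.cell_reads, other.cell_reads
        ):
            return False
        return True

    def to_anndata(self):
        """Export as an AnnData (cells as obs, genes as var) for scanpy et al."""
        import anndata
        import pandas as pd

        obs = pd.DataFrame(index=pd.Index(self.cells, name="cell_id"))
        if self.cell_reads is not None:
            obs["n_reads"] = self.cell_reads
        keys = self.cell_keys()
        obs["round1"] = [k.round1 for k in keys]
        obs["round2"] = [k.round2 for k in keys]
        var = pd.DataFrame(index=pd.Index(self.genes, name="gene_id"))
        return anndata.AnnData(X=self.X.copy(), obs=obs, var=var)


def write_matrix(m: CellGeneMatrix, out_dir: str | os.PathLike) -> None:
    """Write the MTX triplet (matrix.mtx, barcodes.tsv, genes.tsv).

    MatrixMarket stores cells x genes (rows follow barcodes.tsv, columns
    genes.tsv) in coordinate integer form.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(out / MATRIX_FILE), m.X.tocoo(), field="integer", symmetry="general"
    )
    (out / BARCODES_FILE).write_text("".join(c + "\n" for c in m.cells))
    (out / GENES_FILE).write_text("".join(g + "\n" for g in m.genes))
    if m.cell_reads is not None:
        with open(out / CELL_READS_FILE, "w") as fh:
            fh.write("cell_id\tn_reads\n")
            for c, n in zip(m.cells, m.cell_reads):
                fh.write(f"{c}\t{int(n)}\n")


def read_matrix(in_dir: str | os.PathLike) -> CellGeneMatrix:
    """Read a matrix directory written by :func:`write_matrix`."""
    d = Path(in_dir)
    mtx = d / MATRIX_FILE
    if not mtx.exists():
        raise MatrixFormatError(f"{mtx} not found")
    _validate_mtx_header(mtx)
    X = scipy.io.mmread(str(mtx))
    cells = (d / BARCODES_FILE).read_text().splitlines()
    genes = (d / GENES_FILE).read_text().splitlines()
    reads = None
    if (d / CELL_READS_FILE).exists():
        lines = (d / CELL_READS_FILE).read_text().splitlines()[1:]
        by_cell = dict(line.split("\t") for line in lines)
        reads = np.array([int(by_cell[c]) for c in cells], dtype=np.int64)
    X = sp.csr_matrix(X)
    if X.shape != (len(cells), len(genes)):
        raise MatrixFormatError(
            f"{mtx}: dimensions {X.shape} do not match barcodes/genes files "
            f"({len(cells)} cells, {len(genes)} genes)"
        )
    return CellGeneMatrix(X, cells, genes, reads)


def _validate_mtx_header(path: Path) -> None:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("%%MatrixMarket"):
            raise MatrixFormatError(f"{path}: line 1: missing MatrixMarket banner")
        lineno = 1
        for line in fh:
            lineno += 1
            if line.startswith("%"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise MatrixFormatError(
                    f"{path}: line {lineno}: malformed size header {line.strip()!r}"
                )
            try:
                [int(p) for p in parts]
            except ValueError:
                raise MatrixFormatError(
                    f"{path}: line {lineno}: non-integer size header {line.strip()!r}"
                ) from None
            return
        raise MatrixFormatError(f"{path}: missing size header")
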