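"""Readers/writers for count matrices, metadata and spike-ins; gene filter.

Canonical in-memory orientation is genes as rows, cells as columns.
Matrix Market files travel with plain-text gene/cell id sidecars
(one id per line); orientation is auto-detected from the sidecar lengths
with an explicit override for square matrices.  Dense CSV/TSV counts use
gene ids as the index and cell ids as the header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .capture import SpikeInSet

logger = logging.getLogger(__name__)

__all__ = [
    "UMICountMatrix",
    "read_counts",
    "write_counts",
    "filter_genes",
    "read_cell_metadata",
    "read_spikeins",
    "write_spikeins",
]


@dataclass
class UMICountMatrix:
    """Genes x cells matrix of nonnegative integer UMI counts."""

    counts: object  # ndarray or scipy sparse
    gene_ids: list
    cell_ids: list

    def __post_init__(self):
        dense = self.dense()
        if np.any(dense < 0):
            bad = np.argwhere(dense < 0)[0]
            raise ValueError(
                f"negative count at gene {self.gene_ids[bad[0]]!r}, "
                f"cell {self.cell_ids[bad[1]]!r}"
            )
        if not np.all(np.equal(np.mod(dense, 1), 0)):
            bad = np.argwhere(np.mod(dense, 1) != 0)[0]
            raise ValueError(
                f"non-integer count at gene {self.gene_ids[bad[0]]!r}, "
                f"cell {self.cell_ids[bad[1]]!r}"
            )
        if dense.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {dense.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids are not unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids are not unique")

    def dense(self) -> np.ndarray:
        if sparse.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)

    @property
    def shape(self):
        return (len(self.gene_ids), len(self.cell_ids))

    @property
    def library_sizes(self) -> np.ndarray:
        return self.dense().sum(axis=0)


def _sidecar_paths(path: Path, genes, cells):
    genes = Path(genes) if genes else path.with_name(path.stem + "_genes.txt")
    cells = Path(cells) if cells else path.with_name(path.stem + "_cells.txt")
    return genes, cells


def read_counts(path, format=None, genes=None, cells=None,
                orientation="auto") -> UMICountMatrix:
    """Read a count matrix from Matrix Market or dense CSV/TSV.

    For ``.mtx`` input the gene/cell id sidecars default to
    ``<stem>_genes.txt`` / ``<stem>_cells.txt`` next to the matrix.
    ``orientation`` is auto-detected from sidecar lengths; pass
    "genes-rows" or "cells-rows" to override (required for square input).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("mtx" if path.suffix == ".mtx" else path.suffix.lstrip("."))
    if fmt == "mtx":
        gpath, cpath = _sidecar_paths(path, genes, cells)
        for p in (gpath, cpath):
            if not p.exists():
                raise FileNotFoundError(f"missing id sidecar {p}")
        gene_ids = gpath.read_text().split()
        cell_ids = cpath.read_text().split()
        mat = spio.mmread(path).tocsr()
        if orientation == "auto":
            if mat.shape == (len(gene_ids), len(cell_ids)) and mat.shape[0] != mat.shape[1]:
                pass
            elif mat.shape == (len(cell_ids), len(gene_ids)) and mat.shape[0] != mat.shape[1]:
                mat = mat.T.tocsr()
            elif mat.shape[0] == mat.shape[1] == len(gene_ids) == len(cell_ids):
                raise ValueError(
                    "square matrix with equal sidecar lengths: pass "
                    "orientation='genes-rows' or 'cells-rows' explicitly"
                )
            else:
                raise ValueError(
                    f"matrix shape {mat.shape} matches neither sidecar "
                    f"orientation ({len(gene_ids)} genes, {len(cell_ids)} cells)"
                )
        elif orientation == "cells-rows":
            mat = mat.T.tocsr()
        return UMICountMatrix(counts=mat, gene_ids=gene_ids, cell_ids=cell_ids)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        frame = pd.read_csv(path, sep=sep, index_col=0)
        counts = frame.to_numpy()
        m = UMICountMatrix(
            counts=counts,
            gene_ids=[str(g) for g in frame.index],
            cell_ids=[str(c) for c in frame.columns],
        )
        if orientation == "cells-rows":
            m = UMICountMatrix(
                counts=m.dense().T, gene_ids=m.cell_ids, cell_ids=m.gene_ids
            )
        return m
    raise ValueError(f"unknown format {fmt!r}")


def write_counts(matrix: UMICountMatrix, path, format=None,
                 genes=None, cells=None) -> None:
    """Write a count matrix (Matrix Market + sidecars, or dense CSV/TSV)."""
    path = Path(path)
    fmt = format or ("mtx" if path.suffix == ".mtx" else path.suffix.lstrip("."))
    if fmt == "mtx":
        gpath, cpath = _sidecar_paths(path, genes, cells)
        spio.mmwrite(path, sparse.coo_matrix(matrix.dense()))
        gpath.write_text("\n".join(matrix.gene_ids) + "\n")
        cpath.write_text("\n".join(matrix.cell_ids) + "\n")
        return
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        pd.DataFrame(
            matrix.dense(), index=matrix.gene_ids, columns=matrix.cell_ids
        ).to_csv(path, sep=sep)
        return
    raise ValueError(f"unknown format {fmt!r}")


def filter_genes(matrix: UMICountMatrix, min_cells: int = 5) -> UMICountMatrix:
    """Keep genes with non-zero expression in at least ``min_cells`` cells.

    Gene order is preserved; the removed genes are logged.
    """
    dense = matrix.dense()
    keep = (dense > 0).sum(axis=1) >= min_cells
    removed = [g for g, k in zip(matrix.gene_ids, keep) if not k]
    if removed:
        logger.info(
            "filter_genes removed %d of %d genes (non-zero in < %d cells): %s%s",
            len(removed), len(matrix.gene_ids), min_cells,
            ", ".join(removed[:10]), "..." if len(removed) > 10 else "",
        )
    return UMICountMatrix(
        counts=dense[keep],
        gene_ids=[g for g, k in zip(matrix.gene_ids, keep) if k],
        cell_ids=list(matrix.cell_ids),
    )


def read_cell_metadata(path, matrix: UMICountMatrix | None = None) -> pd.DataFrame:
    """Read a per-cell metadata TSV/CSV with a ``cell_id`` column.

    If a matrix is given, rows are aligned to its cell order and checked
    for completeness.
    """
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    meta = pd.read_csv(path, sep=sep)
    if "cell_id" not in meta.columns:
        raise ValueError("metadata must contain a cell_id column")
    if matrix is not None:
        meta = meta.set_index("cell_id")
        missing = [c for c in matrix.cell_ids if c not in meta.index]
        if missing:
            raise ValueError(f"metadata missing cells: {missing[:10]}")
        meta = meta.loc[matrix.cell_ids].reset_index()
    return meta


def read_spikeins(path, concentration_col="concentration",
                  transcript_col="transcript_id") -> SpikeInSet:
    """Read spike-in data from a wide TSV/CSV.

    Expected columns: transcript id, concentration, then one column per
    cell with the spike-in UMI counts.
    """
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep)
    for col in (transcript_col, concentration_col):
        if col not in frame.columns:
            raise ValueError(f"spike-in table must contain a {col!r} column")
    cell_cols = [c for c in frame.columns if c not in (transcript_col, concentration_col)]
    return SpikeInSet(
        concentrations=frame[concentration_col].to_numpy(),
        counts=frame[cell_cols].to_numpy().T,
        transcript_ids=list(frame[transcript_col]),
        cell_ids=cell_cols,
    )


def write_spikeins(spikes: SpikeInSet, path) -> None:
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    frame = pd.DataFrame(
        spikes.counts.T,
        columns=spikes.cell_ids or [f"cell_{i}" for i in range(spikes.n_cells)],
    )
    frame.insert(0, "concentration", spikes.concentrations)
    frame.insert(0, "transcript_id", spikes.transcript_ids)
    frame.to_csv(path, sep=sep, index=False)
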