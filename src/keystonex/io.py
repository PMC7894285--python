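"""Readers and writers for the on-disk formats.

Bulk matrices are plain TSV (genes on rows, samples on columns).  Cell
matrices use the 10x-style trio: ``matrix.mtx`` (MatrixMarket coordinate,
1-based, integer field for raw counts), ``genes.tsv`` (gene_id, symbol,
mito flag 0/1) and ``barcodes.tsv``.  The round trip is bit-exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from keystonex.preprocess import BulkMatrix, CellMatrix, PreprocessError


def write_bulk_tsv(m: BulkMatrix, path: str | Path, meta_path: str | Path | None = None) -> None:
    frame = m.counts.copy()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t")
    if meta_path is not None and m.samples is not None:
        meta = m.samples.copy()
        meta.index.name = "sample_id"
        meta.to_csv(meta_path, sep="\t")


def read_bulk_tsv(path: str | Path, meta_path: str | Path | None = None) -> BulkMatrix:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    samples = None
    if meta_path is not None:
        samples = pd.read_csv(meta_path, sep="\t", index_col=0)
        samples.index = samples.index.astype(str)
        samples = samples.reindex(counts.columns)
    return BulkMatrix(counts=counts, samples=samples)


def write_cell_matrix(m: CellMatrix, out_dir: str | Path) -> None:
    """Write the matrix.mtx / genes.tsv / barcodes.tsv trio."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    field = "real" if m.normalized else "integer"
    mat = sp.coo_matrix(m.counts)
    if field == "integer":
        mat = mat.astype(np.int64)
    sio.mmwrite(out / "matrix.mtx", mat, field=field)
    genes = pd.DataFrame(
        {
            "gene_id": m.gene_ids,
            "symbol": m.gene_ids,
            "mito": m.mito_flags.astype(int),
        }
    )
    genes.to_csv(out / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(m.cell_ids).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)


def read_cell_matrix(in_dir: str | Path) -> CellMatrix:
    in_dir = Path(in_dir)
    mtx_path = in_dir / "matrix.mtx"
    if not mtx_path.exists():
        raise FileNotFoundError(mtx_path)
    mat = sio.mmread(mtx_path)
    genes = pd.read_csv(in_dir / "genes.tsv", sep="\t", header=None, dtype=str)
    if genes.shape[1] < 3:
        raise PreprocessError("genes.tsv must have gene_id, symbol, mito columns")
    barcodes = pd.read_csv(in_dir / "barcodes.tsv", sep="\t", header=None, dtype=str)
    normalized = np.issubdtype(np.asarray(mat.data).dtype, np.floating)
    return CellMatrix(
        counts=mat,
        gene_ids=genes[0].tolist(),
        cell_ids=barcodes[0].tolist(),
        mito_flags=genes[2].astype(int).astype(bool).to_numpy(),
        normalized=normalized,
    )
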