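"""Single-cell QC filtering, median-of-ratios normalization, pseudobulk.

The QC scheme follows common droplet scRNA-seq practice: a permissive basic
filter (cells with >= 20 detected genes, genes detected in >= 3 cells)
followed by a robust-cell window keeping cells with 3,000-9,000 detected
genes, 7,000-180,000 UMIs (both inclusive) and a mitochondrial transcript
fraction strictly below 10%.  Size factors use the classic median-of-ratios
estimator: the reference is the per-gene geometric mean over samples,
restricted to genes positive in every sample, and each sample's factor is
the median of its ratios to the reference.  No gene-length scaling is
applied anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


class PreprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# containers


@dataclass
class BulkMatrix:
    """Integer gene-by-sample counts with per-sample metadata."""

    counts: pd.DataFrame  # genes x samples
    samples: pd.DataFrame | None = None  # index = sample ids; species/stage/replicate

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise PreprocessError(f"duplicate gene_ids in bulk matrix: {dup[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise PreprocessError("bulk counts must be non-negative")
        if self.samples is not None and not self.samples.index.equals(
            self.counts.columns
        ):
            raise PreprocessError("sample metadata index must match count columns")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


class CellMatrix:
    """Sparse gene-by-cell counts with per-gene mitochondrial flags.

    ``counts`` is CSR with genes on rows.  Raw matrices hold integers;
    :func:`normalize` produces a float-valued copy flagged ``normalized``.
    Per-cell totals (UMIs) and detected-gene counts are derived once and
    cached; they always equal the column sums of ``counts``.
    """

    def __init__(
        self,
        counts: sp.spmatrix,
        gene_ids: Sequence[str],
        cell_ids: Sequence[str],
        mito_flags: Sequence[bool],
        normalized: bool = False,
    ) -> None:
        counts = sp.csr_matrix(counts)
        counts.eliminate_zeros()
        if counts.shape != (len(gene_ids), len(cell_ids)):
            raise PreprocessError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(gene_ids)} genes x {len(cell_ids)} cells"
            )
        if len(mito_flags) != len(gene_ids):
            raise PreprocessError("mito_flags must align with gene_ids")
        if len(set(gene_ids)) != len(gene_ids):
            raise PreprocessError("duplicate gene_ids in cell matrix")
        if not normalized:
            if counts.data.size and np.any(counts.data != np.round(counts.data)):
                raise PreprocessError("raw cell counts must be integers")
            if counts.data.size and counts.data.min() < 0:
                raise PreprocessError("cell counts must be non-negative")
        self.counts = counts
        self.gene_ids = np.asarray(gene_ids, dtype=object)
        self.cell_ids = np.asarray(cell_ids, dtype=object)
        self.mito_flags = np.asarray(mito_flags, dtype=bool)
        self.normalized = bool(normalized)
        self._umi_per_cell: np.ndarray | None = None
        self._genes_per_cell: np.ndarray | None = None

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def umi_per_cell(self) -> np.ndarray:
        """Per-cell total counts (column sums)."""
        if self._umi_per_cell is None:
            self._umi_per_cell = np.asarray(self.counts.sum(axis=0)).ravel()
        return self._umi_per_cell

    @property
    def genes_per_cell(self) -> np.ndarray:
        """Per-cell number of detected (nonzero) genes."""
        if self._genes_per_cell is None:
            csc = self.counts.tocsc()
            self._genes_per_cell = np.diff(csc.indptr)
        return self._genes_per_cell

    @property
    def cells_per_gene(self) -> np.ndarray:
        """Per-gene number of cells with nonzero counts."""
        return np.diff(self.counts.indptr)

    def cell_index(self, cell_id: str) -> int:
        hits = np.flatnonzero(self.cell_ids == cell_id)
        if hits.size == 0:
            raise KeyError(cell_id)
        return int(hits[0])

    def subset_cells(self, mask: np.ndarray) -> "CellMatrix":
        return CellMatrix(
            self.counts[:, mask],
            self.gene_ids,
            self.cell_ids[mask],
            self.mito_flags,
            normalized=self.normalized,
        )

    def subset_genes(self, mask: np.ndarray) -> "CellMatrix":
        return CellMatrix(
            self.counts[mask, :],
            self.gene_ids[mask],
            self.cell_ids,
            self.mito_flags[mask],
            normalized=self.normalized,
        )


@dataclass
class QCThresholds:
    """Cell/gene filtering thresholds.

    Gene and UMI windows are inclusive on both ends; the mitochondrial bound
    is a strict upper bound, so a cell at exactly ``max_mito_fraction`` is
    removed.
    """

    min_genes_per_cell: int = 20
    min_cells_per_gene: int = 3
    robust_gene_range: tuple[int, int] = (3000, 9000)
    robust_umi_range: tuple[int, int] = (7000, 180_000)
    max_mito_fraction: float = 0.10

    def validate(self) -> None:
        if self.min_genes_per_cell < 0 or self.min_cells_per_gene < 0:
            raise PreprocessError("minimum thresholds must be non-negative")
        for name, (lo, hi) in (
            ("robust_gene_range", self.robust_gene_range),
            ("robust_umi_range", self.robust_umi_range),
        ):
            if lo > hi:
                raise PreprocessError(f"{name} must be ordered, got ({lo}, {hi})")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise PreprocessError("max_mito_fraction must lie in [0, 1]")


@dataclass
class QCReport:
    """Removed-entity counts per filtering rule, with lineage flags."""

    removed: dict[str, int] = field(default_factory=dict)
    applied: list[str] = field(default_factory=list)
    notes: dict[str, object] = field(default_factory=dict)

    @property
    def basic_applied(self) -> bool:
        return "basic_filter" in self.applied

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"removed": self.removed, "applied": self.applied, "notes": self.notes},
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


# ---------------------------------------------------------------------------
# filtering


def basic_filter(
    m: CellMatrix, t: QCThresholds | None = None
) -> tuple[CellMatrix, QCReport]:
    """Permissive first-pass filter: cell rule then gene rule, one pass each.

    Cells with fewer than ``min_genes_per_cell`` detected genes are removed
    first; genes detected in fewer than ``min_cells_per_gene`` of the
    remaining cells are removed second.  The report also records what the
    reverse order would have removed, for transparency.
    """
    t = t or QCThresholds()
    t.validate()
    cell_keep = m.genes_per_cell >= t.min_genes_per_cell
    after_cells = m.subset_cells(cell_keep)
    gene_keep = after_cells.cells_per_gene >= t.min_cells_per_gene
    out = after_cells.subset_genes(gene_keep)

    # reverse-order outcome, recorded but not applied
    alt_gene_keep = m.cells_per_gene >= t.min_cells_per_gene
    alt = m.subset_genes(alt_gene_keep)
    alt_cell_keep = alt.genes_per_cell >= t.min_genes_per_cell

    report = QCReport(
        removed={
            "cells_min_genes": int((~cell_keep).sum()),
            "genes_min_cells": int((~gene_keep).sum()),
        },
        applied=["basic_filter"],
        notes={
            "order": "cells_then_genes",
            "reverse_order_removed": {
                "genes_min_cells": int((~alt_gene_keep).sum()),
                "cells_min_genes": int((~alt_cell_keep).sum()),
            },
        },
    )
    return out, report


def mito_fraction(m: CellMatrix, cell_id: str) -> float:
    """Fraction of one cell's counts coming from mitochondrial genes."""
    j = m.cell_index(cell_id)
    total = m.umi_per_cell[j]
    if total <= 0:
        raise PreprocessError(f"cell {cell_id!r} has zero total counts")
    mito = m.counts[m.mito_flags, j].sum()
    return float(mito) / float(total)


def mito_fractions(m: CellMatrix) -> np.ndarray:
    """Vectorized per-cell mitochondrial fraction; NaN for zero-total cells."""
    mito = np.asarray(m.counts[m.mito_flags, :].sum(axis=0)).ravel().astype(float)
    total = m.umi_per_cell.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, mito / total, np.nan)


def robust_cell_filter(
    m: CellMatrix, t: QCThresholds | None = None, report: QCReport | None = None
) -> tuple[CellMatrix, QCReport]:
    """Keep cells inside the detected-gene and UMI windows with low mito share.

    Requires :func:`basic_filter` to have been applied (checked via the
    report's lineage when a report is passed).
    """
    t = t or QCThresholds()
    t.validate()
    if report is not None and not report.basic_applied:
        raise PreprocessError("robust_cell_filter requires basic_filter first")
    genes = m.genes_per_cell
    umis = m.umi_per_cell
    mito = mito_fractions(m)

    ok_genes = (genes >= t.robust_gene_range[0]) & (genes <= t.robust_gene_range[1])
    ok_umis = (umis >= t.robust_umi_range[0]) & (umis <= t.robust_umi_range[1])
    ok_mito = mito < t.max_mito_fraction  # NaN compares False -> removed
    keep = ok_genes & ok_umis & ok_mito

    out = m.subset_cells(keep)
    rep = report or QCReport(applied=["basic_filter"])
    rep.applied.append("robust_cell_filter")
    rep.removed.update(
        {
            "cells_gene_range": int((~ok_genes).sum()),
            "cells_umi_range": int((~ok_umis).sum()),
            "cells_mito": int((~ok_mito).sum()),
            "cells_robust_total": int((~keep).sum()),
        }
    )
    rep.notes["robust_retained"] = int(keep.sum())
    return out, rep


# ---------------------------------------------------------------------------
# normalization


@dataclass
class SizeFactorSet:
    """Per-sample (or per-cell-group) scaling factors, all positive."""

    factors: pd.Series
    n_reference_genes: int
    reference: str = "geometric mean over samples of genes positive in all samples"

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise PreprocessError("size factors must be positive")


def median_ratio_size_factors(counts: pd.DataFrame | np.ndarray) -> SizeFactorSet:
    """Median-of-ratios size factors (genes x samples).

    Restricted to genes with nonzero counts in every sample.  Raises when no
    such gene exists (shallow single-cell columns should be pooled to
    pseudobulk first).
    """
    frame = pd.DataFrame(counts)
    if frame.shape[1] < 2:
        raise PreprocessError("need at least two samples for size factors")
    x = frame.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise PreprocessError(
            "no gene has nonzero counts in every sample; pool cells to "
            "pseudobulk before estimating size factors"
        )
    logx = np.log(x[positive])
    ref = np.exp(logx.mean(axis=1))  # per-gene geometric mean over samples
    factors = np.median(x[positive] / ref[:, None], axis=0)
    return SizeFactorSet(
        factors=pd.Series(factors, index=frame.columns, name="size_factor"),
        n_reference_genes=int(positive.sum()),
    )


def joint_counts(*matrices: BulkMatrix) -> pd.DataFrame:
    """Column-concatenate bulk matrices on their shared genes (inner join).

    Used to normalize single-cell pseudobulk together with bulk samples.
    """
    frames = [m.counts for m in matrices]
    shared = frames[0].index
    for f in frames[1:]:
        shared = shared.intersection(f.index)
    if shared.empty:
        raise PreprocessError("matrices share no genes")
    return pd.concat([f.loc[shared] for f in frames], axis=1)


def normalize(
    m: BulkMatrix | CellMatrix | pd.DataFrame,
    f: SizeFactorSet | Mapping[str, float] | Sequence[float],
) -> pd.DataFrame | CellMatrix:
    """Divide each column by its size factor.

    Bulk input returns a float DataFrame; cell input returns a float-valued
    :class:`CellMatrix` flagged ``normalized``.  Factor order must match the
    column (sample/cell) order; a mapping is aligned by id.
    """
    if isinstance(m, CellMatrix):
        ids = m.cell_ids
    elif isinstance(m, BulkMatrix):
        ids = m.counts.columns
    else:
        ids = m.columns

    if isinstance(f, SizeFactorSet):
        fac = f.factors
        fac = fac.reindex(ids) if set(ids) <= set(fac.index) else fac
        values = fac.to_numpy(dtype=float)
    elif isinstance(f, Mapping):
        values = np.array([f[i] for i in ids], dtype=float)
    else:
        values = np.asarray(f, dtype=float)
    if values.shape[0] != len(ids) or np.isnan(values).any():
        raise PreprocessError(
            f"need one factor per column: {len(ids)} columns, {values.shape[0]} factors"
        )
    if (values <= 0).any():
        raise PreprocessError("size factors must be positive")

    if isinstance(m, CellMatrix):
        scaled = m.counts @ sp.diags(1.0 / values)
        return CellMatrix(scaled, m.gene_ids, m.cell_ids, m.mito_flags, normalized=True)
    frame = m.counts if isinstance(m, BulkMatrix) else m
    return frame / values


def pseudobulk_sum(m: CellMatrix, grouping: Mapping[str, str]) -> BulkMatrix:
    """Sum cell counts into per-group integer profiles.

    Every cell must be assigned to a group; total counts are conserved
    exactly.
    """
    missing = [c for c in m.cell_ids if c not in grouping]
    if missing:
        raise PreprocessError(
            f"{len(missing)} cell(s) unassigned in grouping, e.g. {missing[:3]}"
        )
    labels = np.array([grouping[c] for c in m.cell_ids], dtype=object)
    groups = sorted(set(labels))
    cols = {
        g: np.asarray(m.counts[:, labels == g].sum(axis=1)).ravel().astype(np.int64)
        for g in groups
    }
    counts = pd.DataFrame(cols, index=pd.Index(m.gene_ids, name="gene_id"))
    samples = pd.DataFrame(
        {"species": "", "stage": "", "replicate": range(1, len(groups) + 1)},
        index=counts.columns,
    )
    return BulkMatrix(counts=counts, samples=samples)
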