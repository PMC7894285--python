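"""Gene-set resampling tests and per-cell abundance statistics.

The core test compares a focal gene set's summary expression (median by
default) against a null built by repeatedly drawing size-matched gene sets
from a pool, without replacement within each draw.  One-tailed p-values use
the add-one Monte-Carlo estimator ``p = (1 + #{null >= obs}) / (1 + n_perm)``
(``<=`` for the "low" alternative), which is permutation-valid, never zero,
and conservative on ties.

Per-cell transcript abundance of a gene is ``X_bar = (sum of normalized
expression over expressing cells) / n`` where ``n`` is the number of cells
with nonzero expression — the expression-domain size.  Organ-level total
expression decomposes exactly as ``total = n * X_bar``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from keystonex.categories import PATHWAYS, CategoryTable, pathway_gene_set
from keystonex.preprocess import CellMatrix


class StatsError(ValueError):
    pass


_STATS = {"median": np.median, "mean": np.mean}


@dataclass
class ResampleResult:
    """Outcome of a one-tailed gene-set resampling test."""

    observed: float
    p_one_tailed: float
    n_perm: int
    seed: int
    focal_size: int
    pool_size: int
    statistic_name: str
    alternative: str  # "high" or "low"
    null_quantiles: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "p_one_tailed": self.p_one_tailed,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "focal_size": self.focal_size,
            "pool_size": self.pool_size,
            "statistic": self.statistic_name,
            "alternative": self.alternative,
            "null_quantiles": self.null_quantiles,
        }


def gene_level_values(m: pd.DataFrame, how: str = "median") -> pd.Series:
    """Summarize a normalized gene-by-sample matrix to one value per gene.

    Median across replicate samples by default (configurable to mean).
    """
    if how not in _STATS:
        raise StatsError(f"unknown summary {how!r}")
    return m.median(axis=1) if how == "median" else m.mean(axis=1)


def _as_gene_values(m: pd.DataFrame | pd.Series, how: str = "median") -> pd.Series:
    if isinstance(m, pd.Series):
        return m
    return gene_level_values(m, how=how)


def summary_expression(
    m: pd.DataFrame | pd.Series, genes: Iterable[str], statistic: str = "median"
) -> float:
    """The chosen statistic over a gene set's per-gene expression values."""
    if statistic not in _STATS:
        raise StatsError(f"unknown statistic {statistic!r}")
    genes = list(genes)
    if not genes:
        raise StatsError("empty gene set")
    values = _as_gene_values(m, how=statistic)
    missing = [g for g in genes if g not in values.index]
    if missing:
        raise StatsError(f"gene(s) absent from matrix, e.g. {missing[:5]}")
    return float(_STATS[statistic](values.loc[genes].to_numpy(dtype=float)))


def _null_statistics(
    values: np.ndarray,
    k: int,
    n_perm: int,
    rng: np.random.Generator,
    statistic: str,
    chunk_elems: int = 4_000_000,
) -> np.ndarray:
    """Statistics of n_perm random size-k subsets of values (no replacement
    within a draw), vectorized via random-key argpartition in chunks."""
    m = values.shape[0]
    stat = _STATS[statistic]
    out = np.empty(n_perm)
    per = max(1, min(n_perm, chunk_elems // max(m, 1)))
    pos = 0
    while pos < n_perm:
        b = min(per, n_perm - pos)
        keys = rng.random((b, m))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k] if k < m else np.tile(np.arange(m), (b, 1))
        out[pos : pos + b] = stat(values[idx], axis=1)
        pos += b
    return out


def _resample_from_values(
    observed_values: np.ndarray,
    pool_values: np.ndarray,
    n_perm: int,
    seed: int,
    statistic: str,
    alternative: str,
) -> ResampleResult:
    if statistic not in _STATS:
        raise StatsError(f"unknown statistic {statistic!r}")
    if alternative not in ("high", "low"):
        raise StatsError(f"alternative must be 'high' or 'low', got {alternative!r}")
    k = observed_values.shape[0]
    if k < 1:
        raise StatsError("empty focal set")
    if pool_values.shape[0] < k:
        raise StatsError(
            f"pool ({pool_values.shape[0]}) smaller than focal set ({k})"
        )
    if n_perm < 1:
        raise StatsError("n_perm must be positive")
    observed = float(_STATS[statistic](observed_values))
    rng = np.random.default_rng(seed)
    null = _null_statistics(pool_values, k, n_perm, rng, statistic)
    if alternative == "high":
        tail = int(np.count_nonzero(null >= observed))
    else:
        tail = int(np.count_nonzero(null <= observed))
    p = (1 + tail) / (1 + n_perm)
    qs = np.quantile(null, [0.025, 0.25, 0.5, 0.75, 0.975])
    return ResampleResult(
        observed=observed,
        p_one_tailed=float(p),
        n_perm=int(n_perm),
        seed=int(seed),
        focal_size=int(k),
        pool_size=int(pool_values.shape[0]),
        statistic_name=statistic,
        alternative=alternative,
        null_quantiles={
            "q2.5": float(qs[0]),
            "q25": float(qs[1]),
            "q50": float(qs[2]),
            "q75": float(qs[3]),
            "q97.5": float(qs[4]),
        },
    )


def resample_median_test(
    m: pd.DataFrame | pd.Series,
    focal: Iterable[str],
    pool: Iterable[str],
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: str = "median",
    alternative: str = "high",
) -> ResampleResult:
    """One-tailed gene-set resampling test on per-gene expression values.

    ``pool`` is the set null draws come from; pass a pool containing the
    focal genes for "category vs its pathways" contrasts, or a disjoint
    control set for "category vs control category" contrasts.
    """
    focal, pool = list(focal), list(pool)
    if not focal:
        raise StatsError("empty focal set")
    if not pool:
        raise StatsError("empty pool")
    values = _as_gene_values(m, how=statistic)
    missing = [g for g in focal + pool if g not in values.index]
    if missing:
        raise StatsError(f"gene(s) absent from matrix, e.g. {missing[:5]}")
    return _resample_from_values(
        values.loc[focal].to_numpy(dtype=float),
        values.loc[pool].to_numpy(dtype=float),
        n_perm,
        seed,
        statistic,
        alternative,
    )


# ---------------------------------------------------------------------------
# per-cell abundance


def abundance_profile(
    m: CellMatrix,
    genes: Sequence[str] | None = None,
    expressed_above: float = 0.0,
) -> pd.DataFrame:
    """Per-gene (n, X_bar, total) over a normalized cell matrix.

    ``n`` counts cells with expression strictly above ``expressed_above``
    (default 0: any nonzero value counts as expressing).  ``X_bar`` is NaN
    where ``n = 0``; by construction ``total = n * X_bar`` exactly for every
    expressed gene.
    """
    csr = m.counts.tocsr()
    if expressed_above > 0.0:
        mask = csr.data > expressed_above
        n = np.zeros(m.n_genes, dtype=np.int64)
        total = np.zeros(m.n_genes)
        rows = np.repeat(np.arange(m.n_genes), np.diff(csr.indptr))
        np.add.at(n, rows[mask], 1)
        np.add.at(total, rows[mask], csr.data[mask])
    else:
        n = np.diff(csr.indptr).astype(np.int64)
        total = np.asarray(csr.sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        x_bar = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    # re-derive the total from the decomposition so total == n * x_bar is an
    # exact floating-point identity, not just equal up to rounding
    total = np.where(n > 0, x_bar * n, 0.0)
    prof = pd.DataFrame(
        {"n": n, "x_bar": x_bar, "total": total},
        index=pd.Index(m.gene_ids, name="gene_id"),
    )
    if genes is not None:
        missing = [g for g in genes if g not in prof.index]
        if missing:
            raise StatsError(f"gene(s) absent from matrix, e.g. {missing[:5]}")
        prof = prof.loc[list(genes)]
    return prof


def cell_level_abundance(m: CellMatrix, gene: str) -> tuple[float, int]:
    """(X_bar, n) for one gene; X_bar is NaN when no cell expresses it."""
    prof = abundance_profile(m, genes=[gene])
    return float(prof["x_bar"].iloc[0]), int(prof["n"].iloc[0])


def abundance_category_test(
    m: CellMatrix,
    table: CategoryTable,
    focal_category: str,
    reference_category: str,
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: str = "median",
    pool_mode: str = "combined",
) -> ResampleResult:
    """Compare per-cell abundance (X_bar) of a focal vs a reference category.

    X_bar is computed for every focal and reference gene expressed in at
    least one cell.  With ``pool_mode="combined"`` (default) the null draws
    size-matched gene sets from the pooled focal + reference genes — a
    gene-label permutation, which is calibrated under exchangeability.
    ``pool_mode="reference_only"`` draws from the control category alone;
    this makes the minimum p attainable for an extreme focal set but is
    slightly anti-conservative.  One-tailed "focal high".
    """
    present = set(m.gene_ids)
    focal_ids = [g for g in table.genes_in_category(focal_category) if g in present]
    ref_ids = [g for g in table.genes_in_category(reference_category) if g in present]
    prof = abundance_profile(m, genes=focal_ids + ref_ids)
    prof = prof[prof["n"] >= 1]
    focal_ids = [g for g in focal_ids if g in prof.index]
    ref_ids = [g for g in ref_ids if g in prof.index]
    if not focal_ids or not ref_ids:
        raise StatsError(
            "focal or reference category empty after requiring expression in >= 1 cell"
        )
    if pool_mode not in ("combined", "reference_only"):
        raise StatsError(f"unknown pool_mode {pool_mode!r}")
    pool_ids = focal_ids + ref_ids if pool_mode == "combined" else ref_ids
    xbar = prof["x_bar"]
    return _resample_from_values(
        xbar.loc[focal_ids].to_numpy(dtype=float),
        xbar.loc[pool_ids].to_numpy(dtype=float),
        n_perm,
        seed,
        statistic,
        "high",
    )


def domain_decomposition(
    m: CellMatrix, genes: Sequence[str] | None = None
) -> tuple[pd.DataFrame, float]:
    """Per-gene (n, X_bar, total) plus Spearman correlation of total vs n.

    Quantifies how much of organ-level expression is driven by
    expression-domain size (number of expressing cells) rather than
    per-cell abundance.
    """
    prof = abundance_profile(m, genes=genes)
    expressed = prof[prof["n"] > 0]
    if len(expressed) >= 2 and expressed["n"].nunique() > 1:
        rho = float(sps.spearmanr(expressed["total"], expressed["n"]).statistic)
    else:
        rho = float("nan")
    return prof, rho


# ---------------------------------------------------------------------------
# pathway context and molecule types


def pathway_context_test(
    m: pd.DataFrame | pd.Series,
    table: CategoryTable,
    focal_category: str,
    pathways: Iterable[str] | None = None,
    exclude_ligands: bool = False,
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: str = "median",
) -> ResampleResult:
    """Test a category's expression against all genes of its pathways.

    The pool is the union of the requested pathways' genes (focal genes
    included — the contrast is "category vs all genes in the corresponding
    pathways").  With ``exclude_ligands``, ligand-type genes are removed
    from both the focal set and the pool before testing.
    """
    pathways = tuple(pathways) if pathways is not None else PATHWAYS
    values = _as_gene_values(m, how=statistic)
    pool_ids = [g for g in pathway_gene_set(table, pathways) if g in values.index]
    focal_ids = [
        g for g in table.genes_in_category(focal_category) if g in values.index
    ]
    if exclude_ligands:
        pool_ids = [g for g in pool_ids if table.molecule_type_of(g) != "ligand"]
        focal_ids = [g for g in focal_ids if table.molecule_type_of(g) != "ligand"]
    if not pool_ids:
        raise StatsError("pathway pool empty (after ligand exclusion?)")
    if not focal_ids:
        raise StatsError(f"no {focal_category!r} genes in matrix (after exclusion?)")
    return _resample_from_values(
        values.loc[focal_ids].to_numpy(dtype=float),
        values.loc[pool_ids].to_numpy(dtype=float),
        n_perm,
        seed,
        statistic,
        "high",
    )


def domain_size_by_molecule_type(
    m: CellMatrix,
    table: CategoryTable,
    gene_scope: str = "category_genes",
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, ResampleResult]:
    """Expression-domain sizes per molecule type, with a ligands-low test.

    ``gene_scope='category_genes'`` restricts to progression + shape genes;
    ``'pathway_genes'`` uses all six-pathway genes.  The test contrasts the
    median domain size (number of expressing cells) of ligands against
    size-matched draws from all the other molecule types, one-tailed
    "ligand domain sizes low".
    """
    if gene_scope == "category_genes":
        scope = table.genes_in_category("progression") + table.genes_in_category("shape")
    elif gene_scope == "pathway_genes":
        scope = sorted(pathway_gene_set(table, PATHWAYS))
    else:
        raise StatsError(f"unknown gene_scope {gene_scope!r}")
    present = set(m.gene_ids)
    scope = [g for g in scope if g in present]
    if not scope:
        raise StatsError("no scope genes present in matrix")
    prof = abundance_profile(m, genes=scope)
    mtypes = pd.Series({g: table.molecule_type_of(g) for g in scope}, name="molecule_type")
    by_type = (
        prof.join(mtypes)
        .groupby("molecule_type")["n"]
        .agg(["count", "min", "median", "mean", "max"])
        .rename_axis("molecule_type")
    )
    ligand_ids = [g for g in scope if table.molecule_type_of(g) == "ligand"]
    other_ids = [g for g in scope if table.molecule_type_of(g) != "ligand"]
    if not ligand_ids:
        raise StatsError("no ligand genes in scope")
    if not other_ids:
        raise StatsError("no non-ligand genes in scope")
    result = _resample_from_values(
        prof.loc[ligand_ids, "n"].to_numpy(dtype=float),
        prof.loc[other_ids, "n"].to_numpy(dtype=float),
        n_perm,
        seed,
        "median",
        "low",
    )
    return by_type, result
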