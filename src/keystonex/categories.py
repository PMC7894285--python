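"""Phenotype-severity gene classification tables.

A gene is assigned to exactly one severity category based on the tooth
phenotype of its null mutant: ``progression`` (developmental arrest),
``shape`` (altered crown morphology), ``tissue`` (enamel/dentine defects),
``dispensable`` (no detectable single-knockout phenotype), or ``double``
(phenotype only in combined mutants of paralog pairs).  Genes outside the
curated keystone lists carry ``developmental_process`` (GO-style control
pool) or ``other``.  Independently of the severity category, a gene may be
annotated to one or more signaling pathways (Wnt, Tgfb, Fgf, Hh, Eda,
Notch) and to a molecule type (ligand, receptor, intracellular,
transcription_factor, other).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

KEYSTONE_CATEGORIES: tuple[str, ...] = (
    "progression",
    "shape",
    "tissue",
    "dispensable",
    "double",
)
CATEGORIES: tuple[str, ...] = KEYSTONE_CATEGORIES + ("developmental_process", "other")
PATHWAYS: tuple[str, ...] = ("Wnt", "Tgfb", "Fgf", "Hh", "Eda", "Notch")
MOLECULE_TYPES: tuple[str, ...] = (
    "ligand",
    "receptor",
    "intracellular",
    "transcription_factor",
    "other",
    "unannotated",
)


class CategoryTableError(ValueError):
    """Raised when a category table violates its invariants."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene's annotations.

    ``category`` is the primary (exclusive) severity label.  A keystone gene
    that also belongs to the GO-style developmental-process pool keeps its
    keystone label and sets ``developmental_process=True``; the pool is only
    merged in when explicitly requested (see
    :meth:`CategoryTable.developmental_pool`).
    """

    gene_id: str
    symbol: str
    category: str
    pathways: frozenset[str] = frozenset()
    molecule_type: str = "unannotated"
    developmental_process: bool = False

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise CategoryTableError("gene_id must be nonempty")
        if self.category not in CATEGORIES:
            raise CategoryTableError(
                f"unknown category {self.category!r} for gene {self.gene_id!r}"
            )
        bad = set(self.pathways) - set(PATHWAYS)
        if bad:
            raise CategoryTableError(
                f"unknown pathway token(s) {sorted(bad)} for gene {self.gene_id!r}"
            )
        if self.molecule_type not in MOLECULE_TYPES:
            raise CategoryTableError(
                f"unknown molecule_type {self.molecule_type!r} "
                f"for gene {self.gene_id!r}"
            )


@dataclass
class CategoryTable:
    """A validated collection of :class:`GeneRecord` for one species."""

    records: list[GeneRecord]
    species: str = "mouse"
    _by_id: dict[str, GeneRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        by_id: dict[str, GeneRecord] = {}
        dupes = []
        for rec in self.records:
            if rec.gene_id in by_id:
                dupes.append(rec.gene_id)
            by_id[rec.gene_id] = rec
        if dupes:
            raise CategoryTableError(f"duplicate gene_id(s): {sorted(set(dupes))}")
        self._by_id = by_id

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def genes_in_category(self, category: str) -> list[str]:
        if category not in CATEGORIES:
            raise CategoryTableError(f"unknown category {category!r}")
        return [r.gene_id for r in self.records if r.category == category]

    def developmental_pool(self, include_keystone: bool = False) -> list[str]:
        """Genes in the developmental-process control pool.

        With ``include_keystone=False`` (default), only genes whose primary
        label is ``developmental_process``.  With ``include_keystone=True``,
        keystone genes flagged as developmental-process members are merged in.
        """
        pool = [r.gene_id for r in self.records if r.category == "developmental_process"]
        if include_keystone:
            pool += [
                r.gene_id
                for r in self.records
                if r.category != "developmental_process" and r.developmental_process
            ]
        return pool

    def category_of(self, gene_id: str) -> str:
        return self._by_id[gene_id].category

    def molecule_type_of(self, gene_id: str) -> str:
        return self._by_id[gene_id].molecule_type

    def subset(self, gene_ids: Iterable[str]) -> "CategoryTable":
        keep = set(gene_ids)
        return CategoryTable(
            [r for r in self.records if r.gene_id in keep], species=self.species
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self.records],
                "symbol": [r.symbol for r in self.records],
                "category": [r.category for r in self.records],
                "pathways": [",".join(sorted(r.pathways)) for r in self.records],
                "molecule_type": [r.molecule_type for r in self.records],
                "developmental_process": [
                    int(r.developmental_process) for r in self.records
                ],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class OrthologMap:
    """Strictly one-to-one mapping of gene ids between two genomes."""

    pairs: Mapping[str, str]

    def __post_init__(self) -> None:
        targets = list(self.pairs.values())
        if len(set(targets)) != len(targets):
            seen: set[str] = set()
            dup = sorted({t for t in targets if t in seen or seen.add(t)})
            raise CategoryTableError(
                f"ortholog map is not one-to-one; duplicated target(s): {dup}"
            )

    def __len__(self) -> int:
        return len(self.pairs)

    def inverted(self) -> "OrthologMap":
        return OrthologMap({v: k for k, v in self.pairs.items()})


def _parse_pathways(cell: object) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    text = str(cell).strip()
    if not text:
        return frozenset()
    return frozenset(tok.strip() for tok in text.split(",") if tok.strip())


def load_category_table(path: str | Path, species: str = "mouse") -> CategoryTable:
    """Load and validate a gene category table from TSV.

    Expected columns: ``gene_id``, ``symbol``, ``category``, ``pathways``
    (comma-joined within the field, may be empty), ``molecule_type``.  An
    optional ``developmental_process`` column (0/1) marks keystone genes that
    also belong to the GO-style pool.  Lines starting with ``#`` are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = {"gene_id", "symbol", "category", "pathways", "molecule_type"}
    missing = required - set(df.columns)
    if missing:
        raise CategoryTableError(f"missing column(s) {sorted(missing)} in {path}")
    records = []
    for row in df.itertuples(index=False):
        mt = getattr(row, "molecule_type", "").strip() or "unannotated"
        dev = str(getattr(row, "developmental_process", "0")).strip() in {"1", "true", "True"}
        records.append(
            GeneRecord(
                gene_id=row.gene_id.strip(),
                symbol=row.symbol.strip(),
                category=row.category.strip(),
                pathways=_parse_pathways(row.pathways),
                molecule_type=mt,
                developmental_process=dev,
            )
        )
    return CategoryTable(records, species=species)


def load_ortholog_map(path: str | Path) -> OrthologMap:
    """Load a one-to-one ortholog table (columns source_gene_id, target_gene_id)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = {"source_gene_id", "target_gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise CategoryTableError(f"missing column(s) {sorted(missing)} in {path}")
    sources = df["source_gene_id"].tolist()
    if len(set(sources)) != len(sources):
        seen: set[str] = set()
        dup = sorted({s for s in sources if s in seen or seen.add(s)})
        raise CategoryTableError(
            f"ortholog map is not one-to-one; duplicated source(s): {dup}"
        )
    return OrthologMap(dict(zip(sources, df["target_gene_id"].tolist())))


def count_by_category(table: CategoryTable) -> dict[str, int]:
    """Number of genes per primary category; every category key is present."""
    counts = {c: 0 for c in CATEGORIES}
    for rec in table.records:
        counts[rec.category] += 1
    return counts


def round_half_up(x: float, digits: int = 2) -> float:
    """Half-up decimal rounding used for displayed fractions."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def molecule_type_fraction(
    table: CategoryTable, category: str, molecule_type: str
) -> float:
    """Fraction of a category's genes with the given molecule type (raw, unrounded)."""
    if category not in CATEGORIES:
        raise CategoryTableError(f"unknown category {category!r}")
    if molecule_type not in MOLECULE_TYPES:
        raise CategoryTableError(f"unknown molecule_type {molecule_type!r}")
    members = [r for r in table.records if r.category == category]
    if not members:
        raise CategoryTableError(f"category {category!r} has no genes")
    hits = sum(1 for r in members if r.molecule_type == molecule_type)
    return hits / len(members)


def pathway_gene_set(table: CategoryTable, pathways: Iterable[str]) -> set[str]:
    """Union of gene ids annotated to any of the requested pathways."""
    requested = set(pathways)
    if not requested:
        raise CategoryTableError("pathways must be a nonempty set")
    bad = requested - set(PATHWAYS)
    if bad:
        raise CategoryTableError(f"unknown pathway token(s) {sorted(bad)}")
    return {r.gene_id for r in table.records if r.pathways & requested}


def transfer_orthologs(
    table: CategoryTable, omap: OrthologMap, target_species: str
) -> CategoryTable:
    """Relabel a table to one-to-one orthologs in a target genome.

    Genes without a one-to-one ortholog are dropped (counted in a log
    message); all annotations are carried over unchanged.
    """
    mapped, dropped = [], 0
    for rec in table.records:
        target = omap.pairs.get(rec.gene_id)
        if target is None:
            dropped += 1
            continue
        mapped.append(replace(rec, gene_id=target))
    if dropped or not mapped:
        logger.warning(
            "transfer_orthologs: dropped %d/%d genes without a one-to-one ortholog",
            dropped,
            len(table),
        )
    return CategoryTable(mapped, species=target_species)
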