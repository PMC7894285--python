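"""End-to-end orchestration: simulate/load -> QC -> normalize -> stats -> report.

A run is driven by a single :class:`RunConfig` (plain YAML on disk).  All
stochastic steps derive from one seed, so re-running the same config
reproduces every number in the report; the report carries a hash of the
config and library versions for provenance.  Reports contain no timestamps,
which keeps repeated runs byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

import keystonex
from keystonex.categories import (
    CATEGORIES,
    PATHWAYS,
    CategoryTable,
    count_by_category,
    load_category_table,
    molecule_type_fraction,
)
from keystonex.io import read_bulk_tsv, read_cell_matrix
from keystonex.preprocess import (
    BulkMatrix,
    CellMatrix,
    QCThresholds,
    basic_filter,
    joint_counts,
    median_ratio_size_factors,
    normalize,
    pseudobulk_sum,
    robust_cell_filter,
)
from keystonex.simulate import (
    KEYSTONE_BULK_SIGNAL,
    KEYSTONE_CELL_SIGNAL,
    BulkSimParams,
    CellSimParams,
    keystone_preset,
    simulate_bulk_counts,
    simulate_cell_counts,
)
from keystonex.stats import (
    abundance_category_test,
    domain_decomposition,
    domain_size_by_molecule_type,
    gene_level_values,
    pathway_context_test,
    resample_median_test,
)

logger = logging.getLogger(__name__)

_DEFAULT_CONTRASTS: list[dict[str, Any]] = [
    {"kind": "bulk_category", "focal": "progression", "reference": "dispensable"},
    {"kind": "bulk_category", "focal": "shape", "reference": "dispensable"},
    {"kind": "pathway_context", "focal": "progression",
     "pathways": ["Wnt", "Tgfb", "Fgf", "Hh"], "exclude_ligands": False},
    {"kind": "pathway_context", "focal": "shape",
     "pathways": list(PATHWAYS), "exclude_ligands": False},
    {"kind": "pathway_context", "focal": "shape",
     "pathways": list(PATHWAYS), "exclude_ligands": True},
    {"kind": "abundance", "focal": "progression", "reference": "dispensable"},
    {"kind": "domain_by_type", "scope": "category_genes"},
    {"kind": "domain_by_type", "scope": "pathway_genes"},
    {"kind": "domain_decomposition"},
]


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2 from the CLI)."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    seed: int
    out_dir: str
    n_perm: int = 10_000
    statistic: str = "median"
    simulate: dict[str, Any] | None = field(default_factory=dict)
    inputs: dict[str, str] | None = None
    qc: dict[str, Any] = field(default_factory=dict)
    contrasts: list[dict[str, Any]] = field(default_factory=lambda: list(_DEFAULT_CONTRASTS))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {"seed", "out_dir", "n_perm", "statistic", "simulate", "inputs", "qc", "contrasts"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "seed" not in raw:
            raise ConfigError("config must set an explicit seed")
        if "out_dir" not in raw:
            raise ConfigError("config must set out_dir")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "n_perm": self.n_perm,
            "statistic": self.statistic,
            "simulate": self.simulate,
            "inputs": self.inputs,
            "qc": self.qc,
            "contrasts": self.contrasts,
        }

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _thresholds(cfg: Mapping[str, Any]) -> QCThresholds:
    t = QCThresholds(**{k: tuple(v) if isinstance(v, list) else v for k, v in cfg.items()})
    t.validate()
    return t


def _validate_contrasts(contrasts: list[dict[str, Any]], table: CategoryTable) -> None:
    counts = count_by_category(table)
    for c in contrasts:
        kind = c.get("kind")
        if kind not in {"bulk_category", "pathway_context", "abundance",
                        "domain_by_type", "domain_decomposition"}:
            raise ConfigError(f"unknown contrast kind {kind!r}")
        for key in ("focal", "reference"):
            cat = c.get(key)
            if cat is not None:
                if cat not in CATEGORIES:
                    raise ConfigError(f"unknown category {cat!r} in contrast {c}")
                if counts[cat] == 0:
                    raise ConfigError(f"category {cat!r} has no genes in the table")
        for pw in c.get("pathways", []):
            if pw not in PATHWAYS:
                raise ConfigError(f"unknown pathway {pw!r} in contrast {c}")


def _contrast_name(c: Mapping[str, Any]) -> str:
    parts = [c["kind"]]
    for key in ("focal", "reference", "scope"):
        if key in c:
            parts.append(str(c[key]))
    if c.get("pathways"):
        parts.append("+".join(c["pathways"]))
    if c.get("exclude_ligands"):
        parts.append("no_ligands")
    return ":".join(parts)


def _prepare_data(
    config: RunConfig,
) -> tuple[CategoryTable, BulkMatrix | None, CellMatrix | None]:
    if config.inputs:
        table = load_category_table(config.inputs["categories"])
        bulk = read_bulk_tsv(config.inputs["bulk"]) if "bulk" in config.inputs else None
        cells = read_cell_matrix(config.inputs["cells_dir"]) if "cells_dir" in config.inputs else None
        return table, bulk, cells
    sim = dict(config.simulate or {})
    table = keystone_preset(
        n_developmental=sim.pop("n_developmental", 4106),
        n_other=sim.pop("n_other", 16165),
    )
    bulk_over = {**KEYSTONE_BULK_SIGNAL, **sim.pop("bulk", {})}
    cell_over = {**KEYSTONE_CELL_SIGNAL, **sim.pop("cells", {})}
    if sim:
        raise ConfigError(f"unknown simulate key(s): {sorted(sim)}")
    ss = np.random.SeedSequence(config.seed)
    bulk_seed, cell_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    bulk, _ = simulate_bulk_counts(BulkSimParams(seed=bulk_seed, **bulk_over), table)
    cells, _ = simulate_cell_counts(CellSimParams(seed=cell_seed, **cell_over), table)
    return table, bulk, cells


def _tooth_grouping(cells: CellMatrix) -> dict[str, str]:
    # cell ids are "<tooth>_<barcode>"; fall back to one group
    out = {}
    for cid in cells.cell_ids:
        out[cid] = cid.split("_", 1)[0] if "_" in cid else "all"
    return out


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages and return (and write) a machine-readable report."""
    table, bulk, cells = _prepare_data(config)
    _validate_contrasts(config.contrasts, table)
    thresholds = _thresholds(config.qc)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    report: dict[str, Any] = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "versions": {
            "keystonex": keystonex.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "category_counts": count_by_category(table),
        "molecule_type_fractions": {
            cat: {
                "ligand": molecule_type_fraction(table, cat, "ligand"),
                "receptor": molecule_type_fraction(table, cat, "receptor"),
            }
            for cat in ("progression", "shape")
            if count_by_category(table)[cat] > 0
        },
    }

    # --- QC + normalization -------------------------------------------------
    norm_cells = None
    pseudo = None
    if cells is not None:
        logger.info("QC: %d genes x %d cells before filtering", cells.n_genes, cells.n_cells)
        cells_b, qc_report = basic_filter(cells, thresholds)
        cells_r, qc_report = robust_cell_filter(cells_b, thresholds, qc_report)
        logger.info("QC: retained %d cells", cells_r.n_cells)
        report["qc"] = json.loads(qc_report.to_json())
        grouping = _tooth_grouping(cells_r)
        pseudo = pseudobulk_sum(cells_r, grouping)
        if bulk is not None:
            joint = joint_counts(bulk, pseudo)
            factors = median_ratio_size_factors(joint)
            bulk_factors = factors.factors.loc[list(bulk.counts.columns)]
            pseudo_factors = factors.factors.loc[list(pseudo.counts.columns)]
            norm_bulk = bulk.counts / bulk_factors
        else:
            factors = median_ratio_size_factors(pseudo.counts)
            pseudo_factors = factors.factors
            norm_bulk = None
        per_cell = np.array([pseudo_factors[grouping[c]] for c in cells_r.cell_ids])
        norm_cells = normalize(cells_r, per_cell)
        report["size_factors"] = {str(k): float(v) for k, v in factors.factors.items()}
    elif bulk is not None:
        factors = median_ratio_size_factors(bulk.counts)
        norm_bulk = bulk.counts / factors.factors
        report["size_factors"] = {str(k): float(v) for k, v in factors.factors.items()}
    else:
        raise ConfigError("config provides neither bulk nor cell inputs")

    bulk_values = gene_level_values(norm_bulk, how=config.statistic) if norm_bulk is not None else None

    # --- contrasts ----------------------------------------------------------
    seed_root = np.random.SeedSequence([config.seed, 7])
    contrast_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_root.spawn(len(config.contrasts))]
    results: dict[str, Any] = {}
    for c, cseed in zip(config.contrasts, contrast_seeds):
        name = _contrast_name(c)
        logger.info("contrast %s", name)
        kind = c["kind"]
        if kind == "bulk_category":
            if bulk_values is None:
                raise ConfigError(f"contrast {name} needs bulk data")
            focal = [g for g in table.genes_in_category(c["focal"]) if g in bulk_values.index]
            ref = [g for g in table.genes_in_category(c["reference"]) if g in bulk_values.index]
            pool = focal + ref  # gene-label permutation over both categories
            res = resample_median_test(
                bulk_values, focal, pool, n_perm=config.n_perm, seed=cseed,
                statistic=config.statistic,
            ).to_dict()
        elif kind == "pathway_context":
            if bulk_values is None:
                raise ConfigError(f"contrast {name} needs bulk data")
            res = pathway_context_test(
                bulk_values, table, c["focal"], c.get("pathways"),
                exclude_ligands=c.get("exclude_ligands", False),
                n_perm=config.n_perm, seed=cseed, statistic=config.statistic,
            ).to_dict()
        elif kind == "abundance":
            if norm_cells is None:
                raise ConfigError(f"contrast {name} needs cell data")
            res = abundance_category_test(
                norm_cells, table, c["focal"], c["reference"],
                n_perm=config.n_perm, seed=cseed, statistic=config.statistic,
            ).to_dict()
        elif kind == "domain_by_type":
            if norm_cells is None:
                raise ConfigError(f"contrast {name} needs cell data")
            by_type, r = domain_size_by_molecule_type(
                norm_cells, table, c.get("scope", "category_genes"),
                n_perm=config.n_perm, seed=cseed,
            )
            res = r.to_dict()
            res["domain_size_by_type"] = json.loads(by_type.to_json(orient="index"))
        else:  # domain_decomposition
            if norm_cells is None:
                raise ConfigError(f"contrast {name} needs cell data")
            keystone_genes = [
                g for cat in ("progression", "shape", "tissue", "dispensable")
                for g in table.genes_in_category(cat) if g in set(norm_cells.gene_ids)
            ]
            _, rho = domain_decomposition(norm_cells, keystone_genes or None)
            res = {"spearman_total_vs_n": rho, "n_genes": len(keystone_genes)}
        results[name] = res
    report["contrasts"] = results

    # --- per-category box-plot style summaries ------------------------------
    summaries: dict[str, Any] = {}
    if bulk_values is not None:
        for cat in CATEGORIES:
            ids = [g for g in table.genes_in_category(cat) if g in bulk_values.index]
            if not ids:
                continue
            v = bulk_values.loc[ids].to_numpy(dtype=float)
            q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # type-7 linear interpolation
            summaries[cat] = {
                "n_genes": len(ids), "q1": float(q1), "median": float(med),
                "q3": float(q3), "mean": float(v.mean()),
            }
    report["category_summaries"] = summaries

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    render_tables(report, out_dir)
    return report


def render_tables(report: Mapping[str, Any], out_dir: str | Path) -> list[Path]:
    """Write TSV artifacts (contrast table, per-category summaries) from a report."""
    for key in ("contrasts", "category_summaries"):
        if key not in report:
            raise ConfigError(f"incomplete report: missing {key!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for name, res in report["contrasts"].items():
        rows.append(
            {
                "contrast": name,
                "observed": res.get("observed", res.get("spearman_total_vs_n")),
                "p_one_tailed": res.get("p_one_tailed"),
                "n_perm": res.get("n_perm"),
                "focal_size": res.get("focal_size"),
                "pool_size": res.get("pool_size"),
                "alternative": res.get("alternative"),
            }
        )
    contrasts_path = out_dir / "contrasts.tsv"
    pd.DataFrame(rows, columns=["contrast", "observed", "p_one_tailed", "n_perm",
                                "focal_size", "pool_size", "alternative"]).to_csv(
        contrasts_path, sep="\t", index=False
    )

    summary_path = out_dir / "category_summary.tsv"
    summary = pd.DataFrame.from_dict(report["category_summaries"], orient="index")
    summary.index.name = "category"
    summary.to_csv(summary_path, sep="\t")
    return [contrasts_path, summary_path]
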