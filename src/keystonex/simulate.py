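"""Synthetic bulk and single-cell count matrices with category structure.

Both arms use a negative-binomial (gamma-Poisson) count model, the standard
overdispersed model for RNA counts.  Gene baselines are lognormal.  In the
bulk arm a gene's expected count is proportional to
``baseline * category_fold * library depth``.  In the single-cell arm the
two signals the analysis decomposes are generated separately: a gene is
expressed in a Bernoulli(domain_fraction) subset of cells (the expression
domain), and conditional on expression its counts are negative binomial
with mean proportional to ``baseline * abundance_scale * cell depth``
(the per-cell transcript abundance).  Mitochondrial genes are flagged and
their weights inflated to hit a target share of per-cell UMIs; a small
fraction of "damaged" cells gets an elevated mitochondrial share so the
<10% QC filter has something to remove.

:func:`keystone_preset` builds a deterministic category table whose
bookkeeping mirrors the curated tooth-gene tabulations this package is
designed around: 15 progression / 28 shape / 27 tissue / 100 dispensable /
11 double genes, a six-pathway union of 272 genes of which 221 sit in the
four families (Wnt, Tgfb, Fgh, Hh) that contain all progression genes, and
ligand shares of 20% (progression) and 36% (shape).  The gene ids are
synthetic; the table is a structural stand-in, not a curated gene list.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from keystonex.categories import (
    CATEGORIES,
    MOLECULE_TYPES,
    PATHWAYS,
    CategoryTable,
    GeneRecord,
)
from keystonex.preprocess import BulkMatrix, CellMatrix


class SimulationError(ValueError):
    pass


@dataclass
class SimTruth:
    """Ground-truth parameters of a simulated matrix, one row per gene."""

    genes: pd.DataFrame
    cells: pd.DataFrame | None = None

    def to_tsv(self, path: str | Path) -> None:
        self.genes.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# category tables


_PRESET_COUNTS = {
    "progression": 15,
    "shape": 28,
    "tissue": 27,
    "dispensable": 100,
    "double": 11,
}

_FOUR_FAMILIES = ("Wnt", "Tgfb", "Fgf", "Hh")

# molecule-type layout of the preset, per category: (type, count) pairs.
_PRESET_TYPES = {
    "progression": [("ligand", 3), ("receptor", 3), ("intracellular", 5), ("transcription_factor", 4)],
    "shape": [("ligand", 10), ("receptor", 6), ("intracellular", 7), ("transcription_factor", 5)],
    "tissue": [("other", 20), ("intracellular", 4), ("transcription_factor", 3)],
    "dispensable": [("ligand", 20), ("receptor", 20), ("intracellular", 35), ("transcription_factor", 15), ("other", 10)],
    "double": [("ligand", 3), ("receptor", 2), ("intracellular", 3), ("transcription_factor", 3)],
}

_FILLER_TYPE_CYCLE = ("receptor", "intracellular", "transcription_factor", "ligand", "intracellular")


def _expand_types(layout: list[tuple[str, int]]) -> list[str]:
    out: list[str] = []
    for mt, k in layout:
        out.extend([mt] * k)
    return out


def keystone_preset(
    n_developmental: int = 4106,
    n_other: int = 16165,
    species: str = "mouse",
) -> CategoryTable:
    """Deterministic category table mirroring the curated tooth tabulations.

    Keystone counts 15/28/27/100/11; six-pathway union 272 genes, of which
    221 belong to the four families containing all progression genes; ligand
    fractions 3/15 (progression) and 10/28 (shape).  ``n_developmental`` and
    ``n_other`` control the size of the two control pools (defaults mirror
    the gene counts with bulk RNA-seq data in the study system).
    """
    records: list[GeneRecord] = []

    def add(prefix: str, i: int, category: str, mt: str, pathway: str | None, dev: bool) -> None:
        gid = f"{prefix}{i:05d}"
        records.append(
            GeneRecord(
                gene_id=gid,
                symbol=gid.capitalize(),
                category=category,
                pathways=frozenset() if pathway is None else frozenset({pathway}),
                molecule_type=mt,
                developmental_process=dev,
            )
        )

    four = itertools.cycle(_FOUR_FAMILIES)
    edanotch = itertools.cycle(("Eda", "Notch"))

    for i, mt in enumerate(_expand_types(_PRESET_TYPES["progression"])):
        add("prog", i, "progression", mt, next(four), dev=True)
    # 20 shape genes in the four families, 8 in Eda/Notch
    shape_types = _expand_types(_PRESET_TYPES["shape"])
    for i, mt in enumerate(shape_types):
        pw = next(four) if i < 20 else next(edanotch)
        add("shap", i, "shape", mt, pw, dev=True)
    for i, mt in enumerate(_expand_types(_PRESET_TYPES["tissue"])):
        add("tiss", i, "tissue", mt, None, dev=False)
    for i, mt in enumerate(_expand_types(_PRESET_TYPES["dispensable"])):
        add("disp", i, "dispensable", mt, None, dev=False)
    for i, mt in enumerate(_expand_types(_PRESET_TYPES["double"])):
        add("dblx", i, "double", mt, None, dev=False)

    # pathway members outside the keystone lists: union of six pathways must
    # reach 272 with 221 in the four families (15 prog + 20 shape + 186
    # fillers) and 51 in Eda/Notch only (8 shape + 43 fillers).
    type_cycle = itertools.cycle(_FILLER_TYPE_CYCLE)
    for i in range(186):
        add("pwm4", i, "other", next(type_cycle), next(four), dev=False)
    for i in range(43):
        add("pwm2", i, "other", next(type_cycle), next(edanotch), dev=False)

    for i in range(n_developmental):
        add("devp", i, "developmental_process", "unannotated", None, dev=True)
    for i in range(n_other):
        add("othr", i, "other", "unannotated", None, dev=False)

    return CategoryTable(records, species=species)


def simulate_category_table(
    n_per_category: Mapping[str, int],
    seed: int,
    molecule_type_probs: Mapping[str, float] | None = None,
    pathway_prob: float = 0.3,
) -> CategoryTable:
    """Random category table with the requested per-category gene counts.

    Molecule types are sampled i.i.d. from ``molecule_type_probs`` (default:
    ligand .20, receptor .20, intracellular .35, transcription_factor .15,
    other .10); each gene joins a uniformly chosen pathway with probability
    ``pathway_prob``.
    """
    for cat, n in n_per_category.items():
        if cat not in CATEGORIES:
            raise SimulationError(f"unknown category {cat!r}")
        if n < 0:
            raise SimulationError(f"negative count for category {cat!r}")
    probs = molecule_type_probs or {
        "ligand": 0.20,
        "receptor": 0.20,
        "intracellular": 0.35,
        "transcription_factor": 0.15,
        "other": 0.10,
    }
    if set(probs) - set(MOLECULE_TYPES):
        raise SimulationError("unknown molecule type in molecule_type_probs")
    types = list(probs)
    p = np.asarray([probs[t] for t in types], dtype=float)
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    records: list[GeneRecord] = []
    i = 0
    for cat in CATEGORIES:
        for _ in range(n_per_category.get(cat, 0)):
            gid = f"sim{i:06d}"
            mt = types[int(rng.choice(len(types), p=p))]
            pws: frozenset[str] = frozenset()
            if rng.random() < pathway_prob:
                pws = frozenset({PATHWAYS[int(rng.integers(len(PATHWAYS)))]})
            records.append(
                GeneRecord(gene_id=gid, symbol=gid.capitalize(), category=cat,
                           pathways=pws, molecule_type=mt)
            )
            i += 1
    return CategoryTable(records)


def ligand_reversal_preset(
    n_cells: int = 400, seed: int = 0
) -> tuple[CategoryTable, "CellSimParams"]:
    """Constructed scenario where restricted ligand domains mask upregulation.

    A ligand-heavy focal category (60 "shape" genes, 70% ligands) sits inside
    a 272-gene six-pathway pool with a 20% ligand share, over an 800-gene
    background.  Every ligand's expression domain is halved while shape genes
    get a 1.6x per-cell abundance elevation.  At the organ (pseudobulk)
    level the focal category then looks unremarkable against its pathway
    pool — the many small-domain ligands drag its median down — but becomes
    clearly elevated once ligands are excluded from both sides, and ligands
    show systematically smaller expression domains than the other molecule
    types.
    """
    records: list[GeneRecord] = []
    pw = itertools.cycle(PATHWAYS)
    i = 0

    def add(prefix: str, category: str, mt: str, pathway: str | None) -> None:
        nonlocal i
        gid = f"{prefix}{i:04d}"
        records.append(
            GeneRecord(gene_id=gid, symbol=gid.capitalize(), category=category,
                       pathways=frozenset() if pathway is None else frozenset({pathway}),
                       molecule_type=mt)
        )
        i += 1

    for _ in range(42):
        add("sl", "shape", "ligand", next(pw))
    for _ in range(18):
        add("sn", "shape", "intracellular", next(pw))
    # pathway fillers: pool ligand share 20% overall (54 of 272, 42 in shape)
    for j in range(212):
        mt = "ligand" if j < 12 else ("receptor" if j % 2 else "intracellular")
        add("pw", "other", mt, next(pw))
    for _ in range(800):
        add("bg", "other", "unannotated", None)

    params = CellSimParams(
        n_cells=n_cells,
        baseline_log_sd=0.35,
        default_domain_fraction=0.30,
        molecule_type_domain_scale={"ligand": 0.5},
        abundance_scale={"shape": 1.6},
        depth_log_mean=8.0,
        depth_log_sd=0.3,
        mito_gene_fraction=0.0,
        damaged_cell_fraction=0.0,
        seed=seed,
    )
    return CategoryTable(records), params


# ---------------------------------------------------------------------------
# bulk counts


# Default signal structure of the keystone preset, emulating the study
# conditions: progression genes strongly elevated at the organ level, shape
# genes moderately so, pathway members generally upregulated, progression
# genes with high per-cell abundance, and ligands expressed in roughly half
# as many cells as other molecule types.
KEYSTONE_BULK_SIGNAL: dict = {
    "category_fold": {"progression": 3.0, "shape": 1.5, "developmental_process": 1.2},
    "pathway_member_fold": 2.0,
}
KEYSTONE_CELL_SIGNAL: dict = {
    "abundance_scale": {"progression": 3.0},
    "molecule_type_domain_scale": {"ligand": 0.5},
}


@dataclass
class BulkSimParams:
    """Parameters of the bulk count simulator.

    ``n_samples`` defaults to the seven biological replicates used per stage
    in the mouse RNA-seq arm (use 5 for the rat arm).  ``category_fold``
    multiplies the expected expression of every gene in a category; unlisted
    categories default to 1.  ``pathway_member_fold`` additionally multiplies
    every gene annotated to at least one pathway (pathways are generally
    upregulated sets in a developing organ).  ``dispersion`` is the
    negative-binomial shape (larger = closer to Poisson); 10 corresponds to
    a biological coefficient of variation of ~0.3, typical for replicate
    bulk libraries.  ``depth_per_sample`` is the expected library size
    (counted reads); a sequence gives per-sample depths.
    """

    n_samples: int = 7
    baseline_log_mean: float = 1.5
    baseline_log_sd: float = 0.7
    category_fold: Mapping[str, float] = field(default_factory=dict)
    pathway_member_fold: float = 1.0
    dispersion: float = 10.0
    depth_per_sample: float | Sequence[float] = 20e6
    species: str = "mouse"
    stage: str = "E14"
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise SimulationError("n_samples must be positive")
        if not np.isfinite(self.baseline_log_mean) or not (
            np.isfinite(self.baseline_log_sd) and self.baseline_log_sd > 0
        ):
            raise SimulationError("baseline lognormal parameters invalid")
        if not (np.isfinite(self.dispersion) and self.dispersion > 0):
            raise SimulationError("dispersion must be positive")
        depths = np.atleast_1d(np.asarray(self.depth_per_sample, dtype=float))
        if (depths < 0).any() or not np.isfinite(depths).all():
            raise SimulationError("depth_per_sample must be non-negative and finite")
        for cat, f in self.category_fold.items():
            if cat not in CATEGORIES:
                raise SimulationError(f"unknown category {cat!r} in category_fold")
            if f < 0:
                raise SimulationError("category_fold values must be >= 0")
        if self.pathway_member_fold < 0:
            raise SimulationError("pathway_member_fold must be >= 0")


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, r: float) -> np.ndarray:
    """Gamma-Poisson draw with mean mu and NB shape r (var = mu + mu^2/r)."""
    lam = rng.gamma(r, np.asarray(mu, dtype=float) / r)
    return rng.poisson(lam)


def simulate_bulk_counts(
    params: BulkSimParams, table: CategoryTable
) -> tuple[BulkMatrix, SimTruth]:
    """Simulate an integer gene-by-sample count matrix over the table's genes."""
    params.validate()
    if len(table) == 0:
        raise SimulationError("category table is empty")
    ss = np.random.SeedSequence(params.seed)
    rng_genes, rng_counts = (np.random.default_rng(s) for s in ss.spawn(2))

    gene_ids = table.gene_ids
    cats = np.array([table.category_of(g) for g in gene_ids], dtype=object)
    baseline = rng_genes.lognormal(params.baseline_log_mean, params.baseline_log_sd, len(gene_ids))
    fold = np.array([params.category_fold.get(c, 1.0) for c in cats], dtype=float)
    if params.pathway_member_fold != 1.0:
        in_pathway = np.array([bool(table[g].pathways) for g in gene_ids])
        fold = fold * np.where(in_pathway, params.pathway_member_fold, 1.0)
    weight = baseline * fold
    rel = weight / weight.sum()

    depths = np.broadcast_to(
        np.atleast_1d(np.asarray(params.depth_per_sample, dtype=float)),
        (params.n_samples,),
    ) if np.ndim(params.depth_per_sample) == 0 else np.asarray(params.depth_per_sample, dtype=float)
    if depths.shape[0] != params.n_samples:
        raise SimulationError("depth_per_sample length must equal n_samples")

    mu = rel[:, None] * depths[None, :]
    counts = _nb_counts(rng_counts, mu, params.dispersion)

    sample_ids = [f"{params.species}_{params.stage}_r{i + 1}" for i in range(params.n_samples)]
    frame = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    samples = pd.DataFrame(
        {
            "species": params.species,
            "stage": params.stage,
            "replicate": range(1, params.n_samples + 1),
        },
        index=frame.columns,
    )
    truth = SimTruth(
        genes=pd.DataFrame(
            {"category": cats, "baseline": baseline, "fold": fold, "rel_weight": rel},
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )
    return BulkMatrix(counts=frame, samples=samples), truth


# ---------------------------------------------------------------------------
# single-cell counts


@dataclass
class CellSimParams:
    """Parameters of the single-cell count simulator.

    Domain membership is Bernoulli i.i.d. across cells; conditional on
    membership, counts are negative binomial with mean proportional to the
    gene weight times the cell depth.  Defaults are sized so that, over a
    gene universe of ~20,000 genes, per-cell detected genes land in the
    3,000-9,000 window and per-cell UMI totals in 7,000-180,000 — the
    robust-QC window of the E14 tooth dataset the generator emulates.
    ``molecule_type_domain_scale`` multiplies the domain fraction per
    molecule type (e.g. ``{"ligand": 0.5}`` halves ligand expression
    domains), and ``domain_logit_sd`` adds per-gene domain heterogeneity on
    the logit scale (real expression domains range from a few cells to the
    whole organ).  Cells are assigned round-robin to ``n_teeth`` organs.
    """

    n_cells: int = 500
    n_teeth: int = 4
    default_domain_fraction: float = 0.30
    domain_logit_sd: float = 0.0
    domain_fraction: Mapping[str, float] = field(default_factory=dict)
    molecule_type_domain_scale: Mapping[str, float] = field(default_factory=dict)
    abundance_scale: Mapping[str, float] = field(default_factory=dict)
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    mito_gene_fraction: float = 0.002
    mito_expression_share: float = 0.05
    damaged_cell_fraction: float = 0.03
    damaged_mito_share: float = 0.20
    depth_log_mean: float = 10.31  # exp(10.31) ~ 30,100 UMIs
    depth_log_sd: float = 0.30
    dispersion: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 0 or self.n_teeth < 1:
            raise SimulationError("n_cells must be >= 0 and n_teeth >= 1")
        for name, frac in (
            ("default_domain_fraction", self.default_domain_fraction),
            *((f"domain_fraction[{c}]", f) for c, f in self.domain_fraction.items()),
        ):
            if not 0.0 < frac <= 1.0:
                raise SimulationError(f"{name} must lie in (0, 1], got {frac}")
        for c in self.domain_fraction:
            if c not in CATEGORIES:
                raise SimulationError(f"unknown category {c!r} in domain_fraction")
        for mt in self.molecule_type_domain_scale:
            if mt not in MOLECULE_TYPES:
                raise SimulationError(f"unknown molecule type {mt!r}")
        for c, a in self.abundance_scale.items():
            if c not in CATEGORIES:
                raise SimulationError(f"unknown category {c!r} in abundance_scale")
            if a <= 0:
                raise SimulationError("abundance_scale values must be positive")
        for name, frac in (
            ("mito_gene_fraction", self.mito_gene_fraction),
            ("mito_expression_share", self.mito_expression_share),
            ("damaged_cell_fraction", self.damaged_cell_fraction),
            ("damaged_mito_share", self.damaged_mito_share),
        ):
            if not 0.0 <= frac < 1.0:
                raise SimulationError(f"{name} must lie in [0, 1), got {frac}")
        if not (np.isfinite(self.dispersion) and self.dispersion > 0):
            raise SimulationError("dispersion must be positive")
        if self.baseline_log_sd <= 0 or self.depth_log_sd <= 0:
            raise SimulationError("lognormal sd parameters must be positive")
        if self.domain_logit_sd < 0:
            raise SimulationError("domain_logit_sd must be >= 0")


def simulate_cell_counts(
    params: CellSimParams, table: CategoryTable
) -> tuple[CellMatrix, SimTruth]:
    """Simulate a sparse integer gene-by-cell matrix over the table's genes."""
    params.validate()
    if len(table) == 0:
        raise SimulationError("category table is empty")
    ss = np.random.SeedSequence(params.seed)
    rng_genes, rng_cells, rng_counts = (np.random.default_rng(s) for s in ss.spawn(3))

    gene_ids = np.asarray(table.gene_ids, dtype=object)
    G, C = len(gene_ids), params.n_cells
    cats = np.array([table.category_of(g) for g in gene_ids], dtype=object)
    mtypes = np.array([table.molecule_type_of(g) for g in gene_ids], dtype=object)

    baseline = rng_genes.lognormal(params.baseline_log_mean, params.baseline_log_sd, G)
    n_mito = int(round(params.mito_gene_fraction * G))
    mito = np.zeros(G, dtype=bool)
    if n_mito > 0:
        mito[rng_genes.choice(G, size=n_mito, replace=False)] = True

    dom = np.array(
        [
            params.domain_fraction.get(c, params.default_domain_fraction)
            * params.molecule_type_domain_scale.get(mt, 1.0)
            for c, mt in zip(cats, mtypes)
        ],
        dtype=float,
    ).clip(1e-9, 1.0)
    if params.domain_logit_sd > 0:
        # per-gene domain heterogeneity on the logit scale: real expression
        # domains vary widely from a handful of cells to the whole organ
        logit = np.log(dom) - np.log1p(-dom.clip(max=1 - 1e-9))
        jitter = rng_genes.normal(0.0, params.domain_logit_sd, G)
        dom = (1.0 / (1.0 + np.exp(-(logit + jitter)))).clip(1e-9, 1.0)
    dom[mito] = 1.0
    abund = np.array([params.abundance_scale.get(c, 1.0) for c in cats], dtype=float)
    weight = baseline * abund
    # inflate mito weights so the expected mito UMI share hits the target
    if n_mito > 0 and params.mito_expression_share > 0:
        w_eff_nonmito = float((weight * dom)[~mito].sum())
        s = params.mito_expression_share
        weight[mito] = (s / (1.0 - s)) * w_eff_nonmito / n_mito

    tooth = (np.arange(C) % params.n_teeth) + 1
    cell_ids = np.array([f"T{t}_C{i:06d}" for i, t in enumerate(tooth)], dtype=object)
    depth = rng_cells.lognormal(params.depth_log_mean, params.depth_log_sd, C)
    damaged = rng_cells.random(C) < params.damaged_cell_fraction
    mito_boost = np.ones(C)
    if params.damaged_mito_share > 0 and params.mito_expression_share > 0:
        s, d = params.mito_expression_share, params.damaged_mito_share
        mito_boost[damaged] = (d / (1.0 - d)) / (s / (1.0 - s))

    if C == 0:
        empty = sp.csr_matrix((G, 0), dtype=np.int64)
        truth = SimTruth(
            genes=pd.DataFrame(
                {"category": cats, "molecule_type": mtypes, "baseline": baseline,
                 "domain_fraction": dom, "abundance_scale": abund, "weight": weight,
                 "mito": mito},
                index=pd.Index(gene_ids, name="gene_id"),
            ),
            cells=pd.DataFrame(columns=["tooth", "depth", "damaged"]),
        )
        return CellMatrix(empty, gene_ids, cell_ids, mito, normalized=False), truth

    z = rng_counts.random((G, C)) < dom[:, None]
    wz = weight[:, None] * z
    if n_mito > 0:
        wz[mito, :] *= mito_boost[None, :]
    col_w = wz.sum(axis=0)
    mu = wz * (depth / np.maximum(col_w, 1e-300))[None, :]
    del wz, z
    counts = _nb_counts(rng_counts, mu, params.dispersion)
    del mu
    mat = sp.csr_matrix(counts.astype(np.int64))
    del counts

    truth = SimTruth(
        genes=pd.DataFrame(
            {"category": cats, "molecule_type": mtypes, "baseline": baseline,
             "domain_fraction": dom, "abundance_scale": abund, "weight": weight,
             "mito": mito},
            index=pd.Index(gene_ids, name="gene_id"),
        ),
        cells=pd.DataFrame(
            {"tooth": tooth, "depth": depth, "damaged": damaged},
            index=pd.Index(cell_ids, name="cell_id"),
        ),
    )
    return CellMatrix(mat, gene_ids, cell_ids, mito, normalized=False), truth
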