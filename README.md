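# keystonex

Category-level expression analysis of **developmental keystone genes** in
bulk and single-cell RNA-seq count data.

## The problem

Genes required for an organ's normal development can be ranked by how badly
their null mutants fail: some arrest development outright, others merely
modify the phenotype, and many produce no detectable single-knockout
phenotype at all.  In the mouse molar — the best-characterized case — the
curated categories are **progression** (15 genes; null mutation arrests
tooth development), **shape** (28; altered crown morphology), **tissue**
(27; enamel/dentine defects), **dispensable** (100; no detectable tooth
phenotype) and **double** (11; phenotype only in combined mutants of
paralog pairs), against control pools of developmental-process genes and
all other protein-coding genes.

Given such a classification, the analysis asks system-level questions:
Are progression genes more highly expressed than dispensable ones at the
organ level?  Is that elevation still visible within their own signaling
pathways (Wnt, Tgfβ, Fgf, Hh, Eda, Notch)?  At the single-cell level, is a
gene's organ-level expression driven by *how many* cells express it (the
expression-domain size) or by *how strongly* each expressing cell does
(cell-level transcript abundance)?  And do secreted ligands — overrepresented
among shape genes — have systematically smaller expression domains?

`keystonex` implements this analysis as a tested, reusable pipeline, plus a
synthetic-data generator that reproduces the statistical structure the
analysis assumes, so the whole pipeline runs with no external download.

## The statistics

**Gene-set resampling test.**  For a focal gene set *F* inside a pool *P*,
per-gene expression values are summarized (median over replicate samples of
median-of-ratios-normalized counts), the observed statistic is the median
over *F*, and the null is built from `n_perm` random size-|F| draws from
*P* without replacement.  The one-tailed p-value uses the add-one
Monte-Carlo estimator

    p = (1 + #{null ≥ observed}) / (1 + n_perm)

(`≤` for "low" alternatives), which is permutation-valid, never zero, and
conservative on ties.  For category-vs-control contrasts the pool is the
combined focal + reference gene set (a gene-label permutation); for
category-vs-pathway contrasts the pool is all genes of the corresponding
pathways, focal included.

**Cell-level transcript abundance.**  For gene *X* over normalized
single-cell expression *N<sub>Xk</sub>*,

    X̄ = Σₖ N_Xk / n,   n = #{cells with nonzero N_Xk}

where *n* is the expression-domain size.  Organ-level total expression then
decomposes exactly as `total = n · X̄`, separating domain size from
per-cell abundance.

**Preprocessing.**  Cells with ≥ 20 detected genes and genes detected in
≥ 3 cells pass the basic filter; robust cells additionally have 3,000–9,000
detected genes, 7,000–180,000 UMIs (inclusive) and < 10% mitochondrial
transcripts.  Cells are summed to per-organ pseudobulk profiles, normalized
jointly with bulk samples by median-of-ratios size factors, with no
gene-length scaling.

## Worked example

Run the full pipeline on the default synthetic preset (20,692 genes with the
curated category structure; 7 bulk replicates; 300 cells across 4 teeth):

```python
from keystonex.pipeline import RunConfig, run_pipeline

cfg = RunConfig(seed=11, out_dir="out", n_perm=10_000,
                simulate={"cells": {"n_cells": 300}})
report = run_pipeline(cfg)
```

which prints to `out/report.json` / `out/contrasts.tsv`, including:

```
bulk_category:progression:dispensable            observed=1924.3  p=0.0001
bulk_category:shape:dispensable                  observed=811.1   p=0.0001
pathway_context:progression:Wnt+Tgfb+Fgf+Hh      observed=1924.3  p=0.0001
pathway_context:shape:six pathways               observed=811.1   p=0.1407
abundance:progression:dispensable                observed=55.4    p=0.0002
domain_by_type:pathway_genes                     observed=36.0    p=0.0001
domain_decomposition                             rho=0.862
```

Reading: progression genes are strongly elevated at the organ level
(median normalized expression 1924 vs a dispensable-category median of 280;
p = 0.0001 at 10,000 draws is the smallest attainable value), and remain
elevated within their four pathway families.  Their per-cell abundance X̄
is also high (p = 0.0002), while ligands occupy significantly smaller
expression domains (median 36 expressing cells; p = 0.0001, one-tailed
low).  Organ-level totals track domain size (Spearman ρ = 0.86).  These are
the signals the default generator plants; a flat (null) simulation returns
uniform p-values.

The same stages are available as a CLI:

```sh
keystonex simulate --seed 3 --out-dir sim --n-cells 300
keystonex qc --cells-dir sim/cells --out-dir qc
keystonex compare --bulk sim/bulk_counts.tsv --categories sim/categories.tsv \
    --focal progression --reference dispensable --seed 5
keystonex run --config config.yaml
```

## Layout

- `keystonex.categories` — classification tables, pathway/molecule-type
  annotation, one-to-one ortholog transfer
- `keystonex.simulate` — negative-binomial bulk and single-cell generators
  with category-structured signal, plus deterministic presets
- `keystonex.preprocess` — QC filters, median-of-ratios size factors,
  normalization, pseudobulk aggregation
- `keystonex.stats` — resampling tests, abundance profiles, domain
  decomposition, molecule-type domain comparisons
- `keystonex.pipeline` / `keystonex.cli` — end-to-end orchestration and the
  `keystonex` command

See `docs/methods.md` for the statistical model, parameter defaults, and
the design decisions behind them.
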