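# Methods

## Scope and data model

The package analyses gene expression by *phenotype-severity category*.  A
category table assigns each gene exactly one primary label (progression,
shape, tissue, dispensable, double, developmental_process, other), an
optional set of signaling pathways (Wnt, Tgfb, Fgf, Hh, Eda, Notch) and a
molecule type (ligand, receptor, intracellular, transcription_factor,
other, unannotated).  The five keystone labels are mutually exclusive; a
keystone gene that also belongs to the GO-style developmental-process pool
keeps its keystone label and carries a boolean flag, and the pool includes
such genes only when explicitly requested (`developmental_pool(
include_keystone=True)`).  This keeps the keystone-vs-control contrasts
unambiguous while still allowing the GO-style pool to be assembled.  The
developmental-process pool is supplied as a plain gene list (here,
generated); it is not fetched from an annotation database.

Ortholog transfer is table-driven relabeling through a strictly one-to-one
map; genes without a one-to-one ortholog are dropped and counted.  Applying
a map and then its inverse is the identity on the mapped subset.

## Resampling tests

All category comparisons share one primitive: per-gene expression values
(median across replicate samples of normalized counts; configurable to
mean), an observed summary (median by default) over the focal set, and a
null of `n_perm` random equally-sized gene sets drawn from a pool without
replacement within each draw.  One-tailed p-values use the add-one
estimator `p = (1 + #{null >= obs}) / (1 + n_perm)`; ties count toward the
tail, which is conservative, and the smallest attainable value is
`1/(n_perm + 1)`.  `n_perm` defaults to 10,000.

Two pool conventions exist and both are exposed:

- **Label permutation (default for category-vs-control).**  The pool is the
  combined focal + reference set.  Under gene-label exchangeability this is
  an exact permutation null; calibration experiments (200 null simulations
  per test, `n_perm = 999`) put the type-I error at alpha = 0.05 inside the
  binomial 99% confidence interval for every test in the package.
- **Reference-only draws** (`pool_mode="reference_only"`).  The null is
  built from the control category alone.  This makes the minimum p
  attainable for an extreme focal set, but because the null cannot reach
  beyond the reference sample's own spread it is measurably
  anti-conservative (empirically ~0.07-0.10 at alpha = 0.05 with 15 focal /
  100 reference genes), so it is not the default.

Category-vs-pathway contrasts (`pathway_context_test`) draw from all genes
of the requested pathways with the focal genes included, mirroring the
"category against all genes of its pathways" framing; `exclude_ligands`
removes ligand-type genes from both the focal set and the pool.
`domain_size_by_molecule_type` tests the one-tailed "ligand domains small"
alternative against size-matched draws from the non-ligand scope genes.

No multiple-testing correction is applied across the battery of contrasts;
each reported p is a single pre-registered one-tailed comparison.

## Cell-level abundance and the domain decomposition

For a normalized cell matrix, gene X's expression-domain size `n` is the
number of cells with nonzero normalized expression, and its cell-level
abundance is `X_bar = (sum over expressing cells) / n`, undefined (NaN)
when `n = 0`.  The per-gene organ total is *defined* as `n * X_bar`, so
the decomposition identity holds exactly in floating point rather than to
rounding error.  A documented switch (`expressed_above`) changes the
expressing-cell criterion from "nonzero" to "above a threshold" (e.g. > 1)
for sensitivity analyses; the nonzero reading is the default.

`domain_decomposition` reports the Spearman correlation between per-gene
totals and domain sizes.  Note that the correlation is only informative
when domain sizes actually vary across genes (see the generator's
`domain_logit_sd`).

## Preprocessing

**Basic filter** — cells with >= 20 detected genes, then genes detected in
>= 3 of the remaining cells; one pass in that order (no iteration to a
fixpoint, matching common single-pass practice).  The report also records
what the reverse order would have removed.  **Robust filter** — cells with
detected genes in [3000, 9000], UMIs in [7000, 180000] (both ranges
inclusive: a plain reading of "from ... to") and mitochondrial fraction
strictly below 0.10 (a cell at exactly 10% is removed).  All five
thresholds are configurable.  Filters are idempotent and the retained set
equals a per-cell re-evaluation of the three predicates.

**Size factors** — the classic median-of-ratios estimator: restrict to
genes positive in every sample, take the per-gene geometric mean as the
reference, and use each sample's median ratio to the reference.  The median
is taken in ratio space; DESeq2 takes it in log space, which differs only
in how the middle pair is interpolated at even reference-gene counts
(agreement to ~1e-3 relative; exact at odd counts).  Matrices with no
all-positive gene raise an error suggesting pseudobulk pooling first.
Factors are defined up to a global constant: scaling one column by c moves
its factor relative to the others by exactly c.

**Pseudobulk** — integer per-group sums over an explicit cell-to-sample
assignment; total counts are conserved exactly.  Single-cell data is
normalized jointly with bulk samples by concatenating the per-tooth
pseudobulk columns with the bulk matrix on shared genes; each cell then
inherits its tooth's size factor.  No gene-length normalization anywhere.

## The synthetic-data generator

Both arms use a gamma-Poisson (negative binomial) count model with
lognormal gene baselines — the standard overdispersed model for RNA counts.

**Bulk** (`BulkSimParams`): gene g in category c has expected count
proportional to `baseline_g * category_fold[c] * pathway_member_fold^(g in
a pathway) * depth_s`.  Defaults: 7 replicates (the mouse design; 5 for
rat), expected library size 2e7, NB shape 10 (biological CV ~0.3, typical
of replicate bulk libraries), `baseline_log_sd = 0.7`.  The baseline spread
is the one genuinely free scale parameter; it is pinned by the generator's
stated recovery property — a 3x-elevated 15-gene category must be detected
at p <= 0.01 in at least 95% of replicates on 1,500-gene simulations — 
which bounds the gene-to-gene sigma at roughly
`ln 3 >= (z_.01 + z_.05) * sigma / (2 phi(0) sqrt(15))`, i.e. sigma <~ 0.8;
0.7 satisfies the property with margin (97-99% across seed blocks).

**Single cell** (`CellSimParams`): gene g is expressed in a
Bernoulli(`domain_fraction`) subset of cells, i.i.d. across cells (the
analysis uses only expressing-cell counts, not spatial topology);
conditional on expression, counts are NB with mean proportional to
`baseline_g * abundance_scale[c] * depth_cell`, normalized per cell so the
expected total equals the cell's depth.  Domain fraction and abundance
scale are therefore separable signals: raising one changes its statistic
(n or X_bar) while moving the other only through depth renormalization,
which is shared by all genes.  `domain_logit_sd` adds per-gene domain
heterogeneity on the logit scale (real expression domains span orders of
magnitude; the default 0 keeps category-level signals clean).
`molecule_type_domain_scale` multiplies domain fractions per molecule type
(e.g. halving ligand domains).  Per-cell depths are lognormal
(`exp(10.31) ~ 30,000` UMIs, sd 0.3 in log), sized together with the
~20,700-gene default table and `default_domain_fraction = 0.30` so that
simulated cells land inside the 3,000-9,000 detected-gene and
7,000-180,000 UMI QC window.  Mitochondrial genes (0.2% of genes) get
domain 1 and weights inflated to a 5% expected UMI share; a 3% "damaged"
cell fraction gets a 20% share so the <10% filter has something to remove.
One master seed feeds deterministic per-matrix substreams; equal seeds give
byte-identical MTX output.

**Presets.**  `keystone_preset()` is a deterministic table whose
bookkeeping mirrors the curated tooth tabulations: 15/28/27/100/11 keystone
genes, a 272-gene six-pathway union with 221 genes in the four families
containing all progression genes, ligand shares 3/15 and 10/28, and
control pools of 4,106 developmental-process and 16,165 other genes.  Gene
ids are synthetic; the table is a structural stand-in, not a curated list.
The pipeline's default simulation adds the study-like signal structure:
progression fold 3 and shape fold 1.5 at the organ level, pathway members
fold 2, progression per-cell abundance 3x, ligand domains halved.

`ligand_reversal_preset()` is a constructed scenario for the
ligand-masking effect: a ligand-heavy focal category (60 genes, 70%
ligands) inside a 272-gene pathway pool with a 20% ligand share, ligand
domains halved everywhere, focal abundance elevated 1.6x, baseline sigma
0.35.  Its ground truth makes the organ-level focal median approximately
cancel against the pool when ligands are included (the halved-domain
ligands sit near `0.8x` the pool's typical level and dominate the focal
median) while the non-ligand elevation is unambiguous once ligands are
excluded from both sides.  Across seeds this yields a with-ligands p well
above 0.05, a without-ligands p below 0.01, and a ligands-low domain-size
p at or near the attainable minimum.

**What the generator does not emulate.**  Spatial expression structure
(domains are i.i.d. cell subsets), doublets, ambient RNA, batch effects,
gene length effects, cell-type composition, and gene-gene correlation.
Passing tests therefore demonstrate the statistical machinery — 
calibration, power, exact identities, boundary handling — under the
assumed generative structure, not biological conclusions about real teeth.

## Numerical and convention choices

- Add-one Monte-Carlo p-values; `>=` tie handling; one-tailed directions:
  "focal high" everywhere except the ligand domain-size test ("ligand low").
- Null draws are generated by ranking uniform keys per permutation
  (chunked `argpartition`), which is vectorized yet reproducible: the drawn
  index sets depend only on the seed.
- Quantile convention for box-plot-style summaries: linear interpolation
  between order statistics (numpy default, type 7), pinned so table
  assertions are exact.
- Display rounding of fractions: half-up to two decimals; raw fractions
  kept internally.
- Degenerate inputs raise typed errors rather than returning NaN: empty
  focal sets, empty categories (0/0 molecule-type fractions), zero-total
  cells in `mito_fraction`, matrices with no all-positive gene in
  `median_ratio_size_factors`.
- Reports contain no timestamps; re-running a config reproduces the
  report byte for byte, and each report embeds a config hash and library
  versions.

## Problem sizes used by the test suite and acceptance script

Calibration: 200 null replicates per test at `n_perm = 999` (~115-410 gene
tables, 80-cell matrices).  Power: 100 replicates of 1,500-gene bulk
simulations at `n_perm = 2000`.  Enumeration oracle: pools of 6-12 genes
against all subsets at `n_perm = 10,000`.  Ligand reversal: 1,072 genes x
400 cells at `n_perm = 10,000`.  The full suite runs in well under a
minute on one CPU; these sizes are package defaults chosen to make the
checks statistically decisive at interactive runtimes.

## Known limitations

- The resampling nulls assume gene-label exchangeability within the pool;
  correlated genes (co-regulation) would inflate effective significance in
  real data, as in any gene-label permutation scheme.
- `abundance_category_test` conditions on genes expressed in at least one
  cell; categories dominated by undetected genes lose members before
  testing and the report only reflects the detected subset.
- The reference-only pool mode is provided for completeness but is mildly
  anti-conservative; use the default label permutation for inference.
- Median-of-ratios factors require at least one gene positive in all
  columns; very sparse matrices must be pooled (pseudobulk) first, which
  the error message points out.
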