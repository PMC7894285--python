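"""Resampling-test correctness, abundance decomposition, molecule-type tests."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_cell_matrix
from keystonex.categories import PATHWAYS, CategoryTable, GeneRecord
from keystonex.stats import (
    StatsError,
    abundance_category_test,
    abundance_profile,
    cell_level_abundance,
    domain_decomposition,
    domain_size_by_molecule_type,
    gene_level_values,
    pathway_context_test,
    resample_median_test,
    summary_expression,
)


def exhaustive_p(values, focal_idx, pool_idx, statistic=np.median, alternative="high"):
    """Exact one-tailed p by enumerating every size-k subset of the pool."""
    observed = statistic(values[focal_idx])
    k = len(focal_idx)
    stats = [statistic(values[list(c)]) for c in combinations(pool_idx, k)]
    if alternative == "high":
        return sum(s >= observed for s in stats) / len(stats)
    return sum(s <= observed for s in stats) / len(stats)


class TestSummaryExpression:
    def test_single_gene_identity(self):
        s = pd.Series({"a": 5.0, "b": 7.0})
        assert summary_expression(s, ["b"]) == 7.0

    def test_median_of_three(self):
        s = pd.Series({"a": 1.0, "b": 2.0, "c": 9.0})
        assert summary_expression(s, ["a", "b", "c"]) == 2.0

    def test_matrix_summarized_across_samples_first(self):
        m = pd.DataFrame({"s1": [1.0, 10.0], "s2": [3.0, 30.0], "s3": [5.0, 20.0]},
                         index=["a", "b"])
        # per-gene medians: a -> 3, b -> 20; median over set -> 11.5
        assert summary_expression(m, ["a", "b"]) == 11.5
        assert gene_level_values(m).loc["a"] == 3.0

    def test_empty_set_rejected(self):
        with pytest.raises(StatsError):
            summary_expression(pd.Series({"a": 1.0}), [])

    def test_large_set_matches_naive_sort_median(self):
        rng = np.random.default_rng(0)
        s = pd.Series(rng.lognormal(0, 1, 100), index=[f"g{i}" for i in range(100)])
        naive = sorted(s.to_numpy())
        expected = 0.5 * (naive[49] + naive[50])
        assert summary_expression(s, list(s.index)) == pytest.approx(expected, abs=0)


class TestResampleMedianTest:
    def test_focal_equals_pool_gives_p_one(self):
        s = pd.Series({"a": 1.0, "b": 5.0, "c": 2.0})
        res = resample_median_test(s, ["a", "b", "c"], ["a", "b", "c"],
                                   n_perm=500, seed=1)
        assert res.p_one_tailed == 1.0

    def test_matches_exhaustive_enumeration_small_pool(self):
        """Pool of 6, focal of 2: the Monte-Carlo p agrees with exact subset
        enumeration (15 subsets) within 2 Monte-Carlo standard errors."""
        rng = np.random.default_rng(3)
        values = rng.lognormal(0, 1, 6)
        s = pd.Series(values, index=[f"g{i}" for i in range(6)])
        focal = ["g1", "g4"]
        n_perm = 10_000
        res = resample_median_test(s, focal, list(s.index), n_perm=n_perm, seed=5)
        exact = exhaustive_p(values, [1, 4], range(6))
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(res.p_one_tailed - exact) <= 2 * se + 2 / n_perm

    def test_minimum_p_attainable(self):
        s = pd.Series({"hi": 100.0, **{f"g{i}": float(i) for i in range(10)}})
        res = resample_median_test(s, ["hi"], [f"g{i}" for i in range(10)],
                                   n_perm=999, seed=2)
        assert res.p_one_tailed == pytest.approx(1 / 1000)

    def test_p_monotone_in_observed_statistic(self):
        """With pool and seed fixed, a larger observed statistic cannot give
        a larger one-tailed 'high' p."""
        rng = np.random.default_rng(8)
        pool_vals = rng.lognormal(0, 1, 40)
        s = pd.Series(
            {**{f"p{i}": v for i, v in enumerate(pool_vals)},
             "lo1": 0.1, "lo2": 0.2, "hi1": 50.0, "hi2": 60.0}
        )
        pool = [f"p{i}" for i in range(40)]
        p_low = resample_median_test(s, ["lo1", "lo2"], pool, n_perm=2000, seed=4)
        p_high = resample_median_test(s, ["hi1", "hi2"], pool, n_perm=2000, seed=4)
        assert p_high.observed > p_low.observed
        assert p_high.p_one_tailed <= p_low.p_one_tailed

    def test_pool_smaller_than_focal_rejected(self):
        s = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        with pytest.raises(StatsError):
            resample_median_test(s, ["a", "b"], ["c"], n_perm=10, seed=0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        s = pd.Series(rng.lognormal(0, 1, 30), index=[f"g{i}" for i in range(30)])
        focal, pool = ["g0", "g1", "g2"], [f"g{i}" for i in range(3, 30)]
        a = resample_median_test(s, focal, pool, n_perm=500, seed=77)
        b = resample_median_test(s, focal, pool, n_perm=500, seed=77)
        assert a.p_one_tailed == b.p_one_tailed
        assert a.null_quantiles == b.null_quantiles

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n_pool=st.integers(3, 25),
        n_focal=st.integers(1, 3),
        seed=st.integers(0, 10_000),
    )
    def test_p_respects_add_one_bounds(self, n_pool, n_focal, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 1, n_pool + n_focal)
        s = pd.Series(values, index=[f"g{i}" for i in range(len(values))])
        focal = [f"g{i}" for i in range(n_focal)]
        pool = [f"g{i}" for i in range(n_focal, n_focal + n_pool)]
        n_perm = 200
        res = resample_median_test(s, focal, pool, n_perm=n_perm, seed=seed)
        assert 1 / (n_perm + 1) <= res.p_one_tailed <= 1.0


class TestCellLevelAbundance:
    def test_two_expressing_cells(self):
        m = make_cell_matrix(np.array([[0, 2, 4]]), normalized=True)
        x_bar, n = cell_level_abundance(m, "g00000")
        assert (x_bar, n) == (3.0, 2)

    def test_single_expressing_cell(self):
        m = make_cell_matrix(np.array([[0.0, 7.5, 0.0]]), normalized=True)
        x_bar, n = cell_level_abundance(m, "g00000")
        assert (x_bar, n) == (7.5, 1)

    def test_all_zero_gene_flagged_undefined(self):
        m = make_cell_matrix(np.array([[0, 0], [1, 2]]))
        x_bar, n = cell_level_abundance(m, "g00000")
        assert n == 0 and np.isnan(x_bar)

    def test_unknown_gene_rejected(self):
        m = make_cell_matrix(np.array([[1]]))
        with pytest.raises(StatsError):
            cell_level_abundance(m, "nope")

    def test_alternative_denominator_threshold(self):
        """The documented switch counting only cells with expression > 1."""
        m = make_cell_matrix(np.array([[1, 2, 4]]), normalized=True)
        prof = abundance_profile(m, expressed_above=1.0)
        assert prof["n"].iloc[0] == 2
        assert prof["x_bar"].iloc[0] == 3.0


class TestDomainDecomposition:
    def test_identity_exact_for_every_gene(self):
        rng = np.random.default_rng(9)
        dense = rng.poisson(0.8, (200, 60)) * rng.random((200, 60))
        m = make_cell_matrix(dense, normalized=True)
        prof, _ = domain_decomposition(m)
        expressed = prof[prof["n"] > 0]
        residual = expressed["total"] - expressed["n"] * expressed["x_bar"]
        assert (residual == 0.0).all()

    def test_varying_domain_constant_abundance_high_correlation(self):
        """Totals track expressing-cell counts when all expressing cells
        carry the same value (domain size drives organ-level expression)."""
        rng = np.random.default_rng(4)
        n_genes, n_cells = 150, 300
        dense = np.zeros((n_genes, n_cells))
        domain = rng.integers(5, n_cells, n_genes)
        for g in range(n_genes):
            cols = rng.choice(n_cells, domain[g], replace=False)
            dense[g, cols] = 2.0  # constant per-cell abundance
        m = make_cell_matrix(dense, normalized=True)
        _, rho = domain_decomposition(m)
        assert rho >= 0.95

    def test_varying_abundance_constant_domain_low_correlation(self):
        rng = np.random.default_rng(5)
        n_genes, n_cells = 150, 300
        dense = np.zeros((n_genes, n_cells))
        for g in range(n_genes):
            # near-constant domain, widely varying per-cell abundance
            cols = rng.choice(n_cells, int(rng.integers(95, 106)), replace=False)
            dense[g, cols] = rng.lognormal(0, 1)
        m = make_cell_matrix(dense, normalized=True)
        _, rho = domain_decomposition(m)
        assert abs(rho) < 0.3


class TestAbundanceCategoryTest:
    @staticmethod
    def _table(n_focal, n_ref):
        recs = [GeneRecord(f"f{i}", "", "progression") for i in range(n_focal)]
        recs += [GeneRecord(f"r{i}", "", "dispensable") for i in range(n_ref)]
        return CategoryTable(recs)

    def test_extreme_single_gene_reaches_minimum_p(self):
        table = self._table(1, 20)
        dense = np.zeros((21, 10))
        dense[0, :] = 100.0  # focal gene: huge abundance everywhere
        for i in range(1, 21):
            dense[i, : 5] = float(i) / 10
        m = make_cell_matrix(dense, normalized=True)
        m.gene_ids[:] = ["f0"] + [f"r{i}" for i in range(20)]
        res = abundance_category_test(m, table, "progression", "dispensable",
                                      n_perm=999, seed=1,
                                      pool_mode="reference_only")
        assert res.p_one_tailed == pytest.approx(1 / 1000)

    def test_combined_pool_bounds_extreme_p_near_label_share(self):
        """Under the default label permutation the same extreme focal gene
        can be redrawn, so p approaches its share of the pooled labels."""
        table = self._table(1, 20)
        dense = np.zeros((21, 10))
        dense[0, :] = 100.0
        for i in range(1, 21):
            dense[i, :5] = float(i) / 10
        m = make_cell_matrix(dense, normalized=True)
        m.gene_ids[:] = ["f0"] + [f"r{i}" for i in range(20)]
        res = abundance_category_test(m, table, "progression", "dispensable",
                                      n_perm=4000, seed=1)
        assert res.p_one_tailed == pytest.approx(1 / 21, rel=0.3)

    def test_empty_category_after_expression_filter_rejected(self):
        table = self._table(1, 2)
        dense = np.zeros((3, 4))
        dense[1:, :] = 1.0  # focal gene f0 never expressed
        m = make_cell_matrix(dense, normalized=True)
        m.gene_ids[:] = ["f0", "r0", "r1"]
        with pytest.raises(StatsError):
            abundance_category_test(m, table, "progression", "dispensable",
                                    n_perm=10, seed=0)


def _pathway_table():
    recs = []
    for i in range(6):
        recs.append(GeneRecord(f"s{i}", "", "shape", frozenset({"Wnt"}),
                               "ligand" if i < 3 else "intracellular"))
    for i in range(20):
        recs.append(GeneRecord(f"w{i}", "", "other", frozenset({"Wnt"}),
                               "receptor"))
    return CategoryTable(recs)


class TestPathwayContext:
    def test_focal_equals_pool_gives_p_one(self):
        recs = [GeneRecord(f"s{i}", "", "shape", frozenset({"Eda"})) for i in range(5)]
        table = CategoryTable(recs)
        s = pd.Series({f"s{i}": float(i) for i in range(5)})
        res = pathway_context_test(s, table, "shape", {"Eda"}, n_perm=200, seed=3)
        assert res.p_one_tailed == 1.0

    def test_exclude_ligands_drops_them_from_both_sides(self):
        table = _pathway_table()
        values = pd.Series(
            {**{f"s{i}": 0.1 if i < 3 else 5.0 for i in range(6)},
             **{f"w{i}": 1.0 for i in range(20)}}
        )
        with_lig = pathway_context_test(values, table, "shape", {"Wnt"},
                                        n_perm=2000, seed=4)
        without = pathway_context_test(values, table, "shape", {"Wnt"},
                                       exclude_ligands=True, n_perm=2000, seed=4)
        assert with_lig.focal_size == 6 and without.focal_size == 3
        assert without.pool_size == 23
        assert without.observed > with_lig.observed

    def test_empty_pool_after_exclusion_rejected(self):
        recs = [GeneRecord("a", "", "shape", frozenset({"Fgf"}), "ligand")]
        table = CategoryTable(recs)
        s = pd.Series({"a": 1.0})
        with pytest.raises(StatsError):
            pathway_context_test(s, table, "shape", {"Fgf"}, exclude_ligands=True,
                                 n_perm=10, seed=0)


class TestDomainSizeByMoleculeType:
    def test_single_smallest_ligand_reaches_minimum_p(self):
        recs = [GeneRecord("lig", "", "shape", frozenset({"Wnt"}), "ligand")]
        recs += [GeneRecord(f"o{i}", "", "progression", frozenset({"Wnt"}),
                            "receptor") for i in range(15)]
        table = CategoryTable(recs)
        dense = np.zeros((16, 30))
        dense[0, :2] = 1.0  # ligand expressed in 2 cells
        for i in range(1, 16):
            dense[i, : 5 + i] = 1.0  # every other gene in >= 6 cells
        m = make_cell_matrix(dense, normalized=True)
        m.gene_ids[:] = ["lig"] + [f"o{i}" for i in range(15)]
        by_type, res = domain_size_by_molecule_type(m, table, "category_genes",
                                                    n_perm=999, seed=2)
        assert res.alternative == "low"
        assert res.p_one_tailed == pytest.approx(1 / 1000)
        assert by_type.loc["ligand", "median"] == 2.0

    def test_size_one_draws_match_exact_tail_mass(self):
        """One ligand with an interior rank: the resampled p equals the exact
        enumeration of size-1 draws (the fraction of non-ligand domain sizes
        at or below the ligand's) within 3 Monte-Carlo SE."""
        recs = [GeneRecord("lig", "", "shape", frozenset({"Wnt"}), "ligand")]
        recs += [GeneRecord(f"o{i}", "", "shape", frozenset({"Wnt"}),
                            "receptor") for i in range(12)]
        table = CategoryTable(recs)
        dense = np.zeros((13, 40))
        dense[0, :8] = 1.0  # ligand in 8 cells
        for i in range(1, 13):
            dense[i, : 2 + 3 * i] = 1.0  # others: 5, 8, 11, ... up to 38
        m = make_cell_matrix(dense, normalized=True)
        m.gene_ids[:] = ["lig"] + [f"o{i}" for i in range(12)]
        n_perm = 10_000
        _, res = domain_size_by_molecule_type(m, table, "category_genes",
                                              n_perm=n_perm, seed=6)
        others = np.array([min(2 + 3 * i, 40) for i in range(1, 13)], float)
        exact = np.mean(others <= 8.0)
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(res.p_one_tailed - exact) <= 3 * se + 2 / n_perm

    def test_no_ligands_in_scope_rejected(self):
        recs = [GeneRecord("a", "", "progression", frozenset({"Wnt"}), "receptor")]
        table = CategoryTable(recs)
        m = make_cell_matrix(np.ones((1, 4)), normalized=True)
        m.gene_ids[:] = ["a"]
        with pytest.raises(StatsError):
            domain_size_by_molecule_type(m, table, "category_genes", n_perm=10, seed=0)
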