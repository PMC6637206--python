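import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condfdr import (
    ConfigError,
    assign_cfdr,
    build_lookup_table,
    empirical_cfdr,
    monotonize,
    significant_set,
    unconditional_fdr,
)
from condfdr.cfdr import CfdrTable, cfdr_values
from conftest import brute_force_cfdr, make_merged


class TestEmpiricalCfdr:
    def test_single_snp_panel_degenerate_counts(self):
        panel = make_merged([0.01], [0.5])
        assert empirical_cfdr(panel, 0.01, 0.5) == pytest.approx(0.01)

    def test_toy5_reference_value(self, toy5):
        # query at SNP 2: 0.01 * 3 / 2
        assert empirical_cfdr(toy5, 0.01, 0.03) == pytest.approx(0.015)

    def test_matches_brute_force_everywhere(self, toy5):
        p_i = toy5["p_i"].to_numpy()
        p_j = toy5["p_j"].to_numpy()
        for a, b in zip(p_i, p_j):
            assert empirical_cfdr(toy5, a, b) == pytest.approx(
                brute_force_cfdr(p_i, p_j, a, b)
            )

    def test_off_panel_query_is_conservative(self, toy5):
        with pytest.warns(UserWarning):
            assert empirical_cfdr(toy5, 1e-9, 1e-9) == 1.0

    def test_conditioning_at_one_is_bh_rank_quantity(self, rng):
        p = np.sort(rng.uniform(size=200))
        panel = make_merged(p, np.ones(200))
        ranks = np.arange(1, 201)
        expected = np.minimum(p * 200 / ranks, 1.0)
        got = np.array([empirical_cfdr(panel, x, 1.0) for x in p])
        np.testing.assert_allclose(got, expected)


class TestVectorizedCounts:
    def test_fenwick_equals_double_loop_on_random_panels(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 60))
            # coarse grid forces plenty of ties on both axes
            p_i = rng.choice(np.linspace(0.05, 1.0, 8), size=n)
            p_j = rng.choice(np.linspace(0.05, 1.0, 8), size=n)
            got = cfdr_values(p_i, p_j)
            expected = [brute_force_cfdr(p_i, p_j, a, b) for a, b in zip(p_i, p_j)]
            np.testing.assert_allclose(got, expected)

    def test_permutation_invariance(self, rng):
        p_i = rng.uniform(size=300)
        p_j = rng.uniform(size=300)
        perm = rng.permutation(300)
        np.testing.assert_allclose(cfdr_values(p_i, p_j)[perm],
                                   cfdr_values(p_i[perm], p_j[perm]))


class TestLookupTable:
    def test_all_snp_cell_is_one(self, toy5):
        table = build_lookup_table(toy5, np.array([1.0]), np.array([1.0]))
        assert table.values[0, 0] == 1.0

    def test_grid_matches_pointwise_evaluations(self, toy5):
        pi_grid = np.array([0.01, 0.05, 1.0])
        pj_grid = np.array([0.01, 0.1, 1.0])
        table = build_lookup_table(toy5, pi_grid, pj_grid)
        for r, a in enumerate(pi_grid):
            for c, b in enumerate(pj_grid):
                assert table.values[r, c] == pytest.approx(
                    brute_force_cfdr(toy5["p_i"], toy5["p_j"], a, b)
                )

    def test_duplicated_thresholds_duplicate_rows(self, toy5):
        table = build_lookup_table(toy5, np.array([0.05, 0.05, 1.0]), np.array([1.0]))
        np.testing.assert_array_equal(table.values[0], table.values[1])

    def test_empty_grid_rejected(self, toy5):
        with pytest.raises(ConfigError):
            build_lookup_table(toy5, np.array([]), np.array([1.0]))


class TestMonotonize:
    def test_cumulative_min_direction(self):
        # rows ordered by increasing p_i; the scan runs from least
        # significant (bottom) upward, so (0.2, 0.1, 0.3) -> (0.1, 0.1, 0.3)
        table = CfdrTable(
            pi_grid=np.array([0.001, 0.01, 0.1]),
            pj_grid=np.array([1.0]),
            values=np.array([[0.2], [0.1], [0.3]]),
        )
        out = monotonize(table)
        np.testing.assert_allclose(out.values[:, 0], [0.1, 0.1, 0.3])
        assert out.monotonized

    def test_monotone_table_is_fixed_point(self):
        table = CfdrTable(
            pi_grid=np.array([0.001, 0.01, 0.1]),
            pj_grid=np.array([1.0, 0.1]),
            values=np.array([[0.01, 0.005], [0.05, 0.02], [0.5, 0.2]]),
        )
        np.testing.assert_array_equal(monotonize(table).values, table.values)

    def test_constant_column_unchanged(self):
        table = CfdrTable(
            pi_grid=np.array([0.001, 0.01, 0.1]),
            pj_grid=np.array([1.0]),
            values=np.full((3, 1), 0.3),
        )
        np.testing.assert_array_equal(monotonize(table).values, table.values)


class TestAssignCfdr:
    def test_toy5_all_directional_values_match_counting(self, toy5):
        results = assign_cfdr(toy5)
        p_i = toy5["p_i"].to_numpy()
        p_j = toy5["p_j"].to_numpy()
        for k in range(5):
            fwd = brute_force_cfdr(p_i, p_j, p_i[k], p_j[k])
            rev = brute_force_cfdr(p_j, p_i, p_j[k], p_i[k])
            assert results.loc[k, "cfdr_i_given_j"] == pytest.approx(fwd)
            assert results.loc[k, "cfdr_j_given_i"] == pytest.approx(rev)
            assert results.loc[k, "ccfdr"] == pytest.approx(max(fwd, rev))

    def test_symmetric_panel_gives_equal_directions(self, rng):
        p = rng.uniform(size=50)
        results = assign_cfdr(make_merged(p, p))
        np.testing.assert_allclose(results["cfdr_i_given_j"], results["cfdr_j_given_i"])
        np.testing.assert_allclose(results["ccfdr"], results["cfdr_i_given_j"])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_estimator_bounds_on_random_panels(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 200))
        # mix of heavy-tailed and uniform p-values with ties
        p_i = np.round(rng.uniform(size=n) ** rng.integers(1, 4), 3).clip(1e-3, 1.0)
        p_j = np.round(rng.uniform(size=n), 2).clip(1e-2, 1.0)
        results = assign_cfdr(make_merged(p_i, p_j))
        assert (results["cfdr_i_given_j"] >= results["p_i"] - 1e-15).all()
        assert (results["cfdr_j_given_i"] >= results["p_j"] - 1e-15).all()
        assert (results["ccfdr"] <= 1.0).all()
        assert (results["ccfdr"] >= np.maximum(results["p_i"], results["p_j"]) - 1e-15).all()


class TestUnconditionalReduction:
    def test_monotone_unconditional_equals_bh_adjustment(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=1000)
        assert len(np.unique(p)) == 1000  # tie-free panel
        ours = unconditional_fdr(p, monotone=True)
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, bh, rtol=1e-12)

    def test_conditioning_at_one_reduces_to_unconditional(self, rng):
        p = rng.uniform(size=300)
        via_cfdr = cfdr_values(p, np.ones(300))
        np.testing.assert_allclose(via_cfdr, unconditional_fdr(p, monotone=False))


class TestSignificantSet:
    def test_nothing_passes_when_all_one(self, toy5):
        results = assign_cfdr(toy5).assign(ccfdr=1.0)
        assert significant_set(results, "ccfdr", 0.05) == set()

    def test_boundary_value_excluded(self, toy5):
        results = assign_cfdr(toy5).assign(ccfdr=[0.05, 0.049, 0.05, 0.5, 0.9])
        assert significant_set(results, "ccfdr", 0.05) == {"rs2"}

    def test_filtering_by_threshold(self, rng):
        vals = np.array([0.01, 0.2, 0.03, 0.6, 0.04, 0.9, 0.7])
        results = make_merged(vals, vals).assign(
            cfdr_i_given_j=vals, cfdr_j_given_i=vals, ccfdr=vals
        )
        assert significant_set(results, "cfdr_i_given_j", 0.05) == {"rs1", "rs3", "rs5"}

    def test_invalid_alpha_and_field_rejected(self, toy5):
        results = assign_cfdr(toy5)
        with pytest.raises(ConfigError):
            significant_set(results, "ccfdr", 1.5)
        with pytest.raises(ConfigError):
            significant_set(results, "p_i", 0.05)
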