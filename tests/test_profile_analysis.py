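"""ANOVA, fold-change filtering, pattern clustering, growth ratios, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tricross as tc
from tricross.genome_io import GenomeIOError, ProfileMatrix
from tricross.profile_analysis import (
    de_filter,
    enrich_categories,
    hierarchical_cluster,
    one_way_anova,
    relative_growth,
)


def matrix_from(rows, groups):
    cols = [f"s{j+1}" for j in range(len(groups))]
    df = pd.DataFrame(rows, index=[f"r{i+1}" for i in range(len(rows))], columns=cols)
    return ProfileMatrix(values=df, groups=dict(zip(cols, groups)))


class TestOneWayAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.F == 0.0 and res.p_value == 1.0

    def test_textbook_sums_of_squares(self):
        """Groups {1,2,3} vs {4,5,6}: SSB = 13.5, SSW = 4, F = 13.5."""
        res = one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert math.isclose(res.F, 13.5, rel_tol=1e-12)
        assert math.isclose(res.p_value, float(stats.f.sf(13.5, 1, 4)), rel_tol=1e-12)

    def test_zero_within_variance_unequal_means_degenerate(self):
        res = one_way_anova([[2, 2], [5, 5]])
        assert res.p_value == 0.0 and res.degenerate

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            groups = [rng.normal(size=rng.integers(2, 8)) for _ in range(3)]
            res = one_way_anova(groups)
            F, p = stats.f_oneway(*groups)
            assert math.isclose(res.F, F, rel_tol=1e-10)
            assert math.isclose(res.p_value, p, rel_tol=1e-10)

    def test_two_group_anova_equals_t_squared(self):
        """With two groups, F = t^2 and the p-values coincide."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            a = rng.normal(size=int(rng.integers(2, 10)))
            b = rng.normal(1.0, 2.0, size=int(rng.integers(2, 10)))
            res = one_way_anova([a, b])
            t, p = stats.ttest_ind(a, b, equal_var=True)
            assert math.isclose(res.F, t**2, rel_tol=1e-9)
            assert math.isclose(res.p_value, p, rel_tol=1e-9)

    def test_type_one_error_calibration(self):
        """On null data ~1% of rows reach p < 0.01."""
        rng = np.random.default_rng(43)
        n = 10_000
        flagged = sum(
            one_way_anova([rng.normal(size=4), rng.normal(size=4)]).p_value < 0.01
            for _ in range(n)
        )
        assert abs(flagged / n - 0.01) < 4 * np.sqrt(0.01 * 0.99 / n)

    def test_input_contract_errors(self):
        with pytest.raises(GenomeIOError):
            one_way_anova([[1, 2, 3]])
        with pytest.raises(GenomeIOError):
            one_way_anova([[1], [2, 3]])
        with pytest.raises(GenomeIOError):
            one_way_anova([[1, np.nan], [2, 3]])


class TestDeFilter:
    def test_planted_fold_changes_recovered(self):
        """Rows planted at true 8-fold difference pass the 5-fold filter;
        null rows trip it at ~ the nominal 1% rate."""
        rng = np.random.default_rng(44)
        rows, ids_up = [], []
        for i in range(50):
            a = rng.normal(8.0, 0.3, 3).clip(0.1)
            b = rng.normal(1.0, 0.3, 3).clip(0.1)
            rows.append(np.concatenate([a, b]))
        for i in range(500):
            v = rng.normal(2.0, 0.3, 6).clip(0.1)
            rows.append(v)
        m = matrix_from(rows, ["A", "A", "A", "B", "B", "B"])
        res = de_filter(m, "A", "B", fc_threshold=5.0, p_threshold=0.01)
        planted = {f"r{i+1}" for i in range(50)}
        assert len(planted & res.up) >= 45
        false_pos = (res.up | res.down) - planted
        assert len(false_pos) <= 0.05 * 500

    def test_vacuous_thresholds_flag_every_row(self):
        rng = np.random.default_rng(45)
        rows = rng.uniform(0.5, 4.0, size=(30, 6))
        m = matrix_from(rows, ["A", "A", "A", "B", "B", "B"])
        res = de_filter(m, "A", "B", fc_threshold=1.0, p_threshold=1.01)
        assert res.up | res.down == {f"r{i+1}" for i in range(30)}

    def test_label_swap_mirrors_up_and_down(self):
        rng = np.random.default_rng(46)
        rows = rng.uniform(0.5, 4.0, size=(40, 6))
        m = matrix_from(rows, ["A", "A", "A", "B", "B", "B"])
        ab = de_filter(m, "A", "B", 2.0, 0.05)
        ba = de_filter(m, "B", "A", 2.0, 0.05)
        assert ab.up == ba.down and ab.down == ba.up

    def test_zero_denominator_rows_excluded_with_tally(self):
        rows = [[1, 1, 1, 0, 0, 0], [2, 2, 2, 1, 1, 1.5]]
        m = matrix_from(rows, ["A", "A", "A", "B", "B", "B"])
        res = de_filter(m, "A", "B", 2.0, 0.01)
        assert res.n_excluded_zero_mean == 1
        assert {r.row_id for r in res.results} == {"r2"}

    def test_small_group_refused(self):
        m = matrix_from([[1, 2, 3]], ["A", "A", "B"])
        with pytest.raises(GenomeIOError, match="< 2 samples"):
            de_filter(m, "A", "B")


class TestHierarchicalCluster:
    def test_two_identical_row_groups_split_perfectly(self):
        rows = [[1, 2, 3, 4]] * 5 + [[4, 3, 2, 1]] * 5
        m = matrix_from(rows, ["A", "A", "B", "B"])
        assign = hierarchical_cluster(m, k=2)
        left = {f"r{i+1}" for i in range(5)}
        assert assign.members(1) in (left, set(assign.labels) - left)
        assert assign.k == 2

    def test_three_planted_archetypes_recovered_exactly(self):
        """The three regulation archetypes (up in background A, flat, up
        in background B) are recovered with adjusted Rand index 1 at low
        noise."""
        from sklearn.metrics import adjusted_rand_score

        matrix, truth = tc.simulate_profile_matrix(noise_sd=0.1, seed=47)
        # Euclidean distance: the flat archetype has no pattern shape, so
        # magnitude (not correlation) is what separates it from the others
        assign = hierarchical_cluster(matrix, k=3, distance="euclidean")
        labels = [assign.labels[r] for r in matrix.values.index]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_anticorrelated_patterns_split_by_correlation_distance(self):
        """The default 1 - Pearson distance separates opposite regulation
        patterns regardless of magnitude."""
        from sklearn.metrics import adjusted_rand_score

        matrix, truth = tc.simulate_profile_matrix(
            n_rows_per_archetype=(40, 40),
            archetype_means=((4.0, 1.0), (0.5, 2.0)),
            noise_sd=0.1, seed=51,
        )
        assign = hierarchical_cluster(matrix, k=2)
        labels = [assign.labels[r] for r in matrix.values.index]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_one_puts_everything_together(self):
        matrix, _ = tc.simulate_profile_matrix(noise_sd=0.2, seed=48)
        assign = hierarchical_cluster(matrix, k=1)
        assert set(assign.labels.values()) == {1}

    def test_k_larger_than_rows_errors(self):
        m = matrix_from([[1, 2], [2, 1]], ["A", "B"])
        with pytest.raises(GenomeIOError):
            hierarchical_cluster(m, k=3)

    def test_constant_rows_assigned_not_crashing(self):
        rows = [[1, 2, 3, 4]] * 4 + [[4, 3, 2, 1]] * 4 + [[2, 2, 2, 2]]
        m = matrix_from(rows, ["A", "A", "B", "B"])
        assign = hierarchical_cluster(m, k=2)
        assert len(assign.labels) == 9
        assert set(assign.labels.values()) == {1, 2}

    def test_row_permutation_invariance_up_to_relabeling(self):
        from sklearn.metrics import adjusted_rand_score

        matrix, _ = tc.simulate_profile_matrix(
            n_rows_per_archetype=(20, 20, 20), noise_sd=0.05, seed=49
        )
        assign1 = hierarchical_cluster(matrix, k=3, distance="euclidean")
        perm = np.random.default_rng(50).permutation(len(matrix.values))
        shuffled = ProfileMatrix(matrix.values.iloc[perm], dict(matrix.groups))
        assign2 = hierarchical_cluster(shuffled, k=3, distance="euclidean")
        ids = list(matrix.values.index)
        l1 = [assign1.labels[r] for r in ids]
        l2 = [assign2.labels[r] for r in ids]
        assert adjusted_rand_score(l1, l2) == 1.0


class TestRelativeGrowth:
    def test_identical_replicates_are_100_percent(self):
        r = relative_growth([1.3, 2.0, 0.7], [1.3, 2.0, 0.7])
        assert r.percent == 100.0 and r.sd == 0.0

    def test_double_growth(self):
        r = relative_growth([2, 2, 2], [1, 1, 1])
        assert r.percent == 200.0 and r.sd == 0.0

    def test_paired_ratio_arithmetic(self):
        """a = {1.0, 1.2}, b = {2.0, 2.0}: ratios {50%, 60%}, mean 55%,
        sample SD 7.07%."""
        r = relative_growth([1.0, 1.2], [2.0, 2.0])
        assert math.isclose(r.percent, 55.0, rel_tol=1e-12)
        assert math.isclose(r.sd, np.std([50, 60], ddof=1), rel_tol=1e-12)
        assert r.method == "paired"

    def test_unequal_counts_bootstrap_is_seeded(self):
        r1 = relative_growth([1.0, 1.1, 0.9], [2.0, 2.1], seed=7)
        r2 = relative_growth([1.0, 1.1, 0.9], [2.0, 2.1], seed=7)
        assert r1 == r2
        assert r1.method == "bootstrap"
        assert 40 < r1.percent < 60

    def test_nonpositive_readings_excluded(self):
        r = relative_growth([1.0, 1.0, -1.0], [1.0, 1.0, 0.0])
        assert r.n_excluded_nonpositive == 2
        assert r.percent == 100.0


class TestEnrichCategories:
    def test_complete_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(100)]
        cat = universe[:10]
        p = enrich_categories(cat, universe, {"c": cat})["c"]
        assert math.isclose(p, 1 / math.comb(100, 10), rel_tol=1e-9)

    def test_overlap_of_one_matches_tail_sum_oracle(self):
        universe = [f"g{i}" for i in range(100)]
        cat = universe[:10]
        gene_set = [cat[0]] + universe[50:59]
        p = enrich_categories(gene_set, universe, {"c": cat})["c"]
        oracle = sum(
            math.comb(10, k) * math.comb(90, 10 - k) / math.comb(100, 10)
            for k in range(1, 11)
        )
        assert math.isclose(p, oracle, rel_tol=1e-9)
        assert p > 0.05  # overlap at expectation is not significant

    def test_category_equal_to_universe_is_uninformative(self):
        universe = [f"g{i}" for i in range(30)]
        p = enrich_categories(universe[:5], universe, {"all": universe})["all"]
        assert p == 1.0

    def test_empty_gene_set_gives_all_ones(self):
        universe = ["a", "b", "c"]
        ps = enrich_categories([], universe, {"c1": ["a"], "c2": ["b", "c"]})
        assert set(ps.values()) == {1.0}

    def test_gene_set_outside_universe_errors(self):
        with pytest.raises(GenomeIOError):
            enrich_categories(["x"], ["a", "b"], {"c": ["a"]})
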