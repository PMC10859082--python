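import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from distage.association import (
    DistanceMatrix,
    age_distance_matrix,
    bh_adjust,
    gene_distance_matrices,
    gene_distance_matrix,
    mantel_test,
    pseudobulk_correlation,
    run_workflow,
    run_workflow_multi,
    upper_triangle,
    upper_triangle_spearman,
)
from distage.datamodel import CellExpressionDataset


def matrix_from_upper(values, n):
    m = np.zeros((n, n))
    m[np.triu_indices(n, 1)] = values
    return DistanceMatrix([f"s{i}" for i in range(n)], m + m.T)


def brute_force_spearman(u, v):
    """Rank both vectors (average ranks) and take the Pearson formula."""
    ru, rv = rankdata(u), rankdata(v)
    ru, rv = ru - ru.mean(), rv - rv.mean()
    return float(ru @ rv / np.sqrt((ru @ ru) * (rv @ rv)))


def exhaustive_mantel_p(d1, d2):
    """Exact one-sided Mantel p over all n! simultaneous permutations."""
    n = d1.n
    iu = np.triu_indices(n, 1)
    obs = brute_force_spearman(d1.matrix[iu], d2.matrix[iu])
    count, total = 0, 0
    for perm in itertools.permutations(range(n)):
        p = np.asarray(perm)
        stat = brute_force_spearman(d1.matrix[iu], d2.matrix[np.ix_(p, p)][iu])
        count += stat >= obs - 1e-12
        total += 1
    return count / total


class TestAgeMatrix:
    def test_absolute_differences(self):
        dm = age_distance_matrix(pd.Series([1.0, 2.0, 4.0], index=["a", "b", "c"]))
        np.testing.assert_allclose(upper_triangle(dm.matrix), [1, 3, 2])

    def test_tied_ages_give_zero_and_one_entries(self):
        dm = age_distance_matrix([1, 1, 2, 2], sample_ids=list("abcd"))
        assert set(upper_triangle(dm.matrix)) == {0.0, 1.0}

    def test_fewer_than_three_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            age_distance_matrix([1, 2], sample_ids=["a", "b"])


class TestUpperTriangleSpearman:
    def test_monotone_transform_gives_one(self):
        d1 = matrix_from_upper([1, 2, 3, 4, 5, 6], 4)
        d2 = matrix_from_upper(np.exp([1, 2, 3, 4, 5, 6]), 4)
        assert upper_triangle_spearman(d1, d2) == pytest.approx(1.0)

    def test_monotone_reversal_gives_minus_one(self):
        d1 = matrix_from_upper([1, 2, 3, 4, 5, 6], 4)
        d2 = matrix_from_upper([6, 5, 4, 3, 2, 1], 4)
        assert upper_triangle_spearman(d1, d2) == pytest.approx(-1.0)

    def test_partially_shuffled_triangles_match_rank_oracle(self):
        u, v = [1, 2, 3, 4, 5, 6], [2, 1, 3, 4, 6, 5]
        expected = brute_force_spearman(u, v)
        assert expected == pytest.approx(1 - 6 * 4 / (6 * 35))  # = 0.8857142857
        d = upper_triangle_spearman(matrix_from_upper(u, 4), matrix_from_upper(v, 4))
        assert d == pytest.approx(expected, abs=1e-12)

    def test_constant_triangle_is_flagged_undefined(self):
        d1 = matrix_from_upper([1, 1, 1], 3)
        d2 = matrix_from_upper([1, 2, 3], 3)
        assert np.isnan(upper_triangle_spearman(d1, d2))

    def test_self_correlation_is_one(self):
        d = matrix_from_upper([0.3, 0.9, 0.1, 0.5, 0.2, 0.8], 4)
        assert upper_triangle_spearman(d, d) == pytest.approx(1.0)


class TestMantel:
    def test_observed_statistic_equals_upper_triangle_spearman(self):
        rng = np.random.default_rng(5)
        d1 = matrix_from_upper(rng.random(10), 5)
        d2 = matrix_from_upper(rng.random(10), 5)
        rho, _ = mantel_test(d1, d2, n_perm=10, seed=0)
        assert rho == pytest.approx(upper_triangle_spearman(d1, d2), abs=1e-12)

    def test_p_respects_permutation_floor(self):
        ages = age_distance_matrix([1, 2, 3, 4], sample_ids=list("abcd"))
        _, p = mantel_test(ages, ages, n_perm=99, seed=0)
        assert p >= 1 / 100

    @pytest.mark.parametrize("n_samples,seed", [(4, 0), (5, 1)])
    def test_matches_exhaustive_enumeration(self, n_samples, seed):
        """Monte-Carlo p agrees with the exact all-permutation p within
        three binomial standard errors."""
        rng = np.random.default_rng(seed)
        m = n_samples * (n_samples - 1) // 2
        d1 = matrix_from_upper(rng.random(m), n_samples)
        d2 = matrix_from_upper(rng.random(m), n_samples)
        exact = exhaustive_mantel_p(d1, d2)
        n_perm = 5000
        _, p = mantel_test(d1, d2, n_perm=n_perm, seed=rng)
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(p - exact) <= 3 * se + 2 / n_perm

    def test_pearson_statistic_option(self):
        rng = np.random.default_rng(7)
        d1 = matrix_from_upper(rng.random(10), 5)
        d2 = matrix_from_upper(rng.random(10), 5)
        rho, _ = mantel_test(d1, d2, n_perm=10, seed=0, stat="pearson")
        u, v = upper_triangle(d1.matrix), upper_triangle(d2.matrix)
        assert rho == pytest.approx(np.corrcoef(u, v)[0, 1], abs=1e-12)

    def test_constant_matrix_gives_undefined_with_p_one(self):
        d1 = matrix_from_upper([0, 0, 0], 3)
        d2 = matrix_from_upper([1, 2, 3], 3)
        rho, p = mantel_test(d1, d2, n_perm=50, seed=0)
        assert np.isnan(rho) and p == 1.0


class TestBH:
    def brute_force_bh(self, p):
        p = np.asarray(p, dtype=float)
        n = p.size
        order = np.argsort(p)
        adj = np.empty(n)
        prev = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            r = n - rank_from_end
            prev = min(prev, p[idx] * n / r)
            adj[idx] = prev
        return adj

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.04]), [0.04])

    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = rng.uniform(1e-4, 1.0, size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), self.brute_force_bh(p), atol=1e-12)

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(1e-4, 1.0, 30)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


def _three_sample_dataset(values_by_sample, ages):
    sids = list(values_by_sample)
    cells = sum(len(v) for v in values_by_sample.values())
    expression = np.concatenate([values_by_sample[s] for s in sids])[:, None]
    return CellExpressionDataset(
        expression=expression,
        gene_ids=["g"],
        cell_sample_ids=np.repeat(
            np.asarray(sids, dtype=object),
            [len(values_by_sample[s]) for s in sids],
        ),
        sample_metadata=pd.DataFrame({"age": ages}, index=sids),
    )


class TestGeneDistanceMatrix:
    def test_identical_samples_give_zero_matrix(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        ds = _three_sample_dataset(
            {"a": base, "b": base.copy(), "c": base.copy()}, [1, 2, 3]
        )
        dm = gene_distance_matrix(ds, "g", k=200)
        np.testing.assert_allclose(dm.matrix, 0.0, atol=1e-12)

    def test_far_shifted_sample_pattern(self):
        base = np.array([1.0, 2.0, 3.0])
        ds = _three_sample_dataset(
            {"a": base, "b": base.copy(), "c": base + 1000.0}, [1, 2, 3]
        )
        dm = gene_distance_matrix(ds, "g", k=500)
        tri = upper_triangle(dm.matrix)  # (a,b), (a,c), (b,c)
        assert tri[0] == pytest.approx(0.0, abs=1e-9)
        assert tri[1] > 0.95 and tri[2] > 0.95

    def test_symmetric_zero_diagonal_for_all_metrics(self, small_simulation):
        ds = small_simulation.dataset
        dms = gene_distance_matrices(ds, ds.gene_ids[0], ("hellinger", "js", "ks"), k=200)
        for dm in dms.values():
            np.testing.assert_allclose(dm.matrix, dm.matrix.T)
            np.testing.assert_allclose(np.diag(dm.matrix), 0.0)
            assert np.all(dm.matrix >= 0)


class TestWorkflow:
    def test_constructed_monotone_gene_scores_near_one(self):
        # geometric per-sample spread: the sd ratio (hence the Hellinger
        # distance between the zero-mean normals) depends only on the age
        # gap, so the distance ranks should mirror the age-difference ranks
        rng = np.random.default_rng(3)
        values = {
            f"s{i}": rng.normal(0.0, 0.3 * 2.0**i, 2000) for i in range(6)
        }
        ds = _three_sample_dataset(values, ages=list(range(6)))
        tbl = run_workflow(ds, n_perm=100, seed=0, k=500)
        assert tbl.loc[0, "rho"] > 0.9
        assert tbl.loc[0, "mantel_p"] <= 0.02

    def test_same_seed_reproduces_table(self, small_simulation):
        ds = small_simulation.dataset
        t1 = run_workflow(ds, n_perm=30, seed=9, k=150)
        t2 = run_workflow(ds, n_perm=30, seed=9, k=150)
        pd.testing.assert_frame_equal(t1, t2)

    def test_single_metric_run_matches_multi_metric_run(self, small_simulation):
        ds = small_simulation.dataset
        multi = run_workflow_multi(ds, ("hellinger", "ks"), n_perm=30, seed=9, k=150)
        single = run_workflow(ds, "ks", n_perm=30, seed=9, k=150)
        pd.testing.assert_frame_equal(multi["ks"], single)

    def test_default_cutoff_classification(self):
        rng = np.random.default_rng(4)
        values = {f"s{i}": rng.normal(0.0, 0.1 + i, 400) for i in range(5)}
        ds = _three_sample_dataset(values, ages=list(range(5)))
        tbl = run_workflow(ds, n_perm=50, seed=0, k=300)
        assert bool(tbl.loc[0, "passed_cutoff"]) == (tbl.loc[0, "rho"] > 0.85)


class TestPseudobulk:
    def test_strictly_increasing_means_give_one(self):
        ds = _three_sample_dataset(
            {"a": np.array([1.0, 1.0]), "b": np.array([2.0, 2.0]),
             "c": np.array([3.0, 3.0])},
            [1, 2, 3],
        )
        tbl = pseudobulk_correlation(ds)
        assert tbl.loc[0, "rho"] == pytest.approx(1.0)

    def test_hand_ranked_case(self):
        ds = _three_sample_dataset(
            {"a": np.array([10.0]), "b": np.array([10.1]), "c": np.array([9.9])},
            [1, 2, 3],
        )
        assert pseudobulk_correlation(ds).loc[0, "rho"] == pytest.approx(-0.5)

    def test_constant_means_flagged(self):
        ds = _three_sample_dataset(
            {"a": np.array([5.0]), "b": np.array([5.0]), "c": np.array([5.0])},
            [1, 2, 3],
        )
        assert np.isnan(pseudobulk_correlation(ds).loc[0, "rho"])
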