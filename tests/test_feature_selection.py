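import itertools

import numpy as np
import pytest
from scipy import stats

from evoconn import (
    CohortSpec,
    EaConfig,
    FeatureSubset,
    aco_select,
    evaluate_fitness,
    ga_select,
    generate_feature_cohort,
    nsga2_select,
    pso_select,
    sa_select,
    ttest_select,
)
from evoconn.feature_selection import (
    FitnessCache,
    SaParams,
    fast_fitness_config,
    welch_t_statistics,
)


def counting_fitness(target):
    """Cheap surrogate fitness: overlap with a planted subset (in %)."""
    target = set(target)

    def fn(indices):
        return 100.0 * len(target & set(indices)) / max(len(target), 1)

    return fn


def toy_cfg(seed, iterations=25):
    return EaConfig(iterations=iterations, seed=seed, fitness=fast_fitness_config(seed))


class FakeTable:
    """Minimal stand-in exposing n_features/feature_names for fitness_fn runs."""

    def __init__(self, F):
        self.n_features = F
        self.feature_names = [f"f{i}" for i in range(F)]


# --------------------------------------------------------------------------
# fitness


class TestFitness:
    def test_perfectly_separating_feature_scores_100(self):
        rng = np.random.default_rng(0)
        spec = CohortSpec(n_group0=25, n_group1=25, n_features=5, n_informative=1, effect=20.0, seed=1)
        table, truth = generate_feature_cohort(spec)
        acc = evaluate_fitness(FeatureSubset(truth.informative_indices), table, fast_fitness_config(0))
        assert acc == 100.0

    def test_identical_query_identical_value(self):
        spec = CohortSpec(n_group0=15, n_group1=15, n_features=6, n_informative=1, effect=1.0, seed=2)
        table, _ = generate_feature_cohort(spec)
        cfg = fast_fitness_config(5)
        assert evaluate_fitness((0, 2), table, cfg) == evaluate_fitness((2, 0), table, cfg)

    def test_out_of_range_subset_errors(self):
        spec = CohortSpec(n_group0=15, n_group1=15, n_features=6, n_informative=1, seed=3)
        table, _ = generate_feature_cohort(spec)
        with pytest.raises(IndexError):
            evaluate_fitness((0, 99), table)

    def test_cache_counts_hits_and_misses(self):
        cache = FitnessCache(lambda idx: float(len(idx)))
        cache((1, 2))
        cache((2, 1))
        cache((3,))
        assert cache.misses == 2 and cache.hits == 1


# --------------------------------------------------------------------------
# Welch t baseline


class TestTtestSelect:
    def test_pvalues_match_closed_form_welch(self):
        rng = np.random.default_rng(4)
        spec = CohortSpec(n_group0=12, n_group1=17, n_features=8, n_informative=2, effect=1.0, seed=5)
        table, _ = generate_feature_cohort(spec)
        _, pvals = ttest_select(table, 3)
        g0 = table.data[table.labels == 0]
        g1 = table.data[table.labels == 1]
        for j in range(table.n_features):
            n0, n1 = len(g0), len(g1)
            v0, v1 = g0[:, j].var(ddof=1), g1[:, j].var(ddof=1)
            t = (g0[:, j].mean() - g1[:, j].mean()) / np.sqrt(v0 / n0 + v1 / n1)
            df = (v0 / n0 + v1 / n1) ** 2 / ((v0 / n0) ** 2 / (n0 - 1) + (v1 / n1) ** 2 / (n1 - 1))
            p = 2 * stats.t.sf(abs(t), df)
            assert pvals[j] == pytest.approx(p, abs=1e-10)

    def test_constant_feature_ranked_last(self):
        spec = CohortSpec(n_group0=10, n_group1=10, n_features=5, n_informative=1, effect=3.0, seed=6)
        table, _ = generate_feature_cohort(spec)
        table.data[:, 2] = 4.2  # identical in both groups
        subset, pvals = ttest_select(table, 4)
        assert 2 not in subset.indices
        assert pvals[2] == 1.0

    def test_planted_feature_ranked_first_with_power(self):
        hits = 0
        for seed in range(100):
            spec = CohortSpec(
                n_group0=70, n_group1=70, n_features=51, n_informative=1, effect=2.0, seed=seed
            )
            table, truth = generate_feature_cohort(spec)
            subset, _ = ttest_select(table, 1)
            hits += subset.indices == truth.informative_indices
        assert hits >= 95

    def test_column_order_invariance(self):
        spec = CohortSpec(n_group0=20, n_group1=20, n_features=7, n_informative=2, effect=1.5, seed=7)
        table, _ = generate_feature_cohort(spec)
        subset1, _ = ttest_select(table, 3)
        perm = np.array([3, 0, 6, 1, 5, 2, 4])
        table2_data = table.data[:, perm]
        from evoconn import FeatureTable

        table2 = FeatureTable(table2_data, [table.feature_names[i] for i in perm], table.labels)
        subset2, _ = ttest_select(table2, 3)
        # map back through the permutation
        assert sorted(perm[list(subset2.indices)]) == list(subset1.indices)


# --------------------------------------------------------------------------
# search mechanics (cheap surrogate fitness)


@pytest.mark.parametrize("selector", [ga_select, sa_select, pso_select, aco_select])
def test_fixed_cardinality_and_monotone_history(selector):
    F, k = 20, 4
    fn = counting_fitness({1, 5, 9, 13})
    res = selector(FakeTable(F), k, toy_cfg(seed=11, iterations=30), fitness_fn=fn)
    assert len(res.best_indices) == k
    assert len(set(res.best_indices)) == k
    assert all(0 <= i < F for i in res.best_indices)
    assert (np.diff(res.history) >= 0).all()


@pytest.mark.parametrize("selector", [ga_select, sa_select, pso_select, aco_select])
def test_bit_reproducible_given_seed(selector):
    fn = counting_fitness({2, 3})
    cfg = toy_cfg(seed=21, iterations=10)
    r1 = selector(FakeTable(10), 2, cfg, fitness_fn=fn)
    r2 = selector(FakeTable(10), 2, cfg, fitness_fn=fn)
    assert r1.to_json() == r2.to_json()


def test_k_larger_than_F_errors(planted_table):
    table, _ = planted_table
    for selector in (ga_select, sa_select, pso_select, aco_select):
        with pytest.raises(ValueError):
            selector(table, table.n_features + 1, toy_cfg(0))


def test_ga_full_cardinality_trivial(planted_table):
    table, _ = planted_table
    res = ga_select(table, table.n_features, toy_cfg(0))
    assert res.best_indices == tuple(range(table.n_features))
    assert res.evaluations == 1


def test_sa_zero_temperature_is_hill_climb():
    fn = counting_fitness({0, 1})
    calls = []

    def tracked(indices):
        f = fn(indices)
        calls.append((tuple(indices), f))
        return f

    cfg = toy_cfg(seed=31, iterations=60)
    cfg.sa = SaParams(t0=0.0, cooling=0.99)
    res = sa_select(FakeTable(8), 2, cfg, fitness_fn=tracked)
    # with T=0 the accepted chain never decreases: best == final current
    assert (np.diff(res.history) >= 0).all()
    assert res.best_fitness == 100.0 or res.best_fitness == max(f for _, f in calls)


def test_pso_single_particle_is_stationary():
    fn = counting_fitness({4})
    res = pso_select(FakeTable(9), 1, toy_cfg(seed=41, iterations=12), fitness_fn=fn)
    # one particle: pbest == gbest == position, velocity stays zero
    assert len(set(res.history)) == 1


def test_aco_pheromone_concentrates_on_informative():
    hits = 0
    for seed in range(10):
        fn = counting_fitness({3})
        cfg = toy_cfg(seed=seed, iterations=30)
        res = aco_select(FakeTable(8), 1, cfg, fitness_fn=fn, heuristic=np.ones(8))
        tau = np.array(res.config["pheromone"])
        hits += tau[3] > tau.mean()
    assert hits >= 9


def test_nsga2_single_feature_archive(planted_table):
    table, _ = planted_table
    from evoconn import FeatureTable

    single = FeatureTable(table.data[:, :1], table.feature_names[:1], table.labels)
    res = nsga2_select(single, 1, toy_cfg(seed=51, iterations=5))
    assert res.archive == [((0,), res.archive[0][1])]


def test_nsga2_archive_trades_cardinality_for_accuracy():
    # planted pair {0, 1} where accuracy saturates at both features
    def fn(indices):
        s = set(indices)
        return 60.0 + 20.0 * (0 in s) + 20.0 * (1 in s)

    res = nsga2_select(FakeTable(6), 3, toy_cfg(seed=61, iterations=40), fitness_fn=fn)
    by_k = {len(ind): fit for ind, fit in res.archive}
    assert 1 in by_k and 2 in by_k
    assert by_k[2] >= by_k[1]
    assert by_k[2] == 100.0
    # exhaustive check: no archived point is dominated by any subset of size <= 3
    for ind, fit in res.archive:
        for r in range(1, 4):
            for cand in itertools.combinations(range(6), r):
                if fn(cand) > fit and r <= len(ind):
                    raise AssertionError(f"{cand} dominates archived {ind}")


def test_search_recovers_planted_subset_with_real_fitness(planted_table):
    table, truth = planted_table
    res = ga_select(table, 2, toy_cfg(seed=71, iterations=20))
    # the planted pair is perfectly separable at effect 2: GA must reach
    # the exhaustive-optimum fitness of the true pair
    true_fit = evaluate_fitness(truth.informative_indices, table, toy_cfg(seed=71).fitness)
    assert res.best_fitness >= true_fit - 1e-9
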