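"""MCMC search: moves, initialization, collapsing, optimum recovery."""

import math

import numpy as np
import pytest

from longitree.inference import (
    InferenceConfig,
    InferenceConfigError,
    collapse_indistinguishable,
    initialize_tree,
    mcmc_search,
    propose_move,
)
from longitree.model import (
    LikelihoodEngine,
    MutationTree,
    NoiseModel,
    enumerate_rooted_trees,
    genotypes_from,
)
from longitree.simulate import simulate_tree

from conftest import make_matrix


def noise_free_matrix(tree, attachments, counts):
    D = genotypes_from(tree, np.asarray(attachments))
    return make_matrix(D.astype(float), counts, variants=list(tree.mutations))


class TestCollapse:
    def test_identical_columns_merged(self):
        m = make_matrix([[1, 1, 0], [0, 0, 1], [1, 1, 1]], {"T1": 3},
                        variants=["a", "b", "c"])
        out, groups = collapse_indistinguishable(m)
        assert out.variants == ["a", "c"]
        assert groups["a"] == ["a", "b"]
        assert groups["c"] == ["c"]

    def test_distinct_columns_identity(self):
        m = make_matrix([[1, 0], [0, 1]], {"T1": 2}, variants=["a", "b"])
        out, groups = collapse_indistinguishable(m)
        assert out.variants == ["a", "b"]
        assert all(len(g) == 1 for g in groups.values())

    def test_na_and_zero_not_merged(self):
        m = make_matrix([[1, 1], [0, np.nan]], {"T1": 2}, variants=["a", "b"])
        out, _ = collapse_indistinguishable(m)
        assert out.variants == ["a", "b"]

    def test_na_patterns_merge_when_identical(self):
        m = make_matrix([[1, 1], [np.nan, np.nan]], {"T1": 2},
                        variants=["a", "b"])
        out, groups = collapse_indistinguishable(m)
        assert out.variants == ["a"]
        assert groups["a"] == ["a", "b"]


class TestInitializeTree:
    def test_deterministic_chain_follows_frequency(self):
        m = make_matrix(
            [[1, 1, 0], [1, 1, 0], [1, 0, 0], [1, 0, 1], [1, 1, 0],
             [1, 0, 0], [1, 1, 0], [1, 0, 0], [1, 0, 0], [1, 1, 0]],
            {"T1": 10}, variants=["a", "b", "c"])
        # freqs: a=1.0, b=0.5, c=0.1 -> chain a -> b -> c
        t = initialize_tree(m, random_init=False)
        assert t.parent[0] == -1
        assert t.parent[1] == 0 and t.parent[2] == 1

    def test_random_init_reproducible(self):
        m = make_matrix(np.eye(4), {"T1": 4})
        t1 = initialize_tree(m, True, np.random.default_rng(5))
        t2 = initialize_tree(m, True, np.random.default_rng(5))
        assert t1.parent == t2.parent

    def test_random_init_covers_all_frequency_respecting_trees(self):
        vals = np.array(
            [[1, 1, 1]] * 1 + [[1, 1, 0]] * 4 + [[1, 0, 0]] * 5)
        m = make_matrix(vals, {"T1": 10}, variants=["a", "b", "c"])
        # order a > b > c: valid parents: b->a; c->a or c->b -> 2 trees
        seen = set()
        rng = np.random.default_rng(0)
        for _ in range(200):
            seen.add(initialize_tree(m, True, rng).parent)
        assert seen == {(-1, 0, 0), (-1, 0, 1)}

    def test_empty_matrix_errors(self):
        m = make_matrix(np.zeros((2, 0)), {"T1": 2}, variants=[])
        with pytest.raises(InferenceConfigError):
            initialize_tree(m)


class TestProposeMove:
    def test_moves_preserve_validity(self):
        rng = np.random.default_rng(1)
        tree = simulate_tree(6, rng)
        for _ in range(2000):
            tree = propose_move(tree, rng)  # constructor validates
        assert len(tree.parent) == 6

    def test_single_mutation_is_noop(self):
        t = MutationTree(("a",), (-1,))
        assert propose_move(t, np.random.default_rng(0)) is t

    def test_moves_are_reversible(self):
        """Every proposed neighbor can propose the original back."""
        rng = np.random.default_rng(3)
        tree = simulate_tree(4, rng)
        for _ in range(50):
            new = propose_move(tree, rng)
            found = False
            probe = np.random.default_rng(9)
            for _ in range(4000):
                if propose_move(new, probe).parent == tree.parent:
                    found = True
                    break
            assert found, (tree.parent, new.parent)
            tree = new


class TestMcmcSearch:
    def test_single_mutation_closed_form(self):
        m = make_matrix([[1.0], [0.0]], {"T1": 2}, variants=["a"])
        cfg = InferenceConfig(n_iterations=10, n_restarts=1, early_stopping=5,
                              alpha_grid=0.1, beta_grid=0.2, seed=0)
        res = mcmc_search(m, cfg)
        w = m.metadata.default_weights()["T1"]
        expected = w * (math.log(0.8) + math.log(0.2))  # true genotype is 1
        assert res.best_loglik == pytest.approx(expected, abs=1e-9)

    def test_recovers_exhaustive_optimum_m4(self):
        rng = np.random.default_rng(42)
        tree = simulate_tree(4, rng)
        att = rng.integers(0, 4, size=20)
        m = noise_free_matrix(tree, att, {"T1": 10, "T2": 10})
        noise = NoiseModel.uniform(m.metadata, 0.05, 0.1)
        engine = LikelihoodEngine(m, noise)
        best = max(
            engine.map_loglik(t.phylogenetic_matrix())
            for t in enumerate_rooted_trees(tree.mutations)
        )
        cfg = InferenceConfig(n_iterations=3000, n_restarts=3,
                              early_stopping=400, alpha_grid=0.05,
                              beta_grid=0.1, seed=7,
                              collapse_indistinguishable=False)
        res = mcmc_search(m, cfg)
        assert res.best_loglik == pytest.approx(best, abs=1e-9)

    def test_same_seed_identical_results(self):
        rng = np.random.default_rng(8)
        tree = simulate_tree(5, rng)
        att = rng.integers(0, 5, size=12)
        m = noise_free_matrix(tree, att, {"T1": 12})
        cfg = InferenceConfig(n_iterations=500, n_restarts=2,
                              early_stopping=100, alpha_grid=0.05,
                              beta_grid=0.1, seed=3)
        r1, r2 = mcmc_search(m, cfg), mcmc_search(m, cfg)
        assert r1.best_loglik == r2.best_loglik
        assert r1.best_tree.parent == r2.best_tree.parent
        assert (r1.best_attachments == r2.best_attachments).all()

    def test_parallel_matches_serial(self):
        rng = np.random.default_rng(8)
        tree = simulate_tree(4, rng)
        att = rng.integers(0, 4, size=10)
        m = noise_free_matrix(tree, att, {"T1": 10})
        base = dict(n_iterations=300, n_restarts=3, early_stopping=100,
                    alpha_grid=0.05, beta_grid=0.1, seed=5)
        serial = mcmc_search(m, InferenceConfig(**base, n_processes=1))
        parallel = mcmc_search(m, InferenceConfig(**base, n_processes=2))
        assert serial.best_loglik == parallel.best_loglik
        assert serial.best_tree.parent == parallel.best_tree.parent

    def test_rate_grid_selects_generating_rates(self):
        """With noisy data the grid should prefer rates near the truth."""
        from longitree.simulate import SimulationConfig, simulate_experiment

        tree = simulate_tree(4, 21)
        sim = simulate_experiment(tree, SimulationConfig(
            m=4, S=1, n_per_sample=(120,), alpha=0.02, beta=0.3,
            na_rate=0.0, seed=21))
        cfg = InferenceConfig(n_iterations=1500, n_restarts=2,
                              early_stopping=300,
                              alpha_grid=[0.02], beta_grid=[0.05, 0.3],
                              seed=2)
        res = mcmc_search(sim.G, cfg)
        assert res.best_rates["T1"][1] == pytest.approx(0.3)

    def test_best_loglik_bounds_trace(self):
        m = make_matrix(np.eye(4), {"T1": 4})
        cfg = InferenceConfig(n_iterations=400, n_restarts=3,
                              early_stopping=100, alpha_grid=0.05,
                              beta_grid=0.1, seed=1)
        res = mcmc_search(m, cfg)
        for chain in res.trace:
            values = [v for _it, v in chain]
            assert values == sorted(values)  # best-so-far is non-decreasing
            assert res.best_loglik >= values[-1] - 1e-12

    def test_keep_equivalent_returns_tied_trees(self):
        # two indistinguishable-by-likelihood labelings: cells all NA
        m = make_matrix([[np.nan, np.nan]] * 3, {"T1": 3}, variants=["a", "b"])
        cfg = InferenceConfig(n_iterations=200, n_restarts=2,
                              early_stopping=100, alpha_grid=0.1,
                              beta_grid=0.1, seed=0, keep_equivalent=True,
                              collapse_indistinguishable=False)
        res = mcmc_search(m, cfg)
        # both trees on 2 mutations score 0; the other one must be reported
        assert len(res.equivalent_trees) == 1
        assert res.equivalent_trees[0].parent != res.best_tree.parent

    def test_estimate_rates_moves_toward_truth(self):
        from longitree.simulate import SimulationConfig, simulate_experiment

        tree = simulate_tree(4, 31)
        sim = simulate_experiment(tree, SimulationConfig(
            m=4, S=1, n_per_sample=(150,), alpha=0.01, beta=0.35,
            na_rate=0.0, seed=31))
        cfg = InferenceConfig(n_iterations=4000, n_restarts=2,
                              early_stopping=4000,
                              alpha_grid=0.05, beta_grid=0.1,
                              estimate_rates=True, seed=11)
        res = mcmc_search(sim.G, cfg)
        start_beta = 0.1
        assert abs(res.best_rates["T1"][1] - 0.35) < abs(start_beta - 0.35)

    def test_empty_grid_is_config_error(self):
        m = make_matrix(np.eye(2), {"T1": 2})
        cfg = InferenceConfig(alpha_grid=[], beta_grid=0.1)
        with pytest.raises(InferenceConfigError):
            mcmc_search(m, cfg)

    def test_acceptance_temperature_direction(self):
        """Lower learning rate -> lower acceptance odds for downhill moves."""
        delta = -2.0
        probs = [math.exp(delta / lr) for lr in (0.1, 1.0, 10.0)]
        assert probs == sorted(probs)
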