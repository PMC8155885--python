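"""Binary bee-colony optimizer: update rule, phases, convergence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from implearn import (ABCConfig, FeatureSpace, FoodSource, ParameterError,
                      candidate, gen_feature_table, informative_bits,
                      init_sources, jaccard, make_cv_fitness, run_abc,
                      selection_probabilities)
from implearn.select import _CachedFitness, employed_phase, scout_phase


def ones_fraction_fitness(table):
    """Transparent surrogate: fraction of selected features."""
    per_feature = table.tau_max if table.reduce is None else 1
    return (table.X.shape[1] / per_feature) / table.space.d


def tiny_table(d=8, seed=0):
    channels = tuple(f"C{i}" for i in range(d))
    space = FeatureSpace(channels=channels, bands=("b",))
    return gen_feature_table(n_per_class=6, space=space,
                             informative_set=((channels[0], "b"),),
                             gap=0.3, noise_sd=0.3, tau_max=1, seed=seed)


class TestCandidate:
    def test_worked_example_candidate_set(self):
        """From current {0,1,1,0} and neighbor {0,1,0,1}, exactly four
        candidates are reachable: agreement bits fixed, the two
        disagreeing bits free."""
        current = np.array([0, 1, 1, 0], dtype=np.int8)
        neighbor = np.array([0, 1, 0, 1], dtype=np.int8)
        allowed = {(0, 1, 1, 1), (0, 1, 1, 0), (0, 1, 0, 1), (0, 1, 0, 0)}
        seen = set()
        rng = np.random.default_rng(0)
        for _ in range(400):
            seen.add(tuple(candidate(current, neighbor, rng)))
        assert seen == allowed

    def test_identical_vectors_unchanged(self):
        rng = np.random.default_rng(1)
        bits = np.array([1, 0, 1], dtype=np.int8)
        np.testing.assert_array_equal(candidate(bits, bits.copy(), rng), bits)

    def test_two_bit_disagreement_uniform(self):
        """All four 2-bit outcomes occur with equal frequency."""
        rng = np.random.default_rng(2)
        counts = {}
        n = 4000
        for _ in range(n):
            c = tuple(candidate(np.array([1, 0]), np.array([0, 1]), rng))
            counts[c] = counts.get(c, 0) + 1
        assert set(counts) == {(0, 0), (0, 1), (1, 0), (1, 1)}
        sigma = np.sqrt(n * 0.25 * 0.75)
        for v in counts.values():
            assert abs(v - n / 4) < 3 * sigma

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            candidate(np.array([1, 0]), np.array([1]), np.random.default_rng(0))

    @given(st.integers(0, 2**12 - 1), st.integers(0, 2**12 - 1),
           st.integers(0, 1000))
    @settings(max_examples=60, deadline=None)
    def test_agreeing_positions_never_change(self, a_int, b_int, seed):
        a = np.array([(a_int >> i) & 1 for i in range(12)], dtype=np.int8)
        b = np.array([(b_int >> i) & 1 for i in range(12)], dtype=np.int8)
        out = candidate(a, b, np.random.default_rng(seed))
        agree = a == b
        np.testing.assert_array_equal(out[agree], a[agree])


class TestProbabilities:
    @pytest.mark.parametrize("fitness,expected", [
        ([0.5, 0.5], [0.5, 0.5]),
        ([0.6, 0.3, 0.1], [0.6, 0.3, 0.1]),
    ])
    def test_normalization(self, fitness, expected):
        sources = [FoodSource(np.array([1]), f) for f in fitness]
        np.testing.assert_allclose(selection_probabilities(sources), expected)

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            sources = [FoodSource(np.array([1]), float(f))
                       for f in rng.random(5)]
            assert abs(selection_probabilities(sources).sum() - 1) < 1e-12

    def test_all_zero_fitness_uniform(self):
        sources = [FoodSource(np.array([1]), 0.0) for _ in range(4)]
        np.testing.assert_allclose(selection_probabilities(sources), 0.25)

    def test_single_source_always_selected(self):
        sources = [FoodSource(np.array([1]), 0.7)]
        np.testing.assert_allclose(selection_probabilities(sources), [1.0])

    def test_roulette_frequencies_track_fitness(self):
        """Onlooker visit frequencies follow the 0.9/0.1 fitness split."""
        sources = [FoodSource(np.array([1]), 0.9),
                   FoodSource(np.array([1]), 0.1)]
        probs = selection_probabilities(sources)
        rng = np.random.default_rng(3)
        n = 2000
        draws = rng.choice(2, size=n, p=probs)
        sigma = np.sqrt(n * 0.9 * 0.1)
        assert abs((draws == 0).sum() - 0.9 * n) < 3 * sigma


class TestPhases:
    def test_init_reproducible_and_nonzero(self):
        table = tiny_table(d=6)
        cfg = ABCConfig(n_sources=10, seed=4)
        ev = _CachedFitness(table, ones_fraction_fitness)
        a = init_sources(cfg, 6, np.random.default_rng(4), ev)
        b = init_sources(cfg, 6, np.random.default_rng(4), ev)
        assert all((s.bits == t.bits).all() for s, t in zip(a, b))
        assert all(s.bits.any() for s in a)

    def test_init_d1_always_single_one(self):
        table = tiny_table(d=1)
        ev = _CachedFitness(table, ones_fraction_fitness)
        sources = init_sources(ABCConfig(n_sources=5, seed=0), 1,
                               np.random.default_rng(0), ev)
        assert all(s.bits.tolist() == [1] for s in sources)

    def test_different_seeds_differ(self):
        table = tiny_table(d=12)
        ev = _CachedFitness(table, ones_fraction_fitness)
        cfg = ABCConfig(n_sources=10)
        diffs = 0
        for seed in range(10):
            a = init_sources(cfg, 12, np.random.default_rng(seed), ev)
            b = init_sources(cfg, 12, np.random.default_rng(seed + 1000), ev)
            if any((s.bits != t.bits).any() for s, t in zip(a, b)):
                diffs += 1
        assert diffs == 10

    def test_employed_strict_greedy_and_abandon(self):
        """A tie never replaces; failures increment the counter;
        an improvement resets it."""
        table = tiny_table(d=4)
        ev = _CachedFitness(table, ones_fraction_fitness)
        low = FoodSource(np.array([1, 0, 0, 0], dtype=np.int8), 0.25)
        high = FoodSource(np.array([1, 1, 1, 1], dtype=np.int8), 1.0)
        sources = [low, high]
        employed_phase(sources, np.random.default_rng(0), ev)
        # the all-ones source can only draw candidates <= its own fitness
        assert high.fitness == 1.0
        assert high.abandon_count in (0, 1)
        if high.abandon_count == 1:
            np.testing.assert_array_equal(high.bits, [1, 1, 1, 1])

    def test_scout_threshold_strictly_greater(self):
        table = tiny_table(d=4)
        ev = _CachedFitness(table, ones_fraction_fitness)
        cfg = ABCConfig(n_sources=2, limit=3)
        at_limit = FoodSource(np.array([1, 0, 0, 0], dtype=np.int8), 0.25,
                              abandon_count=3)
        over = FoodSource(np.array([0, 1, 0, 0], dtype=np.int8), 0.25,
                          abandon_count=4)
        scout_phase([at_limit, over], cfg, np.random.default_rng(0), ev)
        np.testing.assert_array_equal(at_limit.bits, [1, 0, 0, 0])
        assert at_limit.abandon_count == 3
        assert over.abandon_count == 0


class TestRunAbc:
    def test_max_iter_zero_returns_best_initial(self):
        table = tiny_table(d=6)
        cfg = ABCConfig(n_sources=8, max_iter=0, seed=1)
        trace = run_abc(table, cfg, ones_fraction_fitness)
        assert trace.curve == []
        assert 0 < trace.best_fitness <= 1.0

    def test_reaches_known_optimum_on_count_ones(self):
        """With ones-counting fitness the exhaustive optimum (all ones)
        is reached within 50 iterations in nearly every run."""
        hits = 0
        for seed in range(20):
            table = tiny_table(d=10, seed=seed)
            cfg = ABCConfig(n_sources=10, limit=5, max_iter=50, seed=seed)
            trace = run_abc(table, cfg, ones_fraction_fitness)
            hits += trace.best_fitness == 1.0
        assert hits >= 19

    def test_best_so_far_curve_non_decreasing(self):
        for seed in range(5):
            table = tiny_table(d=8, seed=seed)
            cfg = ABCConfig(n_sources=6, limit=3, max_iter=20, seed=seed)
            trace = run_abc(table, cfg, ones_fraction_fitness)
            assert all(a <= b + 1e-15 for a, b in zip(trace.curve,
                                                      trace.curve[1:]))

    def test_deterministic_given_seed(self, small_planted_table):
        cfg = ABCConfig(n_sources=6, limit=3, max_iter=5, seed=9)
        fit = make_cv_fitness("knn-coarse", seed=9)
        a = run_abc(small_planted_table, cfg, fit)
        b = run_abc(small_planted_table, cfg, fit)
        np.testing.assert_array_equal(a.best_bits, b.best_bits)
        assert a.curve == b.curve

    def test_single_class_table_rejected(self):
        table = tiny_table(d=4)
        one_class = table.__class__(X=table.X[table.y == "fast"],
                                    y=table.y[table.y == "fast"],
                                    space=table.space, tau_max=table.tau_max)
        with pytest.raises(ParameterError):
            run_abc(one_class, ABCConfig(), ones_fraction_fitness)

    def test_recovers_planted_subset(self, small_space, small_informative,
                                     small_informative_bits):
        """Selection concentrates on the informative features in most
        seeded runs (planted-subset recovery)."""
        hits = 0
        for seed in range(20):
            table = gen_feature_table(n_per_class=60, space=small_space,
                                      informative_set=small_informative,
                                      gap=0.3, noise_sd=0.6, tau_max=10,
                                      seed=seed)
            cfg = ABCConfig(n_sources=10, limit=5, max_iter=30, seed=seed)
            trace = run_abc(table, cfg, make_cv_fitness("knn-coarse", seed=seed))
            hits += jaccard(trace.best_bits, small_informative_bits) >= 0.5
        assert hits >= 16

    def test_selection_beats_all_features_on_planted_table(
            self, small_planted_table, small_informative_bits):
        """The selected subset's CV accuracy is at least the all-features
        accuracy on the same folds, in the median over runs."""
        from implearn import cv_accuracy, mask_features
        diffs = []
        for seed in range(5):
            cfg = ABCConfig(n_sources=8, limit=4, max_iter=10, seed=seed)
            fit = make_cv_fitness("knn-coarse", seed=seed)
            trace = run_abc(small_planted_table, cfg, fit)
            sel = cv_accuracy(mask_features(small_planted_table,
                                            trace.best_bits),
                              "knn-coarse", seed=seed)
            allf = cv_accuracy(small_planted_table, "knn-coarse", seed=seed)
            diffs.append(sel - allf)
        assert np.median(diffs) >= 0.0
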