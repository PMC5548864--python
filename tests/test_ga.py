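"""GA operators and the IBCGA loop."""

import itertools

import numpy as np
import pytest

from survsig import (Chromosome, GAConfig, SimulationSpec, decode_hyper,
                     kfold_indices, mutate, oa_crossover, repair, run_ibcga,
                     simulate_cohort)
from survsig.errors import ConfigError, SchemaError
from survsig.ga import _FitnessCache


class TestDecodeHyper:
    @pytest.mark.parametrize("genes, gamma, C, nu", [
        ((15, 15, 15), 1.0, 1024.0, 1.0),
        ((0, 0, 0), 2.0 ** -15, 2.0 ** -5, 1 / 16),
        ((8, 5, 7), 2.0 ** -7, 1.0, 0.5),
    ])
    def test_grid_points(self, genes, gamma, C, nu):
        h = decode_hyper(genes)
        assert (h.gamma, h.C, h.nu) == (gamma, C, nu)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            decode_hyper((16, 0, 0))


class TestRepair:
    def test_noop_when_satisfied(self):
        bits = np.array([1, 0, 1, 0], dtype=np.uint8)
        out = repair(bits, 2, np.random.default_rng(0))
        np.testing.assert_array_equal(out, bits)

    def test_excess_keeps_two_original_ones(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            out = repair(np.array([1, 1, 1, 0], dtype=np.uint8), 2, rng)
            assert out.sum() == 2
            assert out[3] == 0  # never invents a new 1 when dropping

    def test_deficit_draws_uniformly(self):
        rng = np.random.default_rng(2)
        counts = {}
        for _ in range(1000):
            out = repair(np.zeros(4, dtype=np.uint8), 2, rng)
            counts[tuple(out)] = counts.get(tuple(out), 0) + 1
        assert len(counts) == 6  # all C(4,2) patterns reached
        from scipy.stats import chisquare
        assert chisquare(list(counts.values())).pvalue > 1e-3

    def test_impossible_target(self):
        with pytest.raises(ConfigError):
            repair(np.zeros(3, dtype=np.uint8), 5, np.random.default_rng(0))


class TestMutate:
    def test_popcount_preserved(self):
        rng = np.random.default_rng(3)
        c = Chromosome(np.array([1, 1, 0, 0, 0], dtype=np.uint8), (3, 4, 5))
        for _ in range(100):
            c = mutate(c, rng)
            assert c.popcount == 2

    def test_saturated_bits_untouched(self):
        rng = np.random.default_rng(4)
        c = Chromosome(np.ones(4, dtype=np.uint8), (0, 0, 0))
        out = mutate(c, rng)
        np.testing.assert_array_equal(out.feature_bits, 1)

    def test_reaches_every_subset(self):
        rng = np.random.default_rng(5)
        c = Chromosome(np.array([1, 1, 0, 0], dtype=np.uint8), (0, 0, 0))
        seen = set()
        for _ in range(200):
            c = mutate(c, rng)
            seen.add(tuple(c.feature_bits))
        assert len(seen) == 6  # all of C(4,2)


def _chrom(bits, genes=(0, 0, 0)):
    return Chromosome(np.asarray(bits, dtype=np.uint8), tuple(genes))


class TestOACrossover:
    def test_identical_parents_need_no_evaluation(self):
        calls = []
        a = _chrom([1, 0, 1, 0])
        child = oa_crossover(a, _chrom([1, 0, 1, 0]), lambda c: calls.append(1) or 0.0,
                             np.random.default_rng(0))
        assert not calls
        np.testing.assert_array_equal(child.feature_bits, a.feature_bits)

    def test_popcount_mismatch_rejected(self):
        with pytest.raises(SchemaError):
            oa_crossover(_chrom([1, 0]), _chrom([1, 1]),
                         lambda c: 0.0, np.random.default_rng(0))

    def test_single_factor_picks_the_fitter_variant(self):
        # all differing positions grouped into one factor: the only two
        # candidates are the parents themselves, and the fitter one wins
        a, b = _chrom([1, 0, 0, 1]), _chrom([0, 1, 0, 1])

        def fitness(c):
            return float(c.feature_bits[1])  # b's variant wins

        child = oa_crossover(a, b, fitness, np.random.default_rng(0), max_factors=1)
        np.testing.assert_array_equal(child.feature_bits, b.feature_bits)

    @pytest.mark.parametrize("seed", range(20))
    def test_separable_fitness_recovers_global_best_composite(self, seed):
        """With additive per-factor scores the child must equal the argmax
        over all 2^k factor combinations (brute force)."""
        rng = np.random.default_rng(seed)
        n = 12
        a_bits = rng.integers(0, 2, size=n).astype(np.uint8)
        diff = rng.choice(n, size=rng.integers(2, 9), replace=False)
        b_bits = a_bits.copy()
        b_bits[diff] ^= 1
        # force equal popcount by pairing flips: regenerate until balanced
        while a_bits.sum() != b_bits.sum():
            b_bits = a_bits.copy()
            diff = rng.choice(n, size=2 * rng.integers(1, 5), replace=False)
            b_bits[diff] ^= 1
        a, b = _chrom(a_bits), _chrom(b_bits)

        weights = rng.normal(size=n)

        def fitness(c):
            return float(weights @ c.feature_bits)

        k = min(len(np.flatnonzero(a_bits != b_bits)), 4)
        child = oa_crossover(a, b, fitness, np.random.default_rng(0),
                             target_popcount=None, max_factors=k)

        # brute force over all level assignments of the same contiguous factors
        positions = np.flatnonzero(a_bits != b_bits)
        groups = [g for g in np.array_split(positions, k) if len(g)]
        best = None
        for levels in itertools.product((1, 2), repeat=len(groups)):
            cand = a_bits.copy()
            for g, lv in zip(groups, levels):
                if lv == 2:
                    cand[g] = b_bits[g]
            if best is None or fitness(_chrom(cand)) > fitness(_chrom(best)):
                best = cand
        assert fitness(child) == pytest.approx(fitness(_chrom(best)))


@pytest.fixture(scope="module")
def small_cohort():
    cohort, planted = simulate_cohort(
        SimulationSpec(M=60, n=12, s=3, beta=(8, 6, 5), noise_sd=2, seed=21))
    return cohort, planted


class TestRunIbcga:
    CFG = GAConfig(n_pop=10, p_c=0.8, p_m=0.1, g_max=5, r_start=2, r_end=4,
                   cv_seed=3, ga_seed=17)

    def test_deterministic(self, small_cohort):
        cohort, _ = small_cohort
        s1 = run_ibcga(cohort, self.CFG)
        s2 = run_ibcga(cohort, self.CFG)
        assert s1.selected_features == s2.selected_features
        assert s1.fitness == s2.fitness
        assert s1.per_r_trace == s2.per_r_trace

    def test_elitism_makes_fitness_monotone_within_each_size(self, small_cohort):
        cohort, _ = small_cohort
        sig = run_ibcga(cohort, self.CFG)
        for r, trace in sig.generation_trace.items():
            assert all(b >= a - 1e-12 for a, b in zip(trace, trace[1:]))

    def test_signature_size_within_sweep_bounds(self, small_cohort):
        cohort, _ = small_cohort
        sig = run_ibcga(cohort, self.CFG)
        assert self.CFG.r_start <= sig.m <= self.CFG.r_end
        assert set(sig.per_r_trace) == {2, 3, 4}

    def test_full_feature_set_when_sweep_is_saturated(self, small_cohort):
        cohort, _ = small_cohort
        cfg = GAConfig(n_pop=6, p_c=0.5, p_m=0.2, g_max=3, r_start=12, r_end=12,
                       cv_seed=3, ga_seed=1)
        sig = run_ibcga(cohort, cfg)
        assert sorted(sig.selected_features) == sorted(cohort.feature_names)

    def test_r_end_beyond_feature_count_rejected(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ConfigError):
            run_ibcga(cohort, GAConfig(r_start=2, r_end=50))

    def test_fitness_cache_prevents_duplicate_cv(self, small_cohort):
        cohort, _ = small_cohort
        folds = kfold_indices(cohort.M, 10, 0)
        cache = _FitnessCache(cohort, folds)
        c = _chrom([1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0], genes=(8, 5, 7))
        f1 = cache(c)
        f2 = cache(c.copy())
        assert f1 == f2
        assert cache.evaluations == 1
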