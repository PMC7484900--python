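import math

import numpy as np
import pytest

from restid.nsga3 import (Chromosome, Encoding, GeneSpec, TerminationRule,
                          VariationRates, evolve, generate_reference_points,
                          hypervolume_3d, niching_select, non_dominated_sort,
                          normalize_and_associate, random_chromosome,
                          select_next_population, vary)

from _oracles import brute_force_fronts, dtlz1


class TestReferencePoints:
    def test_single_division_gives_simplex_apexes(self):
        pts = generate_reference_points(3, 1).points
        assert sorted(map(tuple, pts)) == [(0, 0, 1), (0, 1, 0), (1, 0, 0)]

    def test_five_divisions_give_21_points(self):
        assert len(generate_reference_points(3, 5).points) == 21

    @pytest.mark.parametrize("m,p", [(2, 4), (3, 5), (3, 12), (4, 6)])
    def test_count_rows_and_uniqueness(self, m, p):
        pts = generate_reference_points(m, p).points
        assert len(pts) == math.comb(m + p - 1, p)
        np.testing.assert_allclose(pts.sum(axis=1), 1.0, atol=1e-12)
        assert len({tuple(row) for row in pts}) == len(pts)
        assert np.all(pts >= 0)


class TestNonDominatedSort:
    def test_single_point_single_front(self):
        assert non_dominated_sort([np.array([1.0, 2.0, 3.0])]) == [[0]]

    def test_dominance_chain_gives_singleton_fronts(self):
        objs = [np.full(3, v) for v in (1.0, 2.0, 3.0)]
        assert non_dominated_sort(objs) == [[0], [1], [2]]

    def test_empty_input_gives_empty_fronts(self):
        assert non_dominated_sort([]) == []

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 51))
            objs = rng.integers(0, 6, size=(n, 3)).astype(float)  # force ties
            got = [sorted(f) for f in non_dominated_sort(objs)]
            assert got == brute_force_fronts(objs)

    def test_fronts_partition_the_input(self, rng):
        objs = rng.normal(size=(40, 3))
        fronts = non_dominated_sort(objs)
        flat = sorted(i for f in fronts for i in f)
        assert flat == list(range(40))


class TestNormalizeAndAssociate:
    def test_member_on_reference_line_has_zero_distance(self):
        refs = generate_reference_points(3, 1).points
        objs = np.array([[0.5, 0.0, 0.0],    # on the f1 axis line
                         [0.2, 0.9, 0.3],
                         [0.1, 0.2, 0.8]])
        assoc, dist, _ = normalize_and_associate(objs, refs)
        on_axis = int(np.argmax(refs[assoc[0]]))
        assert on_axis == 0
        assert dist[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_point_two_line_toy_matches_hand_projection(self):
        # after ideal translation the points are (0,4) and (3,0); with
        # intercepts (3,4) they normalize to (0,1) and (1,0): each sits on
        # one of the two axis reference lines.
        refs = np.array([[1.0, 0.0], [0.0, 1.0]])
        objs = np.array([[1.0, 5.0], [4.0, 1.0]])
        assoc, dist, norm = normalize_and_associate(objs, refs)
        assert list(assoc) == [1, 0]
        np.testing.assert_allclose(dist, 0.0, atol=1e-12)
        np.testing.assert_allclose(norm, [[0.0, 1.0], [1.0, 0.0]], atol=1e-12)

    def test_translation_invariance(self, rng):
        refs = generate_reference_points(3, 3).points
        objs = rng.uniform(size=(15, 3))
        assoc_a, dist_a, _ = normalize_and_associate(objs, refs)
        assoc_b, dist_b, _ = normalize_and_associate(objs + 7.25, refs)
        np.testing.assert_array_equal(assoc_a, assoc_b)
        np.testing.assert_allclose(dist_a, dist_b, atol=1e-9)

    def test_identical_objectives_fall_back_gracefully(self):
        refs = generate_reference_points(3, 2).points
        objs = np.tile([1.0, 2.0, 3.0], (5, 1))
        assoc, dist, _ = normalize_and_associate(objs, refs)
        assert np.all(np.isfinite(dist))


class TestNiching:
    def test_zero_slots_selects_nothing(self, rng):
        assert niching_select([0, 1], {0: 0, 1: 1}, {0: 0.1, 1: 0.2},
                              np.zeros(2, dtype=int), 0, rng) == []

    def test_more_slots_than_front_rejected(self, rng):
        with pytest.raises(ValueError):
            niching_select([0], {0: 0}, {0: 0.1}, np.zeros(1, dtype=int), 2, rng)

    def test_empty_niches_take_their_closest_member(self, rng):
        """Hand trace: rho all zero, one member per niche -> nearest each."""
        front = [10, 11, 12]
        assoc = {10: 0, 11: 1, 12: 2}
        dist = {10: 0.3, 11: 0.1, 12: 0.2}
        rho = np.zeros(3, dtype=int)
        chosen = niching_select(front, assoc, dist, rho, 3, rng)
        assert sorted(chosen) == front
        assert rho.tolist() == [1, 1, 1]

    def test_niche_without_front_members_is_excluded(self, rng):
        # niche 0 is empty (rho=0) but nothing in the front maps to it: the
        # selection must come from niche 1 and never stall.
        front = [5, 6]
        assoc = {5: 1, 6: 1}
        dist = {5: 0.4, 6: 0.2}
        rho = np.zeros(2, dtype=int)
        chosen = niching_select(front, assoc, dist, rho, 2, rng)
        assert sorted(chosen) == [5, 6]
        assert rho[0] == 0

    def test_occupied_min_niche_picks_among_associated(self, rng):
        front = [1, 2, 3]
        assoc = {1: 0, 2: 0, 3: 1}
        dist = {1: 0.9, 2: 0.1, 3: 0.5}
        rho = np.array([1, 5])
        chosen = niching_select(front, assoc, dist, rho, 1, rng)
        assert chosen[0] in (1, 2)  # random among niche-0 members


class TestSurvivorSelection:
    def test_whole_fronts_admitted_intact(self, rng):
        """Front-1 members that fit within N all survive (elitism)."""
        refs = generate_reference_points(3, 3).points
        for _ in range(20):
            objs = rng.uniform(size=(40, 3))
            chosen = select_next_population(objs, 20, refs, rng)
            assert len(chosen) == 20
            assert len(set(chosen)) == 20
            front1 = set(non_dominated_sort(objs)[0])
            if len(front1) <= 20:
                assert front1 <= set(chosen)


class TestVariation:
    @staticmethod
    def _encoding():
        return Encoding(n_bits=8, genes=(GeneSpec("int", 1, 3),
                                         GeneSpec("real", 0.0, 1.0)))

    def test_zero_rates_copy_selected_parents(self, rng):
        enc = self._encoding()
        parents = [random_chromosome(enc, rng) for _ in range(6)]
        rates = VariationRates(bit_crossover_prob=0.0, bit_flip_prob=0.0,
                               int_mutation_prob=0.0, real_crossover_prob=0.0,
                               real_mutation_prob=0.0)
        keys = {p.key() for p in parents}
        offspring = vary(parents, [0] * 6, [0.0] * 6, enc, rng, rates)
        assert all(child.key() in keys for child in offspring)

    def test_all_zero_mask_repaired_with_single_bit(self, rng):
        enc = self._encoding()
        parents = [Chromosome(bits=np.zeros(8, dtype=np.uint8), genes=[1.0, 0.5])
                   for _ in range(4)]
        rates = VariationRates(bit_crossover_prob=0.0, bit_flip_prob=0.0,
                               int_mutation_prob=0.0, real_crossover_prob=0.0,
                               real_mutation_prob=0.0)
        offspring = vary(parents, [0] * 4, [0.0] * 4, enc, rng, rates)
        assert all(child.bits.sum() == 1 for child in offspring)

    def test_fixed_seed_reproduces_offspring_bitwise(self):
        enc = self._encoding()
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            parents = [random_chromosome(enc, rng) for _ in range(6)]
            off = vary(parents, [0, 0, 1, 1, 2, 2], [0.1] * 6, enc, rng)
            runs.append([c.key() for c in off])
        assert runs[0] == runs[1]

    def test_genes_stay_in_range(self, rng):
        enc = self._encoding()
        parents = [random_chromosome(enc, rng) for _ in range(10)]
        for _ in range(20):
            parents = vary(parents, [0] * 10, [0.0] * 10, enc, rng)
            for c in parents:
                assert c.genes[0] in (1.0, 2.0, 3.0)
                assert 0.0 <= c.genes[1] <= 1.0


class TestTermination:
    def test_identical_fronts_at_consecutive_checks_stop(self):
        rule = TerminationRule(tol=1e-4, period=10, max_gen=300)
        front = np.array([[1.0, 2.0, 3.0]])
        assert not rule.check(0, front)
        assert rule.check(10, front)

    def test_no_tolerance_stop_off_period(self):
        rule = TerminationRule(tol=1e-4, period=10, max_gen=300)
        front = np.array([[1.0, 2.0, 3.0]])
        rule.check(0, front)
        for gen in range(1, 10):
            assert not rule.check(gen, front)

    def test_max_generations_stop_regardless_of_tolerance(self):
        rule = TerminationRule(tol=0.0, period=10, max_gen=300)
        moving = np.array([[1.0, 1.0, 1.0]])
        assert rule.check(300, moving + 99)

    def test_moving_front_keeps_running(self):
        rule = TerminationRule(tol=1e-4, period=10, max_gen=300)
        rule.check(0, np.array([[1.0, 1.0, 1.0]]))
        assert not rule.check(10, np.array([[0.5, 1.0, 1.0]]))


class TestEvolve:
    @staticmethod
    def _dtlz1_encoding():
        return Encoding(n_bits=0,
                        genes=tuple(GeneSpec("real", 0.0, 1.0) for _ in range(7)))

    def test_constant_fitness_terminates_at_first_tolerance_check(self):
        enc = Encoding(n_bits=4, genes=())
        result = evolve(lambda c: (1.0, 2.0, 3.0), enc, population_size=8,
                        rng=0, termination=TerminationRule(period=10,
                                                           max_gen=300))
        assert result.n_generations == 10

    def test_same_seed_reproduces_front_bitwise(self):
        fronts = []
        for _ in range(2):
            result = evolve(lambda c: dtlz1(c.genes), self._dtlz1_encoding(),
                            population_size=12, rng=5,
                            termination=TerminationRule(max_gen=15, tol=0.0))
            fronts.append((result.front_objectives.tolist(),
                           [c.key() for c in result.front]))
        assert fronts[0] == fronts[1]

    def test_dtlz1_hypervolume_improves(self):
        """Archive hypervolume is monotone; the population front can dip by a
        hair when niching swaps boundary members, but must trend upward."""
        result = evolve(lambda c: dtlz1(c.genes), self._dtlz1_encoding(),
                        population_size=20, rng=3,
                        termination=TerminationRule(max_gen=40, tol=0.0))
        ref = (600.0, 600.0, 600.0)
        front_hv, archive_hv = [], []
        seen = []
        for rec in result.history:
            objs = np.array(rec["objectives"])
            front_hv.append(hypervolume_3d(objs[rec["front_indices"]], ref))
            seen.append(objs)
            archive_hv.append(hypervolume_3d(np.vstack(seen), ref))
        archive_hv = np.array(archive_hv)
        front_hv = np.array(front_hv)
        assert np.all(np.diff(archive_hv) >= 0)
        assert np.all(np.diff(front_hv) >= -1e-3 * front_hv[:-1])
        assert front_hv[-1] > front_hv[0]

    def test_failing_fitness_reports_chromosome_context(self):
        def bad(_):
            raise RuntimeError("boom")
        with pytest.raises(RuntimeError, match="chromosome"):
            evolve(bad, Encoding(n_bits=4), population_size=4, rng=0)

    def test_population_size_is_constant(self):
        result = evolve(lambda c: dtlz1(c.genes), self._dtlz1_encoding(),
                        population_size=10, rng=1,
                        termination=TerminationRule(max_gen=12, tol=0.0))
        for rec in result.history:
            assert len(rec["objectives"]) == 10


class TestHypervolume:
    def test_single_point_box(self):
        assert hypervolume_3d(np.array([[1.0, 1.0, 1.0]]),
                              (2.0, 2.0, 2.0)) == pytest.approx(1.0)

    def test_matches_inclusion_exclusion_on_two_points(self):
        a, b = np.array([0.0, 1.0, 0.0]), np.array([1.0, 0.0, 1.0])
        ref = np.array([2.0, 2.0, 2.0])
        va = np.prod(ref - a)
        vb = np.prod(ref - b)
        vab = np.prod(ref - np.maximum(a, b))
        assert hypervolume_3d(np.vstack([a, b]), ref) == pytest.approx(
            va + vb - vab)

    def test_dominated_points_add_nothing(self, rng):
        pts = rng.uniform(0, 1, (10, 3))
        ref = (2.0, 2.0, 2.0)
        shadow = pts + 0.5  # dominated copies
        assert hypervolume_3d(np.vstack([pts, shadow]), ref) == pytest.approx(
            hypervolume_3d(pts, ref))
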