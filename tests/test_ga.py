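"""GA operators against brute-force oracles, and surrogate-backed runs."""

import itertools

import numpy as np
import pytest

from defibopt.ga import (
    GAHyperparams,
    PopulationEntry,
    SurrogateBackend,
    accept,
    classify_convergence,
    crossover,
    init_population,
    mutate,
    percentile_ranks,
    replace_worst,
    run_ga,
)
from defibopt.pacing import PacingProtocol, pacing_cost

HP = GAHyperparams(
    population_size=8,
    n_generations=50,
    amp_range=(0.0, 2.0),
    interval_range=(20.0, 140.0),
    seed=0,
)


def _proto(rng, hp=HP):
    return PacingProtocol(
        tuple(rng.uniform(*hp.amp_range, hp.n_pulses)),
        tuple(rng.uniform(*hp.interval_range, hp.n_pulses - 1)),
    )


class TestMutate:
    def test_changes_exactly_one_coordinate_within_its_interval(self, rng):
        base = _proto(rng)
        for _ in range(50):
            out = mutate(base, HP, rng)
            diff = out.as_vector() != base.as_vector()
            assert diff.sum() == 1
            k = int(np.argmax(diff))
            lo, hi = HP.amp_range if k < 5 else HP.interval_range
            assert lo <= out.as_vector()[k] <= hi

    def test_original_protocol_untouched(self, rng):
        base = _proto(rng)
        vec0 = base.as_vector().copy()
        mutate(base, HP, rng)
        assert np.array_equal(base.as_vector(), vec0)

    def test_coordinate_selection_is_uniform(self, rng):
        base = _proto(rng)
        n_draws = 10_000
        counts = np.zeros(9)
        for _ in range(n_draws):
            out = mutate(base, HP, rng)
            counts[np.argmax(out.as_vector() != base.as_vector())] += 1
        p = 1 / 9
        sigma = np.sqrt(n_draws * p * (1 - p))
        assert np.all(np.abs(counts - n_draws * p) < 3 * sigma + 1)


class TestCrossover:
    def test_self_cross_is_identity(self, rng):
        p = _proto(rng)
        c1, c2 = crossover(p, p, rng)
        assert c1 == p and c2 == p

    def test_children_are_valid_recombinations_only(self, rng):
        p1, p2 = _proto(rng), _proto(rng)
        allowed = set()
        for k in range(1, 5):
            allowed.add((p1.amplitudes[:k] + p2.amplitudes[k:],
                         p1.intervals[:k] + p2.intervals[k:]))
            allowed.add((p2.amplitudes[:k] + p1.amplitudes[k:],
                         p2.intervals[:k] + p1.intervals[k:]))
        assert len(allowed) == 2 * 4
        for _ in range(200):
            c1, c2 = crossover(p1, p2, rng)
            assert (c1.amplitudes, c1.intervals) in allowed
            assert (c2.amplitudes, c2.intervals) in allowed

    def test_cut_at_third_pulse_splits_as_sketched(self, rng):
        p1 = PacingProtocol((1, 2, 3, 4, 5), (10, 20, 30, 40), pulse_len=2.0)
        p2 = PacingProtocol((6, 7, 8, 9, 10), (50, 60, 70, 80), pulse_len=2.0)
        for _ in range(100):
            c1, c2 = crossover(p1, p2, rng)
            if c1.amplitudes[2] == 3 and c1.amplitudes[3] == 9:
                # leading pulses from parent 1, tail from parent 2,
                # bridging interval travels with the leading segment
                assert c1.amplitudes == (1, 2, 3, 9, 10)
                assert c1.intervals == (10, 20, 30, 80)
                assert c2.amplitudes == (6, 7, 8, 4, 5)
                assert c2.intervals == (50, 60, 70, 40)
                break
        else:
            pytest.fail("cut at pulse 3 never drawn in 100 seeded trials")

    def test_mismatched_pulse_counts_rejected(self, rng):
        with pytest.raises(ValueError, match="same pulse count"):
            crossover(
                PacingProtocol((1, 1), (50,)),
                PacingProtocol((1, 1, 1), (50, 50)),
                rng,
            )


def _entries(metrics):
    return [
        PopulationEntry(PacingProtocol((1.0,), ()), pc, tr)
        for pc, tr in metrics
    ]


class TestSelection:
    def test_ranks_match_counting_example(self):
        pop = _entries([(1, 0.5), (2, 0.5), (3, 0.5), (4, 0.5)])
        r_pc, _ = percentile_ranks(pop, pc=2.5, tr=0.5)
        assert r_pc == 0.5

    def test_candidate_beating_all_gets_full_ranks(self):
        pop = _entries([(2, 0.2), (3, 0.3), (4, 0.1)])
        assert percentile_ranks(pop, pc=1.0, tr=0.9) == (1.0, 1.0)

    def test_all_tied_gives_half_ranks(self):
        pop = _entries([(2, 0.5)] * 6)
        assert percentile_ranks(pop, pc=2.0, tr=0.5) == (0.5, 0.5)

    def test_ranks_agree_with_bruteforce_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 30))
            pcs = rng.integers(0, 6, n).astype(float)
            trs = rng.integers(0, 6, n) / 5.0
            pop = _entries(list(zip(pcs, trs)))
            pc_c = float(rng.integers(0, 6))
            tr_c = float(rng.integers(0, 6)) / 5.0
            r_pc, r_tr = percentile_ranks(pop, pc_c, tr_c)
            oracle_pc = (sum(p > pc_c for p in pcs) + 0.5 * sum(p == pc_c for p in pcs)) / n
            oracle_tr = (sum(t < tr_c for t in trs) + 0.5 * sum(t == tr_c for t in trs)) / n
            assert r_pc == pytest.approx(oracle_pc)
            assert r_tr == pytest.approx(oracle_tr)

    @pytest.mark.parametrize(
        "ranks, expected",
        [((0.6, 0.6), True), ((0.6, 0.4), False), ((0.4, 0.6), False)],
    )
    def test_acceptance_is_conjunction(self, ranks, expected):
        hp = GAHyperparams(q_pc=0.5, q_tr=0.5)
        assert accept(ranks, hp) is expected

    def test_zero_thresholds_accept_everything(self):
        hp = GAHyperparams(q_pc=0.0, q_tr=0.0)
        assert accept((0.0, 0.0), hp)


class TestReplacement:
    def test_tr_primary_replaces_low_tr_entry(self):
        pop = _entries([(1, 0.9), (2, 0.5)])
        new = PopulationEntry(PacingProtocol((1.0,), ()), 1.5, 0.7)
        out = replace_worst(pop, new, tr_primary=True)
        assert len(out) == 2
        assert (2, 0.5) not in [(e.pc, e.tr) for e in out]

    def test_pc_primary_replaces_high_pc_entry(self):
        pop = _entries([(1, 0.1), (5, 0.99)])
        new = PopulationEntry(PacingProtocol((1.0,), ()), 2.0, 0.5)
        out = replace_worst(pop, new, tr_primary=False)
        assert (5, 0.99) not in [(e.pc, e.tr) for e in out]

    def test_matches_sort_oracle_on_random_populations(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 20))
            pop = _entries(
                [(float(rng.integers(0, 5)), float(rng.integers(0, 5)) / 4)
                 for _ in range(n)]
            )
            tr_primary = bool(rng.integers(0, 2))
            key = (lambda e: (-e.tr, e.pc)) if tr_primary else (lambda e: (e.pc, -e.tr))
            worst = sorted(pop, key=key)[-1]
            new = PopulationEntry(PacingProtocol((1.0,), ()), 1.0, 0.5)
            out = replace_worst(pop, new, tr_primary)
            assert len(out) == n
            assert not any(e is worst for e in out)

    def test_all_tied_replaces_last_in_population_order(self):
        pop = _entries([(2, 0.5)] * 4)
        new = PopulationEntry(PacingProtocol((1.0,), ()), 2.0, 0.5)
        out = replace_worst(pop, new, tr_primary=True)
        assert not any(e is pop[-1] for e in out)
        assert all(any(o is e for o in out) for e in pop[:-1])

    def test_no_strict_elitism_pc_best_can_fall(self):
        # under TR-primary ordering the cheapest (PC-best) protocol is
        # bottom-ranked when its TR is worst - it gets replaced
        pop = _entries([(1.0, 0.2), (2.0, 0.9), (3.0, 0.5)])
        new = PopulationEntry(PacingProtocol((1.0,), ()), 2.5, 0.6)
        out = replace_worst(pop, new, tr_primary=True)
        assert (1.0, 0.2) not in [(e.pc, e.tr) for e in out]


class TestInitPopulation:
    def test_uniform_scheme_respects_intervals(self, rng):
        pop = init_population("uniform", HP, pacing_cost, rng)
        assert len(pop) == HP.population_size
        for e in pop:
            v = e.protocol.as_vector()
            assert np.all(v[:5] >= HP.amp_range[0]) and np.all(v[:5] <= HP.amp_range[1])
            assert np.all(v[5:] >= HP.interval_range[0])
            assert np.all(v[5:] <= HP.interval_range[1])
            assert e.pc == pacing_cost(e.protocol)

    def test_adp_jitter_zero_gives_identical_copies(self, rng):
        base = PacingProtocol((0.5,) * 5, (50.0, 60.0, 70.0, 80.0))
        pop = init_population(
            "adp-jitter", HP, pacing_cost, rng, base_protocol=base, jitter=0.0
        )
        assert all(e.protocol == base for e in pop)

    def test_unknown_scheme_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown"):
            init_population("tournament", HP, pacing_cost, rng)

    def test_seeded_reproducibility(self):
        a = init_population("uniform", HP, pacing_cost, np.random.default_rng(3))
        b = init_population("uniform", HP, pacing_cost, np.random.default_rng(3))
        assert [e.protocol for e in a] == [e.protocol for e in b]


class TestRunGa:
    def _surrogate(self, hp, target_seed=99):
        rng = np.random.default_rng(target_seed)
        target = PacingProtocol(
            tuple(rng.uniform(*hp.amp_range, hp.n_pulses)),
            tuple(rng.uniform(*hp.interval_range, hp.n_pulses - 1)),
        )
        return SurrogateBackend(target, hp)

    def test_zero_generations_returns_population_unchanged(self, rng):
        hp = GAHyperparams(population_size=6, n_generations=0,
                           interval_range=(20.0, 140.0))
        fit = self._surrogate(hp)
        pop = init_population("uniform", hp, fit, rng)
        out, hist = run_ga(pop, hp, fit)
        assert [e.protocol for e in out] == [e.protocol for e in pop]
        assert len(hist.rows) == 1

    def test_population_size_and_intervals_conserved(self, rng):
        hp = GAHyperparams(population_size=10, n_generations=80,
                           interval_range=(20.0, 140.0), seed=5)
        fit = self._surrogate(hp)
        pop = init_population("uniform", hp, fit, rng)
        out, hist = run_ga(pop, hp, fit)
        assert len(out) == 10
        frame = hist.frame()
        assert (frame["n_accepted"] >= 0).all()
        assert len(frame) == 81
        for e in out:
            v = e.protocol.as_vector()
            assert np.all(v[:5] >= hp.amp_range[0]) and np.all(v[:5] <= hp.amp_range[1])
            assert np.all(v[5:] >= hp.interval_range[0])
            assert np.all(v[5:] <= hp.interval_range[1])

    def test_run_is_reproducible_under_master_seed(self, rng):
        hp = GAHyperparams(population_size=6, n_generations=40,
                           interval_range=(20.0, 140.0), seed=17)
        fit = self._surrogate(hp)
        pop = init_population("uniform", hp, fit, np.random.default_rng(2))
        out1, h1 = run_ga(pop, hp, fit)
        out2, h2 = run_ga(pop, hp, fit)
        assert [e.protocol for e in out1] == [e.protocol for e in out2]
        assert h1.frame().equals(h2.frame())

    def test_surrogate_fitness_improves(self, rng):
        hp = GAHyperparams(population_size=12, n_generations=150,
                           interval_range=(20.0, 140.0), seed=23)
        fit = self._surrogate(hp)
        pop = init_population("uniform", hp, fit, rng)
        out, hist = run_ga(pop, hp, fit)
        frame = hist.frame()
        assert frame["mean_tr"].iloc[-1] > frame["mean_tr"].iloc[0]

    def test_backend_failures_bounded(self, rng):
        hp = GAHyperparams(population_size=6, n_generations=30, seed=3,
                           interval_range=(20.0, 140.0))

        def broken(proto):
            raise RuntimeError("backend down")

        pop = [
            PopulationEntry(PacingProtocol((1.0, 1.0), (50.0,)), 4.0, 0.5)
            for _ in range(6)
        ]
        with pytest.raises(RuntimeError, match="failed"):
            run_ga(pop, hp, broken, max_failures=5)

    def test_wrong_population_size_rejected(self):
        hp = GAHyperparams(population_size=6, interval_range=(20.0, 140.0))
        with pytest.raises(ValueError, match="population size"):
            run_ga(_entries([(1.0, 0.5)] * 4), hp, lambda p: 0.5)


class TestConvergenceClassifier:
    def test_labels_canonical_shapes(self):
        g = np.arange(400, dtype=float)
        asymptotic = 1.0 + 4.0 * np.exp(-g / 40.0)
        linear = 5.0 - 0.01 * g
        rebound = np.concatenate(
            [5.0 - 0.03 * g[:200], 5.0 - 6.0 + 0.02 * (g[200:] - 200)]
        )
        assert classify_convergence(asymptotic) == "asymptotic"
        assert classify_convergence(linear) == "quasi-linear"
        assert classify_convergence(rebound) == "rebounding"

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            classify_convergence(np.arange(10.0))
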