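import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegselect.moo import (
    ArchiveEntry,
    Fitness,
    GAConfig,
    ParetoArchive,
    backward_elimination,
    backward_elimination_with_count,
    crowding_distance,
    das_dennis_points,
    dominates,
    fast_nondominated_sort,
    nsga3_select,
    repair,
    run_nsga,
    termination_check,
)
from helpers import exhaustive_pareto, structured_lookup_table


def brute_force_fronts(fitnesses):
    remaining = set(range(len(fitnesses)))
    fronts = []
    while remaining:
        nd = sorted(
            i for i in remaining
            if not any(dominates(fitnesses[j], fitnesses[i]) for j in remaining if j != i)
        )
        fronts.append(nd)
        remaining -= set(nd)
    return fronts


class TestRepair:
    def test_all_zero_gets_one_gene(self):
        rng = np.random.default_rng(0)
        out = repair(np.zeros(22, dtype=int), rng)
        assert out.sum() == 1

    def test_nonzero_unchanged(self):
        rng = np.random.default_rng(0)
        chrom = np.array([0, 1, 0, 1])
        np.testing.assert_array_equal(repair(chrom, rng), chrom)

    def test_repair_uniform(self):
        rng = np.random.default_rng(42)
        c = 22
        trials = 10_000
        counts = np.zeros(c)
        for _ in range(trials):
            out = repair(np.zeros(c, dtype=int), rng)
            counts[np.argmax(out)] += 1
        p = 1 / c
        sigma = math.sqrt(trials * p * (1 - p))
        assert np.all(np.abs(counts - trials * p) <= 3 * sigma + 1)


class TestDominates:
    def test_strict_dominance(self):
        assert dominates(Fitness(0.9, 3), Fitness(0.8, 5))

    def test_equal_not_dominating(self):
        assert not dominates(Fitness(0.9, 3), Fitness(0.9, 3))

    def test_mutually_nondominated(self):
        a, b = Fitness(0.9, 5), Fitness(0.8, 3)
        assert not dominates(a, b) and not dominates(b, a)


class TestFastNondominatedSort:
    def test_single_point(self):
        assert fast_nondominated_sort([Fitness(0.5, 2)]) == [[0]]

    def test_strict_chain(self):
        fits = [Fitness(0.9, 1), Fitness(0.8, 1), Fitness(0.7, 1)]
        assert fast_nondominated_sort(fits) == [[0], [1], [2]]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            fits = [Fitness(float(rng.random()), int(rng.integers(1, 12))) for _ in range(50)]
            got = [sorted(f) for f in fast_nondominated_sort(fits)]
            assert got == brute_force_fronts(fits)

    def test_every_index_in_exactly_one_front(self):
        rng = np.random.default_rng(1)
        fits = [Fitness(float(rng.random()), int(rng.integers(1, 6))) for _ in range(40)]
        fronts = fast_nondominated_sort(fits)
        flat = sorted(i for f in fronts for i in f)
        assert flat == list(range(40))


class TestCrowdingDistance:
    def test_two_member_front(self):
        d = crowding_distance([Fitness(0.5, 1), Fitness(0.4, 2)])
        assert d == [math.inf, math.inf]

    def test_equally_spaced_middle(self):
        fits = [Fitness(0.9, 1), Fitness(0.8, 2), Fitness(0.7, 3)]
        d = crowding_distance(fits)
        assert d[0] == math.inf and d[2] == math.inf
        assert d[1] == pytest.approx(2.0)

    def test_duplicates_get_zero(self):
        fits = [Fitness(0.9, 1), Fitness(0.8, 2), Fitness(0.8, 2), Fitness(0.7, 3)]
        d = crowding_distance(fits)
        assert min(d[1], d[2]) == pytest.approx(0.0)

    def test_empty_front_rejected(self):
        with pytest.raises(ValueError):
            crowding_distance([])


class TestDasDennis:
    def test_contains_apexes(self):
        for p in (1, 3, 5):
            pts = das_dennis_points(3, p)
            for apex in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]:
                assert any(np.allclose(pt, apex) for pt in pts)

    def test_simplex_constraint(self):
        pts = das_dennis_points(3, 4)
        np.testing.assert_allclose(pts.sum(axis=1), 1.0, atol=1e-12)

    def test_count_matches_compositions(self):
        assert len(das_dennis_points(3, 4)) == 15  # C(6, 4)
        assert len(das_dennis_points(2, 19)) == 20

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            das_dennis_points(1, 3)


class TestNsga3Select:
    def test_first_front_exactly_n(self):
        fits = [Fitness(0.9 - 0.1 * i, i + 1) for i in range(4)]  # one front of 4
        refs = das_dennis_points(2, 3)
        rng = np.random.default_rng(0)
        surv = nsga3_select(fits, refs, 4, rng)
        assert sorted(surv) == [0, 1, 2, 3]

    def test_elitism_front0_always_kept(self):
        fits = [Fitness(0.9, 1), Fitness(0.8, 2),      # front 0
                Fitness(0.7, 3), Fitness(0.6, 4), Fitness(0.5, 5)]  # dominated
        refs = das_dennis_points(2, 2)
        rng = np.random.default_rng(0)
        surv = nsga3_select(fits, refs, 3, rng)
        assert {0, 1} <= set(surv)

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError):
            nsga3_select([Fitness(0.5, 1)], das_dennis_points(2, 1), 2,
                         np.random.default_rng(0))

    def test_association_matches_geometry_oracle(self):
        from eegselect.moo import _normalize_objectives, associate_to_references

        rng = np.random.default_rng(3)
        fits = [Fitness(float(rng.random()), int(rng.integers(1, 9))) for _ in range(30)]
        refs = das_dennis_points(2, 7)
        norm = _normalize_objectives(fits)
        idx, dist = associate_to_references(norm, refs)
        for i, pt in enumerate(norm):
            per_ref = []
            for r in refs:
                u = r / np.linalg.norm(r)
                proj = np.dot(pt, u) * u
                per_ref.append(np.linalg.norm(pt - proj))
            assert idx[i] == int(np.argmin(per_ref))
            assert dist[i] == pytest.approx(min(per_ref), abs=1e-12)


class TestTerminationCheck:
    def test_identical_snapshots(self):
        snap = {1: (0.9, 0.1), 3: (0.95, 0.3)}
        assert termination_check([snap, dict(snap)], tolerance=1e-4)

    def test_moved_objective(self):
        a = {1: (0.90, 0.1)}
        b = {1: (0.91, 0.1)}
        assert not termination_check([a, b], tolerance=1e-4)

    def test_first_check_never_terminates(self):
        assert not termination_check([{1: (0.9, 0.1)}], tolerance=1e-4)

    def test_unmatched_no_counts_as_full_change(self):
        a = {1: (0.9, 0.1)}
        b = {1: (0.9, 0.1), 2: (0.95, 0.2)}
        assert not termination_check([a, b], tolerance=0.5)


class TestParetoArchive:
    def test_no_entry_dominates_another(self):
        arch = ParetoArchive()
        rng = np.random.default_rng(0)
        for _ in range(200):
            no = int(rng.integers(1, 9))
            arch.offer(ArchiveEntry(subset=tuple(range(no)), acc=float(rng.random()), no=no))
        for a in arch.entries:
            for b in arch.entries:
                if a is not b:
                    assert not dominates(Fitness(a.acc, a.no), Fitness(b.acc, b.no))

    def test_sorted_by_no_one_entry_per_no(self):
        arch = ParetoArchive()
        arch.offer(ArchiveEntry(subset=(0,), acc=0.8, no=1))
        arch.offer(ArchiveEntry(subset=(1,), acc=0.9, no=1))
        arch.offer(ArchiveEntry(subset=(0, 1), acc=0.95, no=2))
        assert [e.no for e in arch.entries] == [1, 2]
        assert arch.entries[0].acc == 0.9


class FitnessStub:
    def __init__(self, fn):
        self.fn = fn
        self.calls = 0

    def __call__(self, subset):
        self.calls += 1
        return type("S", (), {"accuracy": self.fn(subset), "classifier_id": "stub"})()


class TestRunNsga:
    def test_determinism(self):
        lut = structured_lookup_table(6, seed=5)
        cfg = GAConfig(seed=3, max_generations=30, tolerance=0.0)
        ev = lambda s: type("S", (), {"accuracy": lut[s], "classifier_id": "stub"})()
        a1, h1 = run_nsga("II", 6, ev, cfg)
        a2, h2 = run_nsga("II", 6, ev, cfg)
        assert [(e.subset, e.acc, e.no) for e in a1.entries] == \
               [(e.subset, e.acc, e.no) for e in a2.entries]
        assert h1[-1]["evaluations"] == h2[-1]["evaluations"]

    def test_runs_exactly_max_generations_when_tolerance_unreachable(self):
        rng_acc = np.random.default_rng(0)

        def noisy(subset):
            return type("S", (), {"accuracy": float(rng_acc.random()), "classifier_id": ""})()

        cfg = GAConfig(seed=1, max_generations=40, tolerance=0.0)
        _, history = run_nsga("II", 6, noisy, cfg)
        assert len(history) == 40

    def test_archive_equals_exhaustive_front_small(self):
        lut = structured_lookup_table(6, seed=1)
        truth = exhaustive_pareto(lut)
        ev = lambda s: type("S", (), {"accuracy": lut[s], "classifier_id": ""})()
        for variant in ("II", "III"):
            arch, _ = run_nsga(variant, 6, ev,
                               GAConfig(seed=2, max_generations=120, tolerance=0.0))
            assert [(e.no, e.acc) for e in arch.entries] == truth

    def test_elitism_best_acc_nondecreasing(self):
        lut = structured_lookup_table(6, seed=9)
        ev = lambda s: type("S", (), {"accuracy": lut[s], "classifier_id": ""})()
        _, history = run_nsga("II", 6, ev, GAConfig(seed=0, max_generations=50, tolerance=0.0))
        prev: dict[int, float] = {}
        for h in history:
            for no, acc in h["best_per_no"].items():
                if no in prev:
                    assert acc >= prev[no] - 1e-12
            prev.update(h["best_per_no"])

    def test_evaluation_caching_bound(self):
        lut = structured_lookup_table(6, seed=4)
        stub = FitnessStub(lambda s: lut[s])
        cfg = GAConfig(seed=5, max_generations=100, tolerance=0.0)
        run_nsga("II", 6, stub, cfg)
        assert stub.calls <= 2**6 - 1

    def test_invalid_variant_rejected(self):
        with pytest.raises(ValueError):
            run_nsga("IV", 4, lambda s: None)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=7)
        with pytest.raises(ValueError):
            GAConfig(tolerance=-1)


class TestBackwardElimination:
    def test_call_count_c22(self, stub_score_cls):
        path, calls = backward_elimination_with_count(22, lambda s: stub_score_cls(0.5))
        assert calls == 253
        assert [e.no for e in path] == list(range(22, 0, -1))

    def test_call_count_c3(self, stub_score_cls):
        _, calls = backward_elimination_with_count(3, lambda s: stub_score_cls(0.5))
        assert calls == 6

    def test_greedy_keeps_best_channel(self, stub_score_cls):
        # channel 2 carries all the accuracy: it must survive to the end
        def acc(subset):
            return 0.5 + 0.4 * (2 in subset) + 0.01 * len(subset)

        path = backward_elimination(5, lambda s: stub_score_cls(acc(s)))
        assert path[-1].subset == (2,)

    def test_tie_removes_lowest_index(self, stub_score_cls):
        path = backward_elimination(3, lambda s: stub_score_cls(0.5))
        # constant fitness: each level removes the lowest-index channel
        assert path[1].subset == (1, 2)
        assert path[2].subset == (2,)

    def test_single_channel_rejected(self, stub_score_cls):
        with pytest.raises(ValueError):
            backward_elimination(1, lambda s: stub_score_cls(0.5))


@settings(max_examples=30, deadline=None)
@given(st.lists(
    st.tuples(st.floats(min_value=0, max_value=1), st.integers(min_value=1, max_value=10)),
    min_size=1, max_size=25,
))
def test_front0_is_nondominated_property(pairs):
    fits = [Fitness(a, n) for a, n in pairs]
    fronts = fast_nondominated_sort(fits)
    for i in fronts[0]:
        assert not any(dominates(fits[j], fits[i]) for j in range(len(fits)) if j != i)


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=2, max_value=5), st.integers(min_value=1, max_value=6))
def test_das_dennis_count_property(m, p):
    pts = das_dennis_points(m, p)
    assert len(pts) == math.comb(m + p - 1, p)
    np.testing.assert_allclose(pts.sum(axis=1), 1.0, atol=1e-12)
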