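"""Channel-subset search: NSGA-II and NSGA-III written from scratch,
plus a greedy backward-elimination baseline.

A candidate solution (chromosome) is a binary mask over the montage, one
gene per channel.  The two objectives are classification accuracy
(maximized) and active-channel count (minimized); internally both are
minimized as (1 - Acc, No).  Fitness comes from an ``evaluator``
callable mapping a channel-index tuple to an object with ``accuracy``
and ``classifier_id`` attributes (``SubsetScore`` in the real pipeline),
memoized on the subset bitmask so each distinct subset is scored once.

Termination follows the front-movement rule: every ``check_interval``
generations the non-dominated set (matched across snapshots by channel
count, objectives normalized) is compared with the previous snapshot;
the run stops when the maximum change falls below ``tolerance``, or at
``max_generations``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Chromosome",
    "Fitness",
    "GAConfig",
    "ParetoArchive",
    "ArchiveEntry",
    "repair",
    "dominates",
    "fast_nondominated_sort",
    "crowding_distance",
    "das_dennis_points",
    "nsga3_select",
    "run_nsga",
    "termination_check",
    "backward_elimination",
]

Chromosome = np.ndarray  # binary gene vector of length C


@dataclass(frozen=True)
class Fitness:
    """Objective pair: CV accuracy (maximized), channel count (minimized)."""

    acc: float
    no: int

    def minimized(self) -> tuple[float, int]:
        return (1.0 - self.acc, self.no)


@dataclass(frozen=True)
class GAConfig:
    """NSGA run parameters: population 20, objective-space tolerance
    1e-4 checked every 5th generation, ceiling of 500 generations."""

    population_size: int = 20
    max_generations: int = 500
    tolerance: float = 0.0001
    check_interval: int = 5
    crossover_prob: float = 0.9
    mutation_prob: float | None = None  # None -> 1/C per gene
    seed: int = 0
    n_objectives: int = 2
    reference_partitions: int | None = None  # None -> population_size - 1

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population_size must be an even integer >= 2")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.check_interval < 1:
            raise ValueError("check_interval must be >= 1")


@dataclass
class ArchiveEntry:
    subset: tuple[int, ...]
    acc: float
    no: int
    classifier_id: str = ""
    sensitivity: float | None = None
    specificity: float | None = None
    generation_found: int = 0


@dataclass
class ParetoArchive:
    """Best-accuracy-per-channel-count entries, mutually non-dominated,
    sorted by channel count ascending."""

    entries: list[ArchiveEntry] = field(default_factory=list)

    def offer(self, entry: ArchiveEntry) -> None:
        by_no = {e.no: e for e in self.entries}
        cur = by_no.get(entry.no)
        if cur is None or entry.acc > cur.acc:
            by_no[entry.no] = entry
        self.entries = self._prune(sorted(by_no.values(), key=lambda e: e.no))

    @staticmethod
    def _prune(entries: list[ArchiveEntry]) -> list[ArchiveEntry]:
        kept: list[ArchiveEntry] = []
        best_acc = -math.inf
        for e in entries:  # ascending no: drop if no better than a smaller subset
            if e.acc > best_acc:
                kept.append(e)
                best_acc = e.acc
        return kept

    def snapshot(self, n_channels: int) -> dict[int, tuple[float, float]]:
        """Normalized objective pairs keyed by channel count."""
        return {e.no: (e.acc, e.no / n_channels) for e in self.entries}


def repair(chrom: Chromosome, rng: np.random.Generator) -> Chromosome:
    """Ensure at least one active gene: an all-zero chromosome gets one
    uniformly chosen gene set."""
    if chrom.any():
        return chrom
    out = chrom.copy()
    out[rng.integers(0, chrom.size)] = 1
    return out


def dominates(a: Fitness, b: Fitness) -> bool:
    """True iff ``a`` is no worse than ``b`` in both objectives and
    strictly better in at least one."""
    return (a.acc >= b.acc and a.no <= b.no) and (a.acc > b.acc or a.no < b.no)


def fast_nondominated_sort(fitnesses: list[Fitness]) -> list[list[int]]:
    """Deb's O(M N^2) non-dominated sorting into successive fronts."""
    n = len(fitnesses)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    dom_count = [0] * n
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(fitnesses[i], fitnesses[j]):
                dominated_by[i].append(j)
                dom_count[j] += 1
            elif dominates(fitnesses[j], fitnesses[i]):
                dominated_by[j].append(i)
                dom_count[i] += 1
    fronts: list[list[int]] = [[i for i in range(n) if dom_count[i] == 0]]
    current = fronts[0]
    while current:
        nxt: list[int] = []
        for i in current:
            for j in dominated_by[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    nxt.append(j)
        if nxt:
            fronts.append(sorted(nxt))
        current = nxt
    return fronts


def crowding_distance(front_fitnesses: list[Fitness]) -> list[float]:
    """NSGA-II crowding distance within one front: boundary members get
    +inf, interior members the sum of normalized neighbour gaps.

    Distances are computed over distinct objective vectors; members that
    duplicate an earlier one get distance 0.
    """
    n = len(front_fitnesses)
    if n == 0:
        raise ValueError("front must be nonempty")
    dist = [0.0] * n
    seen: dict[tuple[float, int], int] = {}
    reps: list[int] = []
    for i, f in enumerate(front_fitnesses):
        key = (f.acc, f.no)
        if key not in seen:
            seen[key] = i
            reps.append(i)
    m = len(reps)
    if m == 1:
        dist[reps[0]] = math.inf
        return dist
    objs = [[front_fitnesses[i].minimized()[k] for i in reps] for k in range(2)]
    rep_dist = [0.0] * m
    for vals in objs:
        order = sorted(range(m), key=lambda j: vals[j])
        rep_dist[order[0]] = rep_dist[order[-1]] = math.inf
        vrange = vals[order[-1]] - vals[order[0]]
        if vrange <= 0:
            continue
        for pos in range(1, m - 1):
            j = order[pos]
            if not math.isinf(rep_dist[j]):
                rep_dist[j] += (vals[order[pos + 1]] - vals[order[pos - 1]]) / vrange
    for j, i in enumerate(reps):
        dist[i] = rep_dist[j]
    return dist


def das_dennis_points(m: int, p: int) -> np.ndarray:
    """Das-Dennis systematic reference points: all compositions of ``p``
    into ``m`` parts scaled to the unit simplex; C(m+p-1, p) points."""
    if m < 2 or p < 1:
        raise ValueError("need m >= 2 and p >= 1")
    points: list[list[float]] = []

    def rec(prefix: list[int], remaining: int, slots: int) -> None:
        if slots == 1:
            points.append([*prefix, remaining])
            return
        for v in range(remaining + 1):
            rec([*prefix, v], remaining - v, slots - 1)

    rec([], p, m)
    return np.array(points, dtype=float) / p


def _perpendicular_distance(point: np.ndarray, ref_dir: np.ndarray) -> float:
    norm = np.linalg.norm(ref_dir)
    if norm == 0:
        return float(np.linalg.norm(point))
    proj = np.dot(point, ref_dir) / norm
    return float(np.sqrt(max(np.dot(point, point) - proj**2, 0.0)))


def associate_to_references(points: np.ndarray, refs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For each normalized objective point, the index of and distance to
    the closest reference line through the origin."""
    idx = np.empty(len(points), dtype=int)
    dist = np.empty(len(points))
    for i, pt in enumerate(points):
        d = [_perpendicular_distance(pt, r) for r in refs]
        idx[i] = int(np.argmin(d))
        dist[i] = d[idx[i]]
    return idx, dist


def _normalize_objectives(fitnesses: list[Fitness]) -> np.ndarray:
    objs = np.array([f.minimized() for f in fitnesses], dtype=float)
    ideal = objs.min(axis=0)
    span = objs.max(axis=0) - ideal
    span[span <= 0] = 1.0
    return (objs - ideal) / span


def nsga3_select(
    fitnesses: list[Fitness],
    reference_points: np.ndarray,
    n_survivors: int,
    rng: np.random.Generator,
) -> list[int]:
    """Deb & Jain environmental selection: admit whole fronts while they
    fit, resolve the splitting front by reference-point niching."""
    if len(fitnesses) < n_survivors:
        raise ValueError("pool smaller than requested survivor count")
    fronts = fast_nondominated_sort(fitnesses)
    survivors: list[int] = []
    f_idx = 0
    while f_idx < len(fronts) and len(survivors) + len(fronts[f_idx]) <= n_survivors:
        survivors.extend(fronts[f_idx])
        f_idx += 1
    if len(survivors) == n_survivors or f_idx >= len(fronts):
        return survivors[:n_survivors]
    splitting = fronts[f_idx]
    considered = survivors + splitting
    norm = _normalize_objectives([fitnesses[i] for i in considered])
    assoc, dist = associate_to_references(norm, reference_points)
    niche_count = np.zeros(len(reference_points), dtype=int)
    for pos in range(len(survivors)):  # niches filled by already-admitted members
        niche_count[assoc[pos]] += 1
    split_assoc = {
        splitting[j]: (assoc[len(survivors) + j], dist[len(survivors) + j])
        for j in range(len(splitting))
    }
    remaining = list(splitting)
    while len(survivors) < n_survivors:
        active = {split_assoc[i][0] for i in remaining}
        min_count = min(niche_count[r] for r in active)
        candidates_refs = sorted(r for r in active if niche_count[r] == min_count)
        ref = candidates_refs[int(rng.integers(0, len(candidates_refs)))]
        members = [i for i in remaining if split_assoc[i][0] == ref]
        if niche_count[ref] == 0:
            pick = min(members, key=lambda i: (split_assoc[i][1], i))
        else:
            pick = members[int(rng.integers(0, len(members)))]
        survivors.append(pick)
        remaining.remove(pick)
        niche_count[ref] += 1
    return survivors


def termination_check(
    snapshots: list[dict[int, tuple[float, float]]],
    tolerance: float,
) -> bool:
    """True when the latest two front snapshots moved less than
    ``tolerance`` in every (normalized) objective; channel counts present
    in only one snapshot count as a change of 1."""
    if len(snapshots) < 2:
        return False
    prev, cur = snapshots[-2], snapshots[-1]
    max_change = 0.0
    for no in set(prev) | set(cur):
        if no in prev and no in cur:
            change = max(abs(prev[no][0] - cur[no][0]), abs(prev[no][1] - cur[no][1]))
        else:
            change = 1.0
        max_change = max(max_change, change)
    return max_change < tolerance


class _MemoEvaluator:
    """Bitmask-keyed memoization wrapper around the fitness evaluator."""

    def __init__(self, evaluator):
        self._evaluator = evaluator
        self.cache: dict[tuple[int, ...], object] = {}
        self.calls = 0

    def __call__(self, subset: tuple[int, ...]):
        if subset not in self.cache:
            self.cache[subset] = self._evaluator(subset)
            self.calls += 1
        return self.cache[subset]


def _subset_of(chrom: Chromosome) -> tuple[int, ...]:
    return tuple(int(i) for i in np.flatnonzero(chrom))


def _tournament(rng, ranks, crowding, i, j) -> int:
    if ranks[i] != ranks[j]:
        return i if ranks[i] < ranks[j] else j
    if crowding is not None and crowding[i] != crowding[j]:
        return i if crowding[i] > crowding[j] else j
    return i if rng.integers(0, 2) == 0 else j


def _two_point_crossover(a: Chromosome, b: Chromosome, rng) -> tuple[Chromosome, Chromosome]:
    c = a.size
    p1, p2 = sorted(rng.choice(c + 1, size=2, replace=False))
    child1, child2 = a.copy(), b.copy()
    child1[p1:p2], child2[p1:p2] = b[p1:p2].copy(), a[p1:p2].copy()
    return child1, child2


def run_nsga(
    variant: str,
    n_channels: int,
    evaluator,
    config: GAConfig = GAConfig(),
) -> tuple[ParetoArchive, list[dict]]:
    """Generational NSGA-II/III loop over channel-mask chromosomes.

    Returns the accumulated Pareto archive (all non-dominated solutions
    ever evaluated, reduced to best accuracy per channel count) and a
    per-generation history of dicts with keys ``generation``,
    ``evaluations``, ``best_per_no`` and ``winners`` (classifier ids of
    the generation's per-chromosome winners).
    """
    variant = variant.lower().replace("-", "")
    if variant in ("ii", "nsga2", "2"):
        use_nsga3 = False
    elif variant in ("iii", "nsga3", "3"):
        use_nsga3 = True
    else:
        raise ValueError(f"unknown NSGA variant {variant!r}")
    if n_channels < 1:
        raise ValueError("n_channels must be positive")

    rng = np.random.default_rng(config.seed)
    memo = _MemoEvaluator(evaluator)
    n = config.population_size
    mut_p = config.mutation_prob if config.mutation_prob is not None else 1.0 / n_channels
    refs = None
    if use_nsga3:
        p = config.reference_partitions or (n - 1)
        refs = das_dennis_points(config.n_objectives, p)

    archive = ParetoArchive()
    history: list[dict] = []
    snapshots: list[dict[int, tuple[float, float]]] = []

    def evaluate_pop(pop: list[Chromosome], gen: int) -> tuple[list[Fitness], list[str]]:
        fits, winners = [], []
        for chrom in pop:
            subset = _subset_of(chrom)
            score = memo(subset)
            fit = Fitness(acc=float(score.accuracy), no=len(subset))
            fits.append(fit)
            winners.append(getattr(score, "classifier_id", ""))
            archive.offer(ArchiveEntry(
                subset=subset,
                acc=fit.acc,
                no=fit.no,
                classifier_id=getattr(score, "classifier_id", ""),
                sensitivity=getattr(score, "sensitivity", None),
                specificity=getattr(score, "specificity", None),
                generation_found=gen,
            ))
        return fits, winners

    population = [repair((rng.random(n_channels) < 0.5).astype(int), rng) for _ in range(n)]
    fitnesses, winners = evaluate_pop(population, 0)

    for gen in range(1, config.max_generations + 1):
        fronts = fast_nondominated_sort(fitnesses)
        ranks = [0] * n
        crowd = [0.0] * n
        for r, front in enumerate(fronts):
            cds = crowding_distance([fitnesses[i] for i in front])
            for i, cd in zip(front, cds):
                ranks[i] = r
                crowd[i] = cd
        offspring: list[Chromosome] = []
        while len(offspring) < n:
            cands = rng.integers(0, n, size=4)
            p1 = _tournament(rng, ranks, None if use_nsga3 else crowd, int(cands[0]), int(cands[1]))
            p2 = _tournament(rng, ranks, None if use_nsga3 else crowd, int(cands[2]), int(cands[3]))
            if rng.random() < config.crossover_prob:
                c1, c2 = _two_point_crossover(population[p1], population[p2], rng)
            else:
                c1, c2 = population[p1].copy(), population[p2].copy()
            for child in (c1, c2):
                flip = rng.random(n_channels) < mut_p
                child[flip] ^= 1
                offspring.append(repair(child, rng))
        offspring = offspring[:n]
        off_fits, _ = evaluate_pop(offspring, gen)

        pool = population + offspring
        pool_fits = fitnesses + off_fits
        if use_nsga3:
            surv = nsga3_select(pool_fits, refs, n, rng)
        else:
            surv = _nsga2_select(pool_fits, n)
        population = [pool[i] for i in surv]
        fitnesses = [pool_fits[i] for i in surv]
        _, winners = evaluate_pop(population, gen)  # cached; records winners per generation

        history.append({
            "generation": gen,
            "evaluations": memo.calls,
            "best_per_no": {e.no: e.acc for e in archive.entries},
            "winners": list(winners),
        })
        if gen % config.check_interval == 0:
            snapshots.append(archive.snapshot(n_channels))
            if termination_check(snapshots, config.tolerance):
                break
    return archive, history


def _nsga2_select(fitnesses: list[Fitness], n_survivors: int) -> list[int]:
    fronts = fast_nondominated_sort(fitnesses)
    survivors: list[int] = []
    for front in fronts:
        if len(survivors) + len(front) <= n_survivors:
            survivors.extend(front)
            continue
        cds = crowding_distance([fitnesses[i] for i in front])
        order = sorted(range(len(front)), key=lambda j: (-cds[j], front[j]))
        survivors.extend(front[j] for j in order[: n_survivors - len(survivors)])
        break
    return survivors


def backward_elimination(n_channels: int, evaluator) -> list[ArchiveEntry]:
    """Greedy channel reduction: evaluate the full montage, then at each
    level drop the channel whose removal yields the highest accuracy,
    down to a single channel.

    Total evaluator calls are C(C+1)/2 (253 for the 22-channel montage),
    counting the initial full-set evaluation.  Ties remove the
    lowest-index channel.  Returns one entry per subset size, C down
    to 1.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    memo = _MemoEvaluator(evaluator)
    current = tuple(range(n_channels))
    score = memo(current)
    path = [ArchiveEntry(
        subset=current, acc=float(score.accuracy), no=n_channels,
        classifier_id=getattr(score, "classifier_id", ""),
        sensitivity=getattr(score, "sensitivity", None),
        specificity=getattr(score, "specificity", None),
    )]
    while len(current) > 1:
        best_subset, best_score = None, None
        for drop in current:  # ascending: ties keep the first (lowest drop index)
            cand = tuple(c for c in current if c != drop)
            s = memo(cand)
            if best_score is None or s.accuracy > best_score.accuracy:
                best_subset, best_score = cand, s
        current = best_subset
        path.append(ArchiveEntry(
            subset=current, acc=float(best_score.accuracy), no=len(current),
            classifier_id=getattr(best_score, "classifier_id", ""),
            sensitivity=getattr(best_score, "sensitivity", None),
            specificity=getattr(best_score, "specificity", None),
        ))
    return path


def backward_elimination_with_count(n_channels: int, evaluator) -> tuple[list[ArchiveEntry], int]:
    """As :func:`backward_elimination` but also returning the number of
    distinct evaluator calls made."""
    counter = {"calls": 0}

    def counting(subset):
        counter["calls"] += 1
        return evaluator(subset)

    path = backward_elimination(n_channels, counting)
    return path, counter["calls"]
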