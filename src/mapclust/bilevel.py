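"""Bi-level medoid clustering solved by NSGA-II with an exact follower.

The model is a Stackelberg game between two distance metrics.  The
*leader* picks the set of medoids (binary variables x_jj) and is scored
on the bi-objective

    min F = ( sum_i d1(i, owner(i)),  sum_j x_jj )

i.e. intra-class inertia under the leader metric d1 and the number of
clusters k.  The *follower* assigns every element to one chosen medoid
(x_ij) optimally under the second metric d2.  With the medoids fixed the
follower problem's constraint matrix is totally unimodular, so its LP
relaxation has an integral optimum and the problem separates per
element: each element simply takes its d2-nearest medoid.  That
separable argmin is the runtime solver here; equivalence with an LP
solve is exercised in the test suite, not at runtime.

The leader is explored by NSGA-II over medoid bit-vectors (binary
tournament selection, single-point crossover, bit-flip mutation,
elitist non-dominated sorting with crowding distance).  Every genome
evaluation solves the follower exactly, giving a bijection between a
genome and its clustering.  Independent runs are merged into one Pareto
front; duplicates and dominated points are removed.

Swapping (d1, d2) changes the game — the order of the levels matters —
so metric pairs are always given as "leader > follower".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .distances import DistanceMatrix


@dataclass
class EAConfig:
    """Evolutionary-algorithm parameters.

    Defaults are the full-scale experimental settings (population 100,
    30000 generations, 30 independent runs); :meth:`desk` returns the
    desk-scale configuration used for tests and examples.
    """

    population_size: int = 100
    generations: int = 30000
    crossover_prob: float = 0.8
    mutation_prob: float | None = None  # None -> 1/N
    independent_runs: int = 30
    rng_seed: int = 0
    stagnation_window: int | None = None
    init_density: float | None = None  # expected medoid count k0; None -> sqrt(N)

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population size must be even and >= 2")
        for p in (self.crossover_prob,) + (
            (self.mutation_prob,) if self.mutation_prob is not None else ()
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.generations < 1 or self.independent_runs < 1:
            raise ValueError("generations and independent_runs must be >= 1")

    @classmethod
    def desk(cls, rng_seed: int = 0, **overrides) -> "EAConfig":
        kw = dict(population_size=40, generations=500, independent_runs=5,
                  rng_seed=rng_seed)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class MedoidSolution:
    """One point of the Pareto front: genome, exact assignment, objectives."""

    bits: np.ndarray              # bool vector, bit j = element j is a medoid
    assignment: np.ndarray        # int vector, entry i = index of i's medoid
    leader_inertia: float
    n_clusters: int

    @property
    def medoid_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def clustering_labels(self) -> np.ndarray:
        """Contiguous cluster ids 0..k-1 from the medoid assignment."""
        _, labels = np.unique(self.assignment, return_inverse=True)
        return labels

    def objectives(self) -> tuple[float, int]:
        return (self.leader_inertia, self.n_clusters)


@dataclass
class ParetoFront:
    """Mutually non-dominated medoid solutions over one (d1, d2) instance."""

    labels: list[str]
    solutions: list[MedoidSolution] = field(default_factory=list)

    def sorted_by_k(self) -> list[MedoidSolution]:
        return sorted(self.solutions, key=lambda s: s.n_clusters)

    def solution_at_k(self, k: int) -> MedoidSolution | None:
        for s in self.solutions:
            if s.n_clusters == k:
                return s
        return None

    def objective_set(self) -> set[tuple[float, int]]:
        return {(round(s.leader_inertia, 9), s.n_clusters) for s in self.solutions}

    def to_json(self, path: str | Path) -> None:
        doc = {
            "labels": self.labels,
            "solutions": [
                {
                    "medoids": [self.labels[j] for j in s.medoid_indices],
                    "leader_inertia": s.leader_inertia,
                    "n_clusters": s.n_clusters,
                    "assignment": [self.labels[j] for j in s.assignment],
                }
                for s in self.sorted_by_k()
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    def to_tsv(self, path: str | Path) -> None:
        lines = ["k\tleader_inertia\tmedoid_ids"]
        for s in self.sorted_by_k():
            meds = ",".join(self.labels[j] for j in s.medoid_indices)
            lines.append(f"{s.n_clusters}\t{s.leader_inertia:.10g}\t{meds}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Exact follower and genome evaluation
# ---------------------------------------------------------------------------

def repair(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Make a genome feasible: an all-zero vector gets one random bit set."""
    if bits.any():
        return bits
    out = bits.copy()
    out[rng.integers(len(bits))] = True
    return out


def assign_followers(bits: np.ndarray, d2: DistanceMatrix) -> np.ndarray:
    """Solve the follower problem exactly: each element takes its
    d2-nearest medoid (ties to the lowest medoid index).

    With medoids fixed the assignment LP is totally unimodular and
    separable per element, so this argmin is globally optimal.
    """
    bits = np.asarray(bits, dtype=bool)
    if bits.shape != (d2.n,):
        raise ValueError("genome length does not match matrix dimension")
    medoids = np.flatnonzero(bits)
    if medoids.size == 0:
        raise ValueError("all-zero genome: repair before assignment")
    # argmin returns the first minimum; medoids are ascending, so ties
    # resolve to the lowest medoid index.
    owner_pos = np.argmin(d2.values[:, medoids], axis=1)
    return medoids[owner_pos]


def evaluate(
    bits: np.ndarray, d1: DistanceMatrix, d2: DistanceMatrix
) -> tuple[np.ndarray, tuple[float, int]]:
    """Exact follower assignment under d2, then leader objectives under d1."""
    if d1.labels != d2.labels:
        raise ValueError("leader and follower matrices have different labels")
    assignment = assign_followers(bits, d2)
    inertia = float(d1.values[np.arange(d1.n), assignment].sum())
    return assignment, (inertia, int(np.asarray(bits, bool).sum()))


# ---------------------------------------------------------------------------
# NSGA-II machinery (vectorized over the population)
# ---------------------------------------------------------------------------

def nondominated_ranks(objs: np.ndarray) -> np.ndarray:
    """Fast non-dominated sorting; returns 0-based rank per row of objs."""
    P = len(objs)
    le = (objs[:, None, :] <= objs[None, :, :]).all(axis=2)
    lt = (objs[:, None, :] < objs[None, :, :]).any(axis=2)
    dom = le & lt                      # dom[i, j]: i dominates j
    n_dominators = dom.sum(axis=0).astype(int)
    ranks = np.full(P, -1, dtype=int)
    rank = 0
    remaining = np.ones(P, dtype=bool)
    while remaining.any():
        front = remaining & (n_dominators == 0)
        if not front.any():  # cannot happen for a strict partial order
            front = remaining
        ranks[front] = rank
        remaining &= ~front
        n_dominators -= dom[front].sum(axis=0)
        rank += 1
    return ranks


def crowding_distance(objs: np.ndarray, ranks: np.ndarray) -> np.ndarray:
    """Per-individual crowding distance within its non-domination front."""
    P, M = objs.shape
    crowd = np.zeros(P)
    for r in np.unique(ranks):
        idx = np.flatnonzero(ranks == r)
        if idx.size <= 2:
            crowd[idx] = np.inf
            continue
        for m in range(M):
            vals = objs[idx, m]
            order = np.argsort(vals, kind="stable")
            lo, hi = vals[order[0]], vals[order[-1]]
            crowd[idx[order[0]]] = crowd[idx[order[-1]]] = np.inf
            if hi > lo:
                gaps = (vals[order[2:]] - vals[order[:-2]]) / (hi - lo)
                crowd[idx[order[1:-1]]] += gaps
    return crowd


def _tournament(ranks, crowd, rng, n_picks):
    a = rng.integers(len(ranks), size=n_picks)
    b = rng.integers(len(ranks), size=n_picks)
    better_b = (ranks[b] < ranks[a]) | ((ranks[b] == ranks[a]) & (crowd[b] > crowd[a]))
    return np.where(better_b, b, a)


class _Archive:
    """Best-ever inertia per cluster count k, plus its genome/assignment."""

    def __init__(self) -> None:
        self.best: dict[int, tuple[float, np.ndarray, np.ndarray]] = {}
        self.improved_at = 0

    def offer(self, gen, bits, assignment, inertia, k) -> None:
        cur = self.best.get(k)
        if cur is None or inertia < cur[0] - 1e-12:
            self.best[k] = (inertia, bits.copy(), assignment.copy())
            self.improved_at = gen

    def front(self, labels: Sequence[str]) -> ParetoFront:
        sols = []
        best_so_far = np.inf
        for k in sorted(self.best):
            inertia, bits, assignment = self.best[k]
            if inertia < best_so_far - 1e-12:  # dominated k's are skipped
                sols.append(MedoidSolution(bits, assignment, inertia, k))
                best_so_far = inertia
            elif not sols:
                sols.append(MedoidSolution(bits, assignment, inertia, k))
                best_so_far = inertia
        return ParetoFront(labels=list(labels), solutions=sols)


def nsga2_run(
    d1: DistanceMatrix, d2: DistanceMatrix, config: EAConfig
) -> ParetoFront:
    """One seeded NSGA-II run; returns its non-dominated archive."""
    if d1.labels != d2.labels:
        raise ValueError("leader and follower matrices have different labels")
    N = d1.n
    P = config.population_size
    pm = config.mutation_prob if config.mutation_prob is not None else 1.0 / N
    k0 = config.init_density if config.init_density is not None else np.sqrt(N)
    rng = np.random.default_rng(config.rng_seed)

    pop = rng.random((P, N)) < (k0 / N)
    for i in range(P):
        pop[i] = repair(pop[i], rng)

    cache: dict[bytes, tuple[np.ndarray, float, int]] = {}
    archive = _Archive()

    def eval_pop(pop_arr, gen):
        objs = np.empty((len(pop_arr), 2))
        for i, bits in enumerate(pop_arr):
            key = bits.tobytes()
            hit = cache.get(key)
            if hit is None:
                assignment, (inertia, k) = evaluate(bits, d1, d2)
                cache[key] = hit = (assignment, inertia, k)
                archive.offer(gen, bits, assignment, inertia, k)
            objs[i] = (hit[1], hit[2])
        return objs

    objs = eval_pop(pop, 0)
    ranks = nondominated_ranks(objs)
    crowd = crowding_distance(objs, ranks)

    for gen in range(1, config.generations + 1):
        parents = _tournament(ranks, crowd, rng, P)
        children = pop[parents].copy()
        # single-point crossover on consecutive parent pairs
        do_cx = rng.random(P // 2) < config.crossover_prob
        if N > 1:
            points = rng.integers(1, N, size=P // 2)
            for p in range(P // 2):
                if do_cx[p]:
                    c = points[p]
                    a, b = 2 * p, 2 * p + 1
                    tail = children[a, c:].copy()
                    children[a, c:] = children[b, c:]
                    children[b, c:] = tail
        flips = rng.random((P, N)) < pm
        children ^= flips
        for i in range(P):
            children[i] = repair(children[i], rng)

        child_objs = eval_pop(children, gen)
        union = np.concatenate([pop, children])
        union_objs = np.concatenate([objs, child_objs])
        u_ranks = nondominated_ranks(union_objs)
        u_crowd = crowding_distance(union_objs, u_ranks)
        # elitist environmental selection: (rank asc, crowding desc)
        order = np.lexsort((-u_crowd, u_ranks))
        keep = order[:P]
        pop, objs = union[keep], union_objs[keep]
        ranks, crowd = u_ranks[keep], u_crowd[keep]

        if (
            config.stagnation_window is not None
            and gen - archive.improved_at >= config.stagnation_window
        ):
            break

    return archive.front(d1.labels)


def merge_fronts(fronts: Sequence[ParetoFront]) -> ParetoFront:
    """Union of fronts with duplicate and dominated solutions removed."""
    if not fronts:
        raise ValueError("no fronts to merge")
    labels = fronts[0].labels
    for f in fronts[1:]:
        if f.labels != labels:
            raise ValueError("fronts come from different instances")
    best: dict[int, MedoidSolution] = {}
    for f in fronts:
        for s in f.solutions:
            cur = best.get(s.n_clusters)
            if cur is None or s.leader_inertia < cur.leader_inertia - 1e-12:
                best[s.n_clusters] = s
    sols = []
    best_so_far = np.inf
    for k in sorted(best):
        s = best[k]
        if s.leader_inertia < best_so_far - 1e-12 or not sols:
            sols.append(s)
            best_so_far = s.leader_inertia
    return ParetoFront(labels=list(labels), solutions=sols)


def run_bilevel(
    d1: DistanceMatrix, d2: DistanceMatrix, config: EAConfig
) -> ParetoFront:
    """Independent NSGA-II runs merged into one Pareto front."""
    fronts = []
    seeds = np.random.SeedSequence(config.rng_seed).spawn(config.independent_runs)
    for ss in seeds:
        run_cfg = EAConfig(
            population_size=config.population_size,
            generations=config.generations,
            crossover_prob=config.crossover_prob,
            mutation_prob=config.mutation_prob,
            independent_runs=1,
            rng_seed=int(ss.generate_state(1)[0] % (2**31)),
            stagnation_window=config.stagnation_window,
            init_density=config.init_density,
        )
        fronts.append(nsga2_run(d1, d2, run_cfg))
    return merge_fronts(fronts)


def select_per_k(
    front: ParetoFront, reference, beta: float = 5.0
) -> dict[int, tuple[MedoidSolution, float]]:
    """For each cluster count on the front, keep the solution with the best
    F-measure against the expert reference (post-processing only; the
    reference never feeds back into the optimization)."""
    from .evaluation import f_beta  # local import: evaluation is downstream

    out: dict[int, tuple[MedoidSolution, float]] = {}
    for s in front.solutions:
        score = f_beta(s.clustering_labels(), front.labels, reference, beta=beta)
        cur = out.get(s.n_clusters)
        if cur is None or score > cur[1]:
            out[s.n_clusters] = (s, score)
    return out
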