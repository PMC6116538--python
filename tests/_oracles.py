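"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a route unrelated to the package's
implementation: exhaustive enumeration, an LP solve, plain breadth-first
search, or a direct objective recomputation.  They are deliberately slow
and only run at tiny problem sizes.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from scipy.optimize import linprog


def bfs_all_pairs(adjacency: dict[int, set[int]], n: int) -> np.ndarray:
    """Plain breadth-first search hop counts; inf for unreachable pairs."""
    out = np.full((n, n), np.inf)
    for src in range(n):
        out[src, src] = 0.0
        frontier = [src]
        depth = 0
        seen = {src}
        while frontier:
            depth += 1
            nxt = []
            for u in frontier:
                for v in adjacency.get(u, ()):  # noqa: B905
                    if v not in seen:
                        seen.add(v)
                        out[src, v] = depth
                        nxt.append(v)
            frontier = nxt
    return out


def exhaustive_follower(bits: np.ndarray, d2: np.ndarray) -> tuple[np.ndarray, float]:
    """Enumerate every feasible assignment x_ij; return the optimum."""
    medoids = np.flatnonzero(bits)
    n = len(bits)
    best_obj = np.inf
    best = None
    for choice in itertools.product(medoids, repeat=n):
        obj = sum(d2[i, j] for i, j in enumerate(choice))
        if obj < best_obj - 1e-12:
            best_obj = obj
            best = np.array(choice)
    return best, float(best_obj)


def lp_follower(bits: np.ndarray, d2: np.ndarray) -> float:
    """Solve the follower assignment LP relaxation (totally unimodular,
    so its optimum equals the integral optimum)."""
    medoids = np.flatnonzero(bits)
    n, k = len(bits), len(medoids)
    c = d2[:, medoids].ravel()  # x[i, m] row-major
    a_eq = np.zeros((n, n * k))
    for i in range(n):
        a_eq[i, i * k : (i + 1) * k] = 1.0
    res = linprog(c, A_eq=a_eq, b_eq=np.ones(n), bounds=(0, 1), method="highs")
    assert res.status == 0
    return float(res.fun)


def exhaustive_kmedoid_front(d1: np.ndarray, d2: np.ndarray,
                             k_max: int | None = None) -> dict[int, float]:
    """Best leader inertia per cluster count by enumerating medoid sets;
    the follower is re-solved by direct per-element scan."""
    n = len(d1)
    k_max = n if k_max is None else k_max
    best: dict[int, float] = {}
    for k in range(1, k_max + 1):
        for meds in itertools.combinations(range(n), k):
            owners = [min(meds, key=lambda j: (d2[i, j], j)) for i in range(n)]
            inertia = sum(d1[i, j] for i, j in enumerate(owners))
            if k not in best or inertia < best[k] - 1e-12:
                best[k] = float(inertia)
    return best


def pareto_staircase(best_per_k: dict[int, float]) -> list[tuple[int, float]]:
    """Non-dominated (k, inertia) points from per-k optima."""
    front: list[tuple[int, float]] = []
    bound = np.inf
    for k in sorted(best_per_k):
        if best_per_k[k] < bound - 1e-12 or not front:
            front.append((k, best_per_k[k]))
            bound = best_per_k[k]
    return front


def brute_ward(values: np.ndarray) -> list[tuple[int, int, float, int]]:
    """Ward agglomeration by direct recomputation of the merge cost.

    Entries are read as squared Euclidean-like distances; the cost of
    merging clusters A, B is computed from the raw matrix with the
    centroid identity D(A,B) = 2|A||B|/(|A|+|B|) * ||c_A - c_B||^2,
    never via the Lance-Williams recurrence the implementation uses.
    """
    n = len(values)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}  # slot -> members
    ids = {i: i for i in range(n)}
    merges = []

    def cost(a: int, b: int) -> float:
        A, B = clusters[a], clusters[b]
        na, nb = len(A), len(B)
        s_ab = values[np.ix_(A, B)].sum()
        s_aa = values[np.ix_(A, A)].sum()
        s_bb = values[np.ix_(B, B)].sum()
        centroid_sq = s_ab / (na * nb) - s_aa / (2 * na * na) - s_bb / (2 * nb * nb)
        return 2.0 * na * nb / (na + nb) * centroid_sq

    for step in range(n - 1):
        slots = sorted(clusters)
        best = None
        for ia, a in enumerate(slots):
            for b in slots[ia + 1 :]:
                c = cost(a, b)
                if best is None or c < best[0] - 1e-12:
                    best = (c, a, b)
        c, a, b = best
        left, right = sorted((ids[a], ids[b]))
        merges.append((left, right, float(c), len(clusters[a]) + len(clusters[b])))
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
        ids[a] = n + step
    return merges


def brute_f_beta(labels, element_ids, classes, beta: float) -> float:
    """F-measure by enumerating every (class, cluster) pair explicitly."""
    beta2 = beta * beta
    clusters: dict[int, set[str]] = {}
    for eid, lab in zip(element_ids, labels):
        clusters.setdefault(int(lab), set()).add(eid)
    total = sum(len(m) for _, m in classes)
    score = 0.0
    for _, members in classes:
        best = 0.0
        for g in clusters.values():
            inter = len(members & g)
            if inter == 0:
                continue
            p = inter / len(g)
            r = inter / len(members)
            f = (1 + beta2) * p * r / (beta2 * p + r)
            best = max(best, f)
        score += len(members) / total * best
    return score


def exact_hypergeom_tail(a: int, M: int, K: int, n: int) -> float:
    """P[X >= a] for X hypergeometric(M, K, n) by direct combinatorial sum."""
    total = comb(M, n)
    return sum(comb(K, x) * comb(M - K, n - x) for x in range(a, min(K, n) + 1)) / total
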