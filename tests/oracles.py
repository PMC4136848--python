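"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive expected results by a different route than
the package implementation (exhaustive enumeration, direct graph path
sums), so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np


def motif_matches_bruteforce(seq: str, n_cys: int, min_first_gap: int,
                             min_inner_gap: int, max_inner_gap: int | None,
                             window_min: int, window_max: int) -> list[tuple[int, ...]]:
    """Every consecutive-cysteine n-tuple tested against all constraints."""
    cys = [i for i, c in enumerate(seq) if c == "C"]
    out = []
    for k in range(len(cys) - n_cys + 1):
        run = tuple(cys[k : k + n_cys])
        gaps = [b - a - 1 for a, b in zip(run, run[1:])]
        if gaps[0] < min_first_gap:
            continue
        if any(g < min_inner_gap for g in gaps[1:]):
            continue
        if max_inner_gap is not None and any(g > max_inner_gap for g in gaps[1:]):
            continue
        span = run[-1] - run[0] + 1
        if not (window_min <= span <= window_max):
            continue
        out.append(run)
    return out


def random_additive_tree(n: int, rng: np.random.Generator):
    """A random unrooted binary tree with positive branch lengths.

    Returns (taxa, distance matrix of exact path lengths, set of
    non-trivial bipartitions canonicalized on the lexicographically
    smallest taxon).
    """
    adjacency: dict[str, list[str]] = {}
    edges: dict[frozenset, float] = {}

    def add_edge(a: str, b: str, w: float) -> None:
        adjacency.setdefault(a, []).append(b)
        adjacency.setdefault(b, []).append(a)
        edges[frozenset((a, b))] = w

    add_edge("t0", "t1", float(rng.uniform(0.1, 1.0)))
    n_internal = 0
    for i in range(2, n):
        split = list(edges)[int(rng.integers(len(edges)))]
        a, b = tuple(split)
        w = edges.pop(split)
        adjacency[a].remove(b)
        adjacency[b].remove(a)
        v = f"v{n_internal}"
        n_internal += 1
        f = float(rng.uniform(0.2, 0.8))
        add_edge(a, v, w * f)
        add_edge(v, b, w * (1.0 - f))
        add_edge(v, f"t{i}", float(rng.uniform(0.1, 1.0)))

    taxa = [f"t{i}" for i in range(n)]
    d = np.zeros((n, n))
    for i, ti in enumerate(taxa):
        dist = {ti: 0.0}
        queue = [ti]
        while queue:
            u = queue.pop()
            for v in adjacency[u]:
                if v not in dist:
                    dist[v] = dist[u] + edges[frozenset((u, v))]
                    queue.append(v)
        for j, tj in enumerate(taxa):
            d[i, j] = dist[tj]

    anchor = min(taxa)
    bips: set[frozenset] = set()
    for e in edges:
        a, b = tuple(e)
        seen = {a, b}
        queue = [a]
        side: set[str] = set()
        while queue:
            u = queue.pop()
            if u.startswith("t"):
                side.add(u)
            for v in adjacency[u]:
                if v not in seen and frozenset((u, v)) != e:
                    seen.add(v)
                    queue.append(v)
        if 1 < len(side) < n - 1:
            bips.add(
                frozenset(side) if anchor not in side
                else frozenset(set(taxa) - side)
            )
    return taxa, d, bips


def global_alignment_bruteforce(a: str, b: str, score, gap_open: float,
                                gap_extend: float) -> float:
    """Best global alignment score by exhaustive enumeration.

    Enumerates all monotone alignments of two short strings recursively,
    charging gap_open for the first position of a gap run and gap_extend
    for each further position.  Exponential — keep inputs tiny.
    """
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def go(i: int, j: int, state: int) -> float:
        # state: 0 none/match, 1 gap-in-b run, 2 gap-in-a run
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            best = max(best, score(a[i], b[j]) + go(i + 1, j + 1, 0))
        if i < len(a):
            cost = gap_extend if state == 1 else gap_open
            best = max(best, -cost + go(i + 1, j, 1))
        if j < len(b):
            cost = gap_extend if state == 2 else gap_open
            best = max(best, -cost + go(i, j + 1, 2))
        return best

    return go(0, 0, 0)


def kmeans_inertia_direct(Z: np.ndarray, labels: np.ndarray) -> float:
    """Total Pearson distance of standardized rows to their cluster's
    normalized mean direction, computed naively."""
    total = 0.0
    for c in np.unique(labels):
        members = Z[labels == c]
        centre = members.mean(axis=0)
        centre = centre / np.linalg.norm(centre)
        total += float(np.sum(1.0 - members @ centre))
    return total
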