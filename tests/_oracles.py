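"""Brute-force oracles, independent of the library's implementations."""

from __future__ import annotations

import itertools
from math import comb

import networkx as nx
import numpy as np


def wilcoxon_perm_p(x, y) -> float:
    """Two-sided permutation p for the rank-sum: enumerate every assignment
    of the pooled values to a group of size len(x)."""
    pooled = list(x) + list(y)
    n1, N = len(x), len(x) + len(y)
    # midranks by direct definition
    order = sorted(range(N), key=lambda i: pooled[i])
    ranks = [0.0] * N
    i = 0
    while i < N:
        j = i
        while j < N and pooled[order[j]] == pooled[order[i]]:
            j += 1
        mid = (i + 1 + j) / 2.0
        for t in range(i, j):
            ranks[order[t]] = mid
        i = j
    w_obs = sum(ranks[:n1])
    mean = n1 * (N + 1) / 2.0
    dev = abs(w_obs - mean)
    hits = total = 0
    for subset in itertools.combinations(range(N), n1):
        w = sum(ranks[i] for i in subset)
        total += 1
        if abs(w - mean) >= dev - 1e-9:
            hits += 1
    return hits / total


def fisher_enum_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing hypergeometric probabilities of all
    tables with the observed margins whose probability <= observed."""
    r1, c1, n = a + b, a + c, a + b + c + d

    def prob(x: int) -> float:
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > n - r1:
            return 0.0
        return comb(r1, x) * comb(n - r1, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(0, min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by direct summation."""
    return sum(
        comb(K, i) * comb(N - K, n - i) / comb(N, n)
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    )


def perturbagen_brute(
    edges: list[tuple[str, str, int]],
    deg_signs: dict[str, int],
    candidate: str,
    max_depth: int = 5,
) -> tuple[int, int]:
    """Perturbagen score via exhaustive simple-path enumeration.

    For every DEG-signed node, enumerate ALL simple directed paths from the
    candidate (length <= max_depth), keep only the minimum-length ones, and
    apply the same ambiguity rule: conflicting sign products exclude the
    target.  Score = max reversal count over modulation direction, ties to
    inhibition (-1).
    """
    g = nx.DiGraph()
    for u, v, s in edges:
        g.add_edge(u, v, sign=s)
    n_inh = n_act = 0
    for target, obs in deg_signs.items():
        if target == candidate or target not in g or candidate not in g:
            continue
        paths = list(
            nx.all_simple_paths(g, candidate, target, cutoff=max_depth)
        )
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        prods = set()
        for p in paths:
            if len(p) != shortest:
                continue
            s = 1
            for u, v in zip(p, p[1:]):
                s *= g[u][v]["sign"]
            prods.add(s)
        if len(prods) != 1:
            continue
        (infl,) = prods
        if infl == obs:  # d = -1 reverses it
            n_inh += 1
        else:  # d = +1 reverses it
            n_act += 1
    if n_act > n_inh:
        return n_act, 1
    return n_inh, -1
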