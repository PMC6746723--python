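"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (enumeration, O(n^2) scans) and shares
no code path with the package internals it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_clusters(genes) -> set[frozenset]:
    """Connected components (size >= 2) of the pairwise-overlap graph,
    via an O(n^2) scan and union-find."""
    parent = {g.gene_id: g.gene_id for g in genes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for a, b in combinations(genes, 2):
        if (a.chromosome == b.chromosome
                and a.start <= b.end and b.start <= a.end):
            union(a.gene_id, b.gene_id)

    comps: dict[str, set] = {}
    for g in genes:
        comps.setdefault(find(g.gene_id), set()).add(g.gene_id)
    return {frozenset(c) for c in comps.values() if len(c) >= 2}


def enumerate_mannwhitney(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration (tie-free data).

    Enumerates every assignment of the pooled ranks to the first sample and
    doubles the smaller tail probability (point mass included), capped at 1.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(x)
    u_obs = sum(rank[v] for v in x) - n1 * (n1 + 1) / 2

    us = []
    for subset in combinations(range(1, len(pooled) + 1), n1):
        us.append(sum(subset) - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2.0 * min(p_low, p_high))


def bh_over_thresholds(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values by minimising over every threshold.

    q_i = min over thresholds t (taken from the observed p-values, t >= p_i)
    of m * t / #{j : p_j <= t}, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    q = np.empty(m)
    for i, pi in enumerate(p):
        cands = [m * t / np.sum(p <= t) for t in p if t >= pi]
        q[i] = min(1.0, min(cands))
    return q
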