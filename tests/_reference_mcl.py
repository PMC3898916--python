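"""Synthetic reference MCL implementation (test oracle).

An independently written, deliberately plain transcription of the Markov
Cluster algorithm used only to cross-check ``amsnet.mcl``: dense loops,
no shared helpers, same mathematical definition (unit self-loops,
column-stochastic flow, expansion by matrix power, entrywise inflation,
pruning with renormalisation, attractor-row cluster read-out with
largest-mass assignment of contested nodes).  It stands in for an external
MCL package and is synthetic in that sense: correctness rests on it being
a separate, simpler derivation from the algorithm's definition, not on a
third-party codebase.
"""

from __future__ import annotations

import numpy as np


def reference_mcl_partition(
    adj: np.ndarray,
    inflation: float,
    expansion: int = 2,
    self_loop: float = 1.0,
    prune_below: float = 1e-6,
    tol: float = 1e-8,
    max_iters: int = 200,
) -> list[frozenset[int]]:
    """Partition node indices 0..n-1 of a weighted adjacency matrix."""
    n = adj.shape[0]
    m = np.array(adj, dtype=float)
    for i in range(n):
        m[i, i] = self_loop
    m = m / m.sum(axis=0)

    for _ in range(max_iters):
        expanded = np.linalg.matrix_power(m, expansion)
        inflated = expanded ** inflation
        inflated = inflated / inflated.sum(axis=0)
        inflated[inflated < prune_below] = 0.0
        inflated = inflated / inflated.sum(axis=0)
        if np.max(np.abs(inflated - m)) < tol:
            m = inflated
            break
        m = inflated

    attractors = [i for i in range(n) if m[i, i] > 0.0]
    if not attractors:
        return [frozenset(range(n))]

    # merge attractors that reach one another into systems (union-find)
    parent = {a: a for a in attractors}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in attractors:
        for b in attractors:
            if a < b and (m[a, b] > 0.0 or m[b, a] > 0.0):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    systems: dict[int, list[int]] = {}
    for a in attractors:
        systems.setdefault(find(a), []).append(a)
    roots = sorted(systems)

    # provisional membership counts (nodes touched by each system's rows)
    touched = {
        r: {j for a in systems[r] for j in range(n) if m[a, j] > 0.0} for r in roots
    }

    clusters: dict[int, set[int]] = {r: set() for r in roots}
    for j in range(n):
        masses = {r: sum(m[a, j] for a in systems[r]) for r in roots}
        best_mass = max(masses.values())
        if best_mass > 0.0:
            tied = [r for r in roots if masses[r] == best_mass]
            if len(tied) > 1:
                biggest = max(len(touched[r]) for r in tied)
                tied = [r for r in tied if len(touched[r]) == biggest]
            clusters[tied[0]].add(j)
        else:
            row = int(np.argmax(m[:, j]))
            home = next((r for r in roots if row in systems[r]), None)
            if home is None:
                clusters[j] = {j}
            else:
                clusters[home].add(j)
    return [frozenset(c) for c in clusters.values() if c]
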