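"""Independent brute-force oracles used to validate the graph metrics.

These deliberately avoid the package's own code paths: clustering by
explicit triangle enumeration, distances by Floyd-Warshall, local
efficiency by per-node subgraph recomputation, and modularity by
exhaustive search over set partitions.
"""

from __future__ import annotations

import itertools

import numpy as np


def oracle_clustering(adj: np.ndarray) -> float:
    n = adj.shape[0]
    coeffs = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        k = len(nb)
        if k < 2:
            coeffs.append(0.0)
            continue
        links = sum(
            1 for a, b in itertools.combinations(nb, 2) if adj[a, b]
        )
        coeffs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(coeffs))


def oracle_distances(adj: np.ndarray) -> np.ndarray:
    """Floyd-Warshall all-pairs shortest paths."""
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def oracle_inv_distance_sum(adj: np.ndarray) -> float:
    d = oracle_distances(adj)
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total


def oracle_path_length(adj: np.ndarray) -> float:
    n = adj.shape[0]
    s = oracle_inv_distance_sum(adj)
    return n * (n - 1) / s


def oracle_global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    return oracle_inv_distance_sum(adj) / (n * (n - 1))


def oracle_local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    effs = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        if len(nb) < 2:
            effs.append(0.0)
            continue
        sub = adj[np.ix_(nb, nb)]
        effs.append(oracle_global_efficiency(sub))
    return float(np.mean(effs))


def oracle_modularity(adj: np.ndarray, labels) -> float:
    labels = np.asarray(labels)
    m2 = adj.sum()
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        e_cc = adj[np.ix_(mask, mask)].sum() / m2
        a_c = adj[mask].sum() / m2
        q += e_cc - a_c**2
    return q


def set_partitions(n: int):
    """All set partitions of range(n) as restricted-growth label arrays."""
    labels = np.zeros(n, dtype=int)

    def rec(i, max_label):
        if i == n:
            yield labels.copy()
            return
        for lab in range(max_label + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    yield from rec(1, 0)


def oracle_best_partition(adj: np.ndarray) -> tuple[np.ndarray, float]:
    """Exhaustive maximum-modularity partition (feasible for n <= ~10)."""
    best_q, best = -np.inf, None
    for labels in set_partitions(adj.shape[0]):
        q = oracle_modularity(adj, labels)
        if q > best_q:
            best_q, best = q, labels
    return best, best_q
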