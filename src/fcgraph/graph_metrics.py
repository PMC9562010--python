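"""Small-world and efficiency metrics on binary undirected graphs.

Implements the global topological measures used throughout the analysis:
clustering coefficient (Cp), characteristic path length (Lp, harmonic-mean
convention so fragmented sparse graphs stay finite), global and local
efficiency (Eglob, Eloc), degree-preserving Maslov-Sneppen rewiring for
random null models, the normalised ratios gamma = Cp/Cp_rand,
lambda = Lp/Lp_rand and small-worldness sigma = gamma/lambda, and the
trapezoid-rule area under a metric's curve over the sparsity grid (AUC),
which summarises a metric into a single threshold-free scalar per subject.

A network is considered small-world when gamma > 1 together with
lambda close to 1, equivalently sigma = gamma/lambda > 1.

The rewiring inner loop is JIT-compiled with numba; all randomness is drawn
in advance from a numpy Generator so results are reproducible bit-for-bit
regardless of compilation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .network_construction import BinaryGraphStack

logger = logging.getLogger("fcgraph")

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@dataclass
class MetricCurve:
    """A metric's values over the sparsity grid plus its AUC."""

    metric_name: str
    sparsities: np.ndarray
    values: np.ndarray
    auc: float

    @classmethod
    def from_points(
        cls, name: str, sparsities: np.ndarray, values: np.ndarray
    ) -> "MetricCurve":
        s = np.asarray(sparsities, dtype=float)
        v = np.asarray(values, dtype=float)
        curve = cls(name, s, v, auc=np.nan)
        curve.auc = auc_over_sparsity(curve)
        return curve


@dataclass
class SmallWorldSummary:
    """Normalised small-world ratios for one graph against rewired nulls."""

    cp: float
    lp: float
    cp_rand: float
    lp_rand: float
    gamma: float
    lam: float
    sigma: float
    n_null: int
    null_seed: int


@dataclass
class RewireResult:
    adjacency: np.ndarray
    n_swaps: int
    unchanged: bool


def _validate_adjacency(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(np.diag(adj) != 0):
        raise ValueError("adjacency must have a zero diagonal (simple graph)")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric (undirected graph)")
    return adj.astype(np.uint8, copy=False)


def _distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths; inf for disconnected pairs."""
    if adj.sum() == 0:
        d = np.full(adj.shape, np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    return shortest_path(csr_matrix(adj), method="D", unweighted=True,
                         directed=False)


def clustering_coefficient(adj: np.ndarray) -> float:
    """Mean local clustering: 2 * (edges among neighbours) / (k(k-1)).

    Nodes with degree < 2 contribute 0 to the mean.
    """
    adj = _validate_adjacency(adj)
    a = adj.astype(float)
    deg = a.sum(axis=1)
    triangles = ((a @ a) * a).sum(axis=1) / 2.0  # = diag(A^3)/2
    denom = deg * (deg - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return float(c.mean())


@njit(cache=True)
def _bfs_inv_sum_csr(indptr, indices, n):  # pragma: no cover - jitted
    """Sum over ordered pairs of 1/d via BFS from every source."""
    total = 0.0
    dist = np.empty(n, np.int32)
    queue = np.empty(n, np.int32)
    for src in range(n):
        for i in range(n):
            dist[i] = -1
        dist[src] = 0
        queue[0] = src
        head, tail = 0, 1
        while head < tail:
            u = queue[head]
            head += 1
            du = dist[u]
            for ptr in range(indptr[u], indptr[u + 1]):
                v = indices[ptr]
                if dist[v] < 0:
                    dist[v] = du + 1
                    queue[tail] = v
                    tail += 1
        for i in range(n):
            if i != src and dist[i] > 0:
                total += 1.0 / dist[i]
    return total


@njit(cache=True)
def _local_eff_kernel(adj, n):  # pragma: no cover - jitted
    total = 0.0
    nb = np.empty(n, np.int32)
    dist = np.empty(n, np.int32)
    queue = np.empty(n, np.int32)
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j]:
                nb[k] = j
                k += 1
        if k < 2:
            continue
        inv = 0.0
        for s in range(k):
            for t in range(k):
                dist[t] = -1
            dist[s] = 0
            queue[0] = s
            head, tail = 0, 1
            while head < tail:
                u = queue[head]
                head += 1
                du = dist[u]
                nu = nb[u]
                for t in range(k):
                    if dist[t] < 0 and adj[nu, nb[t]]:
                        dist[t] = du + 1
                        queue[tail] = t
                        tail += 1
            for t in range(k):
                if t != s and dist[t] > 0:
                    inv += 1.0 / dist[t]
        total += inv / (k * (k - 1))
    return total / n


def _to_csr_arrays(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = np.nonzero(adj)
    indptr = np.zeros(adj.shape[0] + 1, dtype=np.int64)
    np.cumsum(np.bincount(rows, minlength=adj.shape[0]), out=indptr[1:])
    return indptr, cols.astype(np.int64)


def _inv_distance_sum(adj: np.ndarray) -> float:
    if _HAVE_NUMBA:
        indptr, indices = _to_csr_arrays(adj)
        return float(_bfs_inv_sum_csr(indptr, indices, adj.shape[0]))
    d = _distances(adj)
    n = adj.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum())


def characteristic_path_length(adj: np.ndarray) -> float:
    """Harmonic-mean path length: N(N-1) / sum over pairs of 1/d_ij.

    Disconnected pairs contribute 0 to the sum, so fragmented graphs remain
    finite; only an edgeless graph is rejected.
    """
    adj = _validate_adjacency(adj)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("path length needs at least 2 nodes")
    total = _inv_distance_sum(adj)
    if total == 0.0:
        raise ValueError(
            "edgeless graph: no finite paths (network density too low)"
        )
    return n * (n - 1) / total


def global_efficiency(adj: np.ndarray) -> float:
    """Mean inverse shortest-path length over all ordered pairs, in [0, 1]."""
    adj = _validate_adjacency(adj)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    return _inv_distance_sum(adj) / (n * (n - 1))


def local_efficiency(adj: np.ndarray) -> float:
    """Mean over nodes of the global efficiency of each neighbour subgraph.

    The node itself is excluded from its neighbour subgraph; nodes with
    fewer than 2 neighbours contribute 0.
    """
    adj = _validate_adjacency(adj)
    n = adj.shape[0]
    if _HAVE_NUMBA:
        return float(_local_eff_kernel(np.ascontiguousarray(adj), n))
    eff = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        if nb.size < 2:
            continue
        sub = adj[np.ix_(nb, nb)]
        eff[i] = _inv_distance_sum(sub) / (nb.size * (nb.size - 1))
    return float(eff.mean())


@njit(cache=True)
def _swap_loop(adj, edges, pick1, pick2, flip):  # pragma: no cover - jitted
    n_success = 0
    for t in range(pick1.shape[0]):
        i1 = pick1[t]
        i2 = pick2[t]
        if i1 == i2:
            continue
        a = edges[i1, 0]
        b = edges[i1, 1]
        c = edges[i2, 0]
        d = edges[i2, 1]
        if flip[t]:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[c, d] = 0
        adj[d, c] = 0
        adj[a, d] = 1
        adj[d, a] = 1
        adj[c, b] = 1
        adj[b, c] = 1
        edges[i1, 0] = a
        edges[i1, 1] = d
        edges[i2, 0] = c
        edges[i2, 1] = b
        n_success += 1
    return n_success


def degree_preserving_rewire(
    adj: np.ndarray,
    n_swap_factor: float = 10,
    seed: int | np.random.SeedSequence = 0,
) -> RewireResult:
    """Maslov-Sneppen double-edge swaps preserving every node's degree.

    ``n_swap_factor * |E|`` swap attempts are made; a proposal
    (a-b, c-d) -> (a-d, c-b) is rejected whenever it would create a
    self-loop or a multi-edge.  Graphs admitting no valid swap (e.g.
    complete graphs) are returned unchanged with ``unchanged=True``.
    Deterministic given the seed.
    """
    adj = _validate_adjacency(adj).copy()
    iu, ju = np.nonzero(np.triu(adj, k=1))
    m = iu.size
    if m < 2:
        raise ValueError("rewiring needs at least 2 edges")
    edges = np.column_stack([iu, ju]).astype(np.int64)
    n_attempts = int(round(n_swap_factor * m))
    if n_attempts == 0:
        return RewireResult(adj, 0, True)
    rng = np.random.default_rng(seed)
    pick1 = rng.integers(0, m, size=n_attempts)
    pick2 = rng.integers(0, m, size=n_attempts)
    flip = rng.integers(0, 2, size=n_attempts).astype(np.uint8)
    n_success = int(_swap_loop(adj, edges, pick1, pick2, flip))
    return RewireResult(adj, n_success, n_success == 0)


def small_world_normalize(
    adj: np.ndarray,
    n_null: int = 100,
    seed: int = 0,
    n_swap_factor: float = 10,
) -> SmallWorldSummary:
    """Normalise Cp and Lp against degree-preserving random nulls.

    ``Cp_rand`` and ``Lp_rand`` are means over ``n_null`` rewired graphs
    (metrics averaged first, ratios formed after); per-null seeds are
    spawned deterministically from ``seed``.  Nulls whose clustering is
    exactly 0 are excluded with a warning; if every null is excluded an
    error is raised.
    """
    adj = _validate_adjacency(adj)
    if int(adj.sum()) // 2 < 2:
        raise ValueError("small-world normalisation needs at least 2 edges")
    cp = clustering_coefficient(adj)
    lp = characteristic_path_length(adj)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_null)
    cps, lps = [], []
    for child in children:
        null = degree_preserving_rewire(adj, n_swap_factor, child).adjacency
        c = clustering_coefficient(null)
        if c == 0.0:
            logger.warning("null graph with zero clustering excluded")
            continue
        cps.append(c)
        lps.append(characteristic_path_length(null))
    if not cps:
        raise ValueError("every null graph had zero clustering")
    cp_rand = float(np.mean(cps))
    lp_rand = float(np.mean(lps))
    gamma = cp / cp_rand
    lam = lp / lp_rand
    return SmallWorldSummary(
        cp=cp, lp=lp, cp_rand=cp_rand, lp_rand=lp_rand,
        gamma=gamma, lam=lam, sigma=gamma / lam,
        n_null=len(cps), null_seed=seed,
    )


def auc_over_sparsity(curve: MetricCurve) -> float:
    """Trapezoid-rule area under a metric curve over the sparsity grid."""
    s = np.asarray(curve.sparsities, dtype=float)
    v = np.asarray(curve.values, dtype=float)
    if s.size < 2:
        raise ValueError("AUC needs at least 2 grid points")
    if np.any(np.diff(s) <= 0):
        raise ValueError("sparsity grid must be strictly increasing")
    return float(np.trapezoid(v, s))


RAW_METRICS = ("Cp", "Lp", "Eglob", "Eloc")
NORMALIZED_METRICS = ("gamma", "lambda", "sigma")


def compute_metric_curves(
    stack: BinaryGraphStack,
    n_null: int = 100,
    seed: int = 0,
    n_swap_factor: float = 10,
) -> dict[str, MetricCurve]:
    """All global metrics of one subject's graph stack across the grid.

    Returns curves for Cp, Lp, Eglob, Eloc and, when ``n_null > 0``, the
    normalised gamma/lambda/sigma.  With ``n_null = 0`` normalisation is
    skipped with an explicit warning and raw metrics are still produced.
    Per-sparsity null seeds are spawned from ``seed``.
    """
    sparsities = stack.grid.values
    raw: dict[str, list[float]] = {m: [] for m in RAW_METRICS}
    norm: dict[str, list[float]] = {m: [] for m in NORMALIZED_METRICS}
    ss = np.random.SeedSequence(seed)
    level_seeds = ss.spawn(len(stack.adjacency))
    for adj, child in zip(stack.adjacency, level_seeds):
        raw["Cp"].append(clustering_coefficient(adj))
        raw["Lp"].append(characteristic_path_length(adj))
        raw["Eglob"].append(global_efficiency(adj))
        raw["Eloc"].append(local_efficiency(adj))
        if n_null > 0:
            level_seed = int(child.generate_state(1)[0] % (2**31))
            sw = small_world_normalize(adj, n_null, level_seed, n_swap_factor)
            norm["gamma"].append(sw.gamma)
            norm["lambda"].append(sw.lam)
            norm["sigma"].append(sw.sigma)
    curves = {
        name: MetricCurve.from_points(name, sparsities, vals)
        for name, vals in raw.items()
    }
    if n_null > 0:
        for name, vals in norm.items():
            curves[name] = MetricCurve.from_points(name, sparsities, vals)
    else:
        logger.warning(
            "n_null=0: small-world normalisation skipped; "
            "raw metrics only"
        )
    return curves
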