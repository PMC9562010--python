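"""Functional connectivity matrices and sparsity-thresholded binary graphs.

Per-subject whole-brain networks are built from ROI time series in three
steps: (1) pairwise Pearson correlation, (2) Fisher r-to-z transform to
improve normality, (3) binarisation at a grid of sparsity levels, keeping at
each level the strongest strictly positive z edges so every subject's graph
has the same number of edges at a given sparsity.  Negative and zero
correlations are never admitted as edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .signal_cleaning import RoiTimeSeries

#: Clamp for |r| before atanh so duplicated ROIs yield a large finite z.
R_CLAMP = 1.0 - 1e-12


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI Pearson r and Fisher z values.

    ``r`` has unit diagonal; ``z = atanh(r)`` off-diagonal with the diagonal
    set to 0 (self-correlations carry no information for thresholding).
    ``clamped_pairs`` records index pairs whose |r| hit the clamp.
    """

    r: np.ndarray
    z: np.ndarray
    roi_ids: list[str]
    clamped_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_rois(self) -> int:
        return self.r.shape[0]


@dataclass
class SparsityGrid:
    """Ordered sparsity levels at which networks are binarised.

    The default grid spans 0.05 to 0.40 over 18 evenly spaced levels.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("sparsity grid must be a non-empty 1-D array")
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("sparsity levels must be strictly increasing")
        if np.any((self.values <= 0) | (self.values >= 1)):
            raise ValueError("sparsity levels must lie in (0, 1)")

    def __len__(self) -> int:
        return self.values.size

    @classmethod
    def default(cls) -> "SparsityGrid":
        return cls(np.linspace(0.05, 0.40, 18))


@dataclass
class BinaryGraphStack:
    """Per-sparsity binary undirected adjacency matrices for one subject.

    Edge sets are nested across the grid (a lower sparsity level's edges are
    a subset of a higher one's) because all levels share a single edge
    ranking.  ``warnings`` records levels where fewer positive edges existed
    than the target count.
    """

    grid: SparsityGrid
    adjacency: list[np.ndarray]
    edge_counts: list[int]
    roi_ids: list[str]
    warnings: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(zip(self.grid.values, self.adjacency))


def pearson_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pairwise Pearson correlations with Fisher r-to-z transform.

    Raises
    ------
    ValueError
        On fewer than 3 frames, non-finite input, or a zero-variance ROI
        (named in the message).
    """
    x = ts.values
    if x.shape[0] < 3:
        raise ValueError("Pearson correlation needs at least 3 frames")
    if not np.all(np.isfinite(x)):
        raise ValueError("time series contains non-finite values")
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(ts.roi_ids[i] for i in dead[:5])
        raise ValueError(f"zero-variance ROI(s): {names}")
    r = np.corrcoef(x, rowvar=False)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    off = ~np.eye(r.shape[0], dtype=bool)
    clamped = off & (np.abs(r) >= R_CLAMP)
    z = np.zeros_like(r)
    z[off] = np.arctanh(np.clip(r[off], -R_CLAMP, R_CLAMP))
    iu = np.triu_indices_from(r, k=1)
    pairs = [
        (int(i), int(j))
        for i, j in zip(*iu)
        if clamped[i, j]
    ]
    return ConnectivityMatrix(r=r, z=z, roi_ids=list(ts.roi_ids),
                              clamped_pairs=pairs)


def fisher_z(r):
    """Fisher r-to-z transform, ``z = atanh(r)``, with |r| clamped just
    below 1 so perfectly correlated pairs map to a large finite value."""
    r = np.clip(np.asarray(r, dtype=float), -R_CLAMP, R_CLAMP)
    return np.arctanh(r)


def target_edge_count(sparsity: float, n_rois: int) -> int:
    """Edges targeted at a sparsity level: round-half-up of S*N(N-1)/2."""
    return int(math.floor(sparsity * n_rois * (n_rois - 1) / 2.0 + 0.5))


def sparsity_binarize(
    cm: ConnectivityMatrix, grid: SparsityGrid | None = None
) -> BinaryGraphStack:
    """Binarise a connectivity matrix at every sparsity level of the grid.

    At level S the target edge count is ``k = round(S * N(N-1)/2)`` and the
    k largest strictly positive z edges are kept.  Ties on z are broken by
    ascending (i, j) lexicographic index for reproducibility.  If fewer than
    k positive edges exist, all positive edges are kept and a warning is
    recorded; degenerate matrices yield empty graphs, never failures.
    """
    if grid is None:
        grid = SparsityGrid.default()
    n = cm.n_rois
    if n < 2:
        raise ValueError("need at least 2 ROIs to build a network")
    iu, ju = np.triu_indices(n, k=1)
    zvals = cm.z[iu, ju]
    pos = zvals > 0
    # descending z, ties by ascending (i, j): lexsort keys are last-primary
    order = np.lexsort((ju[pos], iu[pos], -zvals[pos]))
    pi, pj = iu[pos][order], ju[pos][order]
    n_pos = pi.size

    adjacency: list[np.ndarray] = []
    counts: list[int] = []
    warnings: list[str] = []
    for s in grid.values:
        k = target_edge_count(float(s), n)
        if n_pos < k:
            warnings.append(
                f"sparsity {s:.4f}: only {n_pos} positive edges available "
                f"for target {k}"
            )
        kk = min(k, n_pos)
        adj = np.zeros((n, n), dtype=np.uint8)
        adj[pi[:kk], pj[:kk]] = 1
        adj[pj[:kk], pi[:kk]] = 1
        adjacency.append(adj)
        counts.append(int(kk))
    if n_pos == 0:
        warnings.append("no positive correlations: all graphs are empty")
    return BinaryGraphStack(
        grid=grid,
        adjacency=adjacency,
        edge_counts=counts,
        roi_ids=list(cm.roi_ids),
        warnings=warnings,
    )
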