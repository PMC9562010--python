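"""Modular (sub-network) connectivity analysis.

Two complementary views of mesoscale organisation:

* **A-priori six-module strengths** — the brain is partitioned into six
  named functional systems (cingulo-opercular, fronto-parietal, default
  mode, sensorimotor, occipital, cerebellum) and the averaged Fisher-z
  connectivity strength is computed within and between modules at every
  sparsity level, then summarised by the trapezoid AUC.  Group comparisons
  downstream use these a-priori blocks.
* **Data-driven modularity** — Newman's spectral (leading-eigenvector)
  optimisation with Kernighan-Lin-style fine-tuning, reported per
  subject/threshold as the modularity score Q and the number of modules
  found.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_metrics import _validate_adjacency
from .network_construction import BinaryGraphStack, ConnectivityMatrix

#: The six a-priori functional systems, in canonical order.
DEFAULT_MODULE_LABELS = (
    "cingulo-opercular",
    "fronto-parietal",
    "default",
    "sensorimotor",
    "occipital",
    "cerebellum",
)

#: Default ROI counts per system for the 160-ROI functional parcellation.
DEFAULT_MODULE_SIZES = (32, 21, 34, 33, 22, 18)


@dataclass
class ModulePartition:
    """Assignment of every ROI to exactly one named module."""

    assignments: dict[str, str]
    module_labels: tuple[str, ...] = DEFAULT_MODULE_LABELS

    def __post_init__(self) -> None:
        labels_present = set(self.assignments.values())
        unknown = labels_present - set(self.module_labels)
        if unknown:
            raise ValueError(f"unknown module label(s): {sorted(unknown)}")
        if len(labels_present) < 2:
            raise ValueError("a partition needs at least 2 modules")

    @classmethod
    def from_sizes(
        cls,
        roi_ids: list[str],
        sizes: tuple[int, ...] = DEFAULT_MODULE_SIZES,
        labels: tuple[str, ...] = DEFAULT_MODULE_LABELS,
    ) -> "ModulePartition":
        if len(sizes) != len(labels):
            raise ValueError("sizes and labels must have equal length")
        if sum(sizes) != len(roi_ids):
            raise ValueError(
                f"module sizes sum to {sum(sizes)} but there are "
                f"{len(roi_ids)} ROIs"
            )
        assignments: dict[str, str] = {}
        pos = 0
        for label, size in zip(labels, sizes):
            for rid in roi_ids[pos:pos + size]:
                assignments[rid] = label
            pos += size
        return cls(assignments, labels)

    def indices(self, label: str, roi_ids: list[str]) -> np.ndarray:
        """Column indices of the ROIs belonging to one module."""
        return np.array(
            [i for i, rid in enumerate(roi_ids)
             if self.assignments.get(rid) == label],
            dtype=int,
        )

    def blocks(self) -> list[tuple[str, str]]:
        """All unordered module pairs (A, B) with A <= B in label order."""
        labs = self.module_labels
        return [
            (labs[i], labs[j])
            for i in range(len(labs))
            for j in range(i, len(labs))
        ]


@dataclass
class BlockStrength:
    """Averaged connectivity strength of one module block over the grid."""

    block: tuple[str, str]
    sparsities: np.ndarray
    strength: np.ndarray
    auc: float
    denominator: str = "all_pairs"


@dataclass
class ModularityResult:
    """Data-driven community structure of one binary graph."""

    labels: np.ndarray  # per-node community index
    q: float
    n_modules: int


def _block_pair_indices(
    partition: ModulePartition,
    block: tuple[str, str],
    roi_ids: list[str],
) -> tuple[np.ndarray, np.ndarray]:
    a, b = block
    ia = partition.indices(a, roi_ids)
    ib = partition.indices(b, roi_ids)
    missing = set(partition.assignments) ^ set(roi_ids)
    if set(roi_ids) - set(partition.assignments):
        raise ValueError(
            f"partition does not cover ROIs: "
            f"{sorted(set(roi_ids) - set(partition.assignments))[:5]}"
        )
    del missing
    if a == b:
        if ia.size < 2:
            raise ValueError(
                f"within-module block {a!r} has fewer than 2 ROIs (no pairs)"
            )
        ii, jj = np.triu_indices(ia.size, k=1)
        return ia[ii], ia[jj]
    return np.repeat(ia, ib.size), np.tile(ib, ia.size)


def block_strength_curve(
    cm: ConnectivityMatrix,
    stack: BinaryGraphStack,
    partition: ModulePartition,
    block: tuple[str, str],
    denominator: str = "all_pairs",
) -> BlockStrength:
    """Averaged Fisher-z strength of a module block at each sparsity.

    At a sparsity level the strength is the sum of z over the block's ROI
    pairs whose edge survives binarisation, divided by either the total
    number of ROI pairs in the block (``all_pairs``, the default, making
    strength monotone in sparsity and comparable across subjects) or by the
    number of retained edges (``retained``; 0 retained edges give 0).
    """
    if denominator not in ("all_pairs", "retained"):
        raise ValueError("denominator must be 'all_pairs' or 'retained'")
    rows, cols = _block_pair_indices(partition, tuple(sorted(block)),
                                     cm.roi_ids)
    zvals = cm.z[rows, cols]
    strengths = []
    for adj in stack.adjacency:
        present = adj[rows, cols].astype(bool)
        if denominator == "all_pairs":
            strengths.append(float(zvals[present].sum() / rows.size))
        else:
            strengths.append(
                float(zvals[present].mean()) if present.any() else 0.0
            )
    # single-level stacks carry no area; AUC needs >= 2 grid points
    auc = (
        float(np.trapezoid(strengths, stack.grid.values))
        if len(stack.grid) >= 2
        else float("nan")
    )
    return BlockStrength(
        block=tuple(sorted(block)),
        sparsities=stack.grid.values,
        strength=np.asarray(strengths),
        auc=auc,
        denominator=denominator,
    )


def all_block_strengths(
    cm: ConnectivityMatrix,
    stack: BinaryGraphStack,
    partition: ModulePartition,
    denominator: str = "all_pairs",
) -> dict[tuple[str, str], BlockStrength]:
    """Block strengths for every within- and between-module pair."""
    return {
        blk: block_strength_curve(cm, stack, partition, blk, denominator)
        for blk in partition.blocks()
    }


# ---------------------------------------------------------------------------
# Data-driven spectral modularity (Newman leading-eigenvector bisection)
# ---------------------------------------------------------------------------

_EIG_TOL = 1e-9
_Q_TOL = 1e-12


def modularity_score(adj: np.ndarray, labels: np.ndarray) -> float:
    """Direct evaluation of Q = sum_c (e_cc - a_c^2) for a partition."""
    adj = _validate_adjacency(adj).astype(float)
    m2 = adj.sum()  # = 2m
    if m2 == 0:
        raise ValueError("modularity is undefined for an edgeless graph")
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        e_cc = adj[np.ix_(mask, mask)].sum() / m2
        a_c = adj[mask].sum() / m2
        q += e_cc - a_c**2
    return q


def _fine_tune(bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin-style refinement of a +/-1 split vector.

    Repeated passes: each pass moves every node exactly once (always the
    move with the largest gain, even if negative), keeps the best
    configuration seen, and repeats while a pass improves s^T B s.
    """
    n = s.size
    best = s.copy()
    best_val = best @ bg @ best
    while True:
        s_work = best.copy()
        val = best_val
        movable = np.ones(n, dtype=bool)
        pass_best = best_val
        pass_best_state = best.copy()
        for _ in range(n):
            # gain of flipping i: -4 s_i (B[i]@s - B_ii s_i)
            row = bg @ s_work
            gains = -4.0 * s_work * (row - np.diag(bg) * s_work)
            gains[~movable] = -np.inf
            i = int(np.argmax(gains))
            s_work[i] = -s_work[i]
            movable[i] = False
            val += gains[i]
            if val > pass_best:
                pass_best = val
                pass_best_state = s_work.copy()
        if pass_best > best_val + _Q_TOL:
            best_val = pass_best
            best = pass_best_state
        else:
            return best


def spectral_modularity(adj: np.ndarray) -> ModularityResult:
    """Newman spectral community detection on a binary undirected graph.

    Recursively bisects by the leading eigenvector of the (generalised)
    modularity matrix, refines each split with Kernighan-Lin-style moves,
    and stops a branch when the leading eigenvalue is non-positive or the
    split no longer increases Q.
    """
    adj = _validate_adjacency(adj).astype(float)
    n = adj.shape[0]
    m2 = adj.sum()
    if m2 == 0:
        raise ValueError("modularity is undefined for an edgeless graph")
    deg = adj.sum(axis=1)
    b_full = adj - np.outer(deg, deg) / m2

    labels = np.zeros(n, dtype=int)
    next_label = 1
    stack: list[np.ndarray] = [np.arange(n)]
    while stack:
        group = stack.pop()
        if group.size < 2:
            continue
        bsub = b_full[np.ix_(group, group)]
        bg = bsub - np.diag(bsub.sum(axis=1))
        evals, evecs = np.linalg.eigh(bg)
        if evals[-1] <= _EIG_TOL:
            continue
        s = np.where(evecs[:, -1] >= 0, 1.0, -1.0)
        if np.all(s == s[0]):
            continue
        s = _fine_tune(bg, s)
        gain = s @ bg @ s  # proportional to delta Q (factor 1/(4m))
        if gain <= _Q_TOL or np.all(s == s[0]):
            continue
        g_pos = group[s > 0]
        g_neg = group[s < 0]
        labels[g_neg] = next_label
        next_label += 1
        stack.append(g_pos)
        stack.append(g_neg)

    # compact label ids
    _, labels = np.unique(labels, return_inverse=True)
    return ModularityResult(
        labels=labels,
        q=modularity_score(adj.astype(np.uint8), labels),
        n_modules=int(labels.max()) + 1,
    )
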