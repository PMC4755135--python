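"""Winner-take-all back-projection of columns onto the whole brain.

Every brain voxel is assigned to the column whose retained seed voxels
connect to it most strongly (mean connection probability over the column's
seed voxels), provided that maximum reaches the probability floor
(P >= 3e-4); voxels below the floor from every column stay unlabeled (0).
Exact ties are resolved to 0 as well — no evidence, no claim — and reported
in a tie mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .segmentation import UNASSIGNED, ClusterResult
from .tracking import ConnectivityMatrix

__all__ = ["BackProjection", "backproject"]


@dataclass
class BackProjection:
    """Whole-brain column label map plus per-column strength volumes."""

    labels: np.ndarray  # int volume, 0 = unassigned
    strengths: np.ndarray  # (k, *grid) mean connection probability per column
    cluster_ids: Tuple[int, ...]
    tie_mask: np.ndarray
    threshold: float


def backproject(
    cluster_result: ClusterResult,
    cm: ConnectivityMatrix,
    prob_threshold: float = 0.0003,
    reduce: str = "mean",
    brain_mask: Optional[np.ndarray] = None,
) -> BackProjection:
    """Label each brain voxel with its most strongly connected column.

    ``reduce`` selects how a column's strength at a voxel is summarized over
    its retained seed voxels ('mean' by default, 'max' available). The label
    is the argmax column when the winning strength is >= ``prob_threshold``,
    else 0.
    """
    if reduce not in ("mean", "max"):
        raise ValueError("reduce must be 'mean' or 'max'")
    clusters = [
        c
        for c in sorted(cluster_result.column_identity)
        if cluster_result.column_identity[c] != UNASSIGNED
    ]
    if not clusters:
        clusters = sorted(c for c in np.unique(cluster_result.labels) if c > 0)
    probs = cm.probabilities()

    shape = cm.grid_shape
    strengths = np.zeros((len(clusters),) + tuple(shape))
    for i, c in enumerate(clusters):
        sel = (cluster_result.labels == c) & cluster_result.retained
        if not sel.any():
            continue
        sub = probs[np.flatnonzero(sel)]
        if reduce == "mean":
            vec = np.asarray(sub.mean(axis=0)).ravel()
        else:
            vec = np.asarray(sub.max(axis=0).todense()).ravel()
        strengths[i] = vec.reshape(shape)

    best = strengths.max(axis=0)
    winner = strengths.argmax(axis=0)
    n_best = (strengths >= best[None] - 1e-15).sum(axis=0)
    tie = (n_best > 1) & (best >= prob_threshold)

    labels = np.zeros(shape, dtype=np.int16)
    assign = (best >= prob_threshold) & ~tie
    cluster_arr = np.asarray(clusters, dtype=np.int16)
    labels[assign] = cluster_arr[winner[assign]]
    if brain_mask is not None:
        labels[~brain_mask] = 0
    return BackProjection(
        labels=labels,
        strengths=strengths,
        cluster_ids=tuple(int(c) for c in clusters),
        tie_mask=tie,
        threshold=prob_threshold,
    )
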