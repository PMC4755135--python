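"""Template-space group probability maps.

Per-subject label or probability volumes are resampled onto the template
grid using the subject's stored affine (nearest-neighbour for labels, linear
for probabilities), then combined into voxelwise fraction-of-cohort maps.
The population threshold follows the study convention of keeping voxels
present in more than 30% of subjects (a >35% variant is used for display in
some figures; both are reachable through the ``threshold`` argument).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = ["GroupMap", "to_template", "group_probability_map"]


@dataclass
class GroupMap:
    """Voxelwise fraction of the cohort positive at each template voxel."""

    values: np.ndarray
    n_subjects: int
    threshold: float = 0.30

    def support(self) -> np.ndarray:
        """Voxels present in more than ``threshold`` of the population."""
        return self.values > self.threshold


def to_template(
    subject_map: np.ndarray,
    subject_affine: np.ndarray,
    template_affine: np.ndarray,
    template_shape: Tuple[int, int, int],
    order: int = 0,
) -> np.ndarray:
    """Resample a subject volume onto the template grid.

    ``order=0`` (nearest neighbour) for label maps, ``order=1`` (trilinear)
    for probability volumes. Both affines map voxel indices to the shared
    world space; they must be invertible.
    """
    subject_affine = np.asarray(subject_affine, dtype=np.float64)
    template_affine = np.asarray(template_affine, dtype=np.float64)
    for A in (subject_affine, template_affine):
        if A.shape != (4, 4) or abs(np.linalg.det(A[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
    # template voxel -> world -> subject voxel
    M = np.linalg.inv(subject_affine) @ template_affine
    out = ndimage.affine_transform(
        subject_map.astype(np.float64),
        M[:3, :3],
        offset=M[:3, 3],
        output_shape=template_shape,
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    if order == 0:
        return np.rint(out).astype(subject_map.dtype)
    return out


def group_probability_map(
    binary_maps: Sequence[np.ndarray],
    threshold: float = 0.30,
) -> GroupMap:
    """Fraction of subjects positive at each voxel, with population cutoff.

    With 19 subjects, 6 positives give 6/19 = 0.3158 > 0.30 (retained) while
    5 positives give 0.2632 (excluded).
    """
    maps = list(binary_maps)
    if not maps:
        raise ValueError("at least one subject map is required")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("subject maps must share one grid shape")
    stack = np.stack([np.asarray(m, dtype=bool) for m in maps])
    values = stack.mean(axis=0)
    return GroupMap(values=values, n_subjects=len(maps), threshold=threshold)
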