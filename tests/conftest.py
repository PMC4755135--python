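"""Shared fixtures: small, fast phantom configurations and tracked sides.

The "tiny" configuration shrinks every radial band and the seed length so a
full track-and-cluster cycle runs in about a second; the acceptance tests
use the default (full-size) configuration via their own session fixtures.
"""

from __future__ import annotations

import numpy as np
import pytest

from pagseg import (
    Phantom,
    PhantomConfig,
    OrientationField,
    TrackingParams,
    generate_phantom,
    track_seed_mask,
)

TINY_KW = dict(
    grid_shape=(22, 22, 10),
    voxel_size_mm=1.5,
    seed_length_mm=4.5,
    seed_width_mm=3.0,
    aqueduct_radius_mm=1.8,
    seed_inner_radius_mm=2.7,
    shared_inner_radius_mm=7.5,
    shared_outer_radius_mm=9.0,
    target_inner_radius_mm=10.5,
    target_outer_radius_mm=12.75,
)


@pytest.fixture(scope="session")
def tiny_config() -> PhantomConfig:
    return PhantomConfig(rng_seed=42, **TINY_KW)


@pytest.fixture(scope="session")
def tiny_phantom(tiny_config) -> Phantom:
    return generate_phantom(tiny_config)


@pytest.fixture(scope="session")
def tiny_cm(tiny_phantom):
    """Right-side connectivity of the tiny phantom at 300 samples/voxel."""
    params = TrackingParams(n_samples=300, rng_seed=5)
    return track_seed_mask(tiny_phantom, params, side="right")


def uniform_field(shape, direction, kappa=np.inf, voxel_size_mm=1.5) -> OrientationField:
    """Constant-direction, single-population orientation field."""
    d = np.asarray(direction, dtype=np.float64)
    d = d / np.linalg.norm(d)
    dirs = np.broadcast_to(d, shape + (1, 3)).copy()
    weights = np.ones(shape + (1,))
    kap = np.full(shape, float(kappa))
    return OrientationField(dirs, weights, kap, voxel_size_mm=voxel_size_mm)


def make_box_phantom(shape=(12, 12, 12), direction=(1.0, 0.0, 0.0), kappa=np.inf,
                     seed_voxels=((6, 6, 6),), targets=None):
    """Minimal phantom around a hand-built field, for oracle tests."""
    cfg = PhantomConfig(rng_seed=0, **TINY_KW)
    fieldv = uniform_field(shape, direction, kappa=kappa)
    seed = np.zeros(shape, dtype=bool)
    for v in seed_voxels:
        seed[v] = True
    truth = np.zeros(shape, dtype=np.int16)
    truth[seed] = 1
    return Phantom(
        config=cfg,
        orientation_field=fieldv,
        seed_mask_left=np.zeros(shape, dtype=bool),
        seed_mask_right=seed,
        aqueduct_mask=np.zeros(shape, dtype=bool),
        target_masks=targets or {},
        brain_mask=np.ones(shape, dtype=bool),
        truth_labels=truth,
        subject_affine=np.eye(4),
        center_xy=((shape[0] - 1) / 2, (shape[1] - 1) / 2),
        seed_z_range=(0, shape[2] - 1),
    )
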