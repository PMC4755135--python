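"""Tracker: orientation sampling, propagation, counting, probabilities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pagseg import (
    OrientationField,
    TrackingParams,
    apply_probability_floor,
    connection_probability,
    propagate_streamline,
    sample_orientation,
    track_seed_mask,
)

from conftest import make_box_phantom, uniform_field


def test_params_validation():
    with pytest.raises(ValueError):
        TrackingParams(n_samples=0)
    with pytest.raises(ValueError):
        TrackingParams(step_size_mm=0)
    with pytest.raises(ValueError):
        TrackingParams(prob_threshold=1.5)


# ---------------------------------------------------------------------------
# sample_orientation
# ---------------------------------------------------------------------------


def test_zero_dispersion_returns_mean_direction_exactly():
    f = uniform_field((6, 6, 6), (0.0, 1.0, 0.0), kappa=np.inf)
    rng = np.random.default_rng(0)
    d = sample_orientation(f, (3.0, 3.0, 3.0), (0.0, 1.0, 0.0), rng)
    assert np.allclose(d, [0.0, 1.0, 0.0], atol=1e-12)


def test_axial_sign_flips_against_antialigned_previous_direction():
    f = uniform_field((6, 6, 6), (0.0, 1.0, 0.0), kappa=np.inf)
    rng = np.random.default_rng(0)
    d = sample_orientation(f, (3.0, 3.0, 3.0), (0.0, -1.0, 0.0), rng)
    assert np.allclose(d, [0.0, -1.0, 0.0], atol=1e-12)
    # and the contract dot(returned, prev) >= 0 holds at finite kappa too
    f2 = uniform_field((6, 6, 6), (0.0, 1.0, 0.0), kappa=8.0)
    for _ in range(200):
        d = sample_orientation(f2, (3.0, 3.0, 3.0), (0.2, -0.9, 0.1), rng)
        assert d @ np.array([0.2, -0.9, 0.1]) >= 0


def test_outside_brain_returns_termination_signal():
    f = uniform_field((6, 6, 6), (1.0, 0.0, 0.0))
    f.weights[:] = 0.0  # no fiber population anywhere
    assert sample_orientation(f, (3.0, 3.0, 3.0), None, np.random.default_rng(0)) is None


def test_vmf_sampler_matches_rejection_sampling_oracle():
    """Mean angular deviation agrees with an independent rejection sampler."""
    kappa = 5.0
    mu = np.array([0.0, 0.0, 1.0])
    f = uniform_field((4, 4, 4), mu, kappa=kappa)
    rng = np.random.default_rng(123)
    n = 30_000
    angles = np.empty(n)
    for i in range(n):
        d = sample_orientation(f, (1.0, 1.0, 1.0), mu, rng)
        angles[i] = math.acos(min(1.0, abs(d @ mu)))
    # Rejection oracle: uniform sphere proposals accepted w.p. exp(kappa(w-1)).
    orng = np.random.default_rng(456)
    m = 400_000
    z = orng.normal(size=(m, 3))
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    w = z @ mu
    acc = orng.random(m) < np.exp(kappa * (w - 1.0))
    # fold to the axial convention used by the tracker (|angle| <= 90 deg)
    oracle_angles = np.arccos(np.abs(w[acc]))
    se = np.sqrt(angles.var() / n + oracle_angles.var() / oracle_angles.size)
    assert abs(angles.mean() - oracle_angles.mean()) < 4 * se


# ---------------------------------------------------------------------------
# propagate_streamline
# ---------------------------------------------------------------------------


def test_straight_field_gives_closed_form_positions():
    f = uniform_field((20, 8, 8), (1.0, 0.0, 0.0), voxel_size_mm=1.5)
    params = TrackingParams(n_samples=1, step_size_mm=0.75, rng_seed=0)
    rng = np.random.default_rng(0)
    path = propagate_streamline(f, (2.0, 4.0, 4.0), params, rng)
    step_vox = 0.75 / 1.5
    for k, p in enumerate(path):
        assert np.allclose(p, [2.0 + k * step_vox, 4.0, 4.0], atol=1e-9)
    # terminated by the grid boundary
    assert path[-1][0] > 18.9


def test_streamline_follows_ninety_degree_bend():
    """Circular-arc field: endpoint matches the quarter-circle, within a voxel."""
    shape = (40, 40, 5)
    cx, cy, radius = 2.0, 2.0, 30.0
    dirs = np.zeros(shape + (1, 3))
    x = np.arange(shape[0])[:, None] - cx
    y = np.arange(shape[1])[None, :] - cy
    r = np.where(np.hypot(x, y) == 0, 1.0, np.hypot(x, y))
    # tangent of circles around (cx, cy)
    dirs[..., 0, 0] = (-y / r)[:, :, None]
    dirs[..., 0, 1] = (x / r)[:, :, None]
    f = OrientationField(dirs, np.ones(shape + (1,)), np.full(shape, np.inf), 1.5)
    params = TrackingParams(
        n_samples=1, step_size_mm=0.3, max_steps=1000, curvature_limit_deg=80, rng_seed=0
    )
    start = np.array([cx + radius, cy, 2.0])
    path = propagate_streamline(f, start, params, np.random.default_rng(0))
    # the quarter-circle endpoint (cx, cy + radius) is reached within one voxel
    dists = np.linalg.norm(path - np.array([cx, cy + radius, 2.0]), axis=1)
    assert dists.min() < 1.0
    # radius is conserved along the path to within a voxel
    rr = np.hypot(path[:, 0] - cx, path[:, 1] - cy)
    assert np.all(np.abs(rr - radius) < 1.0)


def test_zero_curvature_limit_stops_at_first_turn():
    shape = (40, 40, 5)
    cx, cy = 2.0, 2.0
    dirs = np.zeros(shape + (1, 3))
    x = np.arange(shape[0])[:, None] - cx
    y = np.arange(shape[1])[None, :] - cy
    r = np.where(np.hypot(x, y) == 0, 1.0, np.hypot(x, y))
    dirs[..., 0, 0] = (-y / r)[:, :, None]
    dirs[..., 0, 1] = (x / r)[:, :, None]
    f = OrientationField(dirs, np.ones(shape + (1,)), np.full(shape, np.inf), 1.5)
    params = TrackingParams(
        n_samples=1, step_size_mm=0.75, curvature_limit_deg=0.0, rng_seed=0
    )
    path = propagate_streamline(f, (32.0, 2.0, 2.0), params, np.random.default_rng(0))
    assert len(path) <= 3  # terminates as soon as the field requires a turn


def test_curvature_contract_holds_on_noisy_paths(tiny_phantom):
    params = TrackingParams(n_samples=1, curvature_limit_deg=45.0, rng_seed=9)
    rng = np.random.default_rng(9)
    start = np.argwhere(tiny_phantom.seed_mask_right)[0].astype(float)
    limit = math.radians(45.0) + 1e-6
    for _ in range(20):
        path = propagate_streamline(
            tiny_phantom.orientation_field,
            start,
            params,
            rng,
            brain_mask=tiny_phantom.brain_mask,
            aqueduct_mask=tiny_phantom.aqueduct_mask,
        )
        if len(path) < 3:
            continue
        steps = np.diff(np.asarray(path), axis=0)
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        cosang = np.clip(np.einsum("ij,ij->i", steps[:-1], steps[1:]), -1, 1)
        assert np.all(np.arccos(cosang) <= limit)


# ---------------------------------------------------------------------------
# track_seed_mask
# ---------------------------------------------------------------------------


def test_deterministic_straight_field_counts_equal_n_samples_on_path():
    """Oracle equivalence: counts are n_samples on the known line, 0 elsewhere."""
    ph = make_box_phantom(shape=(15, 7, 7), direction=(1, 0, 0), seed_voxels=((7, 3, 3),))
    params = TrackingParams(n_samples=120, step_size_mm=0.75, rng_seed=1)
    cm = track_seed_mask(ph, params, side="right")
    counts = np.asarray(cm.counts.todense())[0].reshape(ph.grid_shape)
    expected = np.zeros(ph.grid_shape, dtype=int)
    expected[:, 3, 3] = 120  # the full x-line through the seed voxel
    assert np.array_equal(counts, expected)


def test_empty_seed_mask_rejected(tiny_phantom):
    with pytest.raises(ValueError):
        track_seed_mask(
            tiny_phantom,
            TrackingParams(n_samples=10),
            seed_mask=np.zeros(tiny_phantom.grid_shape, dtype=bool),
        )


def test_tracking_reproducible_and_counts_bounded(tiny_phantom):
    params = TrackingParams(n_samples=100, rng_seed=21)
    a = track_seed_mask(tiny_phantom, params, side="left")
    b = track_seed_mask(tiny_phantom, params, side="left")
    assert (a.counts != b.counts).nnz == 0
    assert np.array_equal(a.target_counts, b.target_counts)
    assert a.counts.max() <= params.n_samples
    assert a.counts.min() >= 0


def test_high_kappa_column_samples_reach_designated_target(tiny_cm, tiny_phantom):
    """Most samples from column-1 voxels arrive at column 1's target."""
    truth = tiny_phantom.truth_labels[tuple(tiny_cm.seed_index.T)]
    t_idx = tiny_cm.target_names.index("dm_right")
    probs = tiny_cm.target_probabilities()[truth == 1, t_idx]
    assert probs.mean() >= 0.9


def test_aqueduct_blocks_streamlines(tiny_cm, tiny_phantom):
    """CSF is a hard termination region: aqueduct voxels are never visited."""
    aq_flat = np.flatnonzero(tiny_phantom.aqueduct_mask.ravel())
    assert tiny_cm.counts[:, aq_flat].nnz == 0


# ---------------------------------------------------------------------------
# probabilities
# ---------------------------------------------------------------------------


def test_connection_probability_threshold_arithmetic():
    n = 10_000
    assert connection_probability(np.array([3]), n)[0] == pytest.approx(0.0003)
    assert connection_probability(np.array([0]), n)[0] == 0.0
    probs = connection_probability(np.array([3, 2, 0, 10]), n)
    kept = apply_probability_floor(probs, 0.0003)
    assert kept[0] == pytest.approx(0.0003)  # count 3 survives P < 3e-4 removal
    assert kept[1] == 0.0  # count 2 removed
    assert kept[2] == 0.0
    assert kept[3] == pytest.approx(0.001)


def test_connection_probability_requires_samples():
    with pytest.raises(ValueError):
        connection_probability(np.array([1]), 0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    counts=st.lists(st.integers(min_value=0, max_value=100), min_size=1, max_size=30),
    t1=st.floats(min_value=0, max_value=0.01),
    t2=st.floats(min_value=0, max_value=0.01),
)
def test_probability_floor_monotone(counts, t1, t2):
    """Raising the floor never enlarges the surviving voxel set."""
    lo, hi = sorted([t1, t2])
    probs = connection_probability(np.array(counts), 10_000)
    surv_lo = apply_probability_floor(probs, lo) > 0
    surv_hi = apply_probability_floor(probs, hi) > 0
    assert not np.any(surv_hi & ~surv_lo)
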