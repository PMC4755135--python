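"""Synthetic brainstem phantom with four connectivity-defined columns per side.

The phantom emulates the geometry relevant to connectivity-based parcellation
of the periaqueductal gray (PAG): a cerebrospinal-fluid void (the "aqueduct")
running longitudinally through the volume, flanked on each side by a thin
annular seed wall (~14 mm long, ~4.5 mm wide) subdivided into four angular
sectors — dorsomedial (dm), dorsolateral (dl), lateral (l) and ventrolateral
(vl). Each sector is the ground-truth analogue of one PAG column.

The fiber-orientation field forms one fasciculating bundle per sector:
trajectories leave the seed roughly radially and steer toward the sector's
bisector angle and the seed's central slice, so streamlines from all voxels
of a column converge onto a common downstream tube — the feature that makes
connectivity profiles column-specific rather than voxel-specific. Column
targets are placed on an outer radial band where that tube crosses it, one
target per sector per side, so each column connects to a distinct target.
Two extra targets exercise downstream logic:

* a "shared" mid-radius ring under the lateral + ventrolateral sectors that
  every l/vl streamline traverses on the way out (a hypothalamus-like hub
  touched by more than one column), and
* a "distractor" band in the ventral midline gap that no seed sector points
  at, so its connection probability sits below the removal threshold
  (an anterior-cingulate-like target that fails thresholding).

Per-subject variation consists of a rigid translation of the whole geometry
(rounded to whole voxels so the stored affine maps subject space onto the
template grid exactly) plus independent angular noise on every voxel's mean
fiber orientation. Orientation uncertainty at tracking time is governed by a
von Mises-Fisher concentration ``dispersion_kappa``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Tuple

import numpy as np

__all__ = [
    "PhantomConfig",
    "OrientationField",
    "Phantom",
    "COLUMN_NAMES",
    "generate_phantom",
    "generate_cohort",
    "canonical_sector_centers_deg",
]

#: Anatomical column identities, dorsal to ventral, numbered 1..4.
COLUMN_NAMES = ("dm", "dl", "l", "vl")


def column_name(col: int) -> str:
    """Short identity for column ``col`` (1-based); generic past four columns."""
    return COLUMN_NAMES[col - 1] if col <= len(COLUMN_NAMES) else f"c{col}"

# Angular layout (degrees from the dorsal midline toward lateral/ventral).
_SECTOR_START_DEG = 10.0
_SECTOR_END_DEG = 150.0
_DISTRACTOR_HALF_WIDTH_DEG = 12.0


class PhantomSizingError(ValueError):
    """Raised when the configured geometry cannot fit inside the grid."""


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and noise parameters of the synthetic phantom.

    All physical lengths are millimetres on an isotropic grid.
    """

    grid_shape: Tuple[int, int, int] = (30, 30, 24)
    voxel_size_mm: float = 1.5
    seed_length_mm: float = 14.0
    seed_width_mm: float = 4.5
    n_columns: int = 4
    dispersion_kappa: float = 50.0
    geometry_jitter_mm: float = 1.5
    orientation_noise_deg: float = 3.0
    rng_seed: int = 0
    # Radial layout (mm from the aqueduct axis).
    aqueduct_radius_mm: float = 1.8
    seed_inner_radius_mm: float = 2.7
    shared_inner_radius_mm: float = 10.5
    shared_outer_radius_mm: float = 12.75
    target_inner_radius_mm: float = 15.0
    target_outer_radius_mm: float = 18.0
    brain_margin_mm: float = 1.5

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.n_columns < 2:
            raise ValueError("n_columns must be >= 2")
        if self.dispersion_kappa < 0:
            raise ValueError("dispersion_kappa must be >= 0")
        if self.geometry_jitter_mm < 0:
            raise ValueError("geometry_jitter_mm must be >= 0")
        radii = (
            self.aqueduct_radius_mm,
            self.seed_inner_radius_mm,
            self.seed_inner_radius_mm + self.seed_width_mm,
            self.shared_inner_radius_mm,
            self.shared_outer_radius_mm,
            self.target_inner_radius_mm,
            self.target_outer_radius_mm,
        )
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise PhantomSizingError(
                "radial bands must be strictly nested: aqueduct < seed < shared ring < targets"
            )
        self._validate_fit()

    # Derived quantities -------------------------------------------------
    @property
    def seed_outer_radius_mm(self) -> float:
        return self.seed_inner_radius_mm + self.seed_width_mm

    @property
    def brain_radius_mm(self) -> float:
        return self.target_outer_radius_mm + self.brain_margin_mm

    @property
    def n_seed_slices(self) -> int:
        return max(1, int(round(self.seed_length_mm / self.voxel_size_mm)))

    @property
    def max_jitter_vox(self) -> int:
        """Per-axis cap on the (whole-voxel) geometric jitter."""
        if self.geometry_jitter_mm == 0:
            return 0
        return max(1, int(math.ceil(self.geometry_jitter_mm / self.voxel_size_mm)))

    def _validate_fit(self) -> None:
        nx, ny, nz = self.grid_shape
        half_extent = (min(nx, ny) / 2.0 - 0.5) * self.voxel_size_mm
        needed = self.target_outer_radius_mm + self.max_jitter_vox * self.voxel_size_mm
        if needed > half_extent + 1e-9:
            raise PhantomSizingError(
                f"target band (r={self.target_outer_radius_mm} mm) plus jitter does not "
                f"fit in a {nx}x{ny} grid at {self.voxel_size_mm} mm voxels"
            )
        if self.n_seed_slices + 2 * self.max_jitter_vox > nz:
            raise PhantomSizingError(
                f"seed length {self.seed_length_mm} mm plus jitter does not fit in "
                f"{nz} axial slices"
            )


@dataclass
class OrientationField:
    """Per-voxel axial fiber-orientation model (one or two populations).

    ``mean_dirs`` has shape (nx, ny, nz, n_pop, 3) with unit vectors where a
    population is present; ``weights`` (nx, ny, nz, n_pop) are volume
    fractions summing to <= 1; ``kappa`` (nx, ny, nz) is the von Mises-Fisher
    concentration (``inf`` means zero dispersion). Orientations are axial:
    v and -v are equivalent and the tracker resolves the sign.
    """

    mean_dirs: np.ndarray
    weights: np.ndarray
    kappa: np.ndarray
    voxel_size_mm: float = 1.5

    def __post_init__(self) -> None:
        self.mean_dirs = np.asarray(self.mean_dirs, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.kappa = np.asarray(self.kappa, dtype=np.float64)
        if self.mean_dirs.ndim != 5 or self.mean_dirs.shape[-1] != 3:
            raise ValueError("mean_dirs must have shape (nx, ny, nz, n_pop, 3)")
        if self.weights.shape != self.mean_dirs.shape[:4]:
            raise ValueError("weights shape must match mean_dirs populations")
        if self.kappa.shape != self.mean_dirs.shape[:3]:
            raise ValueError("kappa must be a scalar volume")
        if np.any(self.weights < -1e-12) or np.any(self.weights.sum(axis=-1) > 1 + 1e-9):
            raise ValueError("population weights must lie in [0, 1] and sum to <= 1")
        if np.any(self.kappa < 0):
            raise ValueError("kappa must be >= 0")

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return self.mean_dirs.shape[:3]

    @property
    def n_populations(self) -> int:
        return self.mean_dirs.shape[3]


@dataclass
class Phantom:
    """One synthetic subject: masks, orientation field and ground truth."""

    config: PhantomConfig
    orientation_field: OrientationField
    seed_mask_left: np.ndarray
    seed_mask_right: np.ndarray
    aqueduct_mask: np.ndarray
    target_masks: Dict[str, np.ndarray]
    brain_mask: np.ndarray
    truth_labels: np.ndarray
    subject_affine: np.ndarray
    center_xy: Tuple[float, float]
    seed_z_range: Tuple[int, int]
    jitter_vox: Tuple[int, int, int] = (0, 0, 0)

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return self.brain_mask.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.config.voxel_size_mm

    def seed_mask(self, side: str) -> np.ndarray:
        if side == "left":
            return self.seed_mask_left
        if side == "right":
            return self.seed_mask_right
        if side == "both":
            return self.seed_mask_left | self.seed_mask_right
        raise ValueError(f"unknown side {side!r}")

    def designated_target(self, side: str, column: int) -> str:
        """Name of the outer-band target paired with a ground-truth column."""
        return f"{column_name(column)}_{side}"

    def validate(self) -> None:
        """Assert mask disjointness/containment invariants over all voxels."""
        seed = self.seed_mask_left | self.seed_mask_right
        stack = [self.aqueduct_mask, seed] + list(self.target_masks.values())
        total = np.zeros(self.grid_shape, dtype=np.int32)
        for m in stack:
            total += m.astype(np.int32)
        if total.max() > 1:
            raise AssertionError("seed, aqueduct and target masks overlap")
        for m in stack:
            if np.any(m & ~self.brain_mask):
                raise AssertionError("a mask extends outside the brain mask")
        if self.seed_mask_left.any() and np.any(self.seed_mask_right & self.seed_mask_left):
            raise AssertionError("left/right seed masks overlap")
        labels = self.truth_labels[seed]
        if labels.min() < 1 or labels.max() > self.config.n_columns:
            raise AssertionError("truth labels out of range over seed voxels")
        if np.linalg.matrix_rank(self.subject_affine) != 4:
            raise AssertionError("subject affine is singular")


def canonical_sector_centers_deg(n_columns: int = 4) -> np.ndarray:
    """Centers of the canonical angular sectors, dorsal to ventral (degrees)."""
    edges = np.linspace(_SECTOR_START_DEG, _SECTOR_END_DEG, n_columns + 1)
    return (edges[:-1] + edges[1:]) / 2.0


def _sector_edges_deg(n_columns: int) -> np.ndarray:
    return np.linspace(_SECTOR_START_DEG, _SECTOR_END_DEG, n_columns + 1)


def _polar_coords(shape, center_xy):
    """Radius (voxels) and per-side angle (deg from dorsal +y) of voxel centers."""
    nx, ny, _ = shape
    x = np.arange(nx, dtype=np.float64)[:, None] - center_xy[0]
    y = np.arange(ny, dtype=np.float64)[None, :] - center_xy[1]
    r = np.hypot(x, y)
    # theta: 0 at dorsal midline (+y), 180 at ventral midline, per side.
    theta = np.degrees(np.arctan2(np.abs(x), y))
    side_right = np.broadcast_to(x > 0, r.shape)
    return r, theta, side_right


# Bundle steering gains: angular and longitudinal convergence rates and the
# clamps keeping the local fiber direction within the tracker's curvature
# tolerance.
_STEER_ANGULAR_GAIN = 2.0
_STEER_LONGITUDINAL_GAIN = 2.0
_STEER_ANGULAR_MAX = 1.0
_STEER_LONGITUDINAL_MAX = 1.2


def bundle_direction(
    points: np.ndarray,
    center_xy: Tuple[float, float],
    z_center: float,
    n_columns: int,
) -> np.ndarray:
    """Analytic fiber direction of the converging column bundles.

    At a point with per-side angle theta (0 = dorsal midline) the direction
    is outward-radial plus a tangential component steering toward the
    bisector of the containing sector and a longitudinal component steering
    toward the seed's central slice; both decay as the trajectory approaches
    the bundle core, so each column's streamlines fasciculate onto a single
    tube. Outside the sector wedges the field is purely radial.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    dx = pts[:, 0] - center_xy[0]
    dy = pts[:, 1] - center_xy[1]
    r = np.hypot(dx, dy)
    r_safe = np.where(r < 1e-9, 1.0, r)
    s = np.where(dx >= 0, 1.0, -1.0)  # lateral sign (right/left side)
    theta = np.arctan2(np.abs(dx), dy)  # [0, pi] from dorsal

    edges = np.radians(_sector_edges_deg(n_columns))
    in_sectors = (theta >= edges[0]) & (theta < edges[-1])
    sector = np.clip(np.digitize(theta, edges[1:-1]), 0, n_columns - 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    theta_c = centers[sector]

    a = np.clip(
        _STEER_ANGULAR_GAIN * (theta_c - theta),
        -_STEER_ANGULAR_MAX,
        _STEER_ANGULAR_MAX,
    )
    b = np.clip(
        _STEER_LONGITUDINAL_GAIN * (z_center - pts[:, 2]) / r_safe,
        -_STEER_LONGITUDINAL_MAX,
        _STEER_LONGITUDINAL_MAX,
    )
    a = np.where(in_sectors, a, 0.0)
    b = np.where(in_sectors, b, 0.0)

    u_r = np.stack([dx / r_safe, dy / r_safe, np.zeros_like(r)], axis=1)
    u_r[r < 1e-9] = (0.0, 1.0, 0.0)
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    u_t = np.stack([s * cos_t, -sin_t, np.zeros_like(r)], axis=1)
    u_z = np.array([0.0, 0.0, 1.0])

    v = u_r + a[:, None] * u_t + b[:, None] * u_z[None, :]
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _trace_bundle_voxels(start, center_xy, z_center, n_columns, shape, r_stop):
    """Voxels visited by the ideal (noise-free) trajectory from ``start``."""
    pos = np.asarray(start, dtype=np.float64).copy()
    voxels = []
    for _ in range(2000):
        d = bundle_direction(pos[None, :], center_xy, z_center, n_columns)[0]
        pos = pos + 0.25 * d
        dx, dy = pos[0] - center_xy[0], pos[1] - center_xy[1]
        if math.hypot(dx, dy) > r_stop:
            break
        ix, iy, iz = (int(round(c)) for c in pos)
        if 0 <= ix < shape[0] and 0 <= iy < shape[1] and 0 <= iz < shape[2]:
            voxels.append((ix, iy, iz))
    return voxels


def _march_bundles(starts, center_xy, z_center, n_columns, shape, r_stop):
    """Union of voxels visited by the ideal trajectories from many starts."""
    hit = np.zeros(shape, dtype=bool)
    pos = np.array(starts, dtype=np.float64)
    for _ in range(2000):
        if pos.shape[0] == 0:
            break
        pos = pos + 0.25 * bundle_direction(pos, center_xy, z_center, n_columns)
        r = np.hypot(pos[:, 0] - center_xy[0], pos[:, 1] - center_xy[1])
        pos = pos[r <= r_stop]
        vox = np.rint(pos).astype(np.int64)
        ok = np.all((vox >= 0) & (vox < np.asarray(shape)[None, :]), axis=1)
        v = vox[ok]
        hit[v[:, 0], v[:, 1], v[:, 2]] = True
    return hit


def generate_phantom(config: PhantomConfig) -> Phantom:
    """Build one phantom subject; deterministic given ``config.rng_seed``."""
    rng = np.random.default_rng(config.rng_seed)
    nx, ny, nz = config.grid_shape
    vs = config.voxel_size_mm

    # Whole-voxel geometric jitter keeps the subject->template affine an
    # exact grid translation, so nearest-neighbour resampling is lossless.
    if config.geometry_jitter_mm > 0:
        raw = rng.normal(0.0, config.geometry_jitter_mm / vs, size=3)
        cap = config.max_jitter_vox
        jitter = tuple(int(np.clip(np.round(v), -cap, cap)) for v in raw)
    else:
        rng.normal(0.0, 1.0, size=3)  # keep the stream position stable
        jitter = (0, 0, 0)

    cx = (nx - 1) / 2.0 + jitter[0]
    cy = (ny - 1) / 2.0 + jitter[1]
    r, theta, side_right = _polar_coords(config.grid_shape, (cx, cy))

    n_slices = config.n_seed_slices
    z0 = (nz - n_slices) // 2 + jitter[2]
    z1 = z0 + n_slices - 1
    z_in = np.zeros(nz, dtype=bool)
    z_in[z0 : z1 + 1] = True
    in_seed_z = np.broadcast_to(z_in[None, None, :], config.grid_shape)

    def band(lo_mm, hi_mm):
        return (r >= lo_mm / vs) & (r <= hi_mm / vs)

    aqueduct = np.broadcast_to(
        (r <= config.aqueduct_radius_mm / vs)[:, :, None], config.grid_shape
    ).copy()
    brain = np.broadcast_to(
        (r <= config.brain_radius_mm / vs)[:, :, None], config.grid_shape
    ).copy()

    edges = _sector_edges_deg(config.n_columns)
    in_sectors = (theta >= edges[0]) & (theta < edges[-1])
    seed_xy = band(config.seed_inner_radius_mm, config.seed_outer_radius_mm) & in_sectors
    seed_right = seed_xy[:, :, None] & in_seed_z & side_right[:, :, None]
    seed_left = seed_xy[:, :, None] & in_seed_z & ~side_right[:, :, None]

    # Ground-truth column id from angular sector membership (1=dm .. 4=vl).
    sector_id = np.digitize(theta, edges[1:-1]) + 1  # 1..n_columns inside sectors
    truth = np.zeros(config.grid_shape, dtype=np.int16)
    seed_all = seed_left | seed_right
    truth[seed_all] = np.broadcast_to(sector_id[:, :, None], config.grid_shape)[seed_all]

    # Column targets: outer-band voxels on the ideal bundle trajectories.
    z_center = (z0 + z1) / 2.0
    target_band = band(config.target_inner_radius_mm, config.target_outer_radius_mm)
    r_stop_vox = config.target_outer_radius_mm / vs + 0.5
    ray_hit = _march_bundles(
        np.argwhere(seed_all).astype(np.float64),
        (cx, cy),
        z_center,
        config.n_columns,
        config.grid_shape,
        r_stop_vox,
    )

    target_masks: Dict[str, np.ndarray] = {}
    for side, side_sel in (("left", ~side_right), ("right", side_right)):
        for col in range(1, config.n_columns + 1):
            in_sec = (theta >= edges[col - 1]) & (theta < edges[col])
            mask = (target_band & in_sec & side_sel)[:, :, None] & in_seed_z & ray_hit
            target_masks[f"{column_name(col)}_{side}"] = mask

    # Shared mid-radius ring under the lateral + ventrolateral sectors.
    l_lo = edges[max(0, config.n_columns - 2)]
    shared_xy = (
        band(config.shared_inner_radius_mm, config.shared_outer_radius_mm)
        & (theta >= l_lo)
        & (theta < edges[-1])
    )
    target_masks["shared"] = shared_xy[:, :, None] & in_seed_z

    # Weakly connected distractor in the ventral midline gap.
    distractor_xy = target_band & (theta >= 180.0 - _DISTRACTOR_HALF_WIDTH_DEG)
    target_masks["distractor"] = distractor_xy[:, :, None] & in_seed_z

    # Converging-bundle axial orientation field, perturbed per voxel.
    grid_pts = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    dirs = bundle_direction(
        grid_pts.astype(np.float64), (cx, cy), z_center, config.n_columns
    ).reshape(nx, ny, nz, 1, 3)

    if config.orientation_noise_deg > 0:
        sigma = math.radians(config.orientation_noise_deg)
        noise = rng.normal(0.0, sigma, size=dirs.shape)
        dirs = dirs + noise
        dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)

    weights = np.where(brain[..., None], 1.0, 0.0)
    dirs[~brain] = 0.0
    kappa = np.full(config.grid_shape, float(config.dispersion_kappa))
    fieldv = OrientationField(dirs, weights, kappa, voxel_size_mm=vs)

    # Subject voxel (i) sits at template world coordinate vs * (i - jitter).
    affine = np.eye(4)
    affine[:3, :3] *= vs
    affine[:3, 3] = -vs * np.asarray(jitter, dtype=np.float64)

    phantom = Phantom(
        config=config,
        orientation_field=fieldv,
        seed_mask_left=seed_left,
        seed_mask_right=seed_right,
        aqueduct_mask=aqueduct,
        target_masks=target_masks,
        brain_mask=brain,
        truth_labels=truth,
        subject_affine=affine,
        center_xy=(cx, cy),
        seed_z_range=(z0, z1),
        jitter_vox=jitter,
    )
    phantom.validate()
    return phantom


def subject_seeds(rng_seed: int, n_subjects: int) -> List[int]:
    """Per-subject seeds fanned out from one master seed (documented derivation)."""
    ss = np.random.SeedSequence(rng_seed)
    return [int(child.generate_state(1)[0] & 0x7FFFFFFF) for child in ss.spawn(n_subjects)]


def generate_cohort(config: PhantomConfig, n_subjects: int) -> List[Phantom]:
    """Generate ``n_subjects`` phantoms with independent jitter and noise."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return [
        generate_phantom(replace(config, rng_seed=s))
        for s in subject_seeds(config.rng_seed, n_subjects)
    ]


def template_phantom(config: PhantomConfig) -> Phantom:
    """The zero-jitter, zero-noise reference subject defining template space."""
    return generate_phantom(
        replace(config, geometry_jitter_mm=0.0, orientation_noise_deg=0.0)
    )
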