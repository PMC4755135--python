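# Methods

This note records the models, parameter choices and numerical decisions
behind `pagseg`, and what the synthetic validation does and does not show.

## Synthetic phantom

The phantom stands in for a human cohort: per subject it provides a
voxelwise fiber-orientation model, binary seed/aqueduct/target/brain masks,
ground-truth column labels, and a voxel-to-template affine.

**Geometry.** On an isotropic grid (default 30×30×24 voxels at 1.5 mm) an
"aqueduct" cylinder (radius 1.8 mm) runs longitudinally through the center.
The seed is a thin annular wall around it — inner radius 2.7 mm, width
4.5 mm, length 14 mm (9 slices) — split into left and right halves, each
divided into four 35° angular sectors from dorsal to ventral: dm, dl, l, vl.
Sector membership defines the ground-truth column label, which makes
"parallel to the aqueduct" an explicitly testable property.

**Orientation field.** Each sector projects through its own *converging*
bundle: the local fiber direction is outward-radial plus a tangential
component steering toward the sector's bisector and a longitudinal component
steering toward the seed's central slice (gains 2.0, clamped at 1.0/1.2 so
per-step turning stays far inside the tracker's curvature limit). Under this
field the trajectories of all voxels in a column fasciculate onto a single
tube — the feature that makes connectivity profiles column-specific. An
earlier purely radial field was rejected: with straight rays every seed
voxel has its *own* ray, profiles are voxel-specific rather than
column-specific, and clustering recovers angle/slice bins instead of
columns. Convergent bundles are also the physically sensible model of a
projection system.

**Targets.** Each column's designated target is the set of voxels its ideal
(noise-free) bundle crosses in an outer radial band (15–18 mm), restricted
to the column's sector. Two additional targets exercise downstream logic: a
"shared" annulus segment at 10.5–12.75 mm under the l+vl sectors, crossed by
both of those bundles on the way out (a hub connected to more than one
column), and a "distractor" band at the ventral midline that no bundle
points at, so its whole-seed connection probability sits far below the
3·10⁻⁴ floor and the removal rule always has something to remove.

**Per-subject variability.** Two knobs, both deliberately simple:

* *Geometric jitter* — a rigid translation drawn per subject from
  N(0, 1.5 mm) per axis and rounded to whole voxels. Rounding keeps the
  subject affine an exact grid translation, so nearest-neighbour resampling
  through the stored affines is lossless and group mapping can be tested
  for exact truth reconstruction. No published estimate of inter-subject
  PAG position scatter was available; the scale is chosen small relative to
  the seed width.
* *Orientation noise* — each voxel's mean axis is perturbed by an isotropic
  Gaussian of 3° (then renormalized), independently per subject.

Orientation *uncertainty* (what the tracker samples at run time) is a von
Mises–Fisher cone around the voxel mean with concentration κ (default 50,
i.e. ≈8° angular standard deviation — a tight, high-quality fiber estimate).
The field supports up to two fiber populations per voxel with volume
fractions; the phantom itself emits one.

**What the phantom does not emulate.** Raw diffusion signal, crossing-fiber
posteriors, partial-volume mixtures at column borders, CSF pulsation,
registration error beyond a rigid shift, and any between-column similarity
structure (each column has its own clean target). Passing the validation
therefore shows the *pipeline* recovers planted structure under dispersion
and jitter; it does not certify performance on real diffusion data, where
bundle overlap and registration error are the dominant failure modes.

## Tracking

Monte-Carlo streamline propagation in the FDT style. From each seed voxel,
`n_samples` samples (default 10,000; the validation suite uses 1,000) are
launched bidirectionally along the initial axis. Per step: trilinear
interpolation of the orientation populations at the continuous position
(axial sign of each interpolation corner aligned with the previous
direction before averaging; population chosen proportional to interpolated
fractions), a vMF draw around the interpolated mean (closed-form inverse-CDF
sampler for S², κ = ∞ handled exactly), sign resolution against the previous
direction, then a 0.75 mm step (half a voxel). A path terminates on leaving
the brain mask, entering the aqueduct (CSF is not traversable), exceeding
the per-step curvature limit (80°), or at 2,000 steps. Masks are looked up
at the nearest voxel — smooth propagation, crisp termination.

**Counting.** A sample contributes at most 1 to any voxel's count no matter
how often (or in which direction) its path revisits it, so counts ≤
n_samples and `P = count / n_samples ∈ [0, 1]`. With 10,000 samples the
`P < 3·10⁻⁴` removal keeps exactly counts ≥ 3. Per-target hits are binary
per sample as well. The denominator convention (samples, not
samples×directions) is a deliberate choice; the alternative only rescales
probabilities by 2 and the floor accordingly.

**Implementation.** Streams are propagated in lockstep as arrays; the
per-step interpolate-sample-check kernel is JIT-compiled (numba), with all
random numbers drawn from a single numpy Generator outside the kernel, so
results are bit-reproducible for a given seed and independent of the
compiled path (a pure-numpy fallback implements the same semantics). Visit
pairs are deduplicated by sort.

## Segmentation

* Feature space: rows of the seed×seed Pearson cross-correlation matrix of
  thresholded profiles (a config switch in principle; correlation rows are
  the default and the validated path). Before correlation the brain
  dimension is down-binned 3× spatially to keep matrices small; `bin_factor=1`
  gives the exact computation and is used in oracle tests.
* Zero-variance (zero-connectivity) profiles are excluded and reported
  unclassified, never imputed.
* k-means: k = 4 per side, 50 k-means++ restarts, best by within-cluster sum
  of squares, fixed seed. Left and right are clustered independently.
* Silhouette in correlation distance `1 − r`, cutoff 0.25; singleton
  clusters get silhouette 0 by the usual convention (and are filtered at
  the default cutoff).
* Identity: clusters are matched to the four canonical sector centers
  (27.5°, 62.5°, 97.5°, 132.5° from dorsal) by minimum total circular
  discrepancy of their mean angles (Hungarian assignment). *Columnarity*
  operationalizes "parallel to the aqueduct": longitudinal extent ≥ 60% of
  the seed length and angular spread ≤ 120°, both configurable. A cluster
  failing columnarity keeps its label but is reported `unassigned` — the
  rostral/caudal split failure mode. This rule is our formalization of what
  was originally a visual judgment; it is a definition, not a reproduction
  of anyone's procedure.

## Profiles and statistics

Whole-seed connectivity to each target is the mean over seed voxels of the
per-voxel target-hit probability; targets below the 3·10⁻⁴ floor are removed
before column profiling. Column profiles are means over the column's
retained voxels; relative connectivity normalizes each target across the
four columns (shares sum to 1 whenever any column connects).

For cohort comparisons, a classical repeated-measures MANOVA was replaced by
a within-subject permutation test: for a column pair, the per-subject
difference vectors over targets are sign-flipped at random (the
exchangeability implied by swapping the two column labels within a
subject); the statistic is the sum over targets of squared paired-t values;
p-values use the add-one convention over 10,000 permutations (fewer in
quick tests). The permutation test is exact under the null regardless of
the covariance structure — which is unverifiable at n = 19 — and its type-I
error is checked by simulation. Per-target pairwise comparisons are paired
t-tests (Wilcoxon switch available), Bonferroni-corrected over the six
column pairs.

## Back-projection and group maps

A brain voxel's strength for a column is the *mean* connection probability
over the column's retained seed voxels (a `max` option exists; the mean is
the default because single-voxel outliers should not claim territory). The
voxel takes the argmax column if the winning strength reaches 3·10⁻⁴;
exact ties resolve to unlabeled, on the principle that no evidence should
mean no claim, and are reported in a tie mask.

Group maps resample per-subject label maps to the template grid with
nearest-neighbour interpolation through the stored affines (trilinear for
probability volumes) and keep voxels where the cohort fraction strictly
exceeds the population threshold, 0.30 by default (0.35 is a common display
variant and is reachable through the same argument). Only affine mapping is
implemented: the synthetic world has exact affines, and a nonlinear warp
would have nothing to estimate.

## Problem sizes in the validation suite

Unit tests run on a shrunken phantom (22×22×10 grid, 3-slice seed, 200–300
samples). The acceptance suite and `scripts/acceptance.py` use the full
default geometry with 19 subjects and 1,000 samples per seed voxel — enough
that per-voxel probabilities resolve the 3·10⁻⁴ floor while the whole cohort
tracks in a few minutes on one CPU; calibration of the permutation test uses
200 simulated null cohorts at 2,000 permutations each. Seeds are fixed
throughout; rerunning any stage with the same configuration is
bit-identical.

## Known limitations

* The phantom's columns are geometrically clean; the silhouette filter and
  columnarity rule are barely stressed at the default concentration.
  Lowering `dispersion_kappa` degrades recovery smoothly (this is itself
  under test), but no attempt is made to mimic the empirical human success
  rates per column.
* Distance effects are not corrected: nearer targets accumulate more visits
  per sample than distant ones, as in plain probabilistic tractography.
* The tracker has no waypoint/exclusion logic beyond brain/aqueduct
  termination, no crossing-fiber *estimation* (the field may declare two
  populations, but the phantom does not), and no GPU path.
* `n_columns` other than 4 generates valid phantoms, but identity naming
  beyond four columns is generic (`c5`, …) and the canonical-angle matching
  assumes the sector layout.
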