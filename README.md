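# pagseg

Connectivity-based segmentation of a periaqueductal-gray (PAG)-like seed
region from probabilistic diffusion tractography, packaged as a tested,
reusable pipeline and validated on a synthetic brainstem phantom cohort with
known ground truth.

## The problem

The PAG is a small midbrain structure wrapped around the cerebral aqueduct.
Animal work divides it into four longitudinal columns — dorsomedial (dm),
dorsolateral (dl), lateral (l) and ventrolateral (vl) — that differ in
anatomical connectivity and function, but the columns are invisible to
structural MRI. They can, however, be recovered from diffusion MRI: voxels
of the same column share long-range connections, so clustering seed voxels
by the similarity of their connectivity profiles segments the region.

`pagseg` implements that pipeline end to end:

1. **Tractography** — from every seed voxel, launch `N` Monte-Carlo
   streamline samples (default 10,000) through a voxelwise fiber-orientation
   field (von Mises–Fisher dispersion around per-voxel mean axes). The
   connectivity profile of seed voxel *i* is the count `c_ij` of samples
   that reach brain voxel *j*; connection probability is `P_ij = c_ij / N`,
   thresholded at `P < 3·10⁻⁴` to suppress false positives.
2. **Segmentation** — compute the Pearson cross-correlation matrix `R`
   between thresholded profiles; feed the rows of `R` to k-means with
   `k = 4` per side (left and right clustered independently); remove voxels
   with silhouette `s(i) = (b−a)/max(a,b) < 0.25` in correlation distance
   `1 − r`; name the clusters by their mean angular position around the
   aqueduct (dm → vl, dorsal → ventral) and check each is *columnar*
   (parallel to the aqueduct) rather than split rostro-caudally.
3. **Profiles** — per column, the mean connection probability to each named
   target region (targets whose whole-seed probability falls below 3·10⁻⁴
   are removed first) and each column's relative share of the four-column
   total; columns are compared pairwise across subjects with paired t-tests
   (Bonferroni over the six pairs) and a within-subject permutation test on
   the full target vector.
4. **Back-projection** — assign every brain voxel to the column it connects
   to most strongly (winner-take-all, floor 3·10⁻⁴; ties stay unlabeled).
5. **Group maps** — resample per-subject maps to the template grid through
   the stored affines and keep voxels present in >30% of the population.

Because no real cohort is distributed with the package, a **synthetic
phantom** module generates subjects in which the answer is known: four
angular-sector columns per side around an aqueduct void, each routed by a
smooth converging fiber bundle to its own target region, plus a shared
mid-route target (touched by the l and vl bundles) and a weak ventral
"distractor" target that the probability floor must remove. Subjects get
whole-voxel geometric jitter (recorded exactly in their affine) and
per-voxel orientation noise.

## Worked example

```python
from pagseg import (PhantomConfig, TrackingParams, generate_phantom,
                    track_seed_mask)
from pagseg.pipeline import segment_side

phantom = generate_phantom(PhantomConfig(rng_seed=7))
cm = track_seed_mask(phantom, TrackingParams(n_samples=1000, rng_seed=3),
                     side="right")
result = segment_side(phantom, cm, "right", rng_seed=11)
print(result.column_identity)   # {1: 'dm', 2: 'l', 3: 'vl', 4: 'dl'}
print(result.columnar)          # {1: True, 2: True, 3: True, 4: True}
print(f"{result.retained.sum()}/{result.labels.size} voxels retained")
```

Running this prints cluster-to-identity assignments like
`{1: 'dm', 2: 'l', 3: 'vl', 4: 'dl'}` (cluster numbering is arbitrary; the
identities are what matter), `columnar` flags all `True` — every cluster
runs parallel to the aqueduct — and `213/225 voxels retained`, i.e. 12 of
225 seed voxels fell below the 0.25 silhouette cutoff. Against the phantom's
ground truth this clustering has an adjusted Rand index of 1.0.

The same thing from the shell:

```bash
pagseg run --out run/ --subjects 19 --samples 1000 --seed 1
```

writes per-subject phantoms, connectivity matrices (HDF5), cluster label
maps (NIfTI + TSV), connectivity profiles and pairwise test tables (TSV),
back-projection label maps, and template-space group probability maps.

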