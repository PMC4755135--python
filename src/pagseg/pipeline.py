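"""End-to-end pipeline: simulate -> track -> cluster -> profiles -> backproject -> groupmap.

One master seed fans out deterministically to per-stage, per-subject seeds
through :func:`numpy.random.SeedSequence` spawn keys, so any stage can be
rerun independently and a rerun with the same configuration is bit-identical
for label maps and count matrices.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as pio
from .backprojection import backproject
from .groupmaps import group_probability_map, to_template
from .phantom import (
    COLUMN_NAMES,
    Phantom,
    PhantomConfig,
    column_name,
    generate_phantom,
    subject_seeds,
    template_phantom,
)
from .profiles import (
    column_profiles,
    pairwise_column_tests,
    profiles_to_frame,
    total_seed_connectivity,
)
from .segmentation import (
    UNASSIGNED,
    assign_column_identities,
    cross_correlation_matrix,
    kmeans_columns,
    silhouette_filter,
)
from .tracking import TrackingParams, track_seed_mask

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "segment_side"]

log = logging.getLogger("pagseg")

__version__ = "0.1.0"

SIDES = ("left", "right")


@dataclass
class PipelineConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    n_subjects: int = 19
    k: int = 4
    silhouette_cutoff: float = 0.25
    prob_threshold: float = 0.0003
    group_threshold: float = 0.30
    bin_factor: int = 3
    kmeans_restarts: int = 50
    n_permutations: int = 10_000
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phantom"]["grid_shape"] = list(d["phantom"]["grid_shape"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        ph = dict(d.pop("phantom", {}))
        if "grid_shape" in ph:
            ph["grid_shape"] = tuple(ph["grid_shape"])
        tr = dict(d.pop("tracking", {}))
        return cls(phantom=PhantomConfig(**ph), tracking=TrackingParams(**tr), **d)


@dataclass
class RunManifest:
    """Record of what was run: config hash, seeds and per-stage outputs."""

    config_hash: str
    version: str
    seed: int
    subject_seeds: List[int]
    stage_seeds: Dict[str, int]
    outputs: Dict[str, str] = field(default_factory=dict)

    def save(self, path: Path) -> Path:
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path


def stage_seed(master_seed: int, stage: str, subject: int = 0) -> int:
    """Deterministic per-stage / per-subject seed below 2**31."""
    digest = np.random.SeedSequence(
        [master_seed, zlib.crc32(stage.encode()), subject]
    )
    return int(digest.generate_state(1)[0] & 0x7FFFFFFF)


def segment_side(
    phantom: Phantom,
    cm,
    side: str,
    k: int = 4,
    cutoff: float = 0.25,
    prob_threshold: float = 0.0003,
    bin_factor: int = 3,
    kmeans_restarts: int = 50,
    rng_seed: int = 0,
):
    """Cluster one side's seed voxels and assign anatomical identities."""
    cc = cross_correlation_matrix(cm, prob_threshold=prob_threshold, bin_factor=bin_factor)
    labels = kmeans_columns(cc.matrix, k=k, n_restarts=kmeans_restarts, rng_seed=rng_seed)
    result = silhouette_filter(cc, labels, cutoff=cutoff, seed_index=cm.seed_index, side=side)
    return assign_column_identities(
        result, phantom.seed_mask(side), phantom.aqueduct_mask
    )


@dataclass
class SideAnalysis:
    """Slim per-(subject, side) record of the full analysis chain."""

    subject: int
    side: str
    result: "object"  # ClusterResult
    truth: np.ndarray
    ari: float
    profiles: list
    retained_targets: List[str]
    removed_targets: List[str]
    target_coverage: Dict[str, float]
    identity_volume_template: np.ndarray


@dataclass
class CohortAnalysis:
    config: PipelineConfig
    phantoms: list
    template: Phantom
    sides: List[SideAnalysis]
    first_cm: Optional[object] = None
    first_result: Optional[object] = None

    def success_fractions(self) -> Dict[str, float]:
        from .segmentation import evaluate_success

        return evaluate_success([s.result for s in self.sides])


def analyze_cohort(config: PipelineConfig, keep_first_cm: bool = False) -> CohortAnalysis:
    """Run simulate→track→cluster→profiles→backproject in memory.

    Returns per-side records with recovery scores against the phantom ground
    truth: adjusted Rand index over retained voxels, per-column profile
    shares, and the fraction of each designated target's voxels that the
    back-projection labels with the paired column.
    """
    from sklearn.metrics import adjusted_rand_score

    base = replace(config.phantom, rng_seed=stage_seed(config.seed, "simulate"))
    phantoms = [
        generate_phantom(replace(base, rng_seed=s))
        for s in subject_seeds(base.rng_seed, config.n_subjects)
    ]
    template = template_phantom(config.phantom)
    sides: List[SideAnalysis] = []
    first_cm = first_result = None

    for i, ph in enumerate(phantoms):
        for side in SIDES:
            cm = track_seed_mask(
                ph,
                replace(config.tracking, rng_seed=stage_seed(config.seed, f"track_{side}", i)),
                side=side,
            )
            result = segment_side(
                ph,
                cm,
                side,
                k=config.k,
                cutoff=config.silhouette_cutoff,
                prob_threshold=config.prob_threshold,
                bin_factor=config.bin_factor,
                kmeans_restarts=config.kmeans_restarts,
                rng_seed=stage_seed(config.seed, f"cluster_{side}", i),
            )
            truth = ph.truth_labels[tuple(cm.seed_index.T)]
            keep = result.retained
            ari = (
                adjusted_rand_score(truth[keep], result.labels[keep])
                if keep.sum() >= 2
                else 0.0
            )
            totals, removed = total_seed_connectivity(cm, config.prob_threshold)
            retained_targets = [t for t in cm.target_names if t not in removed]
            profs = column_profiles(result, cm, retained_targets)

            bp = backproject(result, cm, prob_threshold=config.prob_threshold)
            ident_to_cluster = {v: c for c, v in result.column_identity.items()}
            coverage: Dict[str, float] = {}
            for col in range(1, config.k + 1):
                tname = ph.designated_target(side, col)
                ident = column_name(col)
                cluster = ident_to_cluster.get(ident)
                tgt = ph.target_masks[tname]
                coverage[tname] = (
                    float((bp.labels[tgt] == cluster).mean()) if cluster else 0.0
                )

            ident_tmpl = to_template(
                result.identity_volume(ph.grid_shape),
                ph.subject_affine,
                template.subject_affine,
                template.grid_shape,
            )
            if first_cm is None and keep_first_cm:
                first_cm, first_result = cm, result
            sides.append(
                SideAnalysis(
                    subject=i,
                    side=side,
                    result=result,
                    truth=truth,
                    ari=float(ari),
                    profiles=profs,
                    retained_targets=retained_targets,
                    removed_targets=removed,
                    target_coverage=coverage,
                    identity_volume_template=ident_tmpl,
                )
            )
    return CohortAnalysis(
        config=config,
        phantoms=phantoms,
        template=template,
        sides=sides,
        first_cm=first_cm,
        first_result=first_result,
    )


def run_pipeline(config: PipelineConfig, out_dir: Path | str) -> RunManifest:
    """Run every stage on a synthetic cohort and write all declared outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    manifest = RunManifest(
        config_hash=pio.config_hash(cfg_dict),
        version=__version__,
        seed=config.seed,
        subject_seeds=subject_seeds(config.seed, config.n_subjects),
        stage_seeds={
            "simulate": stage_seed(config.seed, "simulate"),
            "track": stage_seed(config.seed, "track"),
            "cluster": stage_seed(config.seed, "cluster"),
        },
    )
    (out / "config.json").write_text(json.dumps(cfg_dict, indent=2))

    # --- simulate ---------------------------------------------------------
    log.info("simulate: %d subjects", config.n_subjects)
    base = replace(config.phantom, rng_seed=manifest.stage_seeds["simulate"])
    phantoms = [
        generate_phantom(replace(base, rng_seed=s))
        for s in subject_seeds(base.rng_seed, config.n_subjects)
    ]
    template = template_phantom(config.phantom)
    subj_dirs = []
    for i, ph in enumerate(phantoms):
        subj_dirs.append(pio.save_phantom(ph, out / "subjects" / f"sub-{i:02d}"))
    pio.save_phantom(template, out / "template")
    manifest.outputs["subjects"] = str(out / "subjects")

    # --- track + cluster + profiles + backproject --------------------------
    cohort_results = []
    cohort_profiles = []
    backproj_vols: Dict[str, List[np.ndarray]] = {name: [] for name in COLUMN_NAMES}
    cluster_vols: Dict[str, List[np.ndarray]] = {name: [] for name in COLUMN_NAMES}
    tmpl_affine = template.subject_affine
    tmpl_shape = template.grid_shape

    for i, ph in enumerate(phantoms):
        for side in SIDES:
            t_seed = stage_seed(config.seed, f"track_{side}", i)
            cm = track_seed_mask(
                ph, replace(config.tracking, rng_seed=t_seed), side=side
            )
            pio.save_connectivity(cm, out / "runs" / f"sub-{i:02d}_{side}.h5")
            result = segment_side(
                ph,
                cm,
                side,
                k=config.k,
                cutoff=config.silhouette_cutoff,
                prob_threshold=config.prob_threshold,
                bin_factor=config.bin_factor,
                kmeans_restarts=config.kmeans_restarts,
                rng_seed=stage_seed(config.seed, f"cluster_{side}", i),
            )
            cohort_results.append(result)
            pio.save_cluster_result(
                result,
                ph.grid_shape,
                ph.subject_affine,
                out / "clusters" / f"sub-{i:02d}_{side}",
            )

            totals, removed = total_seed_connectivity(cm, config.prob_threshold)
            retained_targets = [t for t in cm.target_names if t not in removed]
            profs = column_profiles(result, cm, retained_targets)
            cohort_profiles.append((i, side, profs))

            bp = backproject(result, cm, prob_threshold=config.prob_threshold)
            pio.save_volume(
                bp.labels, ph.subject_affine, out / "backproject" / f"sub-{i:02d}_{side}.nii.gz"
            )
            # Collect template-space binary maps per column identity.
            ident_vol = result.identity_volume(ph.grid_shape)
            ident_tmpl = to_template(ident_vol, ph.subject_affine, tmpl_affine, tmpl_shape)
            bp_tmpl = to_template(bp.labels, ph.subject_affine, tmpl_affine, tmpl_shape)
            for c, ident in result.column_identity.items():
                if ident == UNASSIGNED:
                    continue
                num = COLUMN_NAMES.index(ident) + 1
                cluster_vols[ident].append(ident_tmpl == num)
                backproj_vols[ident].append(bp_tmpl == c)

    manifest.outputs["runs"] = str(out / "runs")
    manifest.outputs["clusters"] = str(out / "clusters")
    manifest.outputs["backproject"] = str(out / "backproject")

    # --- profiles table + statistics ---------------------------------------
    frame = profiles_to_frame(cohort_profiles)
    frame.to_csv(out / "profiles.tsv", sep="\t", index=False)
    manifest.outputs["profiles"] = str(out / "profiles.tsv")
    if config.n_subjects >= 3 and not frame.empty:
        table, mv = pairwise_column_tests(
            frame,
            n_permutations=config.n_permutations,
            rng_seed=stage_seed(config.seed, "stats"),
        )
        mv_rows = pd.DataFrame(
            [{"pair": f"{a} vs {b}", "target": "multivariate", "p_raw": p, "p_bonferroni": p}
             for (a, b), p in mv.items()]
        )
        pd.concat([table, mv_rows], ignore_index=True).to_csv(
            out / "pairwise_tests.tsv", sep="\t", index=False
        )
        manifest.outputs["pairwise_tests"] = str(out / "pairwise_tests.tsv")

    # --- group maps ---------------------------------------------------------
    legend = {}
    for name in COLUMN_NAMES:
        for kind, vols in (("cluster", cluster_vols), ("backproject", backproj_vols)):
            if not vols[name]:
                continue
            gm = group_probability_map(vols[name], threshold=config.group_threshold)
            p = pio.save_volume(
                gm.values, tmpl_affine, out / "groupmaps" / f"{kind}_{name}.nii.gz"
            )
            legend[f"{kind}_{name}"] = {
                "path": str(p),
                "n_subject_sides": gm.n_subjects,
                "threshold": gm.threshold,
            }
    (out / "groupmaps" / "legend.json").parent.mkdir(parents=True, exist_ok=True)
    (out / "groupmaps" / "legend.json").write_text(json.dumps(legend, indent=2))
    manifest.outputs["groupmaps"] = str(out / "groupmaps")

    manifest.save(out / "manifest.json")
    return manifest
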