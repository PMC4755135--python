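"""Readers and writers: NIfTI volumes, HDF5 connectivity, TSV tables, YAML.

Every volume is written as NIfTI-1 with the affine of the space it lives in
(the subject's voxel-to-template-world transform, or the template affine for
group maps). Connectivity matrices are stored in HDF5 as CSR triplets plus
the seed-voxel table and target-hit counts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Union

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy import sparse

from .phantom import OrientationField, Phantom, PhantomConfig
from .segmentation import ClusterResult
from .tracking import ConnectivityMatrix

__all__ = [
    "save_volume",
    "load_volume",
    "save_phantom",
    "load_phantom",
    "save_connectivity",
    "load_connectivity",
    "save_cluster_result",
    "load_config",
    "config_hash",
]

PathLike = Union[str, Path]


def save_volume(data: np.ndarray, affine: np.ndarray, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine)), str(path))
    return path


def load_volume(path: PathLike):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_phantom(phantom: Phantom, out_dir: PathLike) -> Path:
    """Write a subject's volumes and metadata; returns the subject directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    A = phantom.subject_affine
    save_volume(phantom.seed_mask_left, A, out / "seed_left.nii.gz")
    save_volume(phantom.seed_mask_right, A, out / "seed_right.nii.gz")
    save_volume(phantom.aqueduct_mask, A, out / "aqueduct.nii.gz")
    save_volume(phantom.brain_mask, A, out / "brain.nii.gz")
    save_volume(phantom.truth_labels, A, out / "truth_labels.nii.gz")
    for name, mask in phantom.target_masks.items():
        save_volume(mask, A, out / f"target_{name}.nii.gz")
    f = phantom.orientation_field
    save_volume(f.mean_dirs.reshape(f.grid_shape + (-1,)), A, out / "field_dirs.nii.gz")
    save_volume(f.weights, A, out / "field_weights.nii.gz")
    kappa = np.where(np.isfinite(f.kappa), f.kappa, -1.0)  # -1 encodes infinity
    save_volume(kappa, A, out / "field_kappa.nii.gz")
    meta = {
        "config": asdict(phantom.config),
        "affine": phantom.subject_affine.tolist(),
        "center_xy": list(phantom.center_xy),
        "seed_z_range": list(phantom.seed_z_range),
        "jitter_vox": list(phantom.jitter_vox),
        "targets": sorted(phantom.target_masks.keys()),
    }
    (out / "phantom.json").write_text(json.dumps(meta, indent=2))
    return out


def load_phantom(subject_dir: PathLike) -> Phantom:
    d = Path(subject_dir)
    meta = json.loads((d / "phantom.json").read_text())
    cfg_dict = dict(meta["config"])
    cfg_dict["grid_shape"] = tuple(cfg_dict["grid_shape"])
    config = PhantomConfig(**cfg_dict)
    dirs, affine = load_volume(d / "field_dirs.nii.gz")
    shape = dirs.shape[:3]
    dirs = dirs.reshape(shape + (-1, 3))
    weights, _ = load_volume(d / "field_weights.nii.gz")
    if weights.ndim == 3:
        weights = weights[..., None]
    kappa, _ = load_volume(d / "field_kappa.nii.gz")
    kappa = np.where(kappa < 0, np.inf, kappa)
    fieldv = OrientationField(dirs, weights, kappa, voxel_size_mm=config.voxel_size_mm)
    targets = {
        name: load_volume(d / f"target_{name}.nii.gz")[0].astype(bool)
        for name in meta["targets"]
    }
    return Phantom(
        config=config,
        orientation_field=fieldv,
        seed_mask_left=load_volume(d / "seed_left.nii.gz")[0].astype(bool),
        seed_mask_right=load_volume(d / "seed_right.nii.gz")[0].astype(bool),
        aqueduct_mask=load_volume(d / "aqueduct.nii.gz")[0].astype(bool),
        target_masks=targets,
        brain_mask=load_volume(d / "brain.nii.gz")[0].astype(bool),
        truth_labels=load_volume(d / "truth_labels.nii.gz")[0].astype(np.int16),
        subject_affine=np.asarray(meta["affine"], dtype=np.float64),
        center_xy=tuple(meta["center_xy"]),
        seed_z_range=tuple(meta["seed_z_range"]),
        jitter_vox=tuple(meta["jitter_vox"]),
    )


def save_connectivity(cm: ConnectivityMatrix, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    csr = cm.counts.tocsr()
    with h5py.File(path, "w") as h5:
        h5.attrs["n_samples"] = cm.n_samples
        h5.attrs["grid_shape"] = cm.grid_shape
        h5.attrs["voxel_size_mm"] = cm.voxel_size_mm
        h5.attrs["side"] = cm.side or ""
        h5.create_dataset("seed_index", data=cm.seed_index)
        h5.create_dataset("counts_data", data=csr.data)
        h5.create_dataset("counts_indices", data=csr.indices)
        h5.create_dataset("counts_indptr", data=csr.indptr)
        if cm.target_counts is not None:
            h5.create_dataset("target_counts", data=cm.target_counts)
            h5.create_dataset(
                "target_names",
                data=np.array([n.encode() for n in cm.target_names]),
            )
    return path


def load_connectivity(path: PathLike) -> ConnectivityMatrix:
    with h5py.File(path, "r") as h5:
        grid_shape = tuple(int(s) for s in h5.attrs["grid_shape"])
        n_flat = int(np.prod(grid_shape))
        seed_index = h5["seed_index"][()]
        counts = sparse.csr_matrix(
            (h5["counts_data"][()], h5["counts_indices"][()], h5["counts_indptr"][()]),
            shape=(seed_index.shape[0], n_flat),
        )
        target_counts = h5["target_counts"][()] if "target_counts" in h5 else None
        target_names = (
            tuple(n.decode() for n in h5["target_names"][()])
            if "target_names" in h5
            else ()
        )
        side = str(h5.attrs["side"]) or None
        return ConnectivityMatrix(
            seed_index=seed_index,
            counts=counts,
            n_samples=int(h5.attrs["n_samples"]),
            grid_shape=grid_shape,
            voxel_size_mm=float(h5.attrs["voxel_size_mm"]),
            target_names=target_names,
            target_counts=target_counts,
            side=side,
        )


def save_cluster_result(
    result: ClusterResult,
    grid_shape,
    affine: np.ndarray,
    out_prefix: PathLike,
) -> Dict[str, Path]:
    """Label NIfTI (0 = filtered/unclassified) plus a per-voxel TSV."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["labels"] = save_volume(
        result.label_volume(grid_shape), affine, prefix.with_suffix(".nii.gz")
    )
    ident = {c: result.column_identity.get(c, "") for c in np.unique(result.labels)}
    df = pd.DataFrame(
        {
            "x": result.seed_index[:, 0],
            "y": result.seed_index[:, 1],
            "z": result.seed_index[:, 2],
            "label": result.labels,
            "silhouette": result.silhouette,
            "retained": result.retained.astype(int),
            "identity": [ident.get(l, "") for l in result.labels],
        }
    )
    tsv = prefix.with_suffix(".tsv")
    df.to_csv(tsv, sep="\t", index=False)
    paths["table"] = tsv
    return paths


def load_config(path: PathLike) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} did not parse to a mapping")
    return cfg


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
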