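"""Disk formats: participant CSV, NIfTI volumes, block archives, manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .preprocess import MetabolicBlock, VoxelBlock
from .synth import SyntheticCohort

__all__ = [
    "write_cohort",
    "load_cohort_inputs",
    "save_blocks",
    "load_blocks",
    "write_manifest",
]


def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Write a cohort as participant CSV + per-subject NIfTI + truth JSON."""
    out = Path(out_dir)
    img_dir = out / "gmv"
    img_dir.mkdir(parents=True, exist_ok=True)
    cohort.table.to_csv(out / "participants.csv", index=False)
    aff = cohort.affine
    for i, sid in enumerate(cohort.table["subject_id"]):
        nib.save(
            nib.Nifti1Image(cohort.gmv[i].astype(np.float32), aff),
            img_dir / f"{sid}_gmv.nii.gz",
        )
    nib.save(
        nib.Nifti1Image(cohort.mask_probability.astype(np.float32), aff),
        out / "gm_probability.nii.gz",
    )
    truth = {
        "u_true": cohort.truth.u_true.tolist(),
        "rho": cohort.truth.rho.tolist(),
        "latent_scores": cohort.truth.latent_scores.tolist(),
        "seed": cohort.spec.seed,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    np.save(out / "v_true.npy", cohort.truth.v_true)
    return out


def load_cohort_inputs(participants_csv, image_dir, mask_path):
    """Read the analysis inputs back: table, 4D image stack, probability
    image and affine. Subject order follows the CSV."""
    table = pd.read_csv(participants_csv)
    img_dir = Path(image_dir)
    mask_img = nib.load(mask_path)
    prob = np.asarray(mask_img.dataobj, dtype=float)
    affine = mask_img.affine
    vols = []
    for sid in table["subject_id"]:
        path = img_dir / f"{sid}_gmv.nii.gz"
        if not path.exists():
            raise FileNotFoundError(f"missing GMV image for subject {sid}: {path}")
        img = nib.load(path)
        if img.shape != prob.shape:
            raise ValueError(f"grid mismatch for subject {sid}: {img.shape} vs {prob.shape}")
        vols.append(np.asarray(img.dataobj, dtype=float))
    return table, np.stack(vols), prob, affine


def save_blocks(xblock: MetabolicBlock, yblock: VoxelBlock, raw_y: np.ndarray, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        out / "blocks.npz",
        X=xblock.X,
        Y=yblock.Y,
        raw_Y=raw_y,
        mask=yblock.mask,
        affine=yblock.affine,
        voxel_indices=yblock.voxel_indices,
    )
    meta = {
        "column_names": list(xblock.column_names),
        "confounders": list(xblock.confounders),
        "transform_log": xblock.transform_log,
    }
    (out / "blocks.json").write_text(json.dumps(meta, indent=2))
    return out / "blocks.npz"


def load_blocks(out_dir):
    out = Path(out_dir)
    with np.load(out / "blocks.npz") as npz:
        data = {k: npz[k] for k in npz.files}
    meta = json.loads((out / "blocks.json").read_text())
    xblock = MetabolicBlock(
        X=data["X"],
        column_names=tuple(meta["column_names"]),
        transform_log=meta["transform_log"],
        confounders=tuple(meta["confounders"]),
    )
    yblock = VoxelBlock(
        Y=data["Y"],
        mask=data["mask"].astype(bool),
        affine=data["affine"],
        voxel_indices=data["voxel_indices"],
    )
    return xblock, yblock, data["raw_Y"]


def write_manifest(out_dir, config_dict: dict, seed: int, stages: list[str]) -> Path:
    """Checksum every artifact in the run directory."""
    from . import __version__

    out = Path(out_dir)
    entries = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            entries[str(path.relative_to(out))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config_dict,
        "stages": stages,
        "files": entries,
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
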