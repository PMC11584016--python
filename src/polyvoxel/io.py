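"""Readers and writers for the pipeline's on-disk dialects.

Conventions (fixed and relied on throughout):

* Masked voxel order is the C-order scan of the mask volume
  (``volume[mask]`` with NumPy's default ordering).
* Image sets are written one NIfTI per subject plus a ``manifest.tsv``
  mapping file name to subject id (the default dialect); a single 4-D stack
  with subjects along the 4th axis is also accepted on read.
* Tabular outputs are tab-separated with a header row; missing values are
  encoded as ``NA``.
* Generator ground truth is a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import AlignmentError, AtlasLabels, InputError, VoxelImageSet
from .synthetic import SyntheticTruth

__all__ = [
    "read_mask",
    "read_images",
    "write_image_set",
    "read_image_set",
    "read_subject_table",
    "write_subject_table",
    "write_atlas",
    "read_atlas",
    "write_truth",
    "read_truth",
    "write_weight_map",
]

NA = "NA"


def read_mask(path):
    """Boolean mask volume and its affine."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0, img.affine


def _check_grid(img, mask_shape, affine, path):
    if tuple(img.shape[:3]) != tuple(mask_shape):
        raise AlignmentError(
            f"{path}: grid {img.shape[:3]} does not match mask {mask_shape}"
        )
    if not np.allclose(img.affine, affine, atol=1e-6):
        raise AlignmentError(f"{path}: affine differs from mask affine")


def read_images(paths, mask_path, subject_ids=None, modality="T2w") -> VoxelImageSet:
    """Load per-subject NIfTI volumes into a subjects × masked-voxels matrix.

    ``paths`` may be a list of 3-D volumes (one per subject) or a single 4-D
    stack.  Every volume must share grid and affine with the mask; the
    offending file is named otherwise.
    """
    mask, affine = read_mask(mask_path)
    paths = [paths] if isinstance(paths, (str, Path)) else list(paths)
    rows = []
    for p in paths:
        img = nib.load(str(p))
        _check_grid(img, mask.shape, affine, p)
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim == 3:
            rows.append(data[mask])
        elif data.ndim == 4:
            rows.extend(data[..., t][mask] for t in range(data.shape[3]))
        else:
            raise InputError(f"{p}: expected 3-D or 4-D volume, got {data.ndim}-D")
    matrix = np.vstack(rows)
    if subject_ids is None:
        subject_ids = np.array([f"S{i:06d}" for i in range(len(matrix))])
    return VoxelImageSet(matrix, np.asarray(subject_ids), modality, mask, affine)


def write_image_set(images: VoxelImageSet, out_dir, stem=None) -> Path:
    """Write one NIfTI per subject plus manifest.tsv and the mask.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or images.modality.lower()
    nib.save(
        nib.Nifti1Image(images.mask.astype(np.uint8), images.affine),
        out_dir / f"{stem}_mask.nii.gz",
    )
    records = []
    for i, sid in enumerate(images.subject_ids):
        vol = np.zeros(images.mask.shape, dtype=np.float32)
        vol[images.mask] = images.data[i]
        fname = f"{stem}_{sid}.nii.gz"
        nib.save(nib.Nifti1Image(vol, images.affine), out_dir / fname)
        records.append((fname, sid))
    manifest = pd.DataFrame(records, columns=["file", "subject_id"])
    manifest_path = out_dir / f"{stem}_manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False, na_rep=NA)
    return manifest_path


def read_image_set(manifest_path, modality="T2w") -> VoxelImageSet:
    """Inverse of :func:`write_image_set`."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    stem = manifest_path.name.replace("_manifest.tsv", "")
    mask_path = manifest_path.parent / f"{stem}_mask.nii.gz"
    paths = [manifest_path.parent / f for f in manifest["file"]]
    return read_images(
        paths, mask_path, subject_ids=manifest["subject_id"].to_numpy(), modality=modality
    )


def read_subject_table(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", na_values=[NA], keep_default_na=False,
        dtype={"subject_id": str},
    )


def write_subject_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep=NA)


def write_atlas(atlas: AtlasLabels, mask: np.ndarray, affine, out_dir, stem="atlas"):
    """Integer-label NIfTI (0 outside mask/unlabeled) + region-name TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vol = np.zeros(mask.shape, dtype=np.int32)
    vol[mask] = atlas.labels
    nib.save(nib.Nifti1Image(vol, affine), out_dir / f"{stem}.nii.gz")
    names = pd.DataFrame(
        sorted(atlas.names.items()), columns=["region_id", "region_name"]
    )
    names.to_csv(out_dir / f"{stem}_names.tsv", sep="\t", index=False, na_rep=NA)
    return out_dir / f"{stem}.nii.gz"


def read_atlas(atlas_path, mask_path) -> AtlasLabels:
    mask, affine = read_mask(mask_path)
    img = nib.load(str(atlas_path))
    _check_grid(img, mask.shape, affine, atlas_path)
    labels = np.asarray(img.dataobj).astype(int)[mask]
    names_path = str(atlas_path).replace(".nii.gz", "_names.tsv")
    names_df = pd.read_csv(names_path, sep="\t")
    names = dict(zip(names_df["region_id"].astype(int), names_df["region_name"]))
    return AtlasLabels(labels=labels, names=names)


def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "pattern": truth.pattern.tolist(),
        "latent_iron": truth.latent_iron.tolist(),
        "dosage": truth.dosage.tolist(),
        "risk_params": list(truth.risk_params),
        "pattern_voxels": truth.pattern_voxels.tolist(),
        "variant_dosages": None
        if truth.variant_dosages is None
        else truth.variant_dosages.tolist(),
        "variant_effects": None
        if truth.variant_effects is None
        else truth.variant_effects.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_truth(path) -> SyntheticTruth:
    d = json.loads(Path(path).read_text())
    return SyntheticTruth(
        pattern=np.asarray(d["pattern"], float),
        latent_iron=np.asarray(d["latent_iron"], float),
        dosage=np.asarray(d["dosage"], int),
        risk_params=tuple(d["risk_params"]),
        pattern_voxels=np.asarray(d["pattern_voxels"], int),
        variant_dosages=None
        if d["variant_dosages"] is None
        else np.asarray(d["variant_dosages"], float),
        variant_effects=None
        if d["variant_effects"] is None
        else np.asarray(d["variant_effects"], float),
    )


def write_weight_map(model, mask: np.ndarray, affine, path) -> None:
    """Export fitted weights as a NIfTI map in the mask's space."""
    vol = model.weight_map(mask)
    nib.save(nib.Nifti1Image(np.nan_to_num(vol).astype(np.float32), affine), str(path))
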