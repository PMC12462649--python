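"""NIfTI + CSV dataset interchange.

Each case is stored as ``<id>_pet.nii.gz`` and ``<id>_mri.nii.gz`` (and
``<id>_mask.nii.gz`` when a tumour mask exists) with the voxel pitch in
the NIfTI header, plus one ``labels.csv`` manifest with columns
``case_id, label``.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from petmri3d.phantoms import VolumeCase

__all__ = ["write_dataset", "read_dataset", "write_volume", "read_volume"]


def _affine(voxel_size) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def write_volume(path: Path, data: np.ndarray, voxel_size) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size)), str(path))


def read_volume(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), tuple(float(z) for z in img.header.get_zooms()[:3])


def write_dataset(cases: list[VolumeCase], out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in cases:
        write_volume(out / f"{c.case_id}_pet.nii.gz", c.pet, c.voxel_size)
        write_volume(out / f"{c.case_id}_mri.nii.gz", c.mri, c.voxel_size)
        if c.tumour_mask is not None:
            write_volume(out / f"{c.case_id}_mask.nii.gz", c.tumour_mask, c.voxel_size)
        rows.append({"case_id": c.case_id, "label": c.label})
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)


def read_dataset(in_dir) -> list[VolumeCase]:
    src = Path(in_dir)
    manifest = pd.read_csv(src / "labels.csv", dtype={"case_id": str})
    cases = []
    for _, row in manifest.iterrows():
        cid, label = row["case_id"], int(row["label"])
        pet, voxel = read_volume(src / f"{cid}_pet.nii.gz")
        mri, _ = read_volume(src / f"{cid}_mri.nii.gz")
        mask_path = src / f"{cid}_mask.nii.gz"
        mask = None
        if mask_path.exists():
            mask = read_volume(mask_path)[0].astype(np.uint8)
        cases.append(VolumeCase(case_id=cid, pet=pet, mri=mri, voxel_size=voxel,
                                label=label, tumour_mask=mask))
    return cases
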