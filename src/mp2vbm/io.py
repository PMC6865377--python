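"""NIfTI-1 and tabular I/O.

Volumes are exchanged as NIfTI-1 with isotropic voxels (1% tolerance) and a
diagonal affine; hypotheses and ground truth travel in CSV with
semicolon-separated lobe sets. All grids in a cohort must match exactly —
resampling is out of scope.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import LobarAtlas, Subject

__all__ = [
    "read_volume",
    "write_volume",
    "read_hypotheses",
    "write_cohort",
    "check_cohort_grids",
]


def read_volume(path) -> tuple[np.ndarray, float, np.ndarray]:
    """Load a NIfTI volume; returns (data, voxel_size_mm, affine).

    Rejects anisotropic voxels beyond 1% relative tolerance.
    """
    img = nib.load(os.fspath(path))
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if zooms.max() / zooms.min() - 1.0 > 0.01:
        raise ValueError(f"{path}: anisotropic voxels {tuple(zooms)} (tolerance 1%)")
    data = np.asanyarray(img.dataobj)
    return np.asarray(data), float(zooms.mean()), np.asarray(img.affine)


def write_volume(data, path, voxel_size: float, affine=None, dtype=np.float32) -> None:
    """Write a volume as NIfTI-1; float data are stored as 32-bit float so a
    write/read round trip is bit-identical for float32 inputs."""
    if affine is None:
        affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    arr = np.asarray(data)
    if np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(dtype)
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms((voxel_size,) * 3)
    nib.save(img, os.fspath(path))


def check_cohort_grids(paths: Iterable) -> tuple[int, int, int]:
    """Verify all volumes share one grid; returns it, or names the offender."""
    shape = None
    first = None
    for p in paths:
        img = nib.load(os.fspath(p))
        if shape is None:
            shape, first = tuple(img.shape[:3]), p
        elif tuple(img.shape[:3]) != shape:
            raise ValueError(
                f"grid mismatch: {p} has {tuple(img.shape[:3])}, "
                f"but {first} has {shape}"
            )
    if shape is None:
        raise ValueError("no volumes given")
    return shape


def _format_lobes(lobes) -> str:
    return ";".join(str(int(l)) for l in sorted(lobes))


def read_hypotheses(path) -> dict[str, frozenset[int]]:
    """Read per-subject hypothesis lobe sets from CSV.

    Expects columns ``subject_id`` and ``hypothesis_lobes`` (semicolon
    separated labels; empty for controls).
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "hypothesis_lobes": str})
    out = {}
    for _, row in df.iterrows():
        raw = row.get("hypothesis_lobes")
        if isinstance(raw, str) and raw.strip():
            lobes = frozenset(int(tok) for tok in raw.split(";") if tok.strip())
        else:
            lobes = frozenset()
        out[str(row["subject_id"])] = lobes
    return out


def write_cohort(subjects: Sequence[Subject], atlas: LobarAtlas, out_dir) -> pd.DataFrame:
    """Write per-subject channels + tissue maps, the atlas, and the
    ground-truth/hypothesis table. Returns the table."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    write_volume(atlas.labels.astype(np.int16), os.path.join(out_dir, "atlas.nii.gz"),
                 atlas.voxel_size, dtype=np.int16)
    write_volume(atlas.mask.astype(np.uint8), os.path.join(out_dir, "brain_mask.nii.gz"),
                 atlas.voxel_size, dtype=np.uint8)
    rows = []
    for s in subjects:
        for ch, vol in s.channels.channels.items():
            write_volume(vol, os.path.join(out_dir, f"{s.subject_id}_{ch}.nii.gz"),
                         s.channels.voxel_size)
        for name, vol in (("gm", s.tissues.gm), ("wm", s.tissues.wm), ("csf", s.tissues.csf)):
            write_volume(vol, os.path.join(out_dir, f"{s.subject_id}_{name}.nii.gz"),
                         s.tissues.voxel_size)
        gt = s.ground_truth
        rows.append({
            "subject_id": s.subject_id,
            "group": s.group,
            "lesion_lobe": gt.lobe if gt else 0,
            "hypothesis_lobes": _format_lobes(gt.hypothesis_lobes) if gt else "",
            "center_x": gt.center[0] if gt else -1,
            "center_y": gt.center[1] if gt else -1,
            "center_z": gt.center[2] if gt else -1,
            "seed": s.seed,
        })
    table = pd.DataFrame(rows)
    table.to_csv(os.path.join(out_dir, "cohort.csv"), index=False)
    return table
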