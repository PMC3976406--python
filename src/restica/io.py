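"""NIfTI / TSV / JSON persistence for scans, masks, components, templates."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import ConfoundSet, Scan, VolumeGrid
from .decompose import ComponentSet


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    return aff


def save_mask(grid: VolumeGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(grid.brain_mask.astype(np.uint8), _affine(grid.voxel_size_mm))
    nib.save(img, str(path))


def load_grid(mask_path: str | Path) -> VolumeGrid:
    img = nib.load(str(mask_path))
    voxel = float(img.header.get_zooms()[0])
    mask = np.asarray(img.dataobj) > 0
    return VolumeGrid(dims=mask.shape, voxel_size_mm=voxel, brain_mask=mask)


def save_scan(scan: Scan, path: str | Path) -> None:
    """Write a masked scan as a 4-D NIfTI (x, y, z, t), zeros outside mask."""
    vol4 = np.zeros(scan.grid.dims + (scan.n_timepoints,), dtype=np.float32)
    vol4[scan.grid.brain_mask, :] = scan.data.T
    img = nib.Nifti1Image(vol4, _affine(scan.grid.voxel_size_mm))
    img.header.set_zooms((scan.grid.voxel_size_mm,) * 3 + (scan.tr_s,))
    nib.save(img, str(path))


def load_scan(
    path: str | Path, grid: VolumeGrid, subject: str, day: str, timepoint: str,
    tr_s: float | None = None,
) -> Scan:
    img = nib.load(str(path))
    if tr_s is None:
        tr_s = float(img.header.get_zooms()[3])
    data4 = np.asarray(img.dataobj, dtype=float)
    return Scan(subject=subject, day=day, timepoint=timepoint, tr_s=tr_s,
                data=data4[grid.brain_mask, :].T, grid=grid)


def save_map(values: np.ndarray, grid: VolumeGrid, path: str | Path) -> None:
    """Write a masked V-vector (or boolean mask) as a 3-D NIfTI volume."""
    img = nib.Nifti1Image(grid.to_volume(np.asarray(values, dtype=float)).astype(np.float32),
                          _affine(grid.voxel_size_mm))
    nib.save(img, str(path))


def load_map(path: str | Path, grid: VolumeGrid) -> np.ndarray:
    return grid.from_volume(np.asarray(nib.load(str(path)).dataobj, dtype=float))


def save_confounds(confounds: ConfoundSet, path: str | Path) -> None:
    cols = {f"trans_{ax}_mm": confounds.motion[:, i] for i, ax in enumerate("xyz")}
    cols.update({f"rot_{ax}_deg": confounds.motion[:, i + 3] for i, ax in enumerate("xyz")})
    cols["cardiac_phase"] = confounds.cardiac_phase
    cols["resp_phase"] = confounds.resp_phase
    if confounds.extra is not None:
        for j in range(confounds.extra.shape[1]):
            cols[f"extra_{j}"] = confounds.extra[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def load_confounds(path: str | Path) -> ConfoundSet:
    df = pd.read_csv(path, sep="\t")
    motion = df[[f"trans_{ax}_mm" for ax in "xyz"] + [f"rot_{ax}_deg" for ax in "xyz"]].to_numpy()
    extra_cols = [c for c in df.columns if c.startswith("extra_")]
    return ConfoundSet(
        motion=motion,
        cardiac_phase=df["cardiac_phase"].to_numpy(),
        resp_phase=df["resp_phase"].to_numpy(),
        extra=df[extra_cols].to_numpy() if extra_cols else None,
    )


def save_component_set(cs: ComponentSet, grid: VolumeGrid, prefix: str | Path) -> None:
    """Persist K maps (4-D NIfTI), courses (TSV) and a JSON sidecar."""
    prefix = Path(prefix)
    vol4 = np.zeros(grid.dims + (cs.k,), dtype=np.float32)
    vol4[grid.brain_mask, :] = cs.maps.T
    nib.save(nib.Nifti1Image(vol4, _affine(grid.voxel_size_mm)), str(prefix) + "_maps.nii.gz")
    if cs.courses is not None:
        pd.DataFrame(cs.courses.T, columns=[f"ic{j:02d}" for j in range(cs.k)]).to_csv(
            str(prefix) + "_courses.tsv", sep="\t", index=False)
    sidecar = {"subject": cs.subject, "day": cs.day, "timepoint": cs.timepoint,
               "k": cs.k, "variance_retained": cs.variance_retained}
    Path(str(prefix) + ".json").write_text(json.dumps(sidecar, indent=2))
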