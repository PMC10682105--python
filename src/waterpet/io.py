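"""File formats: 4-D NIfTI dynamic images, frame-timing text files,
trajectory/correction CSVs, TAC CSVs and ground-truth sidecars.

Internally images are ``[frame, x, y, z]`` with +x right→left, +y
posterior→anterior, +z caudal→cranial; NIfTI files are written with a
centred affine expressing that orientation and re-oriented on load via the
affine (axis-aligned affines only).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .correction import CorrectionSet
from .frames import FrameTimeGrid
from .kinetics import MBFResult
from .motion import MotionTrajectory
from .phantom import DynamicImage, GroundTruth

__all__ = [
    "save_dynamic",
    "load_dynamic",
    "save_labels",
    "load_labels",
    "save_ground_truth",
    "save_trajectory_csv",
    "load_trajectory_csv",
    "save_catalogue_yaml",
    "load_catalogue_yaml",
    "save_corrections_csv",
    "load_corrections_csv",
    "save_tac_csv",
    "load_tac_csv",
    "save_mbf_result",
]

#: Label values of the ground-truth label map.
LABELS = {"LAD": 1, "RCA": 2, "LCx": 3, "lv_cavity": 4, "rv": 5, "basal_pool": 6, "liver": 7}


def _affine(voxel_size: float, shape: tuple[int, int, int]) -> np.ndarray:
    """Centred affine for our +x-left (LAS-ordered array) convention."""
    vs = float(voxel_size)
    aff = np.diag([-vs, vs, vs, 1.0])
    aff[:3, 3] = [vs * (shape[0] - 1) / 2, -vs * (shape[1] - 1) / 2, -vs * (shape[2] - 1) / 2]
    return aff


def save_dynamic(image: DynamicImage, path: str | Path, timing_path: str | Path | None = None) -> None:
    """Write a 4-D NIfTI (4th dimension = frames) and optionally the
    two-column frame-timing file."""
    data = np.moveaxis(np.asarray(image.voxels), 0, -1)       # (x, y, z, t)
    img = nib.Nifti1Image(data.astype(np.float32), _affine(image.voxel_size, data.shape[:3]))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    if timing_path is not None:
        image.frame_grid.to_file(timing_path)


def _to_package_axes(img: nib.Nifti1Image) -> tuple[np.ndarray, np.ndarray]:
    """Reorient an axis-aligned NIfTI to +x-left / +y-anterior / +z-cranial."""
    canonical = nib.as_closest_canonical(img)                  # RAS+
    data = np.asanyarray(canonical.dataobj)
    data = data[::-1]                                          # RAS x → right-to-left
    zooms = np.asarray(canonical.header.get_zooms()[:3], float)
    return data, zooms


def load_dynamic(path: str | Path, timing_path: str | Path) -> DynamicImage:
    """Load a 4-D NIfTI plus frame-timing file as a `DynamicImage`."""
    img = nib.load(str(path))
    data, zooms = _to_package_axes(img)
    if data.ndim != 4:
        raise ValueError("expected a 4-D NIfTI (x, y, z, frames)")
    if not np.allclose(zooms, zooms[0], rtol=1e-3):
        raise ValueError(f"anisotropic voxels {zooms} not supported")
    grid = FrameTimeGrid.from_file(timing_path)
    voxels = np.moveaxis(data, -1, 0).astype(np.float32)
    return DynamicImage(voxels, float(zooms[0]), grid)


def save_labels(truth: GroundTruth, voxel_size: float, path: str | Path) -> None:
    """Write the ground-truth masks as a 3-D NIfTI label map."""
    shape = truth.myocardium_mask.shape
    lab = np.zeros(shape, dtype=np.int16)
    lab[truth.liver_mask] = LABELS["liver"]
    lab[truth.basal_pool_mask] = LABELS["basal_pool"]
    lab[truth.rv_mask] = LABELS["rv"]
    lab[truth.lv_cavity_mask] = LABELS["lv_cavity"]
    for name in ("LAD", "RCA", "LCx"):
        lab[truth.territory_masks[name]] = LABELS[name]
    nib.save(nib.Nifti1Image(lab, _affine(voxel_size, shape)), str(path))


def load_labels(path: str | Path) -> dict[str, np.ndarray]:
    """Load a label map back into boolean masks keyed as in ``LABELS``."""
    data, _ = _to_package_axes(nib.load(str(path)))
    return {name: data == val for name, val in LABELS.items()}


def save_ground_truth(truth: GroundTruth, voxel_size: float, out_dir: str | Path) -> None:
    """Write label map + JSON sidecar with true parameters and geometry."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_labels(truth, voxel_size, out / "labels.nii.gz")
    side = {
        "true_params": {
            t: {"mbf": p.mbf, "ptf": p.ptf, "va": p.va, "p": p.p}
            for t, p in truth.true_params.items()
        },
        "aif": {
            "t0": truth.aif.t0, "amplitude": truth.aif.amplitude,
            "alpha": truth.aif.alpha, "beta": truth.aif.beta,
            "recirculation_fraction": truth.aif.recirculation_fraction,
            "recirculation_tau": truth.aif.recirculation_tau,
        },
        "center_vox": truth.center_vox.tolist(),
        "long_axis": truth.long_axis.tolist(),
        "anterior_ref": truth.anterior_ref.tolist(),
        "labels": LABELS,
    }
    (out / "ground_truth.json").write_text(json.dumps(side, indent=2))


def save_trajectory_csv(traj: MotionTrajectory, path: str | Path) -> None:
    df = pd.DataFrame(traj.shifts, columns=["dx_mm", "dy_mm", "dz_mm"])
    df.insert(0, "frame", np.arange(len(traj)))
    df.to_csv(path, index=False)


def load_trajectory_csv(path: str | Path, label: str = "from-file", family: str = "custom") -> MotionTrajectory:
    df = pd.read_csv(path)
    return MotionTrajectory(label, family, df[["dx_mm", "dy_mm", "dz_mm"]].to_numpy(float))


def save_catalogue_yaml(catalogue: list[MotionTrajectory], path: str | Path) -> None:
    """Serialize a motion catalogue as YAML (label, family, per-frame mm)."""
    doc = [
        {"label": t.label, "family": t.family,
         "shifts_mm": [[float(v) for v in row] for row in t.shifts]}
        for t in catalogue
    ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_catalogue_yaml(path: str | Path) -> list[MotionTrajectory]:
    doc = yaml.safe_load(Path(path).read_text())
    return [
        MotionTrajectory(d["label"], d["family"], np.asarray(d["shifts_mm"], float))
        for d in doc
    ]


def save_corrections_csv(corr: CorrectionSet, path: str | Path) -> None:
    df = pd.DataFrame(corr.shifts_mm, columns=["dx_mm", "dy_mm", "dz_mm"])
    df.insert(0, "frame", np.arange(len(corr)))
    df.to_csv(path, index=False)


def load_corrections_csv(path: str | Path) -> CorrectionSet:
    df = pd.read_csv(path)
    return CorrectionSet(df[["dx_mm", "dy_mm", "dz_mm"]].to_numpy())


def save_tac_csv(curve: np.ndarray, grid: FrameTimeGrid, path: str | Path, name: str = "value") -> None:
    pd.DataFrame({
        "time_start": grid.frame_starts,
        "time_end": grid.frame_ends,
        name: np.asarray(curve, float),
    }).to_csv(path, index=False)


def load_tac_csv(path: str | Path, name: str = "value") -> tuple[np.ndarray, FrameTimeGrid]:
    df = pd.read_csv(path)
    grid = FrameTimeGrid(df["time_start"].to_numpy(float), df["time_end"].to_numpy(float))
    return df[name].to_numpy(float), grid


def save_mbf_result(result: MBFResult, path_json: str | Path, path_csv: str | Path | None = None) -> None:
    d = result.as_dict()
    Path(path_json).write_text(json.dumps(d, indent=2))
    if path_csv is not None:
        pd.DataFrame([d]).to_csv(path_csv, index=False)
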