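"""File round-tripping: NRRD/NIfTI rasters, plan files, DVH tables, configs.

Rasters are written as NRRD (masks as unsigned 8-bit) and read back from
NRRD or NIfTI via SimpleITK.  Plans are stored as structured JSON (beams,
weights, objective trace); DVHs as CSV.  Array axis order on disk follows
the image convention (z, y, x) and is transposed to this package's (x, y, z)
on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import yaml

from .grid import VoxelGrid
from .lens import Beam
from .optimize import Plan

__all__ = [
    "read_volume",
    "read_mask",
    "write_nrrd",
    "write_mask",
    "read_structure_dir",
    "save_plan",
    "load_plan",
    "save_dvhs",
]

RASTER_SUFFIXES = (".nrrd", ".nii", ".nii.gz")


def read_volume(path: str | Path) -> VoxelGrid:
    """Read a scalar raster (NRRD or NIfTI) into a VoxelGrid."""
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).astype(float).transpose(2, 1, 0)
    return VoxelGrid(arr, spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin()))


def read_mask(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    """Read a binary mask raster; returns (bool array, geometry grid)."""
    grid = read_volume(path)
    return grid.values > 0.5, grid


def _to_image(grid: VoxelGrid, values: np.ndarray) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    return img


def write_nrrd(grid: VoxelGrid, path: str | Path) -> None:
    """Write a scalar grid as NRRD (float64)."""
    sitk.WriteImage(_to_image(grid, grid.values), str(path))


def write_mask(mask: np.ndarray, grid: VoxelGrid, path: str | Path) -> None:
    """Write a binary mask as unsigned 8-bit NRRD."""
    sitk.WriteImage(_to_image(grid, np.asarray(mask).astype(np.uint8)), str(path))


def read_structure_dir(path: str | Path) -> tuple[dict[str, np.ndarray], VoxelGrid]:
    """Read every mask raster in a directory, keyed by file stem.

    Files named ``density.*`` are skipped.
    """
    path = Path(path)
    masks: dict[str, np.ndarray] = {}
    grid = None
    for f in sorted(path.iterdir()):
        if not any(f.name.endswith(s) for s in RASTER_SUFFIXES):
            continue
        stem = f.name.split(".")[0]
        if stem.lower() == "density":
            continue
        mask, g = read_mask(f)
        masks[stem] = mask
        grid = grid or g
    if not masks:
        raise FileNotFoundError(f"no mask rasters found in {path}")
    return masks, grid


def save_plan(plan: Plan, path: str | Path) -> None:
    """Save a plan as structured JSON (beams, weights, trace, prescription)."""
    payload = {
        "prescription_gy": plan.prescription_gy,
        "fractions": plan.fractions,
        "beams": [
            {
                "target_mm": list(b.target),
                "direction": list(b.direction),
                "weight": float(b.weight),
            }
            for b in plan.beams
        ],
        "objective_trace": [float(v) for v in plan.trace],
        "constraint_violations": plan.constraint_violations,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_plan(path: str | Path) -> Plan:
    """Load a plan saved by :func:`save_plan` (dose grid not included)."""
    payload = json.loads(Path(path).read_text())
    beams = [
        Beam(tuple(b["target_mm"]), tuple(b["direction"]), float(b["weight"]))
        for b in payload["beams"]
    ]
    return Plan(
        beams=beams,
        weights=np.array([b.weight for b in beams]),
        dose=VoxelGrid(np.zeros((1, 1, 1))),
        trace=list(payload["objective_trace"]),
        prescription_gy=float(payload["prescription_gy"]),
        fractions=int(payload["fractions"]),
        constraint_violations=payload.get("constraint_violations", {}),
    )


def save_dvhs(dvhs: dict, path: str | Path) -> None:
    """Write a set of DVH curves as one CSV (structure, dose_gy, volume_fraction)."""
    frames = [curve.to_frame() for curve in dvhs.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_yaml(path: str | Path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path} does not contain a mapping")
    return data
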