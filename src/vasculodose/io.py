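"""File formats: phantoms, vessel trees, dose grids, DVHs and reports.

Phantom and dose grids are stored as raw little-endian arrays next to a
JSON sidecar describing shape, voxel size, label/material map and
provenance; vessel trees and DVH curves are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dosimetry import CDVHCurve
from .phantom import (
    DEFAULT_DENSITIES, LABEL_MATERIALS, LABEL_NAMES, VesselSegment, VesselTree,
    VoxelPhantom,
)
from .transport import DoseGrid


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_phantom(phantom: VoxelPhantom, path) -> Path:
    path = Path(path)
    phantom.labels.astype("<u1").tofile(path)
    meta = {
        "grid_shape": list(phantom.labels.shape),
        "voxel_size_nm": phantom.voxel_size_nm,
        "dtype": "<u1",
        "labels": {str(k): v for k, v in LABEL_NAMES.items()},
        "materials": {str(k): v for k, v in LABEL_MATERIALS.items()},
        "densities_g_cm3": {str(k): v for k, v in phantom.densities_by_label.items()},
        "metadata": _jsonable(phantom.metadata),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def load_phantom(path) -> VoxelPhantom:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    shape = tuple(meta["grid_shape"])
    labels = np.fromfile(path, dtype="<u1").reshape(shape)
    densities = {int(k): v for k, v in meta["densities_g_cm3"].items()}
    md = meta.get("metadata", {})
    for key in ("gold_voxel_indices", "gold_host_labels"):
        if key in md and md[key] is not None:
            md[key] = np.asarray(md[key])
    return VoxelPhantom(labels=labels, voxel_size_nm=meta["voxel_size_nm"],
                        densities_by_label=densities, metadata=md)


def save_tree(tree: VesselTree, path) -> Path:
    path = Path(path)
    rows = [
        {
            "start_x_um": s.start_point[0], "start_y_um": s.start_point[1],
            "start_z_um": s.start_point[2],
            "end_x_um": s.end_point[0], "end_y_um": s.end_point[1],
            "end_z_um": s.end_point[2],
            "inner_radius_um": s.inner_radius,
            "wall_thickness_um": s.wall_thickness,
            "parent_index": -1 if s.parent_index is None else s.parent_index,
        }
        for s in tree.segments
    ]
    pd.DataFrame(rows, columns=[
        "start_x_um", "start_y_um", "start_z_um", "end_x_um", "end_y_um",
        "end_z_um", "inner_radius_um", "wall_thickness_um", "parent_index",
    ]).to_csv(path, index=False)
    return path


def load_tree(path, cube_side: float, rng_seed: int = -1) -> VesselTree:
    df = pd.read_csv(path)
    segments = [
        VesselSegment(
            np.array([r.start_x_um, r.start_y_um, r.start_z_um]),
            np.array([r.end_x_um, r.end_y_um, r.end_z_um]),
            r.inner_radius_um, r.wall_thickness_um,
            None if r.parent_index < 0 else int(r.parent_index),
        )
        for r in df.itertuples()
    ]
    entry = segments[0].start_point if segments else np.zeros(3)
    exit_ = segments[-1].end_point if segments else np.zeros(3)
    return VesselTree(segments=segments, arterial_entry=entry, venous_exit=exit_,
                      rng_seed=rng_seed, cube_side=cube_side)


def save_dose(grid: DoseGrid, path) -> Path:
    path = Path(path)
    grid.dose.astype("<f4").tofile(path)
    meta = {
        "grid_shape": list(grid.dose.shape),
        "dtype": "<f4",
        "meta": _jsonable(grid.meta),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def save_cdvh(curves: list[CDVHCurve], path) -> Path:
    path = Path(path)
    frames = [
        pd.DataFrame({"dose_Gy": c.dose_gy, "volume_fraction": c.volume_fraction,
                      "compartment": c.compartment})
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
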