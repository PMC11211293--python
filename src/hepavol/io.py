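"""NIfTI-1 label-volume I/O with JSON sidecars.

A label volume is stored as one integer-coded ``.nii.gz`` plus a JSON
sidecar (same path with ``.json`` extension) holding the label map and any
case metadata (condition, resection, seed).  Ground-truth vessel trees are
stored as JSON polylines in physical mm coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping, Optional

import nibabel as nib
import numpy as np

from .vesseltree import Centerline, VesselTree
from .volume import LabelVolume, Structure


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_label_volume(
    volume: LabelVolume, path: str | Path, meta: Optional[Mapping[str, Any]] = None
) -> Path:
    """Write a label volume as NIfTI-1 (.nii/.nii.gz) with a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.grid, dtype=np.int16), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    sidecar = {"label_map": dict(volume.label_map)}
    if meta:
        sidecar.update(meta)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_label_volume(path: str | Path) -> tuple[LabelVolume, dict]:
    """Read a NIfTI-1 label volume and its sidecar; returns (volume, meta).

    Rejects non-integer on-disk data and missing sidecars with descriptive
    errors; the round trip preserves grid values, spacing (to float32
    precision) and the label map exactly.
    """
    path = Path(path)
    img = nib.load(str(path))
    dtype = img.get_data_dtype()
    if np.dtype(dtype).kind not in "iu":
        raise ValueError(f"{path}: label volumes must hold integers, found dtype {dtype}")
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"{path}: missing JSON sidecar {sidecar_path.name}")
    sidecar = json.loads(sidecar_path.read_text())
    if "label_map" not in sidecar:
        raise ValueError(f"{sidecar_path}: sidecar lacks a 'label_map'")
    label_map = {str(k): int(v) for k, v in sidecar["label_map"].items()}
    unknown = [k for k in label_map if k not in Structure.__members__]
    if unknown:
        raise ValueError(f"{sidecar_path}: unknown structure names {unknown}")
    grid = np.asanyarray(img.dataobj).astype(np.int16)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    meta = {k: v for k, v in sidecar.items() if k != "label_map"}
    return LabelVolume(grid=grid, spacing=spacing, label_map=label_map), meta


def write_vessel_trees(trees: Mapping[Structure, VesselTree], path: str | Path) -> Path:
    """Serialize ground-truth vessel centerlines as JSON polylines (mm)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        tree.vessel.value: {
            "trunk": np.round(tree.trunk.points, 4).tolist(),
            "branches": [np.round(b.points, 4).tolist() for b in tree.branches],
        }
        for tree in trees.values()
    }
    path.write_text(json.dumps(doc, sort_keys=True))
    return path


def read_vessel_trees(path: str | Path) -> dict[Structure, VesselTree]:
    doc = json.loads(Path(path).read_text())
    trees: dict[Structure, VesselTree] = {}
    for name, entry in doc.items():
        vessel = Structure(name)
        trees[vessel] = VesselTree(
            vessel=vessel,
            trunk=Centerline(np.asarray(entry["trunk"], dtype=float)),
            branches=tuple(
                Centerline(np.asarray(b, dtype=float)) for b in entry["branches"]
            ),
        )
    return trees
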