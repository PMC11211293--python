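"""Label-volume container and the structure vocabulary for liver label maps.

A :class:`LabelVolume` is the universal image currency of the package: a 3D
grid of non-negative integer codes with a physical voxel spacing (mm) and a
mapping from anatomical structure names to those codes.  Every voxel carries
at most one label; the liver parenchyma is represented by the pair of labels
``REMNANT`` / ``RESECT`` (the planned resection partition), and vessels and
lesions carve their own voxels out of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np


class Structure(str, Enum):
    """Closed vocabulary of anatomical structures carried by a label volume."""

    LIVER = "LIVER"          # whole-liver label (used by plain liver masks)
    LESION = "LESION"
    REMNANT = "REMNANT"      # parenchyma retained after the planned resection
    RESECT = "RESECT"        # parenchyma removed by the planned resection
    RHV = "RHV"              # right hepatic vein
    MHV = "MHV"              # middle hepatic vein
    LHV = "LHV"              # left hepatic vein
    SRHV = "SRHV"            # superior right hepatic vein
    IRHV = "IRHV"            # inferior right hepatic vein
    MPV = "MPV"              # main portal vein (may run outside the liver)
    RPV = "RPV"              # right portal vein
    LPV = "LPV"              # left portal vein
    IVC = "IVC"              # inferior vena cava (landmark, extrahepatic)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


HEPATIC_VEINS: tuple[Structure, ...] = (
    Structure.RHV,
    Structure.MHV,
    Structure.LHV,
    Structure.SRHV,
    Structure.IRHV,
)
PORTAL_VEINS: tuple[Structure, ...] = (Structure.MPV, Structure.RPV, Structure.LPV)
#: Portal labels that are intrahepatic by the annotation protocol.  The main
#: portal vein is treated separately because it may run outside the liver.
INTRAHEPATIC_PORTAL: tuple[Structure, ...] = (Structure.RPV, Structure.LPV)
ALL_VESSELS: tuple[Structure, ...] = HEPATIC_VEINS + PORTAL_VEINS

#: Structure groups over which segmentation quality is reported (one Dice /
#: volumetric-similarity value per group, not per named vessel).
STRUCTURE_GROUPS: dict[str, tuple[Structure, ...]] = {
    "liver": (Structure.LIVER, Structure.REMNANT, Structure.RESECT, Structure.LESION),
    "hepatic_veins": HEPATIC_VEINS,
    "portal_veins": PORTAL_VEINS,
}

DEFAULT_LABEL_MAP: dict[str, int] = {
    Structure.REMNANT.value: 1,
    Structure.RESECT.value: 2,
    Structure.LESION.value: 3,
    Structure.RHV.value: 4,
    Structure.MHV.value: 5,
    Structure.LHV.value: 6,
    Structure.SRHV.value: 7,
    Structure.IRHV.value: 8,
    Structure.MPV.value: 9,
    Structure.RPV.value: 10,
    Structure.LPV.value: 11,
    Structure.IVC.value: 12,
}


def _as_name(name: Structure | str) -> str:
    return name.value if isinstance(name, Structure) else str(name)


@dataclass(frozen=True)
class LabelVolume:
    """3D integer label grid with physical voxel spacing.

    Parameters
    ----------
    grid
        3D array of non-negative integer labels.  Frozen (read-only) after
        construction.
    spacing
        Physical size of one voxel along each axis, in mm.
    label_map
        Mapping from structure name to the integer code used in ``grid``.
        Every nonzero code present in the grid must appear here.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    label_map: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise ValueError(f"grid must be 3D, got ndim={grid.ndim}")
        if not np.issubdtype(grid.dtype, np.integer):
            raise ValueError(f"grid must hold integers, got dtype={grid.dtype}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        label_map = {_as_name(k): int(v) for k, v in self.label_map.items()}
        present = np.unique(grid)
        known = set(label_map.values()) | {0}
        unknown = [int(v) for v in present if int(v) not in known]
        if unknown:
            raise ValueError(f"grid contains codes absent from label_map: {unknown}")
        grid = np.ascontiguousarray(grid)
        grid.setflags(write=False)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "label_map", label_map)

    # ------------------------------------------------------------------ masks
    def has(self, name: Structure | str) -> bool:
        return _as_name(name) in self.label_map

    def code(self, name: Structure | str) -> int:
        key = _as_name(name)
        try:
            return self.label_map[key]
        except KeyError:
            raise KeyError(
                f"structure {key!r} not in label_map (known: {sorted(self.label_map)})"
            ) from None

    def mask(self, name: Structure | str) -> np.ndarray:
        """Boolean mask of one structure. Raises KeyError on unknown names."""
        return self.grid == self.code(name)

    def mask_union(
        self, names: Iterable[Structure | str], *, missing: str = "skip"
    ) -> np.ndarray:
        """Boolean union of several structures.

        ``missing='skip'`` silently ignores names absent from the label map
        (useful for structure groups on volumes that carry only a subset);
        ``missing='raise'`` propagates the KeyError.
        """
        out = np.zeros(self.grid.shape, dtype=bool)
        for name in names:
            if not self.has(name):
                if missing == "raise":
                    self.code(name)  # raises
                continue
            out |= self.mask(name)
        return out

    # ------------------------------------------------------------- geometry
    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.grid.shape)  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def voxel_of(self, point_mm: np.ndarray) -> tuple[int, int, int]:
        """Voxel index containing a physical point (voxel centers at i*spacing)."""
        idx = np.round(np.asarray(point_mm, dtype=float) / np.asarray(self.spacing))
        return tuple(int(i) for i in idx)

    def with_grid(self, grid: np.ndarray) -> "LabelVolume":
        """New volume sharing spacing and label_map with a replaced grid."""
        return LabelVolume(grid=grid, spacing=self.spacing, label_map=dict(self.label_map))
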