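"""Blood-filled vs blood-free future-liver-remnant (FLR) volumetry.

CT volumetry measures a *blood-filled* liver: the voxels of the large
hepatic and portal veins are counted as liver.  Intraoperative volumetry is
*blood-free*.  This module computes total liver volume (TLV), FLR and FLR%
in both settings from a single label volume:

    FLR% = FLR / (TLV − V_Lesion) × 100%

with the blood-free quantities obtained by removing every hepatic- and
portal-vein voxel that lies inside the liver.  Voxels of the IVC, and of the
main portal vein outside the liver, are never counted in either setting.
A patient is a candidate for major hepatectomy when FLR% exceeds a
condition-dependent floor: 20% (healthy liver), 30% (steatosis), 40%
(cirrhosis); the comparison is strict ("larger than").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .metrics import mask_volume_ml
from .volume import HEPATIC_VEINS, INTRAHEPATIC_PORTAL, LabelVolume, Structure

CONDITIONS = ("healthy", "fatty", "cirrhosis")
#: Minimum FLR% that must be *exceeded* for major-hepatectomy candidacy.
CANDIDACY_THRESHOLDS_PCT = {"healthy": 20.0, "fatty": 30.0, "cirrhosis": 40.0}

RESECTION_TYPES = ("left", "right", "extended_right")


@dataclass(frozen=True)
class ResectionPlan:
    """Oblique resection plane: the resected side is where n·(x − p) > 0."""

    point_mm: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plan normal must be nonzero")
        object.__setattr__(self, "normal", tuple(n / norm))
        object.__setattr__(self, "point_mm", tuple(float(c) for c in self.point_mm))

    def resect_side(self, points_mm: np.ndarray) -> np.ndarray:
        """Boolean: True where a physical point lies on the resected side."""
        d = np.asarray(points_mm, dtype=float) - np.asarray(self.point_mm)
        return d @ np.asarray(self.normal) > 0


@dataclass(frozen=True)
class VolumetryResult:
    """Blood-filled and blood-free liver volumetry of one case (all mL / %)."""

    tlv_filled: float
    tlv_free: float
    v_lesion: float
    v_hv: float
    v_pv: float
    flr_filled: float
    flr_free: float
    flr_pct_filled: float
    flr_pct_free: float


@dataclass(frozen=True)
class CandidacyDecision:
    """Major-hepatectomy candidacy under one FLR% measurement."""

    candidate: bool
    threshold_pct: float
    condition: str
    basis: str  # "blood_filled" or "blood_free"


def parenchyma_mask(volume: LabelVolume) -> np.ndarray:
    """Liver parenchyma voxels: REMNANT ∪ RESECT, or the plain LIVER label."""
    mask = volume.mask_union((Structure.REMNANT, Structure.RESECT, Structure.LIVER))
    return mask


def liver_region_mask(volume: LabelVolume) -> np.ndarray:
    """Support of the whole liver: parenchyma, lesion and intrahepatic vessels.

    Hepatic veins and the right/left portal veins are intrahepatic by the
    annotation protocol; the region is hole-filled so that any main-portal-
    vein voxels enclosed by it count as intrahepatic.
    """
    base = parenchyma_mask(volume)
    if not base.any():
        raise ValueError("volume has no liver parenchyma (REMNANT/RESECT/LIVER labels)")
    base = base | volume.mask_union((Structure.LESION,))
    base = base | volume.mask_union(HEPATIC_VEINS) | volume.mask_union(INTRAHEPATIC_PORTAL)
    return ndimage.binary_fill_holes(base)


def intrahepatic_vessel_masks(volume: LabelVolume) -> tuple[np.ndarray, np.ndarray]:
    """(hepatic-vein, portal-vein) voxel masks inside the liver.

    All hepatic-vein voxels and RPV/LPV voxels are intrahepatic; main portal
    vein voxels count only where they fall inside the filled liver region.
    """
    region = liver_region_mask(volume)
    hv = volume.mask_union(HEPATIC_VEINS)
    pv = volume.mask_union(INTRAHEPATIC_PORTAL)
    if volume.has(Structure.MPV):
        pv = pv | (volume.mask(Structure.MPV) & region)
    return hv, pv


def blood_free_masks(volume: LabelVolume) -> LabelVolume:
    """Remove intrahepatic hepatic- and portal-vein voxels from a label volume.

    The returned volume carries the same spacing and label vocabulary; vessel
    voxels inside the liver are cleared (set to background) so that liver /
    remnant / resect masks computed from it are blood-free.  A volume without
    vessel voxels is returned unchanged.
    """
    hv, pv = intrahepatic_vessel_masks(volume)
    blood = hv | pv
    if not blood.any():
        return volume
    grid = volume.grid.copy()
    grid[blood] = 0
    return volume.with_grid(grid)


def _side_split(
    volume: LabelVolume, mask: np.ndarray, plan: Optional[ResectionPlan]
) -> np.ndarray:
    """Remnant-side membership for voxels of ``mask`` (lesion / vessel voxels).

    With a resection plan, the side is geometric.  Without one, each voxel is
    assigned the side of its nearest parenchyma voxel (Euclidean, in mm).
    Returns a boolean array: True where the voxel belongs to the remnant side.
    """
    if not mask.any():
        return np.zeros_like(mask)
    if plan is not None:
        idx = np.argwhere(mask)
        pts = idx * np.asarray(volume.spacing)
        remnant_side = ~plan.resect_side(pts)
        out = np.zeros_like(mask)
        out[tuple(idx.T)] = remnant_side
        return out
    remnant = volume.mask(Structure.REMNANT)
    resect = volume.mask_union((Structure.RESECT,))
    parenchyma = remnant | resect
    if not parenchyma.any():
        raise ValueError("cannot assign sides: no remnant/resect parenchyma present")
    _, inds = ndimage.distance_transform_edt(
        ~parenchyma, sampling=volume.spacing, return_indices=True
    )
    nearest_label = volume.grid[inds[0], inds[1], inds[2]]
    out = np.zeros_like(mask)
    out[mask] = nearest_label[mask] == volume.code(Structure.REMNANT)
    return out


def volumetry(volume: LabelVolume, plan: Optional[ResectionPlan] = None) -> VolumetryResult:
    """Blood-filled and blood-free TLV / FLR / FLR% of one labeled case.

    Requires the remnant/resect parenchyma partition.  Lesion and intrahepatic
    vessel voxels are attributed to a side either by the resection plane
    (``plan``) or, when none is given, by nearest-parenchyma assignment.
    Lesion voxels count inside TLV and (on the remnant side) inside FLR in
    both settings; V_Lesion is subtracted only in the FLR% denominator.
    """
    if not volume.has(Structure.REMNANT):
        raise ValueError("volumetry requires a REMNANT/RESECT parenchyma partition")
    spacing = volume.spacing
    remnant = volume.mask(Structure.REMNANT)
    lesion = volume.mask_union((Structure.LESION,))
    hv, pv = intrahepatic_vessel_masks(volume)
    vessels = hv | pv
    parenchyma = parenchyma_mask(volume)

    lesion_remnant = lesion & _side_split(volume, lesion, plan) if lesion.any() else lesion
    vessels_remnant = vessels & _side_split(volume, vessels, plan) if vessels.any() else vessels

    v_lesion = mask_volume_ml(lesion, spacing)
    v_hv = mask_volume_ml(hv, spacing)
    v_pv = mask_volume_ml(pv, spacing)
    tlv_filled = mask_volume_ml(parenchyma | lesion | vessels, spacing)
    tlv_free = tlv_filled - v_hv - v_pv
    flr_filled = mask_volume_ml(remnant | lesion_remnant | vessels_remnant, spacing)
    flr_free = flr_filled - mask_volume_ml(vessels_remnant, spacing)

    denom_filled = tlv_filled - v_lesion
    denom_free = tlv_free - v_lesion
    if denom_filled <= 0 or denom_free <= 0:
        raise ValueError(
            f"degenerate nontumor liver volume (TLV−V_Lesion = "
            f"{denom_filled:.2f} / {denom_free:.2f} mL)"
        )
    return VolumetryResult(
        tlv_filled=tlv_filled,
        tlv_free=tlv_free,
        v_lesion=v_lesion,
        v_hv=v_hv,
        v_pv=v_pv,
        flr_filled=flr_filled,
        flr_free=flr_free,
        flr_pct_filled=100.0 * flr_filled / denom_filled,
        flr_pct_free=100.0 * flr_free / denom_free,
    )


def candidacy(flr_pct: float, condition: str, basis: str = "blood_free") -> CandidacyDecision:
    """Major-hepatectomy candidacy: FLR% strictly above the condition floor."""
    if condition not in CANDIDACY_THRESHOLDS_PCT:
        raise ValueError(f"unknown liver condition {condition!r}; expected one of {CONDITIONS}")
    if not 0.0 <= flr_pct <= 100.0:
        raise ValueError(f"FLR% must lie in [0, 100], got {flr_pct}")
    threshold = CANDIDACY_THRESHOLDS_PCT[condition]
    return CandidacyDecision(
        candidate=flr_pct > threshold,
        threshold_pct=threshold,
        condition=condition,
        basis=basis,
    )
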