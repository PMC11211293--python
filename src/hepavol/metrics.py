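"""Segmentation-quality metrics: Dice similarity and volumetric similarity.

Both metrics operate on boolean voxel masks of equal shape.  DSC measures
voxelwise overlap, DSC = 2|P∩G| / (|P|+|G|); VS measures only the agreement
of total volumes, VS = 1 − |V_G − V_P| / (V_G + V_P), and is therefore
insensitive to where the voxels sit.  For any pair of masks VS ≥ DSC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .volume import STRUCTURE_GROUPS, LabelVolume


@dataclass(frozen=True)
class OverlapResult:
    """Per-structure-group overlap metrics plus physical volumes (mL)."""

    dsc: float
    vs: float
    volume_pred_ml: float
    volume_truth_ml: float


def _check_shapes(pred_mask: np.ndarray, truth_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred_mask, dtype=bool)
    g = np.asarray(truth_mask, dtype=bool)
    if p.shape != g.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {g.shape}")
    return p, g


def dice(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """Dice similarity coefficient 2|P∩G|/(|P|+|G|).

    Two empty masks score 1.0 (perfect agreement on absence).
    """
    p, g = _check_shapes(pred_mask, truth_mask)
    np_, ng = int(p.sum()), int(g.sum())
    if np_ + ng == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(p & g)) / (np_ + ng)


def volumetric_similarity(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """Volumetric similarity 1 − |V_G − V_P|/(V_G + V_P).

    Position-independent: depends only on the two volumes.  Two empty masks
    score 1.0; exactly one empty mask scores 0.0.
    """
    p, g = _check_shapes(pred_mask, truth_mask)
    np_, ng = int(p.sum()), int(g.sum())
    if np_ + ng == 0:
        return 1.0
    return 1.0 - abs(ng - np_) / (ng + np_)


def mask_volume_ml(mask: np.ndarray, spacing: Sequence[float]) -> float:
    """Physical volume of a boolean mask in mL (= cm³)."""
    sx, sy, sz = (float(s) for s in spacing)
    if min(sx, sy, sz) <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    return int(np.count_nonzero(mask)) * sx * sy * sz / 1000.0


def overlap_metrics(
    pred_mask: np.ndarray, truth_mask: np.ndarray, spacing: Sequence[float]
) -> OverlapResult:
    return OverlapResult(
        dsc=dice(pred_mask, truth_mask),
        vs=volumetric_similarity(pred_mask, truth_mask),
        volume_pred_ml=mask_volume_ml(pred_mask, spacing),
        volume_truth_ml=mask_volume_ml(truth_mask, spacing),
    )


def evaluate_structure_groups(
    pred: LabelVolume,
    truth: LabelVolume,
    groups: dict[str, Iterable] | None = None,
) -> pd.DataFrame:
    """Per-group overlap metrics between a predicted and a truth label volume.

    Groups default to the reporting convention of one metric per vessel
    system: ``liver`` (parenchyma + lesion), ``hepatic_veins`` (union of the
    five named hepatic veins) and ``portal_veins`` (union of the three portal
    labels).  Returns one row per group with columns ``group, dsc, vs,
    volume_pred_ml, volume_truth_ml``.
    """
    if pred.shape != truth.shape:
        raise ValueError(f"volume shapes differ: {pred.shape} vs {truth.shape}")
    groups = dict(STRUCTURE_GROUPS) if groups is None else groups
    rows = []
    for name, members in groups.items():
        pm = pred.mask_union(members)
        gm = truth.mask_union(members)
        r = overlap_metrics(pm, gm, truth.spacing)
        rows.append(
            {
                "group": name,
                "dsc": r.dsc,
                "vs": r.vs,
                "volume_pred_ml": r.volume_pred_ml,
                "volume_truth_ml": r.volume_truth_ml,
            }
        )
    return pd.DataFrame(rows)
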