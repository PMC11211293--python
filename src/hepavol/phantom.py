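"""Synthetic CT-like liver label phantoms with hepatic/portal vessel trees.

The generator emulates the annotation protocol of clinical liver volumetry
studies: a deformed-ellipsoid liver, five named hepatic veins and three
portal labels built as capsule-swept polyline trees annotated to the second
branch ramification with every tube at least 2 mm in diameter, an IVC
landmark outside the liver, one or more lesions on the resected side, and a
remnant/resect parenchyma partition defined by an oblique resection plane.
The labeled blood pool is calibrated to a target fraction of the liver
volume (default 9%).

A perturbation simulator stands in for an automated segmentation model: it
degrades the ground-truth labels with spatially smooth boundary noise,
bisecting the noise amplitude per structure group until a requested Dice
score is met, and can drop whole primary branches of a vessel.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .flr import RESECTION_TYPES, ResectionPlan
from .metrics import dice
from .vesseltree import Centerline, VesselTree
from .volume import (
    DEFAULT_LABEL_MAP,
    HEPATIC_VEINS,
    INTRAHEPATIC_PORTAL,
    LabelVolume,
    Structure,
)


class PhantomError(ValueError):
    """Raised when the requested phantom geometry is infeasible."""


class PerturbationError(ValueError):
    """Raised when a perturbation target cannot be met."""


def child_seed(master: int, *tags: Union[str, int]) -> int:
    """Deterministic named substream seed derived from a master seed (< 2^31)."""
    h = zlib.crc32(repr((int(master),) + tags).encode())
    return int(h % (2**31))


def _rng(master: int, *tags: Union[str, int]) -> np.random.Generator:
    return np.random.default_rng(child_seed(master, *tags))


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and protocol parameters of one synthetic patient.

    All lengths in mm.  ``generations=2`` means trunk + primary branches +
    the origin segments of secondary branches (annotation to the second
    ramification); the tube-diameter floor of 2 mm (``min_radius_mm=1``)
    mirrors the annotation floor of the protocol.  ``blood_fraction_target``
    is the fraction of the liver volume occupied by labeled vessels, with
    the literature figure of ~9% as default.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    liver_axes: tuple[float, float, float] = (50.0, 38.0, 30.0)
    surface_irregularity: float = 0.12
    lesion_count: int = 1
    lesion_radius_range: tuple[float, float] = (8.0, 16.0)
    trunk_radius_mm: float = 3.4
    taper: float = 0.65
    branch_angle_deg: tuple[float, float] = (25.0, 50.0)
    generations: int = 2
    min_radius_mm: float = 1.0
    blood_fraction_target: float = 0.09
    resection_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"left": 0.33, "right": 0.62, "extended_right": 0.75}
    )
    condition: str = "healthy"
    resection: str = "right"

    def __post_init__(self) -> None:
        if self.min_radius_mm < 1.0:
            raise ValueError("min_radius_mm must be >= 1.0 (2 mm diameter floor)")
        if not (0.0 < self.blood_fraction_target < 0.2):
            raise ValueError("blood_fraction_target must lie in (0, 0.2)")
        if self.generations != 2:
            raise ValueError("vessel trees are annotated to the second ramification (generations=2)")
        if self.condition not in ("healthy", "fatty", "cirrhosis"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.resection not in RESECTION_TYPES:
            raise ValueError(f"unknown resection {self.resection!r}")
        if not (0.0 < self.taper < 1.0):
            raise ValueError("taper must lie in (0, 1)")


@dataclass(frozen=True)
class TreeParams:
    """Parameters of one capsule-swept vessel tree."""

    direction: tuple[float, float, float]
    trunk_length_mm: float
    trunk_radius_mm: float
    n_primary: int = 2
    taper: float = 0.65
    branch_angle_deg: tuple[float, float] = (25.0, 50.0)
    jitter_deg: float = 7.0
    generations: int = 2
    min_radius_mm: float = 1.0
    clip: Optional[str] = "inside"  # "inside", "outside" or None


@dataclass(frozen=True)
class PerturbationConfig:
    """Controls the simulated automated segmentation.

    ``target_dsc`` may be a single value applied to every structure group or
    a mapping with keys ``liver``, ``hepatic_veins``, ``portal_veins``.  The
    boundary noise is a smooth random field added to each structure's signed
    distance function; its amplitude is bisected per group until the group
    Dice score lands within ±0.05 of the target.  ``boundary_noise_scale``
    seeds the bracket of that search.  A target of ``None`` disables the
    search for that group and applies ``boundary_noise_scale`` (mm) directly.
    ``branch_dropout_prob`` removes whole primary branches (and their
    sub-branches) of a vessel.
    """

    target_dsc: Union[float, None, Mapping[str, Optional[float]]] = 0.66
    boundary_noise_scale: float = 1.0
    branch_dropout_prob: float = 0.0
    field_sigma_vox: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        targets = self.targets()
        for name, t in targets.items():
            if t is not None and not (0.0 < t <= 1.0):
                raise ValueError(f"target_dsc[{name}] must lie in (0, 1], got {t}")
        if not (0.0 <= self.branch_dropout_prob <= 1.0):
            raise ValueError("branch_dropout_prob must lie in [0, 1]")
        if self.boundary_noise_scale < 0:
            raise ValueError("boundary_noise_scale must be >= 0")

    def targets(self) -> dict[str, Optional[float]]:
        if isinstance(self.target_dsc, Mapping):
            return {k: (None if v is None else float(v)) for k, v in self.target_dsc.items()}
        t = None if self.target_dsc is None else float(self.target_dsc)
        return {"liver": t, "hepatic_veins": t, "portal_veins": t}


@dataclass(frozen=True)
class PatientPhantom:
    """One synthetic case: ground-truth labels, vessel trees, resection plan."""

    id: str
    condition: str
    resection: str
    truth: LabelVolume
    trees: Mapping[Structure, VesselTree]
    plan: ResectionPlan
    blood_fraction: float


# --------------------------------------------------------------------------
# low-level geometry
# --------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero direction")
    return np.asarray(v, dtype=float) / n


def _perpendicular(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        r = rng.standard_normal(3)
        p = r - np.dot(r, v) * v
        n = np.linalg.norm(p)
        if n > 1e-6:
            return p / n


def _rotate(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = _unit(axis)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


def smooth_noise_field(
    shape: Sequence[int], sigma_vox: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean, unit-std smooth Gaussian random field on a voxel grid."""
    f = ndimage.gaussian_filter(rng.standard_normal(tuple(shape)), sigma=sigma_vox)
    sd = f.std()
    if sd == 0:  # pragma: no cover - degenerate tiny grids
        return f
    return (f - f.mean()) / sd


def rasterize_capsule(
    mask: np.ndarray, p0: np.ndarray, p1: np.ndarray, radius: float, spacing: Sequence[float]
) -> None:
    """Mark all voxels within ``radius`` of segment p0-p1 (capsule), in place."""
    spacing = np.asarray(spacing, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    lo_mm = np.minimum(p0, p1) - radius
    hi_mm = np.maximum(p0, p1) + radius
    lo = np.maximum(0, np.floor(lo_mm / spacing).astype(int))
    hi = np.minimum(np.asarray(mask.shape), np.ceil(hi_mm / spacing).astype(int) + 1)
    if np.any(lo >= hi):
        return
    ax = [np.arange(lo[k], hi[k]) * spacing[k] for k in range(3)]
    X = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
    d = p1 - p0
    dd = float(np.dot(d, d))
    if dd == 0:
        dist = np.linalg.norm(X - p0, axis=-1)
    else:
        t = np.clip(((X - p0) @ d) / dd, 0.0, 1.0)
        closest = p0 + t[..., None] * d
        dist = np.linalg.norm(X - closest, axis=-1)
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub |= dist <= radius


class _Obstacles:
    """Clearance registry of already-built vessel axes (samples + radii)."""

    def __init__(self) -> None:
        self.points: list[np.ndarray] = []
        self.radii: list[float] = []
        self._tree: Optional[cKDTree] = None

    def add_polyline(self, pts: np.ndarray, radius: float, step: float = 2.0) -> None:
        line = Centerline(pts).resample(step) if len(pts) >= 2 else None
        samples = line.points if line is not None else pts
        for p in samples:
            self.points.append(np.asarray(p, dtype=float))
            self.radii.append(float(radius))
        self._tree = None

    def clearance_ok(self, p: np.ndarray, radius: float, factor: float = 1.3, pad: float = 0.6) -> bool:
        if not self.points:
            return True
        if self._tree is None:
            self._tree = cKDTree(np.asarray(self.points))
        k = min(8, len(self.points))
        dist, idx = self._tree.query(np.asarray(p, dtype=float), k=k)
        dist = np.atleast_1d(dist)
        idx = np.atleast_1d(idx)
        radii = np.asarray(self.radii)[idx]
        return bool(np.all(dist >= factor * (radius + radii) + pad))


# --------------------------------------------------------------------------
# vessel-tree generation
# --------------------------------------------------------------------------


def _grow_polyline(
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    radius: float,
    rng: np.random.Generator,
    jitter_deg: float,
    keep_fn,
    attract: Optional[np.ndarray],
    n_steps: int = 7,
    stop_fn=None,
) -> np.ndarray:
    """Grow a jittered polyline of ~``length`` whose points all satisfy keep_fn.

    When a candidate step violates ``keep_fn`` the direction is blended
    toward ``attract`` (typically the liver centroid) and then randomly
    redirected; growth stops early if no admissible step exists.  A candidate
    satisfying ``stop_fn`` terminates growth cleanly (used to end the main
    portal vein at the liver surface).
    """
    pts = [np.asarray(start, dtype=float)]
    d = _unit(direction)
    step = length / n_steps
    for _ in range(n_steps):
        dd = d
        if jitter_deg > 0:
            angle = np.deg2rad(rng.normal(0.0, jitter_deg))
            dd = _rotate(d, _perpendicular(d, rng), angle)
        cand = pts[-1] + step * dd
        if stop_fn is not None and stop_fn(cand):
            break
        tries = 0
        while not keep_fn(cand, radius) and tries < 24:
            if attract is not None and tries < 10:
                to_c = _unit(attract - pts[-1])
                dd = _unit(0.55 * dd + 0.45 * to_c)
            else:
                dd = _unit(rng.standard_normal(3))
            cand = pts[-1] + step * dd
            if stop_fn is not None and stop_fn(cand):
                return np.asarray(pts) if len(pts) >= 2 else np.asarray(pts + [cand])
            tries += 1
        if not keep_fn(cand, radius):
            break
        pts.append(cand)
        d = dd
    return np.asarray(pts)


def generate_vessel_tree(
    liver_mask: np.ndarray,
    spacing: Sequence[float],
    root_mm: Sequence[float],
    params: TreeParams,
    rng: np.random.Generator,
    *,
    liver_edt: Optional[np.ndarray] = None,
    obstacles: Optional[_Obstacles] = None,
    stop_at_liver: bool = False,
) -> tuple[np.ndarray, VesselTree, list[tuple[np.ndarray, float]]]:
    """Grow one capsule-swept vessel tree rooted at ``root_mm``.

    Returns ``(mask, tree, polylines)`` where ``polylines`` is the list of
    ``(points, radius)`` pairs of every generation (used by the caller to
    re-rasterize during blood-pool calibration).  Trees with ``clip='inside'``
    grow and stay inside the liver with a depth margin that keeps the whole
    tube interior; ``clip='outside'`` trees (main portal vein, IVC) stay
    outside, optionally stopping when they reach the liver surface.
    Radii taper by ``params.taper`` per generation and are floored at
    ``params.min_radius_mm``; a trunk radius below the floor is an error.
    """
    spacing = np.asarray([float(s) for s in spacing])
    root = np.asarray(root_mm, dtype=float)
    shape = np.asarray(liver_mask.shape)

    if params.trunk_radius_mm < params.min_radius_mm:
        raise PhantomError(
            f"trunk radius {params.trunk_radius_mm} mm below the "
            f"{params.min_radius_mm} mm radius floor"
        )

    def in_grid(p: np.ndarray, margin: float) -> bool:
        lo = p - margin
        hi = p + margin
        return bool(np.all(lo >= 0) and np.all(hi <= (shape - 1) * spacing))

    def in_liver(p: np.ndarray) -> bool:
        idx = np.round(p / spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= shape):
            return False
        return bool(liver_mask[tuple(idx)])

    if liver_edt is None and params.clip == "inside":
        liver_edt = ndimage.distance_transform_edt(liver_mask, sampling=spacing)

    def depth(p: np.ndarray) -> float:
        idx = np.round(p / spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= shape):
            return 0.0
        return float(liver_edt[tuple(idx)])

    def keep_inside(p: np.ndarray, r: float) -> bool:
        if not in_grid(p, r + 1.0):
            return False
        if depth(p) < 1.45 * r + 0.8:
            return False
        return obstacles.clearance_ok(p, r) if obstacles is not None else True

    def keep_outside(p: np.ndarray, r: float) -> bool:
        if not in_grid(p, r + 1.0):
            return False
        if in_liver(p):
            return False
        return obstacles.clearance_ok(p, r) if obstacles is not None else True

    def keep_anywhere(p: np.ndarray, r: float) -> bool:
        if not in_grid(p, r + 1.0):
            return False
        return obstacles.clearance_ok(p, r) if obstacles is not None else True

    if params.clip == "inside":
        if not in_liver(root):
            raise PhantomError(f"root {root} lies outside the liver mask")
        keep_fn = keep_inside
        centroid = np.asarray(ndimage.center_of_mass(liver_mask)) * spacing
    elif params.clip == "outside":
        if in_liver(root):
            raise PhantomError(f"root {root} lies inside the liver (expected adjacent/outside)")
        keep_fn = keep_outside
        centroid = None
    else:
        keep_fn = keep_anywhere
        centroid = None

    stop_fn = in_liver if (params.clip == "outside" and stop_at_liver) else None
    r_trunk = float(params.trunk_radius_mm)
    trunk_pts = _grow_polyline(
        root, np.asarray(params.direction, float), params.trunk_length_mm, r_trunk,
        rng, params.jitter_deg, keep_fn, centroid, stop_fn=stop_fn,
    )
    if len(trunk_pts) < 3:
        raise PhantomError(
            f"trunk infeasible at root {np.round(root, 1)}: only {len(trunk_pts)} "
            "admissible points (liver too small for the requested radius/clearance)"
        )
    trunk = Centerline(trunk_pts)

    polylines: list[tuple[np.ndarray, float]] = [(trunk_pts, r_trunk)]
    branches: list[Centerline] = []
    r_primary = max(params.min_radius_mm, params.taper * r_trunk)
    r_secondary = max(params.min_radius_mm, params.taper**2 * r_trunk)
    trunk_dir = _unit(trunk_pts[-1] - trunk_pts[-2])

    def grow_branch(origin, base_dir, length, radius, azimuth):
        lo, hi = params.branch_angle_deg
        for attempt in range(6):
            polar = np.deg2rad(rng.uniform(lo, hi))
            az = azimuth + rng.normal(0.0, 0.4) + attempt * 1.1
            perp = _perpendicular(base_dir, rng)
            d0 = _rotate(base_dir, perp, polar)
            d0 = _rotate(d0, base_dir, az)
            pts = _grow_polyline(
                origin, d0, length * (0.75 if attempt >= 3 else 1.0), radius,
                rng, params.jitter_deg, keep_fn, centroid, n_steps=5,
            )
            if len(pts) >= 3:
                return pts
        return None

    for i in range(params.n_primary):
        azimuth = 2 * np.pi * i / max(1, params.n_primary)
        blen = 0.6 * trunk.length
        pts = grow_branch(trunk_pts[-1], trunk_dir, blen, r_primary, azimuth)
        if pts is None:
            raise PhantomError(
                f"primary branch {i} infeasible at {np.round(trunk_pts[-1], 1)}"
            )
        branches.append(Centerline(pts))
        polylines.append((pts, r_primary))
        if params.generations >= 2:
            bdir = _unit(pts[-1] - pts[-2])
            for j in range(2):
                spts = grow_branch(
                    pts[-1], bdir, 0.35 * trunk.length, r_secondary, np.pi * j
                )
                if spts is not None:
                    polylines.append((spts, r_secondary))

    mask = np.zeros(liver_mask.shape, dtype=bool)
    rasterize_polylines(mask, polylines, spacing, clip=params.clip, liver_mask=liver_mask)

    tree = VesselTree(vessel=Structure.IVC, trunk=trunk, branches=tuple(branches))
    # caller rebinds the vessel name; verify centerline containment here
    for line in (trunk, *branches):
        for p in line.points:
            idx = tuple(np.round(p / spacing).astype(int))
            if not mask[idx]:  # pragma: no cover - construction guarantees this
                raise PhantomError("centerline point escaped its tube mask")
    return mask, tree, polylines


def rasterize_polylines(
    mask: np.ndarray,
    polylines: Sequence[tuple[np.ndarray, float]],
    spacing: Sequence[float],
    *,
    radius_scale: float = 1.0,
    min_radius: float = 1.0,
    clip: Optional[str] = None,
    liver_mask: Optional[np.ndarray] = None,
) -> None:
    """Rasterize capsule-swept polylines into ``mask`` in place."""
    for pts, radius in polylines:
        r = max(min_radius, radius_scale * radius)
        for a, b in zip(pts[:-1], pts[1:]):
            rasterize_capsule(mask, a, b, r, spacing)
    if clip == "inside" and liver_mask is not None:
        mask &= liver_mask
    elif clip == "outside" and liver_mask is not None:
        mask &= ~liver_mask


# --------------------------------------------------------------------------
# whole-phantom assembly
# --------------------------------------------------------------------------

# Vessel layout: roots and initial directions in fractions of the liver
# semi-axes, relative to the liver center.  Axis convention: x = right(-) /
# left(+), y = anterior(-) / posterior(+), z = inferior(-) / superior(+).
# Hepatic veins fan out from the IVC confluence (posterior-superior); portal
# branches fan out from the porta hepatis (inferior); the main portal vein
# approaches the porta from below, outside the liver.
_VESSEL_LAYOUT: dict[Structure, dict] = {
    Structure.RHV: dict(root=(-0.30, 0.30, 0.42), direction=(-0.60, -0.50, -0.55),
                        rscale=1.00, lscale=1.15, n_primary=2, clip="inside"),
    Structure.MHV: dict(root=(0.02, 0.28, 0.52), direction=(-0.05, -0.55, -0.75),
                        rscale=0.95, lscale=1.00, n_primary=2, clip="inside"),
    Structure.LHV: dict(root=(0.30, 0.28, 0.40), direction=(0.65, -0.45, -0.50),
                        rscale=0.90, lscale=0.90, n_primary=2, clip="inside"),
    Structure.SRHV: dict(root=(-0.45, 0.42, 0.20), direction=(-0.75, -0.35, 0.05),
                         rscale=0.65, lscale=0.60, n_primary=2, clip="inside"),
    Structure.IRHV: dict(root=(-0.40, 0.42, -0.30), direction=(-0.60, -0.50, -0.45),
                         rscale=0.65, lscale=0.60, n_primary=2, clip="inside"),
    Structure.RPV: dict(root=(-0.12, 0.20, -0.52), direction=(-0.80, -0.20, 0.15),
                        rscale=1.00, lscale=0.90, n_primary=2, clip="inside"),
    Structure.LPV: dict(root=(0.24, 0.28, -0.40), direction=(0.75, -0.35, 0.20),
                        rscale=0.90, lscale=0.80, n_primary=2, clip="inside"),
    Structure.MPV: dict(root=(0.10, 0.50, -1.50), direction=None,  # aimed at the porta
                        rscale=1.25, lscale=1.10, n_primary=0, clip="outside"),
}

#: Condition presets: global size factor and surface-irregularity multiplier.
#: Qualitative emulation only (no validated shape model for diseased livers).
_CONDITION_EFFECTS = {
    "healthy": (1.00, 1.0),
    "fatty": (1.06, 1.0),
    "cirrhosis": (0.86, 2.0),
}


def generate_liver_mask(
    config: PhantomConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deformed-ellipsoid liver mask; returns (mask, center_mm, axes_mm)."""
    shape = np.asarray(config.grid_shape)
    spacing = np.asarray(config.spacing)
    size_factor, irr_factor = _CONDITION_EFFECTS[config.condition]
    axes = np.asarray(config.liver_axes, dtype=float) * size_factor
    center = (shape - 1) * spacing / 2.0
    ax = [np.arange(shape[k]) * spacing[k] for k in range(3)]
    X = np.meshgrid(*ax, indexing="ij")
    f = sum(((X[k] - center[k]) / axes[k]) ** 2 for k in range(3))
    amp = config.surface_irregularity * irr_factor
    field = smooth_noise_field(shape, sigma_vox=8.0, rng=rng)
    mask = f <= 1.0 + amp * field
    # keep the largest connected component (noise can pinch off crumbs)
    labels, n = ndimage.label(mask)
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(counts)) + 1)
    if not mask.any():
        raise PhantomError("liver mask empty: axes/irregularity infeasible for the grid")
    return mask, center, axes


def _resection_plane(
    liver_mask: np.ndarray,
    spacing: np.ndarray,
    resection: str,
    fraction: float,
    rng: np.random.Generator,
) -> ResectionPlan:
    """Oblique plane resecting ``fraction`` of the liver parenchyma.

    Left hepatectomy resects the left (x+) side; right and extended-right
    resect the right (x-) side; the plane normal is the x axis tilted by a
    small random angle, and its offset is set by the quantile of liver-voxel
    projections so the resected fraction is exact on the ground truth.
    """
    base = np.array([1.0, 0.0, 0.0]) if resection == "left" else np.array([-1.0, 0.0, 0.0])
    tilt = rng.normal(0.0, np.deg2rad(6.0), size=2)
    n = _rotate(base, np.array([0.0, 1.0, 0.0]), tilt[0])
    n = _unit(_rotate(n, np.array([0.0, 0.0, 1.0]), tilt[1]))
    pts = np.argwhere(liver_mask) * spacing
    t = pts @ n
    threshold = float(np.quantile(t, 1.0 - fraction))
    return ResectionPlan(point_mm=tuple(threshold * n), normal=tuple(n))


def _place_lesions(
    liver_mask: np.ndarray,
    resect_side: np.ndarray,
    spacing: np.ndarray,
    config: PhantomConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spherical lesions on the resected side, kept inside the liver."""
    lesion = np.zeros_like(liver_mask)
    if config.lesion_count == 0:
        return lesion
    edt = ndimage.distance_transform_edt(liver_mask, sampling=spacing)
    for _ in range(config.lesion_count):
        radius = float(rng.uniform(*config.lesion_radius_range))
        for depth_factor in (0.7, 0.4, 0.15):
            cand = np.argwhere(liver_mask & resect_side & (edt >= depth_factor * radius))
            if len(cand):
                break
        if not len(cand):
            raise PhantomError("no admissible lesion site on the resected side")
        center = cand[rng.integers(len(cand))] * spacing
        rasterize_capsule(lesion, center, center, radius, spacing)
    return lesion & liver_mask


def generate_phantom(config: PhantomConfig, seed: int) -> PatientPhantom:
    """Generate one synthetic patient (deterministic in ``config`` and ``seed``).

    The labeled vessel volume inside the liver is calibrated to
    ``config.blood_fraction_target`` of the liver volume by rescaling tube
    radii (geometry fixed); calibration failing to land within ±25% relative
    is an error naming the achieved fraction.
    """
    spacing = np.asarray(config.spacing, dtype=float)
    liver_mask, center, axes = generate_liver_mask(config, _rng(seed, "liver"))
    liver_edt = ndimage.distance_transform_edt(liver_mask, sampling=spacing)

    # --- resection plane and lesion ------------------------------------
    fraction = dict(config.resection_fractions)[config.resection]
    plan = _resection_plane(liver_mask, spacing, config.resection, fraction, _rng(seed, "plane"))
    shape = np.asarray(config.grid_shape)
    ax = [np.arange(shape[k]) * spacing[k] for k in range(3)]
    X = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
    resect_side = plan.resect_side(X.reshape(-1, 3)).reshape(liver_mask.shape)
    lesion = _place_lesions(liver_mask, resect_side, spacing, config, _rng(seed, "lesion"))

    # --- vessel trees ---------------------------------------------------
    porta = center + np.array([0.03, 0.22, -0.52]) * axes
    obstacles = _Obstacles()
    trees: dict[Structure, VesselTree] = {}
    built: dict[Structure, list[tuple[np.ndarray, float]]] = {}

    # analytic pre-scaling of tube radii: the blood-pool fraction scales as
    # r^2 * L / V_liver, so solve for the radius factor that puts the planned
    # tree volume at the target before any tube is grown (the post-hoc
    # calibration below then only fine-tunes within a narrow clamp)
    liver_volume_mm3 = float(liver_mask.sum()) * float(np.prod(spacing))
    planned_mm3 = 0.0
    for vessel, lay in _VESSEL_LAYOUT.items():
        if lay["clip"] != "inside":
            continue
        r = config.trunk_radius_mm * lay["rscale"]
        L = 0.85 * axes[0] * lay["lscale"]
        n = lay["n_primary"]
        planned_mm3 += np.pi * r**2 * L
        planned_mm3 += n * np.pi * (max(config.min_radius_mm, config.taper * r)) ** 2 * 0.6 * L
        planned_mm3 += 2 * n * np.pi * (max(config.min_radius_mm, config.taper**2 * r)) ** 2 * 0.35 * L
    prescale = float(
        np.clip(np.sqrt(config.blood_fraction_target * liver_volume_mm3 / planned_mm3), 0.5, 2.0)
    )

    order = [Structure.RHV, Structure.MHV, Structure.LHV, Structure.SRHV,
             Structure.IRHV, Structure.LPV, Structure.RPV, Structure.MPV]
    centroid = np.asarray(ndimage.center_of_mass(liver_mask)) * spacing
    for vessel in order:
        lay = _VESSEL_LAYOUT[vessel]
        root = center + np.asarray(lay["root"]) * axes
        direction = lay["direction"]
        if direction is None:
            direction = porta - root
        params = TreeParams(
            direction=tuple(direction),
            trunk_length_mm=0.85 * axes[0] * lay["lscale"],
            trunk_radius_mm=max(config.min_radius_mm, prescale * config.trunk_radius_mm * lay["rscale"]),
            n_primary=lay["n_primary"],
            taper=config.taper,
            branch_angle_deg=config.branch_angle_deg,
            generations=config.generations,
            min_radius_mm=config.min_radius_mm,
            clip=lay["clip"],
        )
        rng_v = _rng(seed, "tree", vessel.value)
        tree = polylines = None
        last_err: Optional[PhantomError] = None
        for attempt in range(10):
            # nudge an infeasible root toward the liver centroid plus jitter,
            # and from the fourth attempt on shrink the tube (the blood-pool
            # calibration below recovers the lost volume on the other trees)
            toward = (centroid - root) if lay["clip"] == "inside" else (root - centroid)
            root_try = root if attempt == 0 else (
                root + 0.1 * attempt * toward + rng_v.normal(0.0, 2.0, 3)
            )
            params_try = params if attempt < 3 else dataclasses.replace(
                params,
                trunk_radius_mm=max(
                    config.min_radius_mm, params.trunk_radius_mm * 0.85 ** (attempt - 2)
                ),
            )
            try:
                _, tree, polylines = generate_vessel_tree(
                    liver_mask, spacing, root_try, params_try, rng_v,
                    liver_edt=liver_edt, obstacles=obstacles,
                    stop_at_liver=(lay["clip"] == "outside"),
                )
                break
            except PhantomError as err:
                last_err = err
        if tree is None:
            raise PhantomError(f"{vessel.value}: {last_err}")
        trees[vessel] = dataclasses.replace(tree, vessel=vessel)
        built[vessel] = polylines
        for pts, radius in polylines:
            obstacles.add_polyline(pts, radius)

    # IVC landmark: straight vertical tube just posterior to the liver.
    ivc_root = center + np.array([0.0, 1.12, -1.05]) * axes
    ivc_params = TreeParams(
        direction=(0.0, 0.0, 1.0),
        trunk_length_mm=2.1 * axes[2],
        trunk_radius_mm=5.0,
        n_primary=0,
        jitter_deg=0.0,
        clip="outside",
        min_radius_mm=config.min_radius_mm,
        taper=config.taper,
    )
    _, ivc_tree, ivc_polylines = generate_vessel_tree(
        liver_mask, spacing, ivc_root, ivc_params, _rng(seed, "tree", "IVC"),
        stop_at_liver=False,
    )
    trees[Structure.IVC] = dataclasses.replace(ivc_tree, vessel=Structure.IVC)

    # --- blood-pool calibration ------------------------------------------
    liver_vox = int(liver_mask.sum())
    target = config.blood_fraction_target
    k = 1.0
    fraction_achieved = 0.0
    vessel_masks: dict[Structure, np.ndarray] = {}
    for _ in range(4):
        vessel_masks = {}
        for vessel, polylines in built.items():
            m = np.zeros(liver_mask.shape, dtype=bool)
            rasterize_polylines(
                m, polylines, spacing, radius_scale=k,
                min_radius=config.min_radius_mm,
                clip=_VESSEL_LAYOUT[vessel]["clip"], liver_mask=liver_mask,
            )
            vessel_masks[vessel] = m
        inside = np.zeros(liver_mask.shape, dtype=bool)
        for vessel, m in vessel_masks.items():
            if _VESSEL_LAYOUT[vessel]["clip"] == "inside":
                inside |= m
        fraction_achieved = float(inside.sum()) / liver_vox
        if 0.9 * target <= fraction_achieved <= 1.1 * target:
            break
        k = float(np.clip(k * np.sqrt(target / max(fraction_achieved, 1e-9)), 0.7, 1.3))
    if not (0.75 * target <= fraction_achieved <= 1.25 * target):
        raise PhantomError(
            f"blood-pool calibration failed: achieved fraction "
            f"{fraction_achieved:.4f} vs target {target:.4f} (±25%)"
        )

    ivc_mask = np.zeros(liver_mask.shape, dtype=bool)
    rasterize_polylines(
        ivc_mask, ivc_polylines, spacing, min_radius=config.min_radius_mm,
        clip="outside", liver_mask=liver_mask,
    )

    # --- compose the label grid ------------------------------------------
    grid = np.zeros(config.grid_shape, dtype=np.uint8)
    lm = dict(DEFAULT_LABEL_MAP)
    grid[liver_mask & ~resect_side] = lm[Structure.REMNANT.value]
    grid[liver_mask & resect_side] = lm[Structure.RESECT.value]
    grid[lesion] = lm[Structure.LESION.value]
    grid[ivc_mask] = lm[Structure.IVC.value]
    for vessel in order:
        grid[vessel_masks[vessel]] = lm[vessel.value]

    truth = LabelVolume(grid=grid, spacing=tuple(config.spacing), label_map=lm)
    return PatientPhantom(
        id=f"case_{child_seed(seed, 'id') % 10**6:06d}",
        condition=config.condition,
        resection=config.resection,
        truth=truth,
        trees=trees,
        plan=plan,
        blood_fraction=fraction_achieved,
    )


#: Cohort composition presets: liver-condition and resection-type mixes of a
#: typical major-hepatectomy candidate cohort (32 patients: 27 healthy /
#: 3 fatty / 2 cirrhotic; 10 left / 21 right / 1 extended-right).
DEFAULT_CONDITION_MIX = {"healthy": 27 / 32, "fatty": 3 / 32, "cirrhosis": 2 / 32}
DEFAULT_RESECTION_MIX = {"left": 10 / 32, "right": 21 / 32, "extended_right": 1 / 32}


def _allocate(n: int, proportions: Mapping[str, float], rng: np.random.Generator) -> list[str]:
    """Largest-remainder allocation of n slots to categories, then shuffled."""
    keys = list(proportions)
    raw = np.asarray([proportions[k] for k in keys], dtype=float)
    raw = raw / raw.sum() * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    out = [k for k, c in zip(keys, counts) for _ in range(c)]
    rng.shuffle(out)
    return out


def generate_cohort(
    n: int,
    config: PhantomConfig | None = None,
    seed: int = 0,
    condition_mix: Mapping[str, float] | None = None,
    resection_mix: Mapping[str, float] | None = None,
) -> list[PatientPhantom]:
    """Generate a cohort of phantoms with configured condition/resection mixes.

    Per-patient seeds are derived deterministically from the master seed, so
    the cohort is reproducible and individual patients can be regenerated in
    isolation.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    config = PhantomConfig() if config is None else config
    conditions = _allocate(n, condition_mix or DEFAULT_CONDITION_MIX, _rng(seed, "mix", 0))
    resections = _allocate(n, resection_mix or DEFAULT_RESECTION_MIX, _rng(seed, "mix", 1))
    cohort = []
    for i, (cond, res) in enumerate(zip(conditions, resections)):
        cfg_i = dataclasses.replace(config, condition=cond, resection=res)
        phantom = generate_phantom(cfg_i, seed=child_seed(seed, "patient", i))
        phantom = dataclasses.replace(phantom, id=f"case_{i:03d}")
        cohort.append(phantom)
    return cohort


# --------------------------------------------------------------------------
# segmentation perturbation (simulated automated method)
# --------------------------------------------------------------------------


def _signed_distance(mask: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance (mm): negative inside, positive outside."""
    if not mask.any():
        return np.full(mask.shape, np.inf)
    return ndimage.distance_transform_edt(~mask, sampling=spacing) - ndimage.distance_transform_edt(
        mask, sampling=spacing
    )


def _bbox(mask: np.ndarray, margin: int, shape: Sequence[int]) -> tuple[slice, slice, slice]:
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, np.asarray(shape))
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


class _NoisyStructure:
    """One structure's frozen SDF + noise field; perturbed mask is a function of scale."""

    def __init__(self, mask: np.ndarray, spacing: np.ndarray, sigma: float,
                 rng: np.random.Generator, margin: int = 14):
        self.shape = mask.shape
        self.empty = not mask.any()
        if self.empty:
            return
        self.box = _bbox(mask, margin, mask.shape)
        sub = mask[self.box]
        self.sdf = _signed_distance(sub, spacing)
        self.field = smooth_noise_field(sub.shape, sigma, rng)

    def perturbed(self, scale: float) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        if not self.empty:
            out[self.box] = self.sdf + scale * self.field <= 0.0
        return out


def _bisect_scale(structures: list[_NoisyStructure], truth_union: np.ndarray,
                  target: float, s0: float, pred_fn=None) -> tuple[float, float]:
    """Find the noise scale whose group Dice is within ±0.05 of target.

    Dice is non-increasing in the scale (each voxel flips state at most once
    as the scale grows), so bisection on a bracketing interval is exact up to
    the tolerance.  Returns (scale, achieved_dsc).
    """
    if pred_fn is None:
        def pred_fn(s):
            u = np.zeros(truth_union.shape, dtype=bool)
            for st in structures:
                u |= st.perturbed(s)
            return u

    def dsc(s: float) -> float:
        return dice(pred_fn(s), truth_union)

    d0 = dsc(0.0)
    if d0 < target - 0.05:
        raise PerturbationError(
            f"target DSC {target:.2f} unreachable: structure already degraded to "
            f"{d0:.3f} at zero boundary noise (branch dropout too aggressive?)"
        )
    if d0 <= target + 0.05:
        if abs(d0 - target) <= 0.02 or target >= d0:
            return 0.0, d0
    lo, hi = 0.0, max(s0, 0.25)
    d_hi = dsc(hi)
    grow = 0
    while d_hi > target and grow < 12:
        lo, hi = hi, hi * 1.8
        d_hi = dsc(hi)
        grow += 1
    if d_hi > target + 0.05:
        raise PerturbationError(
            f"target DSC {target:.2f} unreachable: noise saturates at DSC {d_hi:.3f}"
        )
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        d_mid = dsc(mid)
        if abs(d_mid - target) <= 0.015:
            return mid, d_mid
        if d_mid > target:
            lo = mid
        else:
            hi = mid
    s = 0.5 * (lo + hi)
    d = dsc(s)
    if abs(d - target) > 0.05:
        raise PerturbationError(
            f"bisection failed to reach DSC {target:.2f} (achieved {d:.3f})"
        )
    return s, d


def perturb_segmentation(
    truth: LabelVolume,
    cfg: PerturbationConfig,
    trees: Optional[Mapping[Structure, VesselTree]] = None,
) -> LabelVolume:
    """Simulate an automated segmentation of a ground-truth label volume.

    Per structure group (liver parenchyma+lesion, hepatic veins, portal
    veins) the boundary of every member structure is displaced by a smooth
    random field whose amplitude is bisected until the group Dice against the
    truth lands within ±0.05 of the configured target.  Primary vessel
    branches are optionally dropped wholesale before the noise step (this
    requires the phantom's ground-truth ``trees``).  The IVC landmark is
    copied unperturbed.  Deterministic given ``cfg.seed``.
    """
    spacing = np.asarray(truth.spacing)
    targets = cfg.targets()
    rng = np.random.default_rng(cfg.seed)

    if cfg.branch_dropout_prob > 0 and trees is None:
        raise PerturbationError("branch dropout requires the ground-truth vessel trees")
    if cfg.branch_dropout_prob > 0:
        for name, t in targets.items():
            if name != "liver" and t is not None and t >= 1.0:
                raise PerturbationError(
                    f"target_dsc[{name}]=1.0 conflicts with branch_dropout_prob="
                    f"{cfg.branch_dropout_prob} (dropout forces DSC < 1)"
                )

    # --- branch dropout ---------------------------------------------------
    vessel_masks: dict[Structure, np.ndarray] = {
        v: truth.mask(v) for v in HEPATIC_VEINS + (Structure.MPV,) + INTRAHEPATIC_PORTAL
        if truth.has(v)
    }
    if cfg.branch_dropout_prob > 0 and trees is not None:
        for vessel, tree in trees.items():
            if vessel not in vessel_masks or not tree.branches:
                continue
            drop = [rng.random() < cfg.branch_dropout_prob for _ in tree.branches]
            if not any(drop):
                continue
            mask = vessel_masks[vessel]
            vox = np.argwhere(mask)
            if not len(vox):
                continue
            # assign each vessel voxel to the nearest centerline (trunk=0,
            # branch i = i+1); a dropped branch removes its voxels (and its
            # sub-branch voxels, which sit nearer to it than to the trunk)
            samples, owner = [], []
            for i, line in enumerate((tree.trunk, *tree.branches)):
                pts = line.resample(1.5).points
                samples.append(pts)
                owner.extend([i] * len(pts))
            kd = cKDTree(np.vstack(samples))
            _, nearest = kd.query(vox * spacing)
            owner = np.asarray(owner)[nearest]
            keep = np.ones(len(vox), dtype=bool)
            for i, dropped in enumerate(drop):
                if dropped:
                    keep &= owner != i + 1
            new_mask = np.zeros_like(mask)
            new_mask[tuple(vox[keep].T)] = True
            vessel_masks[vessel] = new_mask

    # --- boundary noise with per-group DSC bisection ----------------------
    parenchyma = truth.mask_union((Structure.REMNANT, Structure.RESECT, Structure.LIVER))
    lesion = truth.mask_union((Structure.LESION,))
    group_members: dict[str, list[Structure]] = {
        "hepatic_veins": [v for v in HEPATIC_VEINS if v in vessel_masks],
        "portal_veins": [v for v in (Structure.MPV,) + INTRAHEPATIC_PORTAL if v in vessel_masks],
    }

    noisy: dict[Structure, _NoisyStructure] = {}
    perturbed_vessels: dict[Structure, np.ndarray] = {}
    for gname, members in group_members.items():
        target = targets.get(gname, 1.0)
        truth_union = truth.mask_union(members)
        if not truth_union.any():
            continue
        structs = []
        for v in members:
            st = _NoisyStructure(vessel_masks[v], spacing, cfg.field_sigma_vox,
                                 np.random.default_rng(child_seed(cfg.seed, "field", v.value)))
            noisy[v] = st
            structs.append(st)
        if target is None:
            scale = cfg.boundary_noise_scale
        elif target >= 1.0 and cfg.branch_dropout_prob == 0:
            scale = 0.0
        else:
            scale, _ = _bisect_scale(structs, truth_union, target, max(cfg.boundary_noise_scale, 0.25))
        for v, st in zip(members, structs):
            perturbed_vessels[v] = st.perturbed(scale)

    # liver group: parenchyma and lesion share one scale; the group DSC is
    # measured exactly as it will be reported (vessel voxels carved out)
    pred_vessel_union = np.zeros(truth.grid.shape, dtype=bool)
    for m in perturbed_vessels.values():
        pred_vessel_union |= m
    truth_liver_group = parenchyma | lesion
    liver_target = targets.get("liver", 1.0)
    st_par = _NoisyStructure(parenchyma, spacing, 1.6 * cfg.field_sigma_vox,
                             np.random.default_rng(child_seed(cfg.seed, "field", "parenchyma")))
    st_les = (_NoisyStructure(lesion, spacing, cfg.field_sigma_vox,
                              np.random.default_rng(child_seed(cfg.seed, "field", "lesion")))
              if lesion.any() else None)

    def liver_pred(s: float) -> np.ndarray:
        m = st_par.perturbed(s)
        if st_les is not None:
            m |= st_les.perturbed(s)
        return m & ~pred_vessel_union

    if liver_target is None:
        liver_scale = cfg.boundary_noise_scale
    elif liver_target >= 1.0:
        liver_scale = 0.0
    else:
        liver_scale, _ = _bisect_scale([], truth_liver_group, liver_target,
                                       max(cfg.boundary_noise_scale, 0.25), pred_fn=liver_pred)
    pred_parenchyma = st_par.perturbed(liver_scale)
    pred_lesion = st_les.perturbed(liver_scale) if st_les is not None else lesion

    # --- reassemble the label grid ----------------------------------------
    grid = np.zeros(truth.grid.shape, dtype=truth.grid.dtype)
    code = truth.code
    if truth.has(Structure.REMNANT):
        # keep the original side where defined; new boundary voxels take the
        # side of the nearest original parenchyma voxel
        _, inds = ndimage.distance_transform_edt(
            ~parenchyma, sampling=spacing, return_indices=True
        )
        nearest_label = truth.grid[inds[0], inds[1], inds[2]]
        remnant_side = nearest_label == code(Structure.REMNANT)
        grid[pred_parenchyma & remnant_side] = code(Structure.REMNANT)
        grid[pred_parenchyma & ~remnant_side] = code(Structure.RESECT)
    else:
        grid[pred_parenchyma] = code(Structure.LIVER)
    if truth.has(Structure.LESION):
        grid[pred_lesion] = code(Structure.LESION)
    if truth.has(Structure.IVC):
        grid[truth.mask(Structure.IVC)] = code(Structure.IVC)
    for v, m in perturbed_vessels.items():
        grid[m] = code(v)
    return truth.with_grid(grid)
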