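"""Synthetic patient phantoms: grids, masks, tissue-property fields, landmarks.

A phantom stands in for the registered patient-specific anatomical model a
clinical modeling pipeline would produce from contrast CT: a liver region of
interest, a tumor mask, a large-vessel mask, and per-voxel thermal/perfusion
properties, with the simulation domain restricted to a sphere around the
tumor (default 6 cm radius, matching the maximum coagulation diameter of
standard liver RFA protocols, beyond which heating is negligible).

Conventions
-----------
World coordinates are in mm, axis order (x, y, z), voxel indices 0-based.
The orientation matrix is the identity: phantoms are synthetic, so no
direction cosines are carried. A voxel belongs to a shape iff its *center*
lies inside the shape — this makes brute-force voxel-center scans exact
oracles for every mask builder here.

Mask precedence where shapes overlap: vessel > tumor > healthy. Vessels act
as heat sinks and must never be overwritten by tumor tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import PhantomSpecError
from .registration import RigidTransform, apply_transform

__all__ = [
    "Grid",
    "Mask",
    "TissueProperties",
    "PropertyFields",
    "Phantom",
    "HEALTHY_LIVER",
    "TUMOR_TISSUE",
    "VESSEL_BLOOD",
    "make_tumor_mask",
    "make_vessel_mask",
    "crop_domain",
    "make_landmark_pairs",
    "build_phantom",
    "make_default_phantom",
]


@dataclass(frozen=True)
class Grid:
    """Regular voxel grid: shape (voxels), spacing and origin (mm).

    ``origin`` is the world coordinate of the *center* of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(s) for s in self.origin)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise PhantomSpecError(f"grid shape must be three integers >= 1, got {shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise PhantomSpecError(f"grid spacing must be positive in each axis, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis."""
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i]) for i in range(3)
        )

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (sparse meshgrid) world coordinates of voxel centers."""
        ax = self.axes()
        return np.meshgrid(*ax, indexing="ij", sparse=True)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """World-space bounding box of the voxel volume (outer voxel faces)."""
        lo = np.asarray(self.origin) - 0.5 * np.asarray(self.spacing)
        hi = lo + np.asarray(self.spacing) * np.asarray(self.shape)
        return lo, hi

    def contains(self, point: Sequence[float]) -> bool:
        lo, hi = self.bounds()
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= lo) and np.all(p <= hi))

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Nearest voxel index for each world point (no bounds clipping)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.rint((pts - np.asarray(self.origin)) / np.asarray(self.spacing)).astype(int)
        return idx

    def world_to_continuous_index(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (diagonal; identity orientation)."""
        A = np.eye(4)
        A[:3, :3] = np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A


@dataclass(frozen=True, eq=False)
class Mask:
    """Boolean voxel field on a grid."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=bool)
        if vals.shape != self.grid.shape:
            raise PhantomSpecError(
                f"mask values shape {vals.shape} does not match grid shape {self.grid.shape}"
            )
        object.__setattr__(self, "values", vals)

    @property
    def count(self) -> int:
        return int(self.values.sum())

    @property
    def volume_ml(self) -> float:
        # 1 ml = 1000 mm^3
        return self.count * self.grid.voxel_volume_mm3 / 1000.0

    def centroid(self) -> np.ndarray:
        """World-space centroid of the included voxel centers (mm)."""
        if self.count == 0:
            raise PhantomSpecError("centroid undefined for an empty mask")
        idx = np.argwhere(self.values)
        return np.asarray(self.grid.origin) + idx.mean(axis=0) * np.asarray(self.grid.spacing)


@dataclass(frozen=True)
class TissueProperties:
    """Per-tissue-class thermal parameters of the Pennes bioheat model.

    density: rho, kg/m^3
    heat_capacity: c, J/(kg K)
    conductivity: k, W/(m K)
    perfusion: omega_b, kg/(m^3 s) blood mass perfusion rate
    blood_heat_capacity: c_b, J/(kg K)
    blood_temperature: T_b, degC (baseline body/arterial temperature)
    """

    density: float = 1060.0
    heat_capacity: float = 3600.0
    conductivity: float = 0.512
    perfusion: float = 2.0
    blood_heat_capacity: float = 3600.0
    blood_temperature: float = 37.0

    def __post_init__(self) -> None:
        for name in ("density", "heat_capacity", "conductivity", "blood_heat_capacity"):
            if getattr(self, name) <= 0:
                raise PhantomSpecError(f"{name} must be strictly positive")
        if self.perfusion < 0:
            raise PhantomSpecError("perfusion must be >= 0")


# Defaults from standard bioheat literature; healthy-liver perfusion sits in
# the commonly used 0.6-6 kg/(m^3 s) window, tumors modelled as
# hypo-perfused relative to parenchyma. All overridable per phantom spec.
HEALTHY_LIVER = TissueProperties(1060.0, 3600.0, 0.512, 2.0)
TUMOR_TISSUE = TissueProperties(1045.0, 3760.0, 0.552, 1.0)
VESSEL_BLOOD = TissueProperties(1060.0, 3617.0, 0.52, 0.0)


@dataclass(frozen=True, eq=False)
class PropertyFields:
    """Per-voxel realization of the tissue properties on a grid."""

    grid: Grid
    density: np.ndarray
    heat_capacity: np.ndarray
    conductivity: np.ndarray
    perfusion: np.ndarray
    blood_heat_capacity: float = 3600.0
    blood_temperature: float = 37.0

    def __post_init__(self) -> None:
        for name in ("density", "heat_capacity", "conductivity", "perfusion"):
            arr = np.ascontiguousarray(np.asarray(getattr(self, name), dtype=np.float64))
            if arr.shape != self.grid.shape:
                raise PhantomSpecError(f"property field {name} shape does not match grid")
            object.__setattr__(self, name, arr)


@dataclass(frozen=True, eq=False)
class Phantom:
    """Synthetic patient model: grid + masks + per-voxel tissue properties.

    Invariants (enforced by :func:`build_phantom`): tumor is a subset of the
    liver ROI, and vessels never overlap tumor (vessel precedence).
    """

    grid: Grid
    liver_roi: Mask
    tumor: Mask
    vessels: Mask
    properties: PropertyFields

    def with_properties(self, properties: PropertyFields) -> "Phantom":
        return replace(self, properties=properties)


def _distance_to_point(grid: Grid, center: Sequence[float]) -> np.ndarray:
    X, Y, Z = grid.coords()
    cx, cy, cz = (float(c) for c in center)
    return np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)


def make_tumor_mask(grid: Grid, center: Sequence[float], radius: float) -> Mask:
    """Spherical tumor mask: voxel included iff its center lies within ``radius``.

    Stands in for semi-automatic region growing on clinical images.
    """
    if radius < 0:
        raise PhantomSpecError("tumor radius must be >= 0")
    if not grid.contains(center):
        raise PhantomSpecError(f"tumor center {tuple(center)} lies outside the grid bounds")
    return Mask(grid, _distance_to_point(grid, center) <= radius)


def make_vessel_mask(grid: Grid, p0: Sequence[float], p1: Sequence[float], radius: float) -> Mask:
    """Capped-cylinder vessel mask around the segment p0-p1 (world mm).

    Voxel included iff its center lies within ``radius`` of the segment.
    Large vessels are the dominant local heat sinks during ablation.
    """
    a = np.asarray(p0, dtype=float)
    b = np.asarray(p1, dtype=float)
    if np.allclose(a, b):
        raise PhantomSpecError("vessel endpoints must be distinct")
    if radius <= 0:
        raise PhantomSpecError("vessel radius must be > 0")
    X, Y, Z = grid.coords()
    d = b - a
    dd = float(d @ d)
    # parameter of the closest point on the segment, clamped to [0, 1]
    t = ((X - a[0]) * d[0] + (Y - a[1]) * d[1] + (Z - a[2]) * d[2]) / dd
    t = np.clip(t, 0.0, 1.0)
    dist2 = (X - (a[0] + t * d[0])) ** 2 + (Y - (a[1] + t * d[1])) ** 2 + (Z - (a[2] + t * d[2])) ** 2
    return Mask(grid, dist2 <= radius**2)


def crop_domain(phantom: Phantom, center: Sequence[float] | None = None, radius: float = 60.0) -> Phantom:
    """Restrict the liver ROI to a sphere around the tumor (default 6 cm).

    Tissue beyond this border has negligible influence on the heat
    distribution at liver-RFA scales; simulation and metrics operate only
    inside the restricted ROI.
    """
    if radius <= 0:
        raise PhantomSpecError("crop radius must be > 0")
    if center is None:
        if phantom.tumor.count == 0:
            raise PhantomSpecError("cannot crop around an empty tumor mask without an explicit center")
        center = phantom.tumor.centroid()
    sphere = _distance_to_point(phantom.grid, center) <= radius
    roi = Mask(phantom.grid, phantom.liver_roi.values & sphere)
    tumor = Mask(phantom.grid, phantom.tumor.values & roi.values)
    vessels = Mask(phantom.grid, phantom.vessels.values & roi.values)
    return replace(phantom, liver_roi=roi, tumor=tumor, vessels=vessels)


def make_landmark_pairs(
    points: np.ndarray,
    transform: RigidTransform,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired landmarks (p, T(p) + eps) for exercising the rigid registration.

    eps is i.i.d. Gaussian with standard deviation ``noise_sd`` mm;
    reproducible for a fixed seed. At least 3 points are required for the
    downstream rigid fit to be determined.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3:
        raise PhantomSpecError("at least 3 landmark points are required for a rigid fit")
    rng = np.random.default_rng(seed)
    moved = apply_transform(transform, pts)
    if noise_sd > 0:
        moved = moved + rng.normal(0.0, noise_sd, size=moved.shape)
    return pts, moved


def build_phantom(
    grid: Grid,
    tumor: Mask,
    vessels: Mask | None = None,
    liver_roi: Mask | None = None,
    healthy: TissueProperties = HEALTHY_LIVER,
    tumor_props: TissueProperties = TUMOR_TISSUE,
    vessel_props: TissueProperties = VESSEL_BLOOD,
    crop_radius: float | None = 60.0,
) -> Phantom:
    """Assemble a phantom, enforcing mask precedence and the domain restriction.

    Precedence vessel > tumor > healthy: overlap of vessel and tumor shapes is
    resolved in favor of the vessel, and the tumor is clipped to the liver
    ROI. Per-voxel property fields are filled classwise from the three
    :class:`TissueProperties`. With ``crop_radius`` set (default 60 mm) the
    ROI is restricted to a sphere around the tumor centroid.
    """
    if vessels is None:
        vessels = Mask(grid, np.zeros(grid.shape, dtype=bool))
    if liver_roi is None:
        liver_roi = Mask(grid, np.ones(grid.shape, dtype=bool))
    tumor = Mask(grid, tumor.values & liver_roi.values & ~vessels.values)

    fields = {}
    for name in ("density", "heat_capacity", "conductivity", "perfusion"):
        f = np.full(grid.shape, getattr(healthy, name), dtype=np.float64)
        f[tumor.values] = getattr(tumor_props, name)
        f[vessels.values] = getattr(vessel_props, name)
        fields[name] = f
    props = PropertyFields(
        grid,
        blood_heat_capacity=healthy.blood_heat_capacity,
        blood_temperature=healthy.blood_temperature,
        **fields,
    )
    phantom = Phantom(grid, liver_roi, tumor, vessels, props)
    if crop_radius is not None and tumor.count > 0:
        phantom = crop_domain(phantom, radius=crop_radius)
    return phantom


def make_default_phantom(
    shape: tuple[int, int, int] = (48, 48, 48),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    tumor_radius: float = 8.0,
    vessel_radius: float = 3.0,
    vessel_offset: float = 14.0,
    crop_radius: float = 60.0,
) -> Phantom:
    """Reference phantom: central spherical tumor plus one straight vessel.

    The vessel runs along +y at ``vessel_offset`` mm lateral (+x) of the
    tumor center, producing the asymmetric heat-sink geometry typical of
    perivascular liver tumors.
    """
    grid = Grid(shape, spacing)
    lo, hi = grid.bounds()
    center = (lo + hi) / 2.0
    tumor = make_tumor_mask(grid, center, tumor_radius)
    p0 = center + np.array([vessel_offset, lo[1] - center[1], 0.0])
    p1 = center + np.array([vessel_offset, hi[1] - center[1], 0.0])
    vessels = make_vessel_mask(grid, p0, p1, vessel_radius)
    return build_phantom(grid, tumor, vessels, crop_radius=crop_radius)
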