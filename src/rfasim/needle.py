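"""RFA probe geometry: simple and umbrella-shaped needles.

A simple (straight) probe is fully described by its tip and a trocar point
on the shaft. Umbrella probes (RITA-style) additionally deploy curved
prongs from the tip; prong positions for intermediate extensions are
reconstructed by linear interpolation (or extrapolation) from a reference
deployment, optionally rotated about the trocar-tip axis. Uncertainty in
probe placement is modelled by displacing the defining points uniformly
within a ball of radius r.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import NeedleError

__all__ = [
    "NeedleGeometry",
    "SourcePoints",
    "DEFAULT_PRONG_COUNT",
    "make_simple_needle",
    "make_umbrella_needle",
    "default_umbrella_prongs",
    "perturb_needle",
    "source_points",
]

# RITA-style umbrella deployments; configurable per needle.
DEFAULT_PRONG_COUNT = 9


@dataclass(frozen=True, eq=False)
class NeedleGeometry:
    """Probe geometry in world mm.

    ``reference_prongs`` define the fully deployed umbrella (empty for simple
    probes); actual ``prongs`` at any extension are derived as

        prong_i = tip + extension_fraction * R_axis(rotation_deg) @ (reference_prong_i - tip)

    where R_axis rotates about the shaft (trocar-tip) axis through the tip.
    """

    tip: np.ndarray
    shaft_point: np.ndarray
    reference_prongs: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    rotation_deg: float = 0.0
    extension_fraction: float = 1.0

    def __post_init__(self) -> None:
        tip = np.asarray(self.tip, dtype=float).reshape(3)
        shaft = np.asarray(self.shaft_point, dtype=float).reshape(3)
        prongs = np.asarray(self.reference_prongs, dtype=float).reshape(-1, 3)
        if np.allclose(tip, shaft):
            raise NeedleError("needle tip and trocar (shaft) point must be distinct")
        if self.extension_fraction < 0:
            raise NeedleError("extension_fraction must be >= 0")
        object.__setattr__(self, "tip", tip)
        object.__setattr__(self, "shaft_point", shaft)
        object.__setattr__(self, "reference_prongs", prongs)

    @property
    def is_umbrella(self) -> bool:
        return self.reference_prongs.shape[0] > 0

    @property
    def direction(self) -> np.ndarray:
        """Unit insertion direction, from trocar point toward the tip."""
        d = self.tip - self.shaft_point
        return d / np.linalg.norm(d)

    @property
    def prongs(self) -> np.ndarray:
        """Deployed prong tip positions at the current rotation and extension."""
        if not self.is_umbrella:
            return np.zeros((0, 3))
        R = Rotation.from_rotvec(np.deg2rad(self.rotation_deg) * self.direction).as_matrix()
        rel = (self.reference_prongs - self.tip) @ R.T
        return self.tip + self.extension_fraction * rel

    def with_extension(self, extension_fraction: float) -> "NeedleGeometry":
        return replace(self, extension_fraction=float(extension_fraction))


@dataclass(frozen=True, eq=False)
class SourcePoints:
    """Discretized heat source: positions (mm) with power-fraction weights."""

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        w = np.asarray(self.weights, dtype=float).reshape(-1)
        if pts.shape[0] != w.shape[0]:
            raise NeedleError("source point and weight counts differ")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise NeedleError("source weights must be >= 0 and sum to 1")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", w)


def make_simple_needle(tip: Sequence[float], shaft_point: Sequence[float]) -> NeedleGeometry:
    """Straight probe from its tip and a trocar point along the shaft."""
    return NeedleGeometry(np.asarray(tip, float), np.asarray(shaft_point, float))


def make_umbrella_needle(
    tip: Sequence[float],
    shaft_point: Sequence[float],
    reference_prongs: np.ndarray,
    rotation_deg: float = 0.0,
    extension_fraction: float = 1.0,
) -> NeedleGeometry:
    """Umbrella probe with prongs interpolated/extrapolated from a reference.

    ``reference_prongs`` is the (n, 3) array of fully deployed prong tips; an
    empty list is rejected since the umbrella shape would be undefined.
    """
    prongs = np.asarray(reference_prongs, dtype=float).reshape(-1, 3)
    if prongs.shape[0] == 0:
        raise NeedleError("umbrella needle requires a non-empty reference prong list")
    return NeedleGeometry(
        np.asarray(tip, float),
        np.asarray(shaft_point, float),
        prongs,
        rotation_deg=float(rotation_deg),
        extension_fraction=float(extension_fraction),
    )


def default_umbrella_prongs(
    tip: Sequence[float],
    shaft_point: Sequence[float],
    n_prongs: int = DEFAULT_PRONG_COUNT,
    deploy_length: float = 20.0,
    spread_deg: float = 70.0,
) -> np.ndarray:
    """Idealized symmetric umbrella: prongs fanned around the shaft axis.

    Prongs leave the tip at ``spread_deg`` from the insertion direction,
    evenly distributed in azimuth, each of length ``deploy_length`` mm.
    """
    tip = np.asarray(tip, dtype=float)
    axis = tip - np.asarray(shaft_point, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # orthonormal frame around the axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    theta = np.deg2rad(spread_deg)
    phis = 2 * np.pi * np.arange(n_prongs) / n_prongs
    dirs = (
        np.cos(theta) * axis
        + np.sin(theta) * (np.cos(phis)[:, None] * u + np.sin(phis)[:, None] * v)
    )
    return tip + deploy_length * dirs


def _uniform_ball(rng: np.random.Generator, n: int, r: float) -> np.ndarray:
    """Seeded uniform samples in the closed ball of radius r (rejection from cube)."""
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        cand = rng.uniform(-r, r, size=(2 * (n - filled) + 8, 3))
        keep = cand[np.sum(cand**2, axis=1) <= r**2]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def perturb_needle(
    geometry: NeedleGeometry,
    r: float,
    which_points: str | Sequence[str] = "all",
    n: int = 1,
    seed: int = 0,
) -> list[NeedleGeometry]:
    """n probe variants with selected points moved uniformly within a ball of radius r.

    ``which_points`` selects any subset of {"tip", "shaft", "prongs"} (or
    "all"). Each selected point is displaced independently by a vector drawn
    uniformly from the closed ball of radius ``r`` centered at the original
    point; unselected points are unchanged. Reproducible for a fixed seed.
    """
    if r < 0:
        raise NeedleError("perturbation radius r must be >= 0")
    if n < 1:
        raise NeedleError("number of perturbed geometries must be >= 1")
    if isinstance(which_points, str):
        which = {"tip", "shaft", "prongs"} if which_points == "all" else {which_points}
    else:
        which = set(which_points)
    unknown = which - {"tip", "shaft", "prongs"}
    if unknown:
        raise NeedleError(f"unknown point selector(s): {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    out: list[NeedleGeometry] = []
    n_prongs = geometry.reference_prongs.shape[0]
    for _ in range(n):
        tip = geometry.tip.copy()
        shaft = geometry.shaft_point.copy()
        # perturbation acts on the deployed prongs, then is folded back into
        # the reference so later re-extension stays consistent
        deployed = geometry.prongs.copy()
        if r > 0:
            if "tip" in which:
                tip = tip + _uniform_ball(rng, 1, r)[0]
            if "shaft" in which:
                shaft = shaft + _uniform_ball(rng, 1, r)[0]
            if "prongs" in which and n_prongs:
                deployed = deployed + _uniform_ball(rng, n_prongs, r)
        if n_prongs:
            g = NeedleGeometry(tip, shaft, deployed, rotation_deg=0.0, extension_fraction=1.0)
            # keep the nominal extension bookkeeping of the input geometry
            if geometry.extension_fraction > 0:
                ref = tip + (deployed - tip) / geometry.extension_fraction
                g = NeedleGeometry(
                    tip, shaft, ref, rotation_deg=0.0,
                    extension_fraction=geometry.extension_fraction,
                )
        else:
            g = NeedleGeometry(tip, shaft)
        out.append(g)
    return out


def source_points(geometry: NeedleGeometry) -> SourcePoints:
    """Heat-source discretization of a probe.

    Simple probe: all power at the tip. Umbrella probe: tip plus deployed
    prong tips with equal weights summing to 1 — a symmetric default, since
    vendor per-prong power splits are not public.
    """
    if not geometry.is_umbrella:
        return SourcePoints(geometry.tip[None, :], np.array([1.0]))
    pts = np.vstack([geometry.tip[None, :], geometry.prongs])
    w = np.full(pts.shape[0], 1.0 / pts.shape[0])
    return SourcePoints(pts, w)
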