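"""Triangulated surfaces: iso-surface extraction from voxel fields, STL I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from skimage import measure

from .phantom import Grid, Mask

__all__ = ["Surface", "iso_surface", "mask_surface", "save_stl", "load_stl"]


@dataclass(frozen=True, eq=False)
class Surface:
    """Triangle mesh with vertices in world mm."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        f = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def is_empty(self) -> bool:
        return self.vertices.shape[0] == 0

    def translated(self, offset) -> "Surface":
        return Surface(self.vertices + np.asarray(offset, float), self.faces)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


def iso_surface(field: np.ndarray, level: float, grid: Grid) -> Surface:
    """Marching-cubes iso-surface of a scalar voxel field at ``level``.

    Vertices are returned in world mm (grid spacing and origin applied).
    A field that never crosses the level yields an empty surface.
    """
    field = np.asarray(field, dtype=float)
    if field.min() >= level or field.max() < level:
        return Surface(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
    verts, faces, _, _ = measure.marching_cubes(field, level=level, spacing=grid.spacing)
    return Surface(verts + np.asarray(grid.origin), faces)


def mask_surface(mask: Mask) -> Surface:
    """Boundary surface of a boolean mask (iso-level 0.5 of the indicator).

    The mask is zero-padded by one voxel so surfaces touching the grid
    boundary close properly.
    """
    ind = np.pad(mask.values.astype(float), 1)
    if ind.max() < 0.5:
        return Surface(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
    verts, faces, _, _ = measure.marching_cubes(ind, level=0.5, spacing=mask.grid.spacing)
    offset = np.asarray(mask.grid.origin) - np.asarray(mask.grid.spacing)
    return Surface(verts + offset, faces)


def save_stl(surface: Surface, path: str | Path) -> None:
    surface.to_trimesh().export(str(path))


def load_stl(path: str | Path) -> Surface:
    mesh = trimesh.load_mesh(str(path))
    return Surface(np.asarray(mesh.vertices), np.asarray(mesh.faces))
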