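"""Format plumbing: NIfTI volumes, landmark CSV, YAML configs, manifests.

Masks are written as uint8 NIfTI, scalar fields as float32, both with a
diagonal affine carrying spacing and origin (identity orientation — the
phantoms are synthetic). Landmarks are CSV with header ``name,x,y,z`` (mm).
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .phantom import Grid, Mask

__all__ = [
    "save_mask",
    "load_mask",
    "save_field",
    "load_field",
    "save_landmarks",
    "load_landmarks",
    "load_yaml",
    "save_yaml",
    "write_manifest",
]


def _nifti(grid: Grid, data: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(data, affine=grid.affine())


def grid_from_nifti(img: nib.Nifti1Image) -> Grid:
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-6):
        raise ConfigError("only diagonal (identity-orientation) NIfTI affines are supported")
    spacing = np.diag(aff[:3, :3])
    if np.any(spacing <= 0):
        raise ConfigError("NIfTI affine must have positive diagonal spacing")
    return Grid(tuple(img.shape[:3]), tuple(spacing), tuple(aff[:3, 3]))


def save_mask(mask: Mask, path: str | Path) -> None:
    nib.save(_nifti(mask.grid, mask.values.astype(np.uint8)), str(path))


def load_mask(path: str | Path) -> Mask:
    img = nib.load(str(path))
    return Mask(grid_from_nifti(img), np.asarray(img.dataobj) > 0)


def save_field(field: np.ndarray, grid: Grid, path: str | Path) -> None:
    nib.save(_nifti(grid, np.asarray(field, dtype=np.float32)), str(path))


def load_field(path: str | Path) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), grid_from_nifti(img)


def save_landmarks(points: np.ndarray, path: str | Path, names: list[str] | None = None) -> None:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if names is None:
        names = [f"L{i:03d}" for i in range(len(pts))]
    pd.DataFrame({"name": names, "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2]}).to_csv(
        path, index=False
    )


def load_landmarks(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    missing = {"name", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ConfigError(f"landmark CSV is missing columns {sorted(missing)}")
    return df[["x", "y", "z"]].to_numpy(dtype=float), df["name"].astype(str).tolist()


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"expected a YAML mapping at the top level of {path}")
    return data


def save_yaml(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def write_manifest(path: str | Path, config: dict, seed: int | None, extra: dict | None = None) -> None:
    """Per-run provenance record: config hash, seed, package/library versions."""
    from . import __version__

    manifest = {
        "config_sha256": config_hash(config),
        "seed": seed,
        "versions": {
            "rfasim": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2))
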