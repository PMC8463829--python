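"""Voxel grids and structure sets.

Everything downstream (ray tracing, dose, DVHs) operates on a common
``VoxelGrid``: a 3-D scalar field with isotropic-or-not spacing, an origin,
and a unit tag.  The coordinate convention is fixed package-wide:

* axis 0 = x = patient-left (mm)
* axis 1 = y = patient-posterior (mm)
* axis 2 = z = patient-superior (mm)

Voxel (i, j, k) is centered at ``origin + (i, j, k) * spacing``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator

import numpy as np

#: allowed unit tags for a VoxelGrid
UNITS = ("HU", "RSP", "Gy(RBE)")


@dataclass
class VoxelGrid:
    """A 3-D scalar field on a regular grid in patient coordinates.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar per voxel; interpretation given by ``unit``.
    spacing : array-like of 3 floats
        Voxel spacing in mm per axis, strictly positive.
    origin : array-like of 3 floats
        Position (mm) of the center of voxel (0, 0, 0).
    unit : str
        One of ``"HU"``, ``"RSP"``, ``"Gy(RBE)"``.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    unit: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D, got ndim={self.values.ndim}")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be 3 strictly positive floats, got {self.spacing}")
        if self.origin.shape != (3,):
            raise ValueError("origin must have 3 components")
        if self.unit not in UNITS:
            raise ValueError(f"unit must be one of {UNITS}, got {self.unit!r}")
        if min(self.values.shape) < 1:
            raise ValueError("all grid dimensions must be >= 1")

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def index_to_position(self, idx: np.ndarray) -> np.ndarray:
        """Voxel index (possibly fractional) -> physical position (mm)."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def position_to_index(self, pos: np.ndarray) -> np.ndarray:
        """Physical position (mm) -> fractional voxel index."""
        return (np.asarray(pos, dtype=float) - self.origin) / self.spacing

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(low, high) corner positions of the voxel-center bounding box."""
        low = self.origin.copy()
        high = self.origin + (np.array(self.shape) - 1) * self.spacing
        return low, high

    def contains(self, pos: np.ndarray) -> bool:
        low, high = self.bounds()
        pos = np.asarray(pos, dtype=float)
        return bool(np.all(pos >= low - 0.5 * self.spacing) and np.all(pos <= high + 0.5 * self.spacing))

    def voxel_positions(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Positions (n, 3) of all voxel centers, optionally restricted to a mask."""
        if mask is None:
            idx = np.indices(self.shape).reshape(3, -1).T
        else:
            idx = np.argwhere(mask)
        return self.index_to_position(idx)

    def like(self, values: np.ndarray, unit: str | None = None) -> "VoxelGrid":
        """A new grid with the same geometry and different values."""
        return VoxelGrid(values, self.spacing.copy(), self.origin.copy(), unit or self.unit)

    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    # -- I/O: binary array + JSON sidecar ---------------------------------

    def save(self, path: str | Path) -> None:
        """Write ``<path>.npy`` (values) and ``<path>.json`` (geometry sidecar)."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.values)
        meta = {
            "spacing_mm": self.spacing.tolist(),
            "origin_mm": self.origin.tolist(),
            "unit": self.unit,
            "shape": list(self.shape),
            "axes": "x=patient-left, y=patient-posterior, z=patient-superior",
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "VoxelGrid":
        path = Path(path)
        values = np.load(path.with_suffix(".npy"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(values, meta["spacing_mm"], meta["origin_mm"], meta["unit"])


@dataclass
class StructureSet:
    """Named binary masks congruent with one :class:`VoxelGrid`."""

    grid: VoxelGrid
    masks: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, m in self.masks.items():
            self._check(name, m)

    def _check(self, name: str, mask: np.ndarray) -> None:
        if mask.shape != self.grid.shape:
            raise ValueError(
                f"mask {name!r} shape {mask.shape} does not match grid {self.grid.shape}"
            )
        if mask.dtype != bool:
            raise ValueError(f"mask {name!r} must be boolean")

    def add(self, name: str, mask: np.ndarray) -> None:
        mask = np.asarray(mask)
        self._check(name, mask)
        self.masks[name] = mask

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.masks:
            raise KeyError(
                f"unknown structure {name!r}; available: {sorted(self.masks)}"
            )
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    def names(self) -> list[str]:
        return sorted(self.masks)

    def volume_ml(self, name: str) -> float:
        """Structure volume in mL (= cm^3): voxel count x voxel volume."""
        return float(self[name].sum()) * self.grid.voxel_volume_ml

    # -- I/O ---------------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.grid.save(directory / "grid")
        for name, mask in self.masks.items():
            np.save(directory / f"mask_{name}.npy", mask)

    @classmethod
    def load(cls, directory: str | Path) -> "StructureSet":
        directory = Path(directory)
        grid = VoxelGrid.load(directory / "grid")
        masks = {}
        for f in sorted(directory.glob("mask_*.npy")):
            masks[f.stem[len("mask_"):]] = np.load(f).astype(bool)
        return cls(grid, masks)


def mask_run_length_text(mask: np.ndarray) -> str:
    """Per-slice run-length encoding of a mask as plain text (for diffing).

    One line per axial (z) slice with any voxels set:
    ``z i j0:j1 j2:j3 ...`` listing half-open j-runs per i row.
    """
    lines = []
    for k in range(mask.shape[2]):
        sl = mask[:, :, k]
        if not sl.any():
            continue
        for i in np.nonzero(sl.any(axis=1))[0]:
            row = sl[i]
            d = np.diff(np.concatenate(([0], row.view(np.int8), [0])))
            starts = np.nonzero(d == 1)[0]
            stops = np.nonzero(d == -1)[0]
            runs = " ".join(f"{a}:{b}" for a, b in zip(starts, stops))
            lines.append(f"{k} {i} {runs}")
    return "\n".join(lines) + "\n"
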