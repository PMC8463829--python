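"""Synthetic abdominal phantom generation and HU -> RSP calibration.

The phantom emulates the geometry of a pancreatic stereotactic proton plan:
a water-equivalent elliptical body on an air background, an ellipsoidal
gross tumor volume (GTV) seated deep enough that the beam path from the
posterior skin surface to the distal GTV edge is 16-19 cm, and a serial
organ at risk — a curved duodenum-surrogate tube — abutting the GTV
anteriorly.  Optional stomach / bowel / kidney blobs add bystander
structures.  All randomness (blob jitter only) flows from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .grid import VoxelGrid, StructureSet

# Default piecewise-linear HU -> relative stopping power calibration.
# Four nodes: air, lung-ish, water, bone-ish.  The water fixed point
# (0 HU -> RSP 1.0) anchors every sane proton calibration.
DEFAULT_CALIBRATION = np.array(
    [
        [-1000.0, 0.001],
        [-700.0, 0.26],
        [0.0, 1.0],
        [1500.0, 1.85],
    ]
)


@dataclass
class PhantomConfig:
    """Geometry and tissue parameters of the synthetic phantom.

    Distances in mm, HU in Hounsfield units.  Defaults give a ~11 mL GTV
    whose distal surface lies 164 mm beneath the posterior skin surface.
    """

    shape: tuple = (256, 256, 80)
    spacing: tuple = (2.0, 2.0, 2.0)
    # body: elliptical cylinder along z, centered at the origin
    body_semiaxes: tuple = (150.0, 110.0)
    # GTV ellipsoid
    gtv_center: tuple = (0.0, -40.0, 0.0)
    gtv_semiaxes: tuple = (16.0, 14.0, 12.0)
    # duodenum surrogate: bowed vertical tube anterior to the GTV
    duodenum_radius: float = 8.0
    duodenum_gap: float = 0.0       # surface-to-surface gap to GTV; 0 = abutting
    duodenum_half_length: float = 30.0
    duodenum_bow: float = 10.0      # lateral bow of the tube centerline
    include_extra_oars: bool = False
    # tissue HU assignments (the body is water)
    hu_air: float = -1000.0
    hu_body: float = 0.0
    hu_gtv: float = 0.0
    hu_duodenum: float = 30.0
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        for k in ("shape", "spacing", "body_semiaxes", "gtv_center", "gtv_semiaxes"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _centered_origin(shape, spacing) -> np.ndarray:
    return -(np.array(shape) - 1) / 2.0 * np.array(spacing, dtype=float)


def _ellipsoid_mask(grid: VoxelGrid, center, semiaxes) -> np.ndarray:
    """Voxel centers inside the ellipsoid (center-sampling convention)."""
    idx = np.indices(grid.shape, dtype=float)
    pos = [grid.origin[a] + idx[a] * grid.spacing[a] for a in range(3)]
    r2 = sum(((pos[a] - center[a]) / semiaxes[a]) ** 2 for a in range(3))
    return r2 <= 1.0


def _duodenum_centerline(cfg: PhantomConfig, n: int = 400) -> np.ndarray:
    """Bowed vertical tube centerline; apex abuts the GTV anterior surface."""
    t = np.linspace(-1.0, 1.0, n)
    z = cfg.gtv_center[2] + cfg.duodenum_half_length * t
    # apex (t=0) sits at the GTV x-center; ends bow toward patient-right
    x = cfg.gtv_center[0] - cfg.duodenum_bow * t * t
    y0 = cfg.gtv_center[1] - cfg.gtv_semiaxes[1] - cfg.duodenum_radius - cfg.duodenum_gap
    y = np.full_like(t, y0)
    return np.column_stack([x, y, z])


def _tube_mask(grid: VoxelGrid, centerline: np.ndarray, radius: float) -> np.ndarray:
    lo = centerline.min(axis=0) - radius - np.max(grid.spacing)
    hi = centerline.max(axis=0) + radius + np.max(grid.spacing)
    ilo = np.maximum(np.floor(grid.position_to_index(lo)).astype(int), 0)
    ihi = np.minimum(np.ceil(grid.position_to_index(hi)).astype(int) + 1, grid.shape)
    sub = np.indices(tuple(ihi - ilo), dtype=float)
    pos = np.stack(
        [grid.origin[a] + (sub[a] + ilo[a]) * grid.spacing[a] for a in range(3)], axis=-1
    ).reshape(-1, 3)
    d, _ = cKDTree(centerline).query(pos, workers=-1)
    mask = np.zeros(grid.shape, dtype=bool)
    mask[ilo[0]:ihi[0], ilo[1]:ihi[1], ilo[2]:ihi[2]] = (
        d.reshape(tuple(ihi - ilo)) <= radius
    )
    return mask


def make_phantom(config: Optional[PhantomConfig] = None) -> tuple[VoxelGrid, StructureSet]:
    """Build the HU grid and structure set for a phantom configuration.

    Returns
    -------
    (VoxelGrid[HU], StructureSet)
        Water body on an air background, with masks ``body``, ``gtv``,
        ``duodenum`` and (if configured) ``stomach``, ``bowel``,
        ``kidney_l``, ``kidney_r``.  GTV/OAR disjointness is enforced by
        carving precedence: the GTV always wins.

    Raises
    ------
    ValueError
        If the GTV extends outside the body (the message names the axis)
        or voxelizes to zero volume.
    """
    cfg = config or PhantomConfig()
    if cfg.duodenum_gap < 0:
        raise ValueError("duodenum gap must be >= 0")
    origin = _centered_origin(cfg.shape, cfg.spacing)
    grid = VoxelGrid(
        np.full(cfg.shape, cfg.hu_air, dtype=np.float32), cfg.spacing, origin, "HU"
    )

    # body: elliptical cylinder along z
    idx = np.indices(cfg.shape[:2], dtype=float)
    x = origin[0] + idx[0] * cfg.spacing[0]
    y = origin[1] + idx[1] * cfg.spacing[1]
    body2d = (x / cfg.body_semiaxes[0]) ** 2 + (y / cfg.body_semiaxes[1]) ** 2 <= 1.0
    body = np.repeat(body2d[:, :, None], cfg.shape[2], axis=2)
    grid.values[body] = cfg.hu_body

    # GTV containment check, per axis
    zhalf = (cfg.shape[2] - 1) / 2.0 * cfg.spacing[2]
    for a, name in enumerate("xyz"):
        lo = cfg.gtv_center[a] - cfg.gtv_semiaxes[a]
        hi = cfg.gtv_center[a] + cfg.gtv_semiaxes[a]
        if a < 2:
            lim = cfg.body_semiaxes[a]
        else:
            lim = zhalf
        if lo < -lim or hi > lim:
            raise ValueError(f"GTV extends outside the body along axis {name}")

    gtv = _ellipsoid_mask(grid, cfg.gtv_center, cfg.gtv_semiaxes)
    if not gtv.any():
        raise ValueError("GTV voxelizes to zero volume on this grid")
    grid.values[gtv] = cfg.hu_gtv

    duo = _tube_mask(grid, _duodenum_centerline(cfg), cfg.duodenum_radius)
    duo &= body
    duo &= ~gtv  # carving precedence: GTV wins
    grid.values[duo] = cfg.hu_duodenum

    structures = StructureSet(grid, {"body": body, "gtv": gtv, "duodenum": duo})

    if cfg.include_extra_oars:
        rng = np.random.default_rng(cfg.seed)
        blobs = {
            "stomach": ((-55.0, -55.0, 20.0), (30.0, 22.0, 25.0)),
            "bowel": ((45.0, -55.0, -20.0), (35.0, 25.0, 30.0)),
            "kidney_l": ((95.0, 45.0, 0.0), (22.0, 14.0, 32.0)),
            "kidney_r": ((-95.0, 45.0, 0.0), (22.0, 14.0, 32.0)),
        }
        taken = gtv | duo
        for name, (center, semi) in blobs.items():
            jitter = rng.uniform(-5.0, 5.0, size=3)
            m = _ellipsoid_mask(grid, np.array(center) + jitter, semi)
            m &= body & ~taken
            grid.values[m] = cfg.hu_duodenum  # soft tissue, near water
            structures.add(name, m)
            taken |= m

    return grid, structures


def hu_to_rsp(grid: VoxelGrid, calibration: np.ndarray | None = None) -> VoxelGrid:
    """Convert an HU grid to relative stopping power by piecewise-linear
    interpolation on a calibration curve, clamped at the curve ends.

    Parameters
    ----------
    grid : VoxelGrid with unit "HU"
    calibration : (n, 2) array of (HU, RSP) nodes, strictly increasing in HU.
        Defaults to :data:`DEFAULT_CALIBRATION`.
    """
    if grid.unit != "HU":
        raise ValueError(f"expected an HU grid, got unit {grid.unit!r}")
    cal = DEFAULT_CALIBRATION if calibration is None else np.asarray(calibration, dtype=float)
    if cal.ndim != 2 or cal.shape[0] < 2 or cal.shape[1] != 2:
        raise ValueError("calibration needs at least 2 (HU, RSP) nodes")
    if np.any(np.diff(cal[:, 0]) <= 0):
        raise ValueError("calibration nodes must be strictly increasing in HU")
    rsp = np.interp(grid.values, cal[:, 0], cal[:, 1]).astype(np.float32)
    rsp = np.maximum(rsp, 0.0)
    return grid.like(rsp, unit="RSP")
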