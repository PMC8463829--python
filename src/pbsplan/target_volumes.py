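"""Optimization target volume (OTV) construction.

Two margin schemes around the GTV:

* **uniform** — an isotropic geometric expansion (e.g. 2 mm or 5 mm),
  covering setup uncertainty only.
* **beam_specific** — per beam, each lateral ray's GTV interval is
  extended distally by ``fraction x distal WET`` and proximally by
  ``fraction x proximal WET`` (water-equivalent margins converted to
  geometric length through the local stopping power), covering range
  uncertainty along the beam, plus a lateral-only expansion in the
  beam's-eye-view plane for setup uncertainty.

Voxel membership uses the center-sampling convention: a voxel belongs to
a margin if its center lies within the margin distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, distance_transform_edt, map_coordinates

from .beams import Beam, BeamWETMap
from .grid import StructureSet, VoxelGrid


@dataclass
class OTVSpec:
    """Margin parameters for OTV construction."""

    scheme: str = "uniform"  # "uniform" | "beam_specific"
    uniform_margin_mm: float = 2.0
    lateral_margin_mm: float = 2.0
    range_fraction: float = 0.035
    # geometric margin along the beam axis for the setup-error component,
    # added on top of the WET-based range margin (the union-of-scenarios
    # reading of a beam-specific target volume); 0 = range margin only
    axial_setup_margin_mm: float = 0.0
    exclude_oars: list = field(default_factory=list)
    worst_case: bool = False  # beam-specific: single worst-case margin per beam

    def __post_init__(self) -> None:
        if self.scheme not in ("uniform", "beam_specific"):
            raise ValueError(f"unknown OTV scheme {self.scheme!r}")
        if self.uniform_margin_mm < 0 or self.lateral_margin_mm < 0:
            raise ValueError("margins must be >= 0")
        if not (0.0 <= self.range_fraction <= 0.2):
            raise ValueError("range-uncertainty fraction must be in [0, 0.2]")


def expand_uniform(gtv: np.ndarray, margin_mm: float, spacing) -> np.ndarray:
    """All voxels whose center is within ``margin_mm`` (Euclidean) of the GTV.

    Distance is measured to the voxelized GTV solid (the union of voxel
    cubes), not to voxel centers: the structure is supersampled to
    ~0.5 mm inside a cropped bounding box before the distance transform,
    which removes the half-voxel inward bias of a center-to-center
    transform.
    """
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    if margin_mm == 0:
        return gtv.copy()
    spacing = np.asarray(spacing, dtype=float)
    if not gtv.any():
        return gtv.copy()
    idx = np.argwhere(gtv)
    pad = np.ceil(margin_mm / spacing).astype(int) + 2
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, gtv.shape)
    sub = gtv[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    # supersample each voxel into f^3 subvoxels (exact cube representation)
    f = np.maximum(np.round(spacing / 0.5).astype(int), 1)
    fine = sub
    for a in range(3):
        fine = np.repeat(fine, f[a], axis=a)
    dist = distance_transform_edt(~fine, sampling=spacing / f)
    fine_margin = dist <= margin_mm
    # read back the subvoxel containing each coarse voxel center
    c = (f - 1) // 2
    coarse = fine_margin[c[0]::f[0], c[1]::f[1], c[2]::f[2]]
    out = np.zeros_like(gtv)
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = coarse
    return out | gtv


def expand_beam_specific(
    gtv: np.ndarray,
    beam: Beam,
    rsp: VoxelGrid,
    spec: OTVSpec,
    wetmap: BeamWETMap | None = None,
) -> np.ndarray:
    """Beam-specific WET-margin OTV for one beam.

    Works on a beam-aligned grid: extends each GTV ray interval by the
    water-equivalent margins (converted to geometric length by marching
    through the cumulative WET table), dilates laterally in the
    beam's-eye-view plane, and resamples back onto the patient grid.
    The result is guaranteed to be a superset of the GTV.
    """
    if spec.scheme != "beam_specific":
        raise ValueError("spec.scheme must be 'beam_specific'")
    if not gtv.any():
        raise ValueError("GTV mask is empty")
    f = spec.range_fraction
    pad = spec.lateral_margin_mm + 0.2 * 300.0 + 10.0  # generous beam-frame pad
    wm = wetmap or BeamWETMap.for_mask(rsp, beam, gtv, pad_mm=max(30.0, pad / 4))

    # GTV membership on the beam grid
    uu, vv, ww = np.meshgrid(wm.u, wm.v, wm.w, indexing="ij")
    pts = beam.to_patient_coords(np.column_stack([uu.ravel(), vv.ravel(), ww.ravel()]))
    idx = ((pts - rsp.origin) / rsp.spacing).T
    inside = map_coordinates(gtv.astype(np.float32), idx, order=0, mode="constant",
                             cval=0.0).reshape(uu.shape) > 0.5
    hit = inside.any(axis=2)
    if not hit.any():
        raise ValueError("beam misses the GTV entirely")

    rays = np.argwhere(hit)
    k0 = np.empty(len(rays), dtype=int)
    k1 = np.empty(len(rays), dtype=int)
    for n, (iu, iv) in enumerate(rays):
        kk = np.nonzero(inside[iu, iv])[0]
        k0[n], k1[n] = kk[0], kk[-1]

    cum = wm._wet  # cumulative WET along depth, per (u, v)
    wet_p = cum[rays[:, 0], rays[:, 1], k0]
    wet_d = cum[rays[:, 0], rays[:, 1], k1]
    if spec.worst_case:
        wet_p = np.full_like(wet_p, wet_p.min())
        wet_d = np.full_like(wet_d, wet_d.max())

    otv_beam = np.zeros_like(inside)
    nw = len(wm.w)
    ax_steps = int(np.round(spec.axial_setup_margin_mm / wm.step))
    for n, (iu, iv) in enumerate(rays):
        c = cum[iu, iv]
        # proximal: first depth with WET >= wet_prox - f*wet_prox
        k0e = int(np.searchsorted(c, wet_p[n] * (1.0 - f), side="left")) - ax_steps
        # distal: march until f*wet_dist more water-equivalent depth is crossed
        k1e = int(np.searchsorted(c, wet_d[n] * (1.0 + f), side="right")) + ax_steps
        otv_beam[iu, iv, max(k0e, 0):min(k1e + 1, nw)] = True

    # lateral (BEV-plane) dilation only: flat-in-depth disk footprint
    if spec.lateral_margin_mm > 0:
        r = spec.lateral_margin_mm
        n_cells = int(np.ceil(r / wm.lateral_step))
        off = np.arange(-n_cells, n_cells + 1) * wm.lateral_step
        disk = (off[:, None] ** 2 + off[None, :] ** 2) <= r**2 + 1e-9
        otv_beam = binary_dilation(otv_beam, structure=disk[:, :, None])

    # resample back onto the patient grid over a bounding box
    grid_like = VoxelGrid(np.zeros((1, 1, 1)), rsp.spacing, rsp.origin, rsp.unit)
    gtv_idx = np.argwhere(gtv)
    pad_vox = np.ceil((40.0 + spec.lateral_margin_mm) / rsp.spacing).astype(int)
    lo = np.maximum(gtv_idx.min(axis=0) - pad_vox, 0)
    hi = np.minimum(gtv_idx.max(axis=0) + pad_vox + 1, rsp.shape)
    sub = np.indices(tuple(hi - lo), dtype=float)
    pos = np.stack(
        [rsp.origin[a] + (sub[a] + lo[a]) * rsp.spacing[a] for a in range(3)], axis=-1
    ).reshape(-1, 3)
    uvw = beam.to_beam_coords(pos)
    cu = (uvw[:, 0] - wm.u[0]) / wm.lateral_step
    cv = (uvw[:, 1] - wm.v[0]) / wm.lateral_step
    cw = (uvw[:, 2] - wm.w[0]) / wm.step
    vals = map_coordinates(otv_beam.astype(np.float32), np.vstack([cu, cv, cw]),
                           order=0, mode="constant", cval=0.0)
    mask = np.zeros(rsp.shape, dtype=bool)
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = vals.reshape(tuple(hi - lo)) > 0.5
    return mask | gtv


def exclude_overlap(
    otv: np.ndarray,
    oars: StructureSet,
    names: list[str],
    gtv: np.ndarray | None = None,
) -> np.ndarray:
    """Remove named OAR voxels from an OTV; GTV voxels are never removed."""
    out = otv.copy()
    for name in names:
        out &= ~oars[name]
    if gtv is not None:
        out |= otv & gtv
    return out
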