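"""Plan-evaluation metrics.

* cumulative dose-volume histograms (DVH) with Dq / Vd extraction;
* the DVH *bandwidth*: the scenario spread of a DVH metric,
  ``Wd = 2 sqrt( sum_i (D_i - D_nom)^2 / (N - 1) ) / D_nom x 100%``,
  where the N scenario values are deviations from the nominal;
* the *dose spread function* (DSF): the analytic derivative of a sigmoid
  fitted to a line-dose profile sampled across the abutment between the
  100% isodose surface and a serial OAR, summarized by the full widths
  of the DSF peak at 50% (FWHM) and 20% (FW20M) of its maximum.

Two falloff-width readings exist and are both reported: the widths of
the DSF peak (FWHM / FW20M) and the dose-drop widths w(100->50) /
w(100->20) measured on the fitted profile from the plateau level to its
50% / 20% crossings.  They are distinct quantities and never conflated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, map_coordinates
from scipy.optimize import curve_fit
from scipy.special import erfc, erfcinv

from .grid import VoxelGrid

DEFAULT_BIN_GY = 0.05


@dataclass
class DVHCurve:
    """Cumulative DVH: volume fraction (%) receiving at least each dose."""

    edges: np.ndarray  # Gy(RBE), ascending, starting at 0
    cum_pct: np.ndarray  # %, non-increasing, cum_pct[0] = 100
    structure: str = ""
    volume_ml: float = 0.0

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.cum_pct = np.asarray(self.cum_pct, dtype=float)
        if self.edges.shape != self.cum_pct.shape:
            raise ValueError("edges and cum_pct must align")
        if np.any(np.diff(self.cum_pct) > 1e-9):
            raise ValueError("cumulative volume must be non-increasing in dose")


def compute_dvh(
    dose,
    mask: np.ndarray | None = None,
    bin_width_gy: float = DEFAULT_BIN_GY,
    structure: str = "",
    voxel_volume_ml: float | None = None,
) -> DVHCurve:
    """Cumulative DVH of a structure.

    ``dose`` may be a :class:`VoxelGrid` (with ``mask`` selecting the
    structure) or a 1-D array of per-voxel doses already restricted to
    the structure (then ``voxel_volume_ml`` supplies the voxel volume).
    """
    if isinstance(dose, VoxelGrid):
        if mask is None or not mask.any():
            raise ValueError("structure mask is empty")
        values = np.asarray(dose.values[mask], dtype=float)
        vox_ml = dose.voxel_volume_ml
    else:
        values = np.asarray(dose, dtype=float).ravel()
        if values.size == 0:
            raise ValueError("structure dose array is empty")
        vox_ml = voxel_volume_ml or 0.0
    top = float(values.max()) if values.size else 0.0
    edges = np.arange(0.0, top + 2 * bin_width_gy, bin_width_gy)
    # fraction of voxels with dose >= edge
    order = np.sort(values)
    n = order.size
    counts = n - np.searchsorted(order, edges, side="left")
    cum_pct = 100.0 * counts / n
    cum_pct[0] = 100.0
    return DVHCurve(edges, cum_pct, structure=structure, volume_ml=n * vox_ml)


def dose_at_volume(dvh: DVHCurve, q_pct: float) -> float:
    """Dq: the largest dose received by at least q% of the structure."""
    if not (0.0 < q_pct <= 100.0):
        raise ValueError("q must be in (0, 100]")
    cum, edges = dvh.cum_pct, dvh.edges
    above = np.nonzero(cum >= q_pct)[0]
    if above.size == 0:
        return float(edges[0])
    i = above[-1]
    if i == len(edges) - 1 or cum[i] == q_pct:
        return float(edges[i])
    # linear interpolation between (edges[i], cum[i]) and (edges[i+1], cum[i+1])
    c0, c1 = cum[i], cum[i + 1]
    if c0 == c1:
        return float(edges[i])
    frac = (c0 - q_pct) / (c0 - c1)
    return float(edges[i] + frac * (edges[i + 1] - edges[i]))


def volume_at_dose(dvh: DVHCurve, d_gy: float) -> tuple[float, float]:
    """Vd: (% of structure, absolute cm^3) receiving at least ``d_gy``."""
    if d_gy < 0:
        raise ValueError("dose must be >= 0")
    pct = float(np.interp(d_gy, dvh.edges, dvh.cum_pct))
    if d_gy > dvh.edges[-1]:
        pct = 0.0
    return pct, pct / 100.0 * dvh.volume_ml


@dataclass
class BandwidthResult:
    metric: str
    nominal: float
    scenario_values: np.ndarray
    wd_pct: float


def bandwidth(nominal: float, scenario_values) -> float:
    """DVH bandwidth Wd (%) of a metric across perturbation scenarios."""
    values = np.asarray(scenario_values, dtype=float)
    if values.size < 2:
        raise ValueError("bandwidth needs at least 2 scenario values")
    if nominal == 0:
        raise ValueError("bandwidth undefined for nominal = 0")
    n = values.size
    spread = np.sqrt(np.sum((values - nominal) ** 2) / (n - 1))
    return float(2.0 * spread / nominal * 100.0)


def bandwidth_result(metric: str, nominal: float, scenario_values) -> BandwidthResult:
    return BandwidthResult(metric, float(nominal), np.asarray(scenario_values, float),
                           bandwidth(nominal, scenario_values))


def sample_line_dose(
    dose: VoxelGrid, p0, p1, step_mm: float = 0.5
) -> pd.DataFrame:
    """Trilinear line-dose profile from p0 to p1; position = distance from p0."""
    if step_mm <= 0:
        raise ValueError("step must be > 0")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if not (dose.contains(p0) and dose.contains(p1)):
        raise ValueError("line endpoints must lie inside the dose grid")
    length = float(np.linalg.norm(p1 - p0))
    n = max(int(np.ceil(length / step_mm)), 1)
    t = np.linspace(0.0, 1.0, n + 1)
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    idx = ((pts - dose.origin) / dose.spacing).T
    vals = map_coordinates(dose.values.astype(float), idx, order=1, mode="nearest")
    return pd.DataFrame({"position_mm": t * length, "dose": vals})


@dataclass
class DSFResult:
    position_mm: np.ndarray
    raw_dose: np.ndarray
    fitted_dose: np.ndarray
    dsf: np.ndarray  # |d(fit)/dr|
    fwhm_mm: float
    fw20m_mm: float
    w_100_50_mm: float
    w_100_20_mm: float
    error_flag: bool = False
    fit_params: dict = field(default_factory=dict)


def _erf_profile(x, base, amp, x0, sigma):
    return base + 0.5 * amp * erfc((x - x0) / (np.sqrt(2.0) * sigma))


def dose_spread_function(
    profile: pd.DataFrame,
    fit_family: str = "erf",
    plateau_frac: float = 0.95,
    residual_tol: float = 0.05,
) -> DSFResult:
    """Fit a sigmoid to a plateau-to-falloff line dose; differentiate it.

    The default family is a Gaussian edge-spread (erfc) profile, whose
    derivative — the DSF — is an exact Gaussian, making the peak widths
    analytic: FWHM = 2 sigma sqrt(2 ln 2), FW20M = 2 sigma sqrt(2 ln 5).
    A logistic family is available as an alternative.  If the fit
    residual exceeds ``residual_tol`` of the profile amplitude the result
    is flagged and the raw numerical derivative returned for inspection.
    """
    r = np.asarray(profile["position_mm"], dtype=float)
    ld = np.asarray(profile["dose"], dtype=float)
    top = ld.max()
    plateau = ld >= plateau_frac * top
    runs = np.diff(np.concatenate(([0], plateau.view(np.int8), [0])))
    lengths = np.nonzero(runs == -1)[0] - np.nonzero(runs == 1)[0]
    if lengths.size == 0 or lengths.max() < 3:
        raise ValueError(
            "profile has no plateau (>=95% of max over >=3 consecutive samples)"
        )
    plateau_level = float(ld[plateau].mean())

    base0 = float(ld.min())
    amp0 = top - base0
    half_level = base0 + 0.5 * amp0
    below = np.nonzero(ld <= half_level)[0]
    x0_0 = r[below[0]] if below.size else r[len(r) // 2]
    sig0 = max((r[-1] - r[0]) / 20.0, 0.5)

    if fit_family == "erf":
        model = _erf_profile
    elif fit_family == "logistic":
        def model(x, base, amp, x0, s):
            return base + amp / (1.0 + np.exp((x - x0) / s))
    else:
        raise ValueError(f"unknown fit family {fit_family!r}")

    error_flag = False
    try:
        params, _ = curve_fit(
            model, r, ld, p0=[base0, amp0, x0_0, sig0],
            bounds=([-np.inf, 0.0, r[0] - 50.0, 1e-3],
                    [np.inf, np.inf, r[-1] + 50.0, np.inf]),
            maxfev=10000,
        )
    except RuntimeError:
        params = np.array([base0, amp0, x0_0, sig0])
        error_flag = True
    fitted = model(r, *params)
    rms = float(np.sqrt(np.mean((fitted - ld) ** 2)))
    if rms > residual_tol * max(amp0, 1e-12):
        error_flag = True

    base, amp, x0, sig = params
    if error_flag:
        dsf = np.abs(np.gradient(ld, r))
        fwhm = fw20m = w50 = w20 = float("nan")
    elif fit_family == "erf":
        dsf = amp / (np.sqrt(2.0 * np.pi) * sig) * np.exp(-((r - x0) ** 2) / (2 * sig**2))
        fwhm = 2.0 * sig * np.sqrt(2.0 * np.log(2.0))
        fw20m = 2.0 * sig * np.sqrt(2.0 * np.log(5.0))

        def crossing(level):
            t = 2.0 * (level - base) / amp
            if not (0.0 < t < 2.0):
                return float("nan")
            return x0 + np.sqrt(2.0) * sig * erfcinv(t)

        # the fitted asymptote can sit just below the observed plateau
        # mean; clamp the 100% level into the fit's range
        x100 = crossing(min(plateau_level, base + 0.995 * amp))
        w50 = crossing(0.5 * plateau_level) - x100
        w20 = crossing(0.2 * plateau_level) - x100
    else:  # logistic: derivative peak widths from sech^2 level sets
        e = np.exp((r - x0) / sig)
        dsf = amp * e / (sig * (1.0 + e) ** 2)
        fwhm = 2.0 * sig * 2.0 * np.arccosh(np.sqrt(2.0))
        fw20m = 2.0 * sig * 2.0 * np.arccosh(np.sqrt(5.0))

        def crossing(level):
            t = amp / (level - base) - 1.0
            if t <= 0:
                return float("nan")
            return x0 + sig * np.log(t)

        x100 = crossing(min(plateau_level, base + 0.995 * amp))
        w50 = crossing(0.5 * plateau_level) - x100
        w20 = crossing(0.2 * plateau_level) - x100

    return DSFResult(
        position_mm=r,
        raw_dose=ld,
        fitted_dose=fitted,
        dsf=np.asarray(dsf),
        fwhm_mm=float(fwhm),
        fw20m_mm=float(fw20m),
        w_100_50_mm=float(w50),
        w_100_20_mm=float(w20),
        error_flag=error_flag,
        fit_params={"base": float(base), "amp": float(amp), "x0": float(x0),
                    "sigma": float(sig), "family": fit_family, "rms": rms,
                    "plateau_level": plateau_level},
    )


def locate_abutment_line(
    dose: VoxelGrid,
    prescription_gy: float,
    oar: np.ndarray,
    plateau_len_mm: float = 12.0,
    falloff_len_mm: float = 18.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampling segment across the 100%-isodose / OAR abutment region.

    Finds the closest approach between the prescription isodose surface
    and the OAR, directs the segment from the isodose toward the OAR
    along the connecting line, and extends it one plateau length into the
    isodose and one falloff length into the OAR.
    """
    iso = dose.values >= prescription_gy
    if not iso.any():
        raise ValueError("prescription isodose is empty (underdosed plan)")
    if not oar.any():
        raise ValueError("OAR mask is empty")
    overlap = iso & oar
    spacing = dose.spacing
    if overlap.any():
        a = b = dose.index_to_position(np.argwhere(overlap).mean(axis=0))
        ci = dose.index_to_position(np.argwhere(iso).mean(axis=0))
        co = dose.index_to_position(np.argwhere(oar).mean(axis=0))
        direction = co - ci
    else:
        dist, nearest = distance_transform_edt(
            ~oar, sampling=spacing, return_indices=True
        )
        iso_idx = np.argwhere(iso)
        d_at_iso = dist[tuple(iso_idx.T)]
        k = int(np.argmin(d_at_iso))
        ai = iso_idx[k]
        bi = nearest[:, ai[0], ai[1], ai[2]]
        a = dose.index_to_position(ai)
        b = dose.index_to_position(bi)
        direction = b - a
    nrm = np.linalg.norm(direction)
    if nrm < 1e-9:
        direction = np.array([0.0, -1.0, 0.0])
        nrm = 1.0
    direction = direction / nrm
    p0 = a - direction * plateau_len_mm
    p1 = b + direction * falloff_len_mm
    # clamp endpoints into the grid
    low, high = dose.bounds()
    p0 = np.clip(p0, low, high)
    p1 = np.clip(p1, low, high)
    return p0, p1
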