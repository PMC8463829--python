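"""Scenario-set generation and plan robustness evaluation.

Documented scenario-set compositions (setup magnitude ``s`` mm, range
fraction ``f``):

* ``eval42`` — full robustness evaluation: {nominal shift, 5 cardinal
  shifts (anterior, posterior, right, left, inferior), 8 diagonal corner
  shifts} x {scale 1-f, 1, 1+f} = 14 x 3 = 42 scenarios.  A 15-shift
  variant adding the superior direction is selectable.
* ``bandwidth8`` — DVH-bandwidth families: 6 cardinal shifts (both
  directions of each axis) at nominal range, plus the unshifted
  isocenter at scales 1-f and 1+f = 8 scenarios.
* ``ro21`` — robust-optimization set: {nominal + 6 cardinal shifts} x
  {3 scales} = 21 scenarios.  A 42-scenario option mirrors ``eval42``.

Every shift vector has Euclidean norm exactly ``s`` (diagonals are
normalized to the total displacement, not per axis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beams import BeamWETMap
from .dose import BeamDoseOperator, Scenario
from .grid import StructureSet, VoxelGrid
from .metrics import DVHCurve, compute_dvh

# cardinal directions in patient coordinates (x=left, y=posterior, z=superior)
_CARDINAL = {
    "anterior": (0, -1, 0),
    "posterior": (0, 1, 0),
    "right": (-1, 0, 0),
    "left": (1, 0, 0),
    "inferior": (0, 0, -1),
    "superior": (0, 0, 1),
}
# the literal 5-direction list of the full-evaluation composition
_CARDINAL5 = ("anterior", "posterior", "right", "left", "inferior")


@dataclass
class ScenarioSet:
    scenarios: list[Scenario]
    label: str
    setup_mm: float
    range_fraction: float

    def __post_init__(self) -> None:
        keys = set()
        for s in self.scenarios:
            k = (tuple(np.round(s.shift, 9)), round(s.scale, 9))
            if k in keys:
                raise ValueError(f"duplicate scenario {k} in set {self.label!r}")
            keys.add(k)

    def __len__(self) -> int:
        return len(self.scenarios)

    def __iter__(self):
        return iter(self.scenarios)

    def has_nominal(self) -> bool:
        return any(s.is_nominal for s in self.scenarios)


def _diagonals() -> list[tuple[str, np.ndarray]]:
    out = []
    for sx in (1, -1):
        for sy in (1, -1):
            for sz in (1, -1):
                v = np.array([sx, sy, sz], dtype=float) / np.sqrt(3.0)
                out.append((f"diag({sx:+d},{sy:+d},{sz:+d})", v))
    return out


def make_scenarios(
    label: str,
    setup_mm: float = 2.0,
    range_fraction: float = 0.035,
    include_superior: bool = False,
) -> ScenarioSet:
    """Build a documented scenario set; see the module docstring."""
    if setup_mm <= 0:
        raise ValueError("setup magnitude must be > 0")
    if range_fraction <= 0:
        raise ValueError("range fraction must be > 0")
    s, f = float(setup_mm), float(range_fraction)
    scales = [1.0, 1.0 - f, 1.0 + f]

    def shift_list(cardinals, diagonals: bool) -> list[tuple[str, np.ndarray]]:
        shifts = [("nominal", np.zeros(3))]
        shifts += [(n, s * np.array(_CARDINAL[n], dtype=float)) for n in cardinals]
        if diagonals:
            shifts += [(n, s * v) for n, v in _diagonals()]
        return shifts

    scenarios: list[Scenario] = []
    if label in ("eval42", "eval45"):
        cardinals = _CARDINAL5 + (("superior",) if (include_superior or label == "eval45") else ())
        for name, vec in shift_list(cardinals, diagonals=True):
            for sc in scales:
                scenarios.append(Scenario(vec, sc, f"{name}/scale={sc:.3f}"))
    elif label == "bandwidth8":
        for name in _CARDINAL:
            scenarios.append(
                Scenario(s * np.array(_CARDINAL[name], dtype=float), 1.0, f"{name}/scale=1.000")
            )
        for sc in (1.0 - f, 1.0 + f):
            scenarios.append(Scenario(np.zeros(3), sc, f"nominal/scale={sc:.3f}"))
    elif label == "ro21":
        for name, vec in shift_list(tuple(_CARDINAL), diagonals=False):
            for sc in scales:
                scenarios.append(Scenario(vec, sc, f"{name}/scale={sc:.3f}"))
    elif label == "ro42":
        return ScenarioSet(
            make_scenarios("eval42", s, f, include_superior).scenarios, "ro42", s, f
        )
    else:
        raise ValueError(
            f"unknown scenario-set label {label!r}; "
            "expected eval42, eval45, bandwidth8, ro21 or ro42"
        )
    return ScenarioSet(scenarios, label, s, f)


class DoseRecomputer:
    """Recomputes per-structure dose for a plan under arbitrary scenarios.

    Caches the per-beam WET maps and per-structure voxel positions so
    that evaluating many scenarios costs one factorized influence
    evaluation each.
    """

    def __init__(
        self,
        plan,
        rsp: VoxelGrid,
        structures: StructureSet,
        lateral_sigma_mm: float = 5.0,
        wetmaps: list[BeamWETMap] | None = None,
    ):
        self.plan = plan
        self.rsp = rsp
        self.structures = structures
        self.sigma = lateral_sigma_mm
        if wetmaps is None:
            union = np.zeros(rsp.shape, dtype=bool)
            union |= structures["gtv"]
            for n in structures.names():
                if n not in ("body",):
                    union |= structures[n]
            wetmaps = [
                BeamWETMap.for_mask(rsp, b, union, pad_mm=40.0) for b in plan.beams
            ]
        self.wetmaps = wetmaps
        self._pos_cache: dict[str, np.ndarray] = {}

    def positions(self, structure: str) -> np.ndarray:
        if structure not in self._pos_cache:
            idx = np.argwhere(self.structures[structure])
            self._pos_cache[structure] = self.rsp.index_to_position(idx)
        return self._pos_cache[structure]

    def dose(self, structure: str, scenario: Scenario) -> np.ndarray:
        """Total dose (all beams) on the structure's voxels under a scenario."""
        pos = self.positions(structure)
        total = np.zeros(len(pos))
        for b, (spots, w, wm) in enumerate(
            zip(self.plan.spots, self.plan.weights, self.wetmaps)
        ):
            op = BeamDoseOperator(spots, wm, pos, scenario, self.sigma)
            total += op.dose(np.asarray(w))
        return total


def evaluate_passing(
    plan,
    rsp: VoxelGrid,
    structures: StructureSet,
    scenario_set: ScenarioSet,
    prescription_gy: float = 33.0,
    volume_threshold_pct: float = 95.0,
    target: str = "gtv",
    recomputer: DoseRecomputer | None = None,
) -> tuple[float, pd.DataFrame]:
    """Scenario passing rate: % of scenarios with V(prescription) >= threshold.

    A scenario passes if at least ``volume_threshold_pct`` % of the
    target volume receives the full prescription dose under it.  Returns
    the rate (%) and the per-scenario table.
    """
    if len(scenario_set) == 0:
        raise ValueError("scenario set is empty")
    rc = recomputer or DoseRecomputer(plan, rsp, structures)
    rows = []
    for sc in scenario_set:
        d = rc.dose(target, sc)
        v_rx = 100.0 * float(np.mean(d >= prescription_gy))
        rows.append(
            {
                "label": sc.label,
                "shift_x": sc.shift[0],
                "shift_y": sc.shift[1],
                "shift_z": sc.shift[2],
                "scale": sc.scale,
                "v_rx_pct": v_rx,
                "pass": v_rx >= volume_threshold_pct,
            }
        )
    table = pd.DataFrame(rows)
    rate = 100.0 * float(table["pass"].mean())
    return rate, table


def perturbed_dvh_family(
    plan,
    rsp: VoxelGrid,
    structures: StructureSet,
    scenario_set: ScenarioSet,
    structure: str,
    bin_width_gy: float = 0.05,
    recomputer: DoseRecomputer | None = None,
) -> list[DVHCurve]:
    """One DVH per scenario, nominal first (prepended if not in the set)."""
    rc = recomputer or DoseRecomputer(plan, rsp, structures)
    vox_ml = rsp.voxel_volume_ml
    curves: list[DVHCurve] = []
    ordered = list(scenario_set)
    if not scenario_set.has_nominal():
        ordered = [Scenario()] + ordered
    else:
        ordered.sort(key=lambda s: not s.is_nominal)
    for sc in ordered:
        d = rc.dose(structure, sc)
        curves.append(
            compute_dvh(d, bin_width_gy=bin_width_gy, structure=f"{structure}[{sc.label}]",
                        voxel_volume_ml=vox_ml)
        )
    return curves
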